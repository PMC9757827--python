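import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from _oracles import brute_force_loglik
from methylcall.hmm_scoring import (
    MATCH,
    NUM_STATES,
    ParallelFiller,
    TransitionParams,
    add_log,
    hmm_fill_parallel,
    hmm_fill_serial,
    lp_emit_match,
    score_cpg_group,
)
from methylcall.model_types import CpGGroup, Event, ScalingParams, make_methylated_haplotype
from methylcall.synthetic_data import random_hmm_instance

NEG_INF = float("-inf")
IDENT = ScalingParams()


def events_from_levels(levels, rng=None, sd=0.0):
    out = []
    for i, lv in enumerate(levels):
        mean = lv if rng is None else lv + rng.normal(0, sd)
        out.append(Event(start_sample=10 * i, length=10, mean=float(mean), stdv=1.0))
    return out


class TestAddLog:
    def test_halves_sum_to_one(self):
        assert add_log(math.log(0.5), math.log(0.5)) == pytest.approx(0.0, abs=1e-15)

    def test_neg_inf_is_identity(self):
        assert add_log(1.25, NEG_INF) == 1.25
        assert add_log(NEG_INF, NEG_INF) == NEG_INF

    def test_matches_linear_space_sum(self):
        assert add_log(math.log(0.3), math.log(0.2)) == pytest.approx(
            math.log(0.5), abs=1e-12
        )

    @given(st.floats(-700, 700), st.floats(-700, 700))
    def test_commutative_and_stable(self, a, b):
        assert add_log(a, b) == add_log(b, a)
        assert add_log(a, b) >= max(a, b)


class TestEmission:
    def test_density_peak(self, k3_model):
        kmer = "ACA"
        mu, sd = k3_model.lookup(kmer)
        e = Event(start_sample=0, length=5, mean=mu, stdv=0.5)
        assert lp_emit_match(e, kmer, k3_model, IDENT) == pytest.approx(
            -math.log(sd * math.sqrt(2 * math.pi)), abs=1e-12
        )

    def test_matches_independent_gaussian(self, k3_model, rng):
        scaling = ScalingParams(shift=8.0, scale=1.1, var=1.3)
        for _ in range(20):
            kmer = "".join("ACGT"[rng.integers(4)] for _ in range(3))
            mu, sd = k3_model.lookup(kmer)
            e = Event(start_sample=0, length=5, mean=float(rng.normal(100, 20)), stdv=1.0)
            expected = norm.logpdf(e.mean, scaling.scale * mu + scaling.shift,
                                   scaling.var * sd)
            assert lp_emit_match(e, kmer, k3_model, scaling) == pytest.approx(
                expected, abs=1e-10
            )

    def test_unknown_kmer_rejected(self, k3_model):
        e = Event(start_sample=0, length=5, mean=80.0, stdv=1.0)
        with pytest.raises(KeyError):
            lp_emit_match(e, "MAA", k3_model, IDENT)


class TestSerialFill:
    def test_single_event_single_block_closed_form(self, k3_model):
        # One path exists: the seeded start stays into the only k-mer's
        # MATCH (one stay transition), then terminates.
        trans = TransitionParams()
        kmer = "ACA"
        e = events_from_levels([k3_model.level_mean(kmer)])
        mat, score = hmm_fill_serial(e, kmer, k3_model, IDENT, trans)
        expected = trans.lp_stay + lp_emit_match(e[0], kmer, k3_model, IDENT) + trans.lp_end
        assert score.log_lik == pytest.approx(expected, abs=1e-12)

    def test_matrix_has_three_columns_per_kmer(self, k3_model, rng):
        ev, hap, model, scaling, trans = random_hmm_instance(rng, 5, 7)
        mat, _ = hmm_fill_serial(ev, hap, model, scaling, trans)
        n_block = len(hap) - model.k + 1
        assert mat.fm.shape == (len(ev) + 1, NUM_STATES * n_block)
        assert mat.n_block == n_block

    def test_matches_path_enumeration_oracle(self, rng):
        worst = 0.0
        for _ in range(60):
            ev, hap, model, scaling, trans = random_hmm_instance(rng, 4, 4)
            _, score = hmm_fill_serial(ev, hap, model, scaling, trans)
            oracle = brute_force_loglik(ev, hap, model, scaling, trans)
            worst = max(worst, abs(score.log_lik - oracle))
        assert worst <= 1e-9

    def test_rejects_degenerate_inputs(self, k3_model):
        e = events_from_levels([80.0])
        with pytest.raises(ValueError, match="at least one event"):
            hmm_fill_serial([], "ACA", k3_model, IDENT)
        with pytest.raises(ValueError, match="shorter than k"):
            hmm_fill_serial(e, "AC", k3_model, IDENT)

    def test_scaling_invariance_up_to_jacobian(self, k3_model):
        # Rescaling the observation axis changes every matched emission
        # density by exactly log(scale); with a negligible bad-event rate
        # every surviving path matches all events, so the log-likelihood
        # shifts by n_events * log(scale).
        trans = TransitionParams(p_bad=1e-9)
        s, c = 7.0, 1.4
        hap = "ACATG"
        levels = [k3_model.level_mean(hap[i : i + 3]) for i in range(3)]
        events = events_from_levels([c * lv + s + 0.3 for lv in levels])
        scaled = ScalingParams(shift=s, scale=c, var=1.0)
        _, base = hmm_fill_serial(events, hap, k3_model, scaled, trans)

        inv_events = [
            Event(e.start_sample, e.length, (e.mean - s) / c, e.stdv) for e in events
        ]
        unscaled = ScalingParams(shift=0.0, scale=1.0, var=1.0 / c)
        _, other = hmm_fill_serial(inv_events, hap, k3_model, unscaled, trans)
        # compressing the observation axis by 1/c scales every matched
        # density up by c, so the compressed representation gains n*log(c)
        jacobian = len(events) * math.log(c)
        assert other.log_lik - base.log_lik == pytest.approx(jacobian, abs=1e-6)

    def test_outlier_event_degrades_likelihood(self, k3_model):
        hap = "ACATGA"
        levels = [k3_model.level_mean(hap[i : i + 3]) for i in range(4)]
        events = events_from_levels(levels)
        _, base = hmm_fill_serial(events, hap, k3_model, IDENT)
        outlier = Event(start_sample=15, length=10, mean=500.0, stdv=1.0)
        degraded = events[:2] + [outlier] + events[2:]
        _, worse = hmm_fill_serial(degraded, hap, k3_model, IDENT)
        assert worse.log_lik < base.log_lik


class TestParallelFill:
    def test_single_worker_equals_serial(self, rng):
        ev, hap, model, scaling, trans = random_hmm_instance(rng, 10, 8)
        _, s = hmm_fill_serial(ev, hap, model, scaling, trans)
        mat_p, p = hmm_fill_parallel(ev, hap, model, scaling, trans, workers=1)
        assert p.log_lik == s.log_lik

    def test_many_workers_bit_identical_matrix(self, rng):
        ev, hap, model, scaling, trans = random_hmm_instance(rng, 100, 20, k=3)
        # force the stated size
        ev = ev * (100 // len(ev) + 1)
        ev = ev[:100]
        hap = (hap * 10)[: 20 + 2]
        mat_s, s = hmm_fill_serial(ev, hap, model, scaling, trans)
        mat_p, p = hmm_fill_parallel(ev, hap, model, scaling, trans, workers=8)
        assert p.log_lik == s.log_lik
        assert np.array_equal(mat_p.fm, mat_s.fm)

    @given(st.integers(0, 10_000), st.integers(1, 8))
    def test_random_instances_bit_identical(self, seed, workers):
        rng = np.random.default_rng(seed)
        ev, hap, model, scaling, trans = random_hmm_instance(rng, 12, 9)
        _, s = hmm_fill_serial(ev, hap, model, scaling, trans)
        _, p = hmm_fill_parallel(ev, hap, model, scaling, trans, workers=workers)
        assert p.log_lik == s.log_lik

    def test_pool_is_reusable(self, rng):
        with ParallelFiller(3) as pool:
            for _ in range(4):
                ev, hap, model, scaling, trans = random_hmm_instance(rng, 8, 6)
                _, s = hmm_fill_serial(ev, hap, model, scaling, trans)
                _, p = pool.fill(ev, hap, model, scaling, trans)
                assert p.log_lik == s.log_lik


def _group_for(hap_window, k=3, chrom="c", n_events=None):
    from methylcall.model_types import find_cg_sites

    sites = find_cg_sites(hap_window)
    return CpGGroup(
        chrom=chrom,
        group_start=sites[0] if sites else 0,
        group_end=sites[-1] if sites else 0,
        num_motifs=len(sites),
        sequence=hap_window,
        seq_start=0,
        event_range=(0, (n_events or 1) - 1),
    )


class TestScoreCpgGroup:
    def test_ratio_is_difference_by_construction(self, k3_model, rng):
        hap = "TACGTT"
        meth_hap = make_methylated_haplotype(hap)
        levels = [k3_model.level_mean(meth_hap[i : i + 3]) for i in range(4)]
        events = events_from_levels(levels, rng, sd=0.5)
        group = _group_for(hap, n_events=len(events))
        call = score_cpg_group(group, events, k3_model, IDENT)
        assert call.log_lik_ratio == call.log_lik_methylated - call.log_lik_unmethylated

    def test_methylated_events_score_positive(self, k3_model, rng):
        hap = "TACGTT"
        meth_hap = make_methylated_haplotype(hap)
        positives = 0
        for _ in range(20):
            levels = [k3_model.level_mean(meth_hap[i : i + 3]) for i in range(4)]
            events = events_from_levels(levels, rng, sd=1.0)
            group = _group_for(hap, n_events=len(events))
            call = score_cpg_group(group, events, k3_model, IDENT)
            positives += call.log_lik_ratio > 0
        assert positives >= 19

    def test_unmethylated_events_score_negative(self, k3_model, rng):
        hap = "TACGTT"
        negatives = 0
        for _ in range(20):
            levels = [k3_model.level_mean(hap[i : i + 3]) for i in range(4)]
            events = events_from_levels(levels, rng, sd=1.0)
            group = _group_for(hap, n_events=len(events))
            call = score_cpg_group(group, events, k3_model, IDENT)
            negatives += call.log_lik_ratio < 0
        assert negatives >= 19

    def test_no_cpg_window_scores_exactly_zero(self, k3_model, rng):
        hap = "TTATTA"
        levels = [k3_model.level_mean(hap[i : i + 3]) for i in range(4)]
        events = events_from_levels(levels, rng, sd=1.0)
        group = _group_for(hap, n_events=len(events))
        call = score_cpg_group(group, events, k3_model, IDENT)
        assert call.log_lik_ratio == 0.0

    def test_label_swap_negates_ratio(self, k3_model, rng):
        # swapping which haplotype is called "methylated" flips the sign
        hap = "TACGTT"
        meth_hap = make_methylated_haplotype(hap)
        levels = [k3_model.level_mean(hap[i : i + 3]) for i in range(4)]
        events = events_from_levels(levels, rng, sd=1.0)
        _, a = hmm_fill_serial(events, hap, k3_model, IDENT)
        _, b = hmm_fill_serial(events, meth_hap, k3_model, IDENT)
        assert (b.log_lik - a.log_lik) == -(a.log_lik - b.log_lik)

    def test_group_without_events_is_suppressed(self, k3_model, caplog):
        group = _group_for("TACGTT")
        group.event_range = None
        with caplog.at_level("WARNING"):
            call = score_cpg_group(group, [], k3_model, IDENT)
        assert call is None
        assert "suppressed" in caplog.text
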