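"""Independent reference computations used to cross-check the package.

These deliberately avoid the implementation's code paths: the HMM oracle
enumerates alignment paths explicitly and sums them with scipy's logsumexp;
the alignment oracle is an unbanded dynamic program with explicit skip
enumeration; emissions come from scipy.stats.norm.
"""

import math

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

KMER_SKIP, BAD_EVENT, MATCH = 0, 1, 2
NEG_INF = float("-inf")


def oracle_emissions(events, haplotype, model, scaling):
    k = model.k
    kmers = [haplotype[i : i + k] for i in range(len(haplotype) - k + 1)]
    emit = np.empty((len(events), len(kmers)))
    for r, e in enumerate(events):
        for b, km in enumerate(kmers):
            mu, sd = model.lookup(km)
            emit[r, b] = norm.logpdf(
                e.mean, scaling.scale * mu + scaling.shift, scaling.var * sd
            )
    return emit


def brute_force_loglik(events, haplotype, model, scaling, trans):
    """Sum over every monotone alignment path by explicit enumeration.

    A path starts before any event at the first k-mer, moves by k-mer skip
    (same event row), stay/step match (consuming one event) or bad event,
    and may terminate whenever it sits in the MATCH state of the last k-mer
    with at least one event consumed.
    """
    emit = oracle_emissions(events, haplotype, model, scaling)
    n_ev, n_block = emit.shape
    lp_stay, lp_skip = math.log(trans.p_stay), math.log(trans.p_skip)
    lp_bad, lp_step = math.log(trans.p_bad), math.log(trans.p_step)
    lp_bad_emit = math.log(trans.p_bad_emit)
    lp_end = lp_step
    terms = []

    def walk(r, b, state, logw):
        if state == MATCH and r >= 1 and b == n_block - 1:
            terms.append(logw + lp_end)
        if b + 1 < n_block:
            walk(r, b + 1, KMER_SKIP, logw + lp_skip)
        if r < n_ev:
            walk(r + 1, b, MATCH, logw + lp_stay + emit[r, b])
            if b + 1 < n_block:
                walk(r + 1, b + 1, MATCH, logw + lp_step + emit[r, b + 1])
            walk(r + 1, b, BAD_EVENT, logw + lp_bad + lp_bad_emit)

    walk(0, 0, MATCH, 0.0)
    return logsumexp(terms) if terms else NEG_INF


def full_dp_align_score(events, sequence, model, scaling, trans):
    """Optimal unbanded alignment score (stay/step/skip moves), computed
    with explicit skip enumeration."""
    emit = oracle_emissions(events, sequence, model, scaling)
    n_e, n_k = emit.shape
    lp_stay, lp_step = math.log(trans.p_stay), math.log(trans.p_step)
    lp_skip = math.log(trans.p_skip)
    best = np.full((n_e, n_k), NEG_INF)
    for j in range(n_k):
        best[0, j] = emit[0, j] + j * lp_skip
    for i in range(1, n_e):
        for j in range(n_k):
            cand = best[i - 1, j] + lp_stay
            for g in range(j):  # step from j-1-g after g skips
                cand = max(cand, best[i - 1, j - 1 - g] + lp_step + g * lp_skip)
            best[i, j] = emit[i, j] + cand
    return max(best[n_e - 1, j] + (n_k - 1 - j) * lp_skip for j in range(n_k))


def score_alignment(pairs, events, sequence, model, scaling, trans):
    """Score of a concrete event-to-k-mer assignment under the aligner's
    move costs; requires one pair per event in order."""
    assert [e for e, _ in pairs] == list(range(len(events)))
    emit = oracle_emissions(events, sequence, model, scaling)
    n_k = emit.shape[1]
    lp_stay, lp_step = math.log(trans.p_stay), math.log(trans.p_step)
    lp_skip = math.log(trans.p_skip)
    total = pairs[0][1] * lp_skip + emit[0, pairs[0][1]]
    for (e0, j0), (e1, j1) in zip(pairs[:-1], pairs[1:]):
        if j1 == j0:
            total += lp_stay
        else:
            total += lp_step + (j1 - j0 - 1) * lp_skip
        total += emit[e1, j1]
    total += (n_k - 1 - pairs[-1][1]) * lp_skip
    return total
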