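# methylcall

Read-level calling of 5-methylcytosine (5mC) at CpG sites from
nanopore-style raw signal. `methylcall` is for people who work on the
signal-processing side of nanopore epigenomics: it implements the classic
HMM-based call-methylation workflow — event detection, event-to-k-mer
alignment, per-read calibration, and methylation scoring — as a clean,
testable Python package, with two properties at its core:

1. **A block-structured profile HMM with a two-phase parallel fill.** The
   scored haplotype of K k-mers is laid out as K blocks of three states
   (`KMER_SKIP`, `BAD_EVENT`, `MATCH`). Per row, the MATCH/BAD_EVENT columns
   depend only on the previous row and are filled concurrently; a barrier;
   then a single left-to-right scan fills the KMER_SKIP chain. The parallel
   fill is *bit-identical* to the serial reference for any worker count.
2. **A pipelined four-stage batch executor.** Batches flow through the four
   stages concurrently under a window limit (default 3 batches in flight),
   with per-stage exclusivity and in-order entry, and the output is
   byte-identical to a serial run.

For each read and each CpG group (CG dinucleotides ≤ 10 bp apart, scored
jointly), the caller reports the log-likelihood ratio

    LLR = log P(events | methylated haplotype) − log P(events | unmethylated haplotype)

where the methylated haplotype replaces every CpG cytosine by M and events
are scored against a k-mer Gaussian current model
`N(e; c·μ_x + s, (v·σ_x)²)` under per-read shift/scale/var calibration.
Positive LLR supports methylation. See `docs/methods.md` for the model in
full.

## Worked example

Simulate a small synthetic experiment (reference with planted CpGs, reads,
BAM, per-read raw signal, pore model, methylation truth), then call it:

```bash
methylcall simulate -o demo --n-reads 6 --read-length 800 --ref-length 3000 --seed 11
# wrote 6 files to demo

methylcall call-methylation -t 2 -B 2 \
    -r demo/reads.fastq.gz -b demo/alignments.bam -g demo/reference.fa \
    --signals demo/signals.tsv --model demo/pore_model.tsv \
    --engine parallel --trace demo/trace.tsv -o demo/calls.tsv
# wrote 80 calls for 6 reads to demo/calls.tsv
```

The output is a tab-separated table, one row per (read, CpG group):

```
chromosome	strand	start	end	read_name	log_lik_ratio	log_lik_methylated	log_lik_unmethylated	num_calling_strands	num_motifs	sequence
chrSim	+	243	245	simread_0000	-11.01	-29.23	-18.22	1	1	CAAAGCGGCCAC
chrSim	+	257	266	simread_0000	16.54	-37.78	-54.32	1	2	ACAAACGCATGACGTGGTC
chrSim	+	308	310	simread_0000	6.20	-18.16	-24.36	1	1	CACCACGGGAAT
```

Row one: the CpG at reference positions 243–244 on read `simread_0000` has
LLR −11.01 (= −29.23 − (−18.22)), strong evidence *against* methylation.
Row two scores a group of two CpGs jointly (`num_motifs` 2) with LLR +16.54,
strong evidence *for* methylation. `start`/`end` delimit the CG motif span
(0-based, half-open) and `sequence` is the scored reference window including
flanks. The `--trace` file logs every batch's entry/exit through the four
pipeline stages.

The same workflow is available as a library:

```python
from methylcall import CallParams, PipelineConfig, SimConfig, call_methylation
from methylcall.synthetic_data import simulate_dataset

reference, model, reads, truth = simulate_dataset(SimConfig())
run = call_methylation(reads, {"chrSim": reference}, model,
                       CallParams(engine="parallel"),
                       PipelineConfig(batch_count=3, threads=4))
print(len(run.calls))   # 1607 calls, sorted by (chrom, start, read_name)
```

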