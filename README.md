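# pelekit

Rare alleles segregating at 0.2–0.5 % in a pooled sample sit below the
error floor of standard short-read sequencing: at ~1 % per-base
sequencing error, every deeply sequenced position carries spurious
non-reference bases that are indistinguishable from genuine minor
alleles. `pelekit` implements a paired-end low-error analysis strategy
that removes both error classes without sacrificing sensitivity, plus a
desk-scale simulator so the whole pipeline is testable without any
sequencing data:

1. **Overlap merging.** Short-insert libraries are sequenced with fully
   overlapping paired-end reads; each pair is merged into one consensus
   in which agreeing bases carry quality `min(q1+q2, 93)` (retained only
   at Q ≥ 60) and disagreeing bases are masked to `N`. Sequencing
   errors, independent per mate, do not survive.
2. **Dual-barcode filtering.** Each sample is amplified under a mixture
   of two inline barcodes. A PCR-lineage error descends to reads of a
   single barcode; a true allele appears under both. Calling leniently
   per barcode and keeping only variants present in *both* call sets
   (List B), alongside a strict pass on the pooled data (List A),
   yields the final call set `A ∪ B`.
3. **Quality-aware calling.** At each pileup column with `k`
   observations of an alternate base among `n`, the p-value is the
   exact Poisson-binomial tail `P(X ≥ k)` where trial `i` succeeds with
   probability `10^(-q_i/10)/3`, Bonferroni-corrected over
   `3 × (tested columns)`; calls additionally require an allele
   frequency above a floor set from the background error of a pure
   control (default 0.002).

Two-population comparison (putative de-novo alleles: called in one
population, zero supporting observations in the other, ≥ 900× merged
depth in both; lost alleles; fold changes; pyrimidine-class mutation
spectra) and a three-arm matched-budget benchmark harness are included.

## Worked example

Simulate a spike-in library of 8 RAD tags carrying 8 truth alleles at
0.42 % frequency, and analyse the same raw reads three ways at 2000×
merged (OPE) depth per barcode:

```python
from pelekit.bench import ExperimentConfig, run_experiment

cfg = ExperimentConfig(n_tags=8, n_truth=8, truth_af=0.0042, depths=(2000,))
report = run_experiment(cfg, seed=7)
for arm, ev in report.per_depth[2000].items():
    print(arm, ev.as_dict())
```

prints

```
pele     {'n_expected': 8, 'true_positives': 8, 'false_positives': 0, 'sensitivity': 1.0, 'precision': 1.0, ...}
orp      {'n_expected': 8, 'true_positives': 8, 'false_positives': 0, 'sensitivity': 1.0, 'precision': 1.0, ...}
standard {'n_expected': 8, 'true_positives': 8, 'false_positives': 7, 'sensitivity': 1.0, 'precision': 0.53, ...}
```

All three arms find every planted allele, but the standard (unmerged)
arm — called without an allele-frequency floor — also reports 7 false
positives, while the merged arms report none: the consensus step has
removed the sequencing errors, and the frequency floor plus barcode
intersection remove the PCR errors. The merge statistics in
`report.merge_stats` show the definitional 2:1 collapse of raw bases
into consensus bases (`retention_fraction ≈ 0.499` here).

The cost model answers planning questions directly:

```python
from pelekit.bench import lane_fraction, format_lane_percent
format_lane_percent(lane_fraction(1_000, 20_000))   # -> '0.062' (% of a lane)
format_lane_percent(lane_fraction(16_700, 20_000))  # -> '1.0'
```

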