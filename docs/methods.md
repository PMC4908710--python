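# Methods

`pelekit` implements a rare-allele detection pipeline for pooled,
reduced-representation sequencing in which every molecule is read twice
(overlapping paired-end reads merged to a consensus) and every sample is
amplified under two inline barcodes, so that PCR-lineage errors can be
filtered by their barcode confinement. This note describes the models,
the defaults and the numerical choices; everything quantitative stated
here is computed by the test suite or the benchmark harness, not quoted.

## The error model the filters exploit

Three error classes dominate deep short-read data:

* **Sequencing errors** (~1e-3 per base) strike each read base
  independently. Because both mates of a fully overlapping pair read
  the same molecule, requiring agreement between mates removes them:
  a disagreeing position is masked to `N` and a retained base carries
  the summed quality of both mates (min Q60), i.e. two independent
  observations.
* **PCR-lineage errors** (~1e-5 per base per duplication, heavily
  biased toward C>T / G>A when classified on the pyrimidine strand)
  enter during amplification. They are present in *both* mates of every
  read pair descending from the affected fragment, so merging cannot
  remove them — but each lineage is ligated to exactly one of the two
  barcodes, so a lineage error is visible under a single barcode only,
  while a true allele in the pool appears under both.
* **True rare alleles** at frequencies 0.2–0.5 % must survive both
  filters, which is why whole-read rejection on a mismatch is avoided
  (base-level `N` masking keeps the remaining evidence).

## Significance model

At each pileup column, each retained observation is a Bernoulli trial
of erroneously showing a given alternate base, with probability
`10^(-q/10)/3` from its merged Phred `q` (uniform three-way split over
alternates). The p-value of `k` or more alternate observations is the
exact Poisson-binomial upper tail, computed by a grouped dynamic
programme: equal probabilities are collapsed into Binomial blocks, and
the `>= k` mass is accumulated in an absorbing state so every update
adds non-negative numbers — no cancellation, tails accurate to full
relative precision down past 1e-300 (verified against 2^n enumeration
for n <= 15 and against the Binomial survival function for homogeneous
inputs). Bonferroni correction defaults to `3 x (tested columns)`
(three alternates per site); the factor is configurable. Call quality
is the Phred of the corrected p-value, capped at 3000.

The calling thresholds come in two profiles:

* **strict** (List A, pooled barcodes): `min_af = 0.002`, `alpha = 0.05`.
  The AF floor — not the p-value — is what removes PCR errors from
  merged data: merged base qualities imply per-observation error rates
  near 1e-6, so a handful of identical PCR errors at one column is
  overwhelmingly "significant" statistically, yet sits well below an
  allele-frequency floor placed above the background error rate.
* **lenient** (List B, per barcode): `min_af = 0.0005`,
  `min_call_quality = 150` (documented working range 150–820), applied
  to each barcode separately; only variants called under *both*
  barcodes survive. The final call set is the union of Lists A and B;
  where both contain a key, the pooled (List A) record wins.

`estimate_background` profiles a pure control: per-column non-reference
rate, its maximum (the quantity an AF floor must clear — the mean rate
understates locally clustered error), the pyrimidine-class spectrum,
and the smallest round value (1/2/5 decade grid) strictly above the
maximum as a recommended floor. The AF floor's domain of validity is
depth-dependent: at pooled depths below ~2000x, `0.002 x depth` admits
very small alternate counts and coincident PCR errors can clear it, so
the floor should be re-derived from a matched control at the working
depth (the harness uses >= 1000x per barcode).

## Synthetic data

The generator is the study-conditions oracle, not a tuning knob:

* genomes with an exactly controlled restriction-site census (sites
  placed by order statistics under a minimum spacing; accidental motif
  occurrences destroyed by single-base patching, bounded at 100
  rounds);
* 100 bp tags flanking each site (pure flanks, site bases excluded;
  upstream flank reverse-complemented), optional second digest removing
  tags containing a second motif;
* truth alleles at configurable target frequencies (benchmark default:
  16 alleles at 0.42 %), placed >= 5 bp from tag ends;
* molecules drawn uniformly over tags, alleles carried
  Bernoulli(target AF), barcode Bernoulli(0.5), insert 100 bp (jitter
  configurable), 18 PCR cycles at 1e-5 errors/base/duplication with
  C>T-class weight 0.8, sequencing errors 1e-3/base with deterministic
  Phred values so error probabilities are exactly reconstructable.

Simplifications, deliberately accepted: each sequenced fragment draws
an independent PCR lineage (no duplicate families sharing an early
error — barcode confinement and mate sharing, the two properties the
filters use, are preserved); no indels, adapters, optical duplicates,
GC amplification bias or quality miscalibration. Because real libraries
do contain correlated duplicate families, clustered errors and biased
amplification, passing benchmarks here demonstrate the pipeline's
internal correctness and the filters' mechanism, not field performance;
in particular real spike-in sensitivity depends on the true (not
nominal) allele content of the library, which the simulator cannot
reproduce.

## Benchmark harness

`run_experiment` simulates one library and analyses the same raw reads
three ways — standard (unmerged, single-read qualities, truncated to
2.4x the pooled merged depth, the conversion between consensus depth
and the raw depth the same budget buys), ORP (merged, pooled, strict =
List A only) and PELE (A union B) — then scores each against the truth
set: TP requires position *and* alternate to match; "precision" is
TP/(TP+FP); an empty call set reports precision 1.0 with a `vacuous`
flag. Depth truncation keeps reads in stream order until each tag's
mean covered depth reaches the target (per-tag truncation of an
unsorted stream; random subsampling is available behind a flag with an
explicit seed).

The default benchmark (20 tags, 16 truth alleles at 0.42 %, 5000x
merged depth per barcode, 20 seeds) is sized to run on one CPU in
minutes while keeping the per-column counting statistics in the regime
where the 0.002 floor separates true alleles (expected alternate count
~42 at pooled 10000x) from PCR background (~1–2). The acceptance test
asserts: zero PELE false positives on every seed; at least one standard
-arm false positive (no AF floor) in >= 19/20 seeds; PELE sensitivity
>= ORP sensitivity everywhere; and detected-AF recovery, with >= 95 %
of detected truth alleles inside their exact Binomial 99 % interval
(with ~320 variant-seed pairs, demanding every single one inside a 99 %
interval would fail by construction; aggregate coverage is the sound
reading).

The lane-fraction cost model is `region x depth / read_len /
reads_per_lane / retention` with defaults 100 bp reads, 4e8 reads/lane
and 0.80 overlap retention; percentages print at two significant
figures, truncating.

## Numerical and design choices

* Coordinates 0-based half-open internally; 1-based only in VCF.
* Overlap search is exhaustive over all shifts (ties: most matches,
  then longest overlap, then smallest shift); the batch path evaluates
  shifts in decreasing-overlap order with early retirement and is
  asserted identical to the per-pair reference.
* Merged quality = min(q1+q2, 93), so qualities stay printable; the
  Q60 consensus floor subsumes overhang trimming since a single read
  cannot reach it.
* Alignment is ungapped best-Hamming over the known tag space (k-mer
  seeding with an exhaustive fallback; `N` neither matches nor
  mismatches; cross-tag ties dropped). SAM text import/export covers
  external aligners; indel/clipped records are dropped with a count.
* "Absent in the other population" means zero alternate observations
  (`max_other_af = 0`, configurable) at >= 900x merged depth in both
  populations; fold changes are plain count ratios with no continuity
  correction.
* Strand-bias tests are omitted: merged consensus reads have no
  meaningful strand.

## Known limitations

Indel calling, gapped alignment, base-quality recalibration and more
than two barcodes per sample are out of scope. The depth-to-threshold
mapping for the lenient profile is configurable rather than hard-coded,
since the optimum depends on library-specific background that should be
measured from a control amplicon run alongside the samples.
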