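# Methods

This note documents the models, conventions and numerical choices behind
chromdyn, and what the synthetic-data tests do and do not establish about
real data.

## Coordinates and formats

All internal coordinates are 0-based half-open (BED-native); GTF records
(1-based closed) are converted on read, so a single convention holds
everywhere and off-by-one drift cannot accumulate between stages. A gene's
TSS is its strand-aware 5′ base (`start` on +, `end − 1` on −) and its TES
the polyA-addition end. Chromosome names are matched as exact strings — no
"chr" aliasing — so fixture mistakes surface as errors rather than silent
empty joins. bedGraph is the canonical track format (run-length encoded, 6
significant digits); bigWig and BAM are optional adapters behind the same
in-memory types.

## Coverage model

A coverage track stores, per bin, the **mean per-base count of overlapping
fragments** rather than a fragment count. This makes the track's meaning
independent of bin size and matches 1× scaling semantics: after RPGC
normalization the genome-wide total base coverage equals the effective
genome size exactly (checked to 1e-9 relative tolerance), i.e. mean
coverage over the effective genome is 1×.

Fragment transformation precedes binning: `extend_to` spans the nominal
fragment length from the fragment's 5′ end in the strand direction (200 bp
for TF ChIP, 250 bp for PolII ChIP by default), `center_at` places the
window on the fragment midpoint (for single-end centering), `as_is` leaves
spans untouched. Fragments running past a chromosome end are clipped, not
dropped — on the small synthetic chromosomes dropping them would deplete
coverage near every boundary.

Input subtraction operates bin-wise on RPGC tracks (the common 1× scale is
the depth normalization) and **preserves negative values**: a bin where
input exceeds ChIP is genuinely depleted and flooring would bias profile
baselines. Ratio normalization (e.g. a histone mark against H3) adds a
pseudocount to numerator and denominator; the default of 0.1 RPGC units is
small against enriched signal (≫1×) while bounding the ratio at
signal-free bins. Both the track bin size (default 1 bp) and the
enrichment-summary bin size (default 10 bp) are configurable; input
subtraction defaults to the 10-bp scale used for enrichment summaries.

## Peak-set algebra

*Co-bound union*: every cross-set pair overlapping ≥ 1 bp emits the union
span of the pair; emitted spans that overlap or abut are merged
transitively; intervals with no cross-set partner are excluded. This reads
"union of A and B peaks which overlap" as co-bound-only — the plain merged
union of both sets is available (`plain_union`, `--plain`) for the
alternative reading.

*Consensus*: bases covered by intervals from ≥ `min_support` distinct
replicate sets form cores; each core is extended to the union span of all
intervals contributing to it (the convention of diffBind-style consensus
building, which avoids fragmenting a peak into slivers), and extended
spans are merged. Support counts sets, not intervals, so two overlapping
intervals within one replicate count once.

*Intersect-all* keeps first-set intervals overlapped (≥ 1 bp) by every
other set; *blacklist filtering* removes a peak entirely on any ≥ 1 bp
overlap (no trimming). Every one of these operations, plus midpoint
counting, is verified exactly against naive per-base / all-pairs oracles
over hundreds of seeded random instances.

*Classification*: an H3K4me1 region overlapping H3K4me3 is excluded from
the enhancer classes; otherwise it is an active enhancer when it overlaps
both H3K27ac and p300, else inactive. Peak region classes use precedence
promoter > active enhancer > inactive enhancer > other — precedence is not
dictated by the definitions themselves, and the promoter is the most
specific annotation when a peak overlaps several features. The promoter
window for classification reuses the traveling-ratio window (−2000/+500
around the TSS): one documented constant rather than two silent ones.

*Counting* assigns a fragment to a region iff its midpoint lies inside the
half-open span, which keeps counts additive across adjacent windows and
insensitive to fragment-length edge effects. Input-subtracted counts are
`max(0, raw − input_raw × depth_ratio)`.

## Aggregate profiles

`compute_matrix` averages per-base track signal into `binsize`-bp bins
(default 5) over transcription-direction offsets `[−upstream, downstream)`
(default ±1500) around each reference point; minus-strand references are
read rightward-to-leftward, and bases beyond chromosome ends contribute 0.
Bin *j* of a minus-strand row therefore covers exactly the mirrored base
set of the plus-strand row, which is what the reflection-oracle test
checks.

Normalization is two-step: each location's row is divided by its own mean
(rows with **exactly zero** mean are dropped and counted — their
normalization is undefined; near-zero rows are kept, since any threshold
would be arbitrary), then the per-replicate column-mean profile is divided
by the mean of its outermost 50-bp flanks (the first and last 10 bins at
the default geometry). Replicates are baseline-normalized first and
averaged second — the per-replicate aggregate is the unit the baseline is
defined on. The row mean is taken over the full window, including zero
bins, consistent with missing-data-as-zero extraction.

**Bootstrap.** Locations (matrix rows) are the exchangeable unit of a
metagene profile, so they are the resampling unit, drawn with replacement
independently within each replicate; the full normalization pipeline is
re-run per iteration. Resampling-then-averaging is implemented as
multinomial row weights multiplied into the row-normalized matrix —
distribution-identical to index resampling and vectorizable over
iterations. The confidence band is the empirical 2.5/97.5 percentile range
(skew-robust, unlike a normal approximation); the reported center is the
non-resampled estimate. Default 5000 iterations. A resample whose flank
mean is zero has no defined baseline; such iterations are recorded as NaN,
excluded from percentiles and p-value counts, and logged.

**Empirical p-values.** For a chosen bin (default: the central
reference-point bin), both conditions are resampled independently per
iteration and the difference Δ_b recorded; the two-sided add-one-smoothed
p-value is `min(1, 2·min((1+#{Δ≤0})/(B+1), (1+#{Δ≥0})/(B+1)))`, so p ≥
1/(B+1) always. Calibration is tested two ways: on i.i.d. Gaussian rows
(200 locations, 3 replicates: 95% CI coverage within 95±3%, type-I rate at
0.05 within [0.02, 0.09] over 200 seeds) and through the full MNase
pipeline under the null (same bands).

**Nascent RNA** profiles are built per strand, skip both normalizations,
and carry a mean ± 1.96 s.e.m. band (sample s.d. across replicate
profiles over √n); at least two replicates are required. A
plus-strand-only report is available for compatibility with
stranded-display conventions.

## Traveling ratio

Windows (strand-aware, clipped to the chromosome): promoter
`[TSS−2000, TSS+500)`, body `[TSS+500, TES]`; a gene whose body is empty
after clipping is flagged unusable. RPKM uses the clipped window length,
avoiding density inflation at chromosome boundaries. TR =
d_p/(d_p+d_b) is the default definition because it alone reproduces the
defining values — 0.5 for uniform signal, 0.75 for a 3:1 promoter excess —
for any window lengths; the grammatically possible alternative
(promoter density over the density of the combined promoter+body region)
is available as `definition="density-ratio"`. The ≥ 1 RPKM filter in both
windows is applied before tabulation and losses are logged. Distribution
comparisons use the two-sample Kolmogorov–Smirnov test (the canonical
CDF-distance test for the cumulative-TR display; Mann–Whitney available),
and both empirical CDFs are tabulated. Overlapping genes are scored
independently; signal is not deconvolved.

## Synthetic data

Each (library, replicate) draws from an RNG stream keyed by a stable hash
of its name under the master seed, so adding a library never perturbs
another and identical configs produce byte-identical fixture trees.
Replicate library sizes are negative-binomial around the nominal depth
(dispersion 0.1 by default, Poisson in the limit), emulating the
overdispersion of real replicate libraries that the bootstrap must absorb.

Defaults describe a deliberately small but structured cohort: 2
chromosomes × 2 Mb, 50 non-overlapping genes of 3–8 kb on both strands, 40
peaks of 1 kb, 3 replicates of 100,000 fragments. ChIP fragments mix a
genome-uniform background with Gaussian peak-centered enrichment (s.d. =
peak width/6) so that `enrichment=1` is exactly input-like; MNase
fragments are ~N(147, 12) bp long, jittered N(0, 20 bp) around dyads of
5-nucleosome arrays at 180-bp spacing with occupancy 0.8, and occupancy
deltas apply to the central dyad; PolII fragments split promoter/body per
gene in proportion d_p·len_p : d_b·len_b with uniform positions inside
each window, making the true TR exactly d_p/(d_p+d_b); nascent reads mix a
truncated-exponential 5′ component (default scale 750 bp, weight 0.7) with
a uniform gene-body component on the gene's own strand.

What the generators do **not** emulate: sequence composition and
mappability, GC bias, fragment-length/position coupling, copy-number and
blacklist-like artifact regions, correlated replicate structure beyond
library-size dispersion, and real-genome scale. Passing tests therefore
establish the correctness and calibration of the computations under the
stated statistical structure — not robustness to artifacts that only real
libraries exhibit.

## Problem sizes used in tests

Oracle-equivalence suites run 200 seeded trials per operation at ≤ 100
fragments / ≤ 60 intervals on ≤ 10-kb chromosomes — sizes where the naive
oracles are instant and agreement is required exactly. Calibration suites
use 200 locations × 20 bins × 3 replicates (1000 bootstrap iterations for
CI coverage, 500 for type-I rates, 200 seeds), and the MNase
pipeline-level null runs 200 sites on a 500-kb chromosome at 100,000
fragments per library. Parameter-recovery runs use 2000 fragments/gene
across true TR ∈ {0.3, 0.5, 0.75, 0.9} (mean absolute error < 0.02) and a
+0.5 occupancy delta for detection. These sizes were chosen so each
statistical check retains its intended power while the oracles remain
tractable.

## Known limitations

- Peak calling itself is out of scope; peak sets are inputs.
- Differential-binding statistics (the step downstream of the count
  table) and differential expression are out of scope.
- The consensus "extend to contributing intervals" convention can chain
  adjacent cores into one region when their extensions touch; this mirrors
  the reference behaviour but means consensus regions are not guaranteed
  minimal.
- `empirical_pvalue` tests a single bin; no multiple-testing correction
  across bins is applied or implied.
- The BAM adapter takes proper pairs and primary single-end alignments
  only; it does not deduplicate.
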