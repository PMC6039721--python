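# chromdyn

Quantitative chromatin-dynamics analysis for time-resolved ChIP-seq,
MNase-seq and nascent RNA-seq experiments — the kind of data produced when a
chromatin remodeler (e.g. the NuRD complex) is induced and its effect on
nucleosome occupancy and RNA polymerase II is followed over minutes to
hours. The package re-implements, as a tested and reusable pipeline, the
four analysis stages such studies chain together:

1. **Coverage normalization** — aligned fragments are optionally extended
   from their 5′ end (200 bp for transcription-factor ChIP, 250 bp for
   PolII ChIP) or re-centered, binned as mean per-base coverage, and scaled
   to 1× genome coverage (RPGC: values × *G*<sub>eff</sub>/total base
   coverage, with *G*<sub>eff</sub> = 2,150,570,000 bp for mouse mm10).
   Depth-normalized input subtraction and H3-ratio normalization operate on
   RPGC tracks.
2. **Peak-set algebra** — co-bound unions (cross-set overlap ≥ 1 bp),
   replicate consensus (regions supported by ≥ 2 replicates, extended to
   the union of contributing intervals), all-dataset intersection, ENCODE
   blacklist filtering, enhancer classification (H3K4me1 without H3K4me3;
   *active* when co-marked by H3K27ac and p300), and midpoint-assigned
   fragment counts with input subtraction.
3. **Aggregate (metagene) profiles** — signal in 5-bp bins over ±1500 bp
   around TSSs or feature centers; each location's row scaled to its own
   mean; the per-replicate profile scaled to the mean of the outermost
   50-bp flanks (−1500..−1450 and +1450..+1500) to read as enrichment over
   baseline; replicates averaged. 95% confidence bands come from a
   5000-iteration location-level bootstrap with the normalization repeated
   per iteration, and condition differences get empirical two-sided
   p-values. Nascent RNA profiles skip the normalizations and use a plain
   mean ± 1.96 s.e.m. band.
4. **Traveling ratio (TR)** — per gene, with promoter window
   TSS−2000..TSS+500 and body TSS+501..gene end, and d<sub>p</sub>,
   d<sub>b</sub> the PolII S5P densities (RPKM) of the two windows:

   TR = d<sub>p</sub> / (d<sub>p</sub> + d<sub>b</sub>)

   so uniform signal gives TR = 0.5 and a 3:1 promoter excess gives
   TR = 0.75. Genes need ≥ 1 RPKM in both windows; condition comparisons
   use the two-sample Kolmogorov–Smirnov test on the TR distributions.

A seeded synthetic-data generator (`chromdyn.simulate`) produces genomes,
gene models, peak sets and fragment libraries with the statistical
structure these assays assume — peak-centered ChIP enrichment with matched
inputs, positioned nucleosome arrays with per-condition occupancy changes,
promoter-paused PolII with a known true TR, and 5′-weighted stranded
nascent reads — so the whole pipeline runs and is tested without any
download.

## Worked example

The defining TR values, computed from deposited fragments:

```python
import numpy as np
from chromdyn import FragmentSet, GeneModel, GenomeModel, traveling_ratio

genome = GenomeModel((("chr1", 50_000),))
gene = GeneModel("g", "chr1", "+", 10_000, 13_000)   # TSS 10,000

# 3 fragments/bp over the promoter window, 1/bp over the body
positions = np.concatenate([np.repeat(np.arange(8_000, 10_500), 3),
                            np.arange(10_500, 13_000)])
frags = FragmentSet("s5p", np.full(positions.size, "chr1", dtype=object),
                    positions, positions + 1, np.full(positions.size, "+"))
print(traveling_ratio(frags, gene, genome).tr)   # 0.75  (paused gene)
```

An end-to-end run on synthetic data — simulation, coverage, peak
classification, MNase profiles with bootstrap CIs, and the TR table:

```bash
chromdyn demo --seed 3 --out demo_run
```

prints (abridged):

```json
{
  "chip_enrichment_in_peaks": 6.04215067382429,
  "mnase_center_p": 0.5708582834331337,
  "tr_ks_p_rep1_vs_rep2": 0.5220497790075043,
  "tr_median": 0.7496216781830702,
  "tr_n_genes": 30
}
```

The input-subtracted RPGC coverage inside simulated peaks is ~6× baseline
(the generator used 8× enrichment; fragment-extension smearing lowers the
observed ratio). The recovered median TR is 0.7496 against a simulated
truth of 0.75, and the two PolII replicates are statistically
indistinguishable (KS p = 0.52). The small 30-gene demo is underpowered
for the MNase center test (p = 0.57); the test suite runs the same
pipeline at 200 sites, where a +0.5 occupancy gain is detected at
p ≈ 0.002 and the null rejection rate stays at the nominal 5%.

Re-running any command with the same seed reproduces every output file
byte-for-byte.

## Layout

```
src/chromdyn/
  genome.py       coordinate model and domain types
  io.py           BED / bedGraph / GTF (+ optional BAM, bigWig adapters)
  simulate.py     seeded synthetic-data generators
  coverage.py     binning, RPGC, input subtraction, ratio tracks
  intervals.py    peak-set algebra and region classification
  profiles.py     metagene matrices, bootstrap CIs, empirical p-values
  travelratio.py  TR records, tables and CDF comparisons
  cli.py          chromdyn {simulate,coverage,peaks,profile,travelratio,demo}
docs/methods.md   models, assumptions, parameter choices, limitations
```
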