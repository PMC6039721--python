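"""RNA polymerase II traveling ratio: promoter vs gene-body S5P density.

The traveling ratio (TR) contrasts the density of initiating (Ser5-
phosphorylated) polymerase in a fixed promoter-proximal window against the
gene body. With promoter density d_p and body density d_b (both RPKM), the
default definition is

    TR = d_p / (d_p + d_b)

so uniform signal gives TR = 0.5 (unpaused) and a 3:1 promoter excess gives
TR = 0.75 (paused). Higher TR means promoter-proximal accumulation, i.e.
pausing — though initiation and elongation rates also move it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import FragmentSet, GeneModel, GenomeModel, GenomicInterval

logger = logging.getLogger(__name__)

#: promoter-proximal window around the gene start, bp: -2 kb .. +500.
PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 500

#: expression filter: genes need >= 1 RPKM in both promoter and body.
MIN_RPKM = 1.0


@dataclass
class TRRecord:
    gene_id: str
    promoter_count: int
    body_count: int
    promoter_rpkm: float
    body_rpkm: float
    tr: float  # NaN when promoter+body signal is zero
    passed_filter: bool
    usable: bool = True


@dataclass
class TRComparison:
    """Two-sample CDF comparison of traveling-ratio distributions."""

    statistic: float  # Kolmogorov-Smirnov D
    p: float
    n_a: int
    n_b: int
    cdf_a: pd.DataFrame
    cdf_b: pd.DataFrame


def gene_windows(gene: GeneModel, genome: GenomeModel | None = None,
                 upstream: int = PROMOTER_UPSTREAM,
                 downstream: int = PROMOTER_DOWNSTREAM
                 ) -> tuple[GenomicInterval, GenomicInterval] | None:
    """Strand-aware (promoter, body) windows; ``None`` if the gene is unusable.

    On +: promoter [TSS-up, TSS+down), body [TSS+down, gene end).
    On -: promoter [TSS-down, TSS+up), body [gene start, TSS-down).
    Windows are clipped to the chromosome; a gene whose body is empty after
    clipping (span < up+down+2 in practice) is unusable.
    """
    length = genome.length(gene.chrom) if genome is not None else None

    def clip(lo: int, hi: int) -> tuple[int, int]:
        lo = max(lo, 0)
        if length is not None:
            hi = min(hi, length)
        return lo, hi

    if gene.strand == "+":
        p_lo, p_hi = clip(gene.tss - upstream, gene.tss + downstream)
        b_lo, b_hi = clip(gene.tss + downstream, gene.end)
    else:
        p_lo, p_hi = clip(gene.tss - downstream, gene.tss + upstream)
        b_lo, b_hi = clip(gene.start, gene.tss - downstream)
    if b_hi <= b_lo or p_hi <= p_lo:
        return None
    return (
        GenomicInterval(gene.chrom, p_lo, p_hi, gene.strand, "promoter"),
        GenomicInterval(gene.chrom, b_lo, b_hi, gene.strand, "body"),
    )


def count_midpoints(frags: FragmentSet, region: GenomicInterval) -> int:
    """Fragments whose midpoint falls in the half-open region."""
    mask = frags.chroms.astype(str) == region.chrom
    mids = (frags.starts[mask] + frags.ends[mask]) // 2
    return int(np.count_nonzero((mids >= region.start) & (mids < region.end)))


def region_rpkm(frags: FragmentSet, region: GenomicInterval,
                count: int | None = None) -> float:
    """Reads per kb of region per million library fragments (midpoint-assigned)."""
    if len(region) <= 0:
        raise ValueError("zero-length region")
    if frags.library_size <= 0:
        raise ValueError("empty library; RPKM undefined")
    if count is None:
        count = count_midpoints(frags, region)
    return count / (len(region) / 1000 * frags.library_size / 1e6)


def traveling_ratio(frags: FragmentSet, gene: GeneModel,
                    genome: GenomeModel | None = None,
                    definition: str = "fraction",
                    min_rpkm: float = MIN_RPKM) -> TRRecord:
    """Per-gene TR record with the 1-RPKM expression-filter flag.

    ``definition='fraction'`` (default) computes d_p/(d_p+d_b);
    ``'density-ratio'`` computes d_p over the density of the combined
    promoter+body region.
    """
    windows = gene_windows(gene, genome)
    if windows is None:
        return TRRecord(gene.gene_id, 0, 0, 0.0, 0.0, float("nan"), False, usable=False)
    promoter, body = windows
    c_p = count_midpoints(frags, promoter)
    c_b = count_midpoints(frags, body)
    d_p = region_rpkm(frags, promoter, c_p)
    d_b = region_rpkm(frags, body, c_b)
    if definition == "fraction":
        tr = d_p / (d_p + d_b) if (d_p + d_b) > 0 else float("nan")
    elif definition == "density-ratio":
        d_union = region_rpkm(
            frags,
            GenomicInterval(gene.chrom, min(promoter.start, body.start),
                            max(promoter.end, body.end), gene.strand),
            c_p + c_b,
        )
        tr = d_p / d_union if d_union > 0 else float("nan")
    else:
        raise ValueError(f"unknown TR definition {definition!r}")
    passed = d_p >= min_rpkm and d_b >= min_rpkm
    return TRRecord(gene.gene_id, c_p, c_b, d_p, d_b, tr, passed)


def tr_table(frags: FragmentSet, genes, genome: GenomeModel | None = None,
             definition: str = "fraction", min_rpkm: float = MIN_RPKM) -> pd.DataFrame:
    """Filtered TR table: one row per usable gene passing the RPKM filter."""
    records = [traveling_ratio(frags, g, genome, definition, min_rpkm) for g in genes]
    usable = [r for r in records if r.usable]
    kept = [r for r in usable if r.passed_filter and np.isfinite(r.tr)]
    n_lost = len(records) - len(kept)
    if n_lost:
        logger.info("tr_table: %d of %d genes removed (unusable or < %g RPKM)",
                    n_lost, len(records), min_rpkm)
    if not kept:
        logger.warning("tr_table: no genes passed the %g-RPKM filter", min_rpkm)
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in kept],
            "promoter_count": [r.promoter_count for r in kept],
            "body_count": [r.body_count for r in kept],
            "promoter_rpkm": [r.promoter_rpkm for r in kept],
            "body_rpkm": [r.body_rpkm for r in kept],
            "tr": [r.tr for r in kept],
        }
    )


def _ecdf(values: np.ndarray) -> pd.DataFrame:
    x = np.sort(values)
    return pd.DataFrame({"tr": x, "cdf": np.arange(1, x.size + 1) / x.size})


def compare_tr(table_a: pd.DataFrame, table_0: pd.DataFrame,
               test: str = "ks") -> TRComparison:
    """Compare two TR distributions (default: two-sample Kolmogorov-Smirnov).

    Also tabulates both empirical CDFs for plotting cumulative TR curves.
    ``test='mannwhitney'`` swaps in the rank-sum test; the reported
    statistic is then the common-language effect size in [0, 1].
    """
    a = np.asarray(table_a["tr"], dtype=float)
    b = np.asarray(table_0["tr"], dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot compare an empty TR table")
    if test == "ks":
        res = stats.ks_2samp(a, b, method="asymp")
        statistic, p = float(res.statistic), float(res.pvalue)
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        statistic, p = float(res.statistic / (a.size * b.size)), float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return TRComparison(statistic, p, a.size, b.size, _ecdf(a), _ecdf(b))
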