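"""Reference-point signal matrices and aggregate (metagene) statistics.

A :class:`ProfileMatrix` holds binned signal around many reference points
(TSSs or feature centers) for one replicate. Aggregate profiles follow the
two-step normalization used for ChIP/MNase metagenes: each location's row
is scaled to its own mean, the per-replicate column mean is then scaled to
the mean of the outermost flanks ("enrichment over baseline"), and the
final profile averages replicates. Confidence intervals come from a
location-level bootstrap with the normalization repeated per iteration;
empirical p-values compare two conditions at a chosen bin. Nascent RNA
profiles skip the normalizations and use a plain +/- 1.96 s.e.m. interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genome import CoverageTrack, GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

#: outermost flank span (bp) on each side used as the profile baseline;
#: at the default +/-1500 bp window this is positions -1500..-1450 and
#: +1450..+1500.
BASELINE_FLANK_BP = 50

Reference = tuple[str, int, str]  # (chrom, position, strand)


def as_reference(obj, mode: str) -> Reference:
    """Extract a (chrom, position, strand) reference point.

    ``mode='tss'`` uses the strand-aware 5' end; ``mode='center'`` the
    midpoint. Tuples pass through untouched; strand ``'.'`` profiles as +.
    """
    if isinstance(obj, GeneModel):
        pos = obj.tss if mode == "tss" else (obj.start + obj.end) // 2
        return (obj.chrom, pos, obj.strand)
    if isinstance(obj, GenomicInterval):
        if mode == "center":
            pos = obj.midpoint
        else:
            pos = obj.start if obj.strand != "-" else obj.end - 1
        return (obj.chrom, pos, obj.strand if obj.strand in "+-" else "+")
    chrom, pos, strand = obj
    return (chrom, int(pos), strand if strand in "+-" else "+")


@dataclass
class ProfileMatrix:
    """locations x bins signal matrix around reference points, one replicate."""

    replicate_id: str
    references: list[Reference]
    values: np.ndarray
    binsize: int = 5
    upstream: int = 1500
    downstream: int = 1500
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n_bins = (self.upstream + self.downstream) // self.binsize
        if self.values.ndim != 2 or self.values.shape != (len(self.references), n_bins):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.references)} references x {n_bins} bins"
            )

    @property
    def n_locations(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def geometry(self) -> tuple[int, int, int]:
        return (self.binsize, self.upstream, self.downstream)

    def bin_centers(self) -> np.ndarray:
        """Bin-center offsets in bp relative to the reference point."""
        return -self.upstream + (np.arange(self.n_bins) + 0.5) * self.binsize


@dataclass
class AggregateProfile:
    """Mean profile with a per-bin confidence band."""

    mean: np.ndarray
    ci_low: np.ndarray | None
    ci_high: np.ndarray | None
    n_locations: int
    n_replicates: int
    method: str  # bootstrap | sem | none
    normalization: str  # rowwise+baseline | none

    def to_rows(self, bin_centers: np.ndarray):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_center_bp": bin_centers,
                "mean": self.mean,
                "ci_low": self.ci_low if self.ci_low is not None else np.nan,
                "ci_high": self.ci_high if self.ci_high is not None else np.nan,
            }
        )


@dataclass
class CenterTest:
    """Empirical bootstrap test of a condition difference at one bin."""

    position: int
    observed_diff: float
    p: float
    iterations: int


# ---------------------------------------------------------------------------
# matrix construction

def compute_matrix(track: CoverageTrack, refs: Sequence, mode: str = "center",
                   upstream: int = 1500, downstream: int = 1500,
                   binsize: int = 5, replicate_id: str = "") -> ProfileMatrix:
    """Average track signal into bins around each reference point.

    Bin ``j`` covers transcription-direction offsets
    ``[-upstream + j*binsize, -upstream + (j+1)*binsize)``; minus-strand
    references are read rightward-to-leftward so upstream always means
    upstream of transcription. Bases beyond chromosome ends contribute 0
    (missing data as zero).
    """
    if not len(refs):
        raise ValueError("no reference points given")
    if (upstream + downstream) % binsize:
        raise ValueError("window size must be a multiple of binsize")
    points = [as_reference(r, mode) for r in refs]
    n_bins = (upstream + downstream) // binsize
    offsets = np.arange(-upstream, downstream, dtype=np.int64)
    rows = np.zeros((len(points), n_bins))
    for i, (chrom, pos, strand) in enumerate(points):
        if chrom not in track.genome:
            raise ValueError(f"reference on unknown chromosome {chrom!r}")
        length = track.genome.length(chrom)
        bases = pos + offsets if strand == "+" else pos - offsets
        valid = (bases >= 0) & (bases < length)
        vals = np.zeros(offsets.size)
        idx = bases[valid] // track.binsize
        vals[valid] = track.data[chrom][idx]
        rows[i] = vals.reshape(n_bins, binsize).mean(axis=1)
    return ProfileMatrix(replicate_id, points, rows, binsize, upstream, downstream)


# ---------------------------------------------------------------------------
# normalization

def rowwise_normalize(m: ProfileMatrix) -> ProfileMatrix:
    """Scale each location's row by its own mean; drop zero-mean rows.

    Surviving rows have mean exactly 1; the number of dropped locations is
    recorded on the result and logged.
    """
    means = m.values.mean(axis=1)
    keep = means != 0
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError("all rows have zero mean; nothing to normalize")
    if n_dropped:
        logger.info("rowwise_normalize: dropped %d zero-signal locations", n_dropped)
    values = m.values[keep] / means[keep, None]
    refs = [r for r, k in zip(m.references, keep) if k]
    return ProfileMatrix(m.replicate_id, refs, values, m.binsize, m.upstream,
                         m.downstream, m.n_dropped + n_dropped)


def flank_indices(n_bins: int, binsize: int, upstream: int, downstream: int,
                  flank_bp: int = BASELINE_FLANK_BP) -> np.ndarray:
    """Bin indices of the outermost ``flank_bp`` on each side of the window."""
    if flank_bp % binsize:
        raise ValueError("flank span must be a multiple of binsize")
    k = flank_bp // binsize
    if upstream < flank_bp or downstream < flank_bp:
        raise ValueError(f"window too small for {flank_bp}-bp baseline flanks")
    return np.concatenate([np.arange(k), np.arange(n_bins - k, n_bins)])


def baseline_normalize(profile: np.ndarray, binsize: int, upstream: int,
                       downstream: int, flank_bp: int = BASELINE_FLANK_BP) -> np.ndarray:
    """Divide a profile by its mean over the outermost flanks.

    With the default +/-1500 bp window at 5-bp bins the flanks are the
    first and last 10 bins (positions -1500..-1450 and +1450..+1500); the
    result reads as enrichment over local baseline, flank mean 1.
    """
    profile = np.asarray(profile, dtype=np.float64)
    idx = flank_indices(profile.size, binsize, upstream, downstream, flank_bp)
    fm = profile[idx].mean()
    if fm == 0:
        raise ValueError("flank mean is zero; baseline undefined")
    return profile / fm


def _check_geometry(matrices: Sequence[ProfileMatrix]) -> tuple[int, int, int]:
    if not matrices:
        raise ValueError("no matrices given")
    geom = matrices[0].geometry()
    for m in matrices[1:]:
        if m.geometry() != geom:
            raise ValueError(f"geometry mismatch: {m.geometry()} vs {geom}")
    return geom


def _replicate_profile(m: ProfileMatrix, normalized: bool) -> np.ndarray:
    if normalized:
        m = rowwise_normalize(m)
        prof = m.values.mean(axis=0)
        return baseline_normalize(prof, m.binsize, m.upstream, m.downstream)
    return m.values.mean(axis=0)


def aggregate_replicates(matrices: Sequence[ProfileMatrix],
                         normalized: bool = True) -> AggregateProfile:
    """Mean aggregate profile across replicates (no confidence band).

    Per replicate: rows scaled to their own mean, column means taken, then
    flank-baseline scaling — when ``normalized`` — and finally the
    unweighted mean over replicates.
    """
    _check_geometry(matrices)
    profs = np.stack([_replicate_profile(m, normalized) for m in matrices])
    return AggregateProfile(
        mean=profs.mean(axis=0), ci_low=None, ci_high=None,
        n_locations=matrices[0].n_locations, n_replicates=len(matrices),
        method="none", normalization="rowwise+baseline" if normalized else "none",
    )


# ---------------------------------------------------------------------------
# bootstrap inference

def _resample_weights(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    """Row weights of `size` bootstrap resamples of n rows with replacement.

    Resampling rows with replacement and averaging equals weighting rows by
    multinomial counts / n, which vectorizes over iterations.
    """
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=size)
    return counts.astype(np.float64) / n


def _bootstrap_profiles(matrices: Sequence[ProfileMatrix], iterations: int,
                        rng: np.random.Generator, normalized: bool,
                        columns: np.ndarray | None = None) -> np.ndarray:
    """(iterations x bins) matrix of replicate-averaged bootstrap profiles.

    Per iteration, locations are resampled with replacement within each
    replicate and the normalization pipeline is re-run on the resample.
    ``columns`` restricts output to a bin subset (the flanks needed for the
    baseline are always included internally).
    """
    geom = _check_geometry(matrices)
    binsize, upstream, downstream = geom
    n_bins = matrices[0].n_bins
    fidx = flank_indices(n_bins, binsize, upstream, downstream) if normalized else None

    if columns is None:
        out_cols = np.arange(n_bins)
        gather = None
    else:
        out_cols = np.asarray(columns)
        gather = np.concatenate([fidx, out_cols]) if normalized else out_cols

    acc = None
    for m in matrices:
        vals = rowwise_normalize(m).values if normalized else m.values
        if gather is not None:
            vals = vals[:, gather]
        n = vals.shape[0]
        # chunk iterations so the weight matrix stays small
        chunk = max(1, min(iterations, int(2e6) // max(n, 1)))
        profs = np.empty((iterations, vals.shape[1]))
        done = 0
        while done < iterations:
            b = min(chunk, iterations - done)
            w = _resample_weights(rng, n, b)
            profs[done:done + b] = w @ vals
            done += b
        if normalized:
            if gather is None:
                fm = profs[:, fidx].mean(axis=1)
            else:
                fm = profs[:, : fidx.size].mean(axis=1)
                profs = profs[:, fidx.size:]
            # a resample with an all-zero flank has no baseline: mark NaN
            fm[fm == 0] = np.nan
            with np.errstate(invalid="ignore"):
                profs = profs / fm[:, None]
        acc = profs if acc is None else acc + profs
    return acc / len(matrices)


def bootstrap_ci(matrices: Sequence[ProfileMatrix], iterations: int = 5000,
                 alpha: float = 0.05, seed=None,
                 normalized: bool = True) -> AggregateProfile:
    """Aggregate profile with a percentile bootstrap confidence band.

    Locations (matrix rows) are the resampling unit, drawn with replacement
    within each replicate; the row/baseline normalization is repeated
    independently per iteration; the band is the empirical
    ``alpha/2 .. 1-alpha/2`` percentile range of the replicate-averaged
    bootstrap profiles. The reported mean is the non-resampled estimate.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    point = aggregate_replicates(matrices, normalized)
    rng = np.random.default_rng(seed)
    boot = _bootstrap_profiles(matrices, iterations, rng, normalized)
    n_bad = int(np.isnan(boot[:, 0]).sum())
    if n_bad:
        logger.info("bootstrap_ci: %d/%d iterations had no baseline signal",
                    n_bad, iterations)
    lo = np.nanquantile(boot, alpha / 2, axis=0)
    hi = np.nanquantile(boot, 1 - alpha / 2, axis=0)
    return AggregateProfile(
        mean=point.mean, ci_low=lo, ci_high=hi,
        n_locations=point.n_locations, n_replicates=len(matrices),
        method="bootstrap", normalization=point.normalization,
    )


def empirical_pvalue(matrices_a: Sequence[ProfileMatrix],
                     matrices_0: Sequence[ProfileMatrix],
                     position: int | None = None, iterations: int = 5000,
                     seed=None, normalized: bool = True) -> CenterTest:
    """Two-sided empirical bootstrap p-value for a condition difference at a bin.

    Both conditions are resampled independently per iteration; with
    ``delta_b`` the bootstrap difference at ``position`` (default: the
    central / reference-point bin), the add-one-smoothed p-value is
    ``min(1, 2 * min((1+#{delta<=0})/(B+1), (1+#{delta>=0})/(B+1)))``,
    so p >= 1/(B+1) always.
    """
    geom_a = _check_geometry(matrices_a)
    geom_0 = _check_geometry(matrices_0)
    if geom_a != geom_0:
        raise ValueError("conditions have different matrix geometry")
    n_bins = matrices_a[0].n_bins
    if position is None:
        position = matrices_a[0].upstream // matrices_a[0].binsize
    if not 0 <= position < n_bins:
        raise ValueError(f"position {position} outside 0..{n_bins - 1}")
    obs_a = aggregate_replicates(matrices_a, normalized).mean[position]
    obs_0 = aggregate_replicates(matrices_0, normalized).mean[position]
    rng = np.random.default_rng(seed)
    cols = np.array([position])
    boot_a = _bootstrap_profiles(matrices_a, iterations, rng, normalized, columns=cols)[:, 0]
    boot_0 = _bootstrap_profiles(matrices_0, iterations, rng, normalized, columns=cols)[:, 0]
    delta = boot_a - boot_0
    delta = delta[np.isfinite(delta)]  # drop baseline-degenerate iterations
    b = delta.size
    if b == 0:
        raise ValueError("no valid bootstrap iterations (baseline always zero)")
    p_low = (1 + np.sum(delta <= 0)) / (b + 1)
    p_high = (1 + np.sum(delta >= 0)) / (b + 1)
    p = min(1.0, 2 * min(p_low, p_high))
    return CenterTest(position=position, observed_diff=float(obs_a - obs_0),
                      p=float(p), iterations=b)


def sem_profile(matrices: Sequence[ProfileMatrix]) -> AggregateProfile:
    """Unnormalized replicate-mean profile with a +/- 1.96 s.e.m. band.

    Used for nascent RNA metagenes, which skip the row and baseline
    normalizations; needs >= 2 replicates for the s.e.m. to exist.
    """
    _check_geometry(matrices)
    if len(matrices) < 2:
        raise ValueError("s.e.m. needs at least 2 replicates")
    profs = np.stack([m.values.mean(axis=0) for m in matrices])
    mean = profs.mean(axis=0)
    sem = profs.std(axis=0, ddof=1) / np.sqrt(len(matrices))
    return AggregateProfile(
        mean=mean, ci_low=mean - 1.96 * sem, ci_high=mean + 1.96 * sem,
        n_locations=matrices[0].n_locations, n_replicates=len(matrices),
        method="sem", normalization="none",
    )
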