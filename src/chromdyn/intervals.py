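"""Peak-set algebra and regulatory-element classification.

Operations defined here reproduce the peak-processing conventions of
ChIP-seq studies: a co-bound "union" of two factors' peaks requiring
cross-set overlap, a replicate consensus (diffBind-like: a core supported
by >= min_support replicates, extended to the union of contributing
intervals), an all-datasets intersection filter, ENCODE-blacklist removal,
enhancer/promoter classification from histone-mark peak sets, and
midpoint-assigned fragment counts with depth-normalized input subtraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import FragmentSet, GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_VOCABULARY = ("active_enhancer", "inactive_enhancer", "promoter", "other")

#: promoter window around the TSS used for region classification,
#: (upstream, downstream) bp in the transcription direction.
DEFAULT_PROMOTER_WINDOW = (2000, 500)


@dataclass
class LabeledIntervalSet:
    """Sorted intervals whose labels come from a declared vocabulary."""

    intervals: list[GenomicInterval]
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        for iv in self.intervals:
            if iv.label is not None and iv.label not in self.vocabulary:
                raise ValueError(f"label {iv.label!r} not in vocabulary {self.vocabulary}")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def with_label(self, label: str) -> list[GenomicInterval]:
        return [iv for iv in self.intervals if iv.label == label]

    def label_counts(self) -> dict[str, int]:
        counts = {v: 0 for v in self.vocabulary}
        for iv in self.intervals:
            counts[iv.label] = counts.get(iv.label, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# overlap machinery

def _group(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    groups: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        groups.setdefault(iv.chrom, []).append(iv)
    for ivs in groups.values():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
    return groups


class OverlapIndex:
    """Per-chromosome overlap queries on a static interval set.

    Intervals are sorted by start; a prefix running-maximum of ends answers
    "does anything overlap [s, e)?" in O(log n).
    """

    def __init__(self, intervals: Iterable[GenomicInterval]) -> None:
        self._starts: dict[str, np.ndarray] = {}
        self._maxend: dict[str, np.ndarray] = {}
        for chrom, ivs in _group(intervals).items():
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            self._starts[chrom] = starts
            self._maxend[chrom] = np.maximum.accumulate(ends)

    def overlaps(self, iv: GenomicInterval) -> bool:
        starts = self._starts.get(iv.chrom)
        if starts is None:
            return False
        i = int(np.searchsorted(starts, iv.end, side="left"))
        return i > 0 and int(self._maxend[iv.chrom][i - 1]) > iv.start


def _merge_touching(spans: list[tuple[str, int, int]]) -> list[GenomicInterval]:
    """Merge spans that overlap or abut, per chromosome."""
    out: list[GenomicInterval] = []
    spans = sorted(spans)
    for chrom, start, end in spans:
        if out and out[-1].chrom == chrom and start <= out[-1].end:
            out[-1].end = max(out[-1].end, end)
        else:
            out.append(GenomicInterval(chrom, start, end))
    return out


# ---------------------------------------------------------------------------
# set operations

def cobound_union(a: Iterable[GenomicInterval], b: Iterable[GenomicInterval],
                  min_overlap: int = 1) -> list[GenomicInterval]:
    """Co-bound union: merged spans of cross-set pairs overlapping >= min_overlap bp.

    Every pair (x in a, y in b) overlapping by at least ``min_overlap`` bp
    emits the union span of x and y; emitted spans that touch are merged
    transitively. Intervals with no cross-set partner are excluded — the
    result covers only regions bound in both sets.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    ga, gb = _group(a), _group(b)
    spans: list[tuple[str, int, int]] = []
    for chrom in set(ga) & set(gb):
        ys = gb[chrom]
        y_starts = np.array([y.start for y in ys], dtype=np.int64)
        for x in ga[chrom]:
            # candidates: y.start < x.end - (min_overlap - 1)
            hi = int(np.searchsorted(y_starts, x.end - min_overlap, side="right"))
            for y in ys[:hi]:
                if min(x.end, y.end) - max(x.start, y.start) >= min_overlap:
                    spans.append((chrom, min(x.start, y.start), max(x.end, y.end)))
    return _merge_touching(spans)


def plain_union(a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
                ) -> list[GenomicInterval]:
    """Ordinary merged union of both sets (alternative to :func:`cobound_union`)."""
    spans = [(iv.chrom, iv.start, iv.end) for ivs in (a, b) for iv in ivs]
    return _merge_touching(spans)


def consensus(replicate_sets: Sequence[Iterable[GenomicInterval]],
              min_support: int = 2) -> list[GenomicInterval]:
    """Replicate-consensus peaks: cores covered by >= min_support replicates,
    extended to the union span of all intervals contributing to the core.

    Support at a base counts distinct replicate sets (two intervals of one
    replicate count once). Extended spans that then overlap are merged.
    """
    sets = [list(s) for s in replicate_sets]
    if min_support > len(sets):
        raise ValueError(f"min_support {min_support} exceeds number of sets {len(sets)}")
    all_ivs = [iv for s in sets for iv in s]
    groups = _group(all_ivs)
    spans: list[tuple[str, int, int]] = []
    for chrom, ivs in groups.items():
        # coordinate-compressed per-set coverage -> per-segment support
        points = sorted({p for iv in ivs for p in (iv.start, iv.end)})
        if len(points) < 2:
            continue
        pts = np.array(points, dtype=np.int64)
        support = np.zeros(len(pts) - 1, dtype=np.int32)
        for s in sets:
            covered = np.zeros(len(pts) - 1, dtype=bool)
            for iv in s:
                if iv.chrom != chrom:
                    continue
                i0 = int(np.searchsorted(pts, iv.start))
                i1 = int(np.searchsorted(pts, iv.end))
                covered[i0:i1] = True
            support += covered
        core_segments = support >= min_support
        # maximal runs of consecutive supported segments that are contiguous in bp
        cores: list[tuple[int, int]] = []
        for i in np.flatnonzero(core_segments):
            seg = (int(pts[i]), int(pts[i + 1]))
            if cores and cores[-1][1] == seg[0]:
                cores[-1] = (cores[-1][0], seg[1])
            else:
                cores.append(seg)
        for c0, c1 in cores:
            lo, hi = c0, c1
            for iv in ivs:
                if iv.start < c1 and iv.end > c0:
                    lo, hi = min(lo, iv.start), max(hi, iv.end)
            spans.append((chrom, lo, hi))
    return _merge_touching(spans)


def intersect_all(sets: Sequence[Iterable[GenomicInterval]]) -> list[GenomicInterval]:
    """Keep first-set intervals overlapped (>=1 bp) by every other set."""
    if len(sets) == 0:
        raise ValueError("need at least one interval set")
    first = sorted(sets[0], key=lambda iv: (iv.chrom, iv.start, iv.end))
    indexes = [OverlapIndex(s) for s in sets[1:]]
    return [iv for iv in first if all(ix.overlaps(iv) for ix in indexes)]


def filter_blacklist(peaks: Iterable[GenomicInterval],
                     blacklist: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Drop peaks overlapping any blacklisted region by >= 1 bp (no trimming)."""
    index = OverlapIndex(blacklist)
    kept = [iv for iv in peaks if not index.overlaps(iv)]
    return sorted(kept, key=lambda iv: (iv.chrom, iv.start, iv.end))


# ---------------------------------------------------------------------------
# classification

ENHANCER_VOCABULARY = ("active_enhancer", "inactive_enhancer", "h3k4me3_overlap")


def classify_enhancers(h3k4me1: Iterable[GenomicInterval],
                       h3k4me3: Iterable[GenomicInterval],
                       h3k27ac: Iterable[GenomicInterval],
                       p300: Iterable[GenomicInterval]) -> LabeledIntervalSet:
    """Classify H3K4me1 regions into active/inactive enhancers.

    A region overlapping H3K4me3 is excluded from the enhancer classes
    (labeled ``h3k4me3_overlap``); otherwise it is an active enhancer when
    it overlaps both H3K27ac and p300, else an inactive enhancer. The three
    labels partition the input.
    """
    ix_me3 = OverlapIndex(h3k4me3)
    ix_ac = OverlapIndex(h3k27ac)
    ix_p300 = OverlapIndex(p300)
    labeled = []
    for iv in h3k4me1:
        if ix_me3.overlaps(iv):
            label = "h3k4me3_overlap"
        elif ix_ac.overlaps(iv) and ix_p300.overlaps(iv):
            label = "active_enhancer"
        else:
            label = "inactive_enhancer"
        labeled.append(GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand, label, iv.score))
    return LabeledIntervalSet(labeled, ENHANCER_VOCABULARY)


def tss_window(gene: GeneModel, upstream: int, downstream: int) -> GenomicInterval | None:
    """Strand-aware promoter window around the TSS, clipped at position 0."""
    if gene.strand == "+":
        lo, hi = gene.tss - upstream, gene.tss + downstream
    else:
        lo, hi = gene.tss - downstream, gene.tss + upstream
    lo = max(lo, 0)
    if hi <= lo:
        return None
    return GenomicInterval(gene.chrom, lo, hi, gene.strand)


def classify_regions(peaks: Iterable[GenomicInterval], genes: Iterable[GeneModel],
                     enhancers: LabeledIntervalSet,
                     promoter_window: tuple[int, int] = DEFAULT_PROMOTER_WINDOW
                     ) -> LabeledIntervalSet:
    """Label each peak promoter / active_enhancer / inactive_enhancer / other.

    Precedence promoter > active_enhancer > inactive_enhancer > other:
    promoters are the most specific annotation when a peak overlaps several.
    """
    up, down = promoter_window
    windows = [w for g in genes if (w := tss_window(g, up, down)) is not None]
    ix_prom = OverlapIndex(windows)
    ix_active = OverlapIndex(enhancers.with_label("active_enhancer"))
    ix_inactive = OverlapIndex(enhancers.with_label("inactive_enhancer"))
    labeled = []
    for iv in peaks:
        if ix_prom.overlaps(iv):
            label = "promoter"
        elif ix_active.overlaps(iv):
            label = "active_enhancer"
        elif ix_inactive.overlaps(iv):
            label = "inactive_enhancer"
        else:
            label = "other"
        labeled.append(GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand, label, iv.score))
    return LabeledIntervalSet(labeled, DEFAULT_VOCABULARY)


# ---------------------------------------------------------------------------
# counting

def count_in_intervals(frags: FragmentSet, intervals: Sequence[GenomicInterval],
                       input_frags: FragmentSet | None = None) -> pd.DataFrame:
    """Midpoint-assigned fragment counts per interval, with optional
    depth-normalized input subtraction.

    A fragment belongs to an interval iff its midpoint lies inside the
    half-open span, which keeps counts additive across adjacent windows.
    The subtracted count is ``max(0, raw - input_raw * depth_ratio)`` with
    ``depth_ratio = library_size / input_library_size``.
    """
    intervals = list(intervals)
    raw = _midpoint_counts(frags, intervals)
    table = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "count": raw,
        }
    )
    if input_frags is not None:
        input_raw = _midpoint_counts(input_frags, intervals)
        if input_frags.library_size == 0:
            raise ValueError("input library is empty; cannot depth-normalize")
        ratio = frags.library_size / input_frags.library_size
        table["input_count"] = input_raw
        table["subtracted"] = np.maximum(0.0, raw - input_raw * ratio)
    return table


def _midpoint_counts(frags: FragmentSet, intervals: Sequence[GenomicInterval]) -> np.ndarray:
    counts = np.zeros(len(intervals), dtype=np.int64)
    by_chrom = {c: np.sort((s + e) // 2) for c, (s, e, _) in frags.by_chrom().items()}
    for i, iv in enumerate(intervals):
        mids = by_chrom.get(iv.chrom)
        if mids is None:
            continue
        counts[i] = np.searchsorted(mids, iv.end, "left") - np.searchsorted(mids, iv.start, "left")
    return counts
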