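"""Peak-set algebra against brute-force oracles, plus classification rules."""

import numpy as np
import pytest

from chromdyn import (
    FragmentSet,
    GeneModel,
    GenomicInterval,
    LabeledIntervalSet,
    classify_enhancers,
    classify_regions,
    cobound_union,
    consensus,
    count_in_intervals,
    filter_blacklist,
    intersect_all,
)

from conftest import random_intervals


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def spans(intervals):
    return [(i.chrom, i.start, i.end) for i in intervals]


# ---------------------------------------------------------------------------
# oracles: per-base painting / all-pairs scans, deliberately naive

MAX_COORD = 4200


def paint(spans_list):
    """Paint (chrom, start, end) spans per-base and read back maximal runs."""
    grids = {}
    for chrom, start, end in spans_list:
        grids.setdefault(chrom, np.zeros(MAX_COORD, dtype=bool))[start:end] = True
    out = []
    for chrom in sorted(grids):
        g = grids[chrom]
        pos = 0
        while pos < MAX_COORD:
            if g[pos]:
                end = pos
                while end < MAX_COORD and g[end]:
                    end += 1
                out.append((chrom, pos, end))
                pos = end
            else:
                pos += 1
    return out


def oracle_cobound(a, b, min_overlap=1):
    pairs = []
    for x in a:
        for y in b:
            if x.chrom == y.chrom and \
                    min(x.end, y.end) - max(x.start, y.start) >= min_overlap:
                pairs.append((x.chrom, min(x.start, y.start), max(x.end, y.end)))
    return paint(pairs)


def oracle_consensus(sets, min_support=2):
    support = {}
    for s in sets:
        covered = {}
        for i in s:
            covered.setdefault(i.chrom, np.zeros(MAX_COORD, dtype=bool))[i.start:i.end] = True
        for chrom, g in covered.items():
            support.setdefault(chrom, np.zeros(MAX_COORD, dtype=int))
            support[chrom] += g
    extended = []
    for chrom, sup in support.items():
        core = paint([(chrom, s, e) for (c, s, e) in
                      [(chrom, i, i + 1) for i in np.flatnonzero(sup >= min_support)]])
        for c, s, e in core:
            lo, hi = s, e
            for st in sets:
                for i in st:
                    if i.chrom == chrom and i.start < e and i.end > s:
                        lo, hi = min(lo, i.start), max(hi, i.end)
            extended.append((chrom, lo, hi))
    return paint(extended)


def oracle_intersect(sets):
    out = []
    for x in sorted(sets[0], key=lambda i: (i.chrom, i.start, i.end)):
        if all(any(x.chrom == y.chrom and min(x.end, y.end) > max(x.start, y.start)
                   for y in s) for s in sets[1:]):
            out.append((x.chrom, x.start, x.end))
    return out


def oracle_blacklist(peaks, blacklist):
    return [(p.chrom, p.start, p.end)
            for p in sorted(peaks, key=lambda i: (i.chrom, i.start, i.end))
            if not any(p.chrom == b.chrom and min(p.end, b.end) > max(p.start, b.start)
                       for b in blacklist)]


def oracle_midpoint_counts(frags, intervals):
    counts = []
    for region in intervals:
        c = 0
        for f in frags:
            mid = (f.start + f.end) // 2
            if f.chrom == region.chrom and region.start <= mid < region.end:
                c += 1
        counts.append(c)
    return counts


# ---------------------------------------------------------------------------

class TestCoboundUnion:
    def test_single_overlapping_pair_merges(self):
        assert spans(cobound_union([iv(0, 100)], [iv(50, 150)])) == [("chr1", 0, 150)]

    def test_unpartnered_intervals_excluded(self):
        got = cobound_union([iv(0, 100), iv(200, 300)], [iv(50, 150)])
        assert spans(got) == [("chr1", 0, 150)]

    def test_min_overlap_threshold(self):
        assert cobound_union([iv(0, 100)], [iv(95, 200)], min_overlap=10) == []
        assert spans(cobound_union([iv(0, 100)], [iv(90, 200)], min_overlap=10)) == \
            [("chr1", 0, 200)]

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_intervals(rng, int(rng.integers(0, 60)))
        b = random_intervals(rng, int(rng.integers(0, 60)))
        assert spans(cobound_union(a, b)) == oracle_cobound(a, b)


class TestConsensus:
    def test_interval_in_all_replicates_kept(self):
        reps = [[iv(10, 20)], [iv(10, 20)], [iv(10, 20)]]
        assert spans(consensus(reps)) == [("chr1", 10, 20)]

    def test_no_region_with_enough_support_gives_empty(self):
        assert consensus([[iv(0, 10)], [iv(50, 60)], []], min_support=2) == []

    def test_span_extends_to_contributing_interval_union(self):
        reps = [[iv(0, 100)], [iv(80, 200)]]
        assert spans(consensus(reps, 2)) == [("chr1", 0, 200)]

    def test_min_support_exceeding_sets_rejected(self):
        with pytest.raises(ValueError):
            consensus([[iv(0, 10)]], min_support=2)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        sets = [random_intervals(rng, int(rng.integers(0, 40)))
                for _ in range(int(rng.integers(2, 5)))]
        assert spans(consensus(sets, 2)) == oracle_consensus(sets, 2)


class TestIntersectAll:
    def test_single_set_is_identity(self):
        s = [iv(0, 10), iv(20, 30)]
        assert spans(intersect_all([s])) == spans(s)

    def test_disjoint_sets_give_empty(self):
        assert intersect_all([[iv(0, 100)], [iv(200, 300)]]) == []

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_filter(self, seed):
        rng = np.random.default_rng(200 + seed)
        sets = [random_intervals(rng, int(rng.integers(1, 50)))
                for _ in range(int(rng.integers(1, 4)))]
        assert spans(intersect_all(sets)) == oracle_intersect(sets)


class TestFilterBlacklist:
    def test_empty_blacklist_is_identity(self):
        peaks = [iv(0, 10)]
        assert spans(filter_blacklist(peaks, [])) == spans(peaks)

    def test_single_bp_overlap_removes_peak(self):
        assert filter_blacklist([iv(0, 100)], [iv(99, 200)]) == []

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(300 + seed)
        peaks = random_intervals(rng, int(rng.integers(0, 60)))
        blacklist = random_intervals(rng, int(rng.integers(0, 30)))
        assert spans(filter_blacklist(peaks, blacklist)) == \
            oracle_blacklist(peaks, blacklist)


class TestClassifyEnhancers:
    def test_three_way_classification(self):
        me1 = [iv(0, 100), iv(200, 300), iv(400, 500)]
        me3 = [iv(50, 60)]          # marks first region as promoter-like
        ac = [iv(250, 260), iv(450, 460)]
        p300 = [iv(250, 260)]       # only second region has both marks
        result = classify_enhancers(me1, me3, ac, p300)
        assert [r.label for r in result] == [
            "h3k4me3_overlap", "active_enhancer", "inactive_enhancer"]

    @pytest.mark.parametrize("seed", range(10))
    def test_labels_partition_input(self, seed):
        rng = np.random.default_rng(seed)
        me1 = random_intervals(rng, 50)
        result = classify_enhancers(me1, random_intervals(rng, 20),
                                    random_intervals(rng, 20),
                                    random_intervals(rng, 20))
        counts = result.label_counts()
        assert sum(counts.values()) == len(me1)


class TestClassifyRegions:
    GENES = [GeneModel("g1", "chr1", "+", 10_000, 15_000)]

    def test_promoter_takes_precedence_over_enhancer(self):
        enh = LabeledIntervalSet(
            [GenomicInterval("chr1", 9_000, 11_000, label="active_enhancer")])
        # peak overlaps both the TSS window (8000..10500) and the enhancer
        result = classify_regions([iv(9_500, 9_800)], self.GENES, enh)
        assert result.intervals[0].label == "promoter"

    def test_unmatched_peak_is_other(self):
        result = classify_regions([iv(40_000, 40_100)], self.GENES,
                                  LabeledIntervalSet([]))
        assert result.intervals[0].label == "other"

    def test_minus_strand_tss_window(self):
        genes = [GeneModel("g2", "chr1", "-", 10_000, 15_000)]  # TSS 14999
        # window [tss-500, tss+2000) = [14499, 16999)
        result = classify_regions([iv(16_000, 16_100)], genes, LabeledIntervalSet([]))
        assert result.intervals[0].label == "promoter"

    def test_label_counts_sum_to_peak_count(self):
        rng = np.random.default_rng(0)
        peaks = random_intervals(rng, 80, max_pos=20_000, max_len=500)
        result = classify_regions(peaks, self.GENES, LabeledIntervalSet([]))
        assert sum(result.label_counts().values()) == len(peaks)


class TestCountInIntervals:
    def test_midpoint_boundary_half_open(self):
        frags = FragmentSet("x", ["chr1", "chr1"], [90, 190], [110, 210], ["+", "+"])
        table = count_in_intervals(frags, [iv(100, 200)])
        # midpoints 100 (inside) and 200 (outside, half-open)
        assert table["count"].tolist() == [1]

    def test_input_subtraction_with_equal_depths(self):
        chip = FragmentSet("c", *_midpoint_cols([150] * 10))
        inp = FragmentSet("i", *_midpoint_cols([150] * 4 + [5000] * 6))
        table = count_in_intervals(chip, [iv(100, 200)], inp)
        assert table["count"].tolist() == [10]
        assert table["subtracted"].tolist() == [6.0]

    def test_subtracted_counts_floored_at_zero(self):
        chip = FragmentSet("c", *_midpoint_cols([150] * 2 + [5000] * 8))
        inp = FragmentSet("i", *_midpoint_cols([150] * 10))
        table = count_in_intervals(chip, [iv(100, 200)], inp)
        assert table["subtracted"].tolist() == [0.0]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_midpoints(self, seed):
        rng = np.random.default_rng(400 + seed)
        n = int(rng.integers(1, 200))
        starts = rng.integers(0, 3000, n)
        frags = FragmentSet("x", np.full(n, "chr1", dtype=object), starts,
                            starts + rng.integers(1, 200, n),
                            np.full(n, "+"))
        regions = random_intervals(rng, 30, chroms=("chr1",))
        table = count_in_intervals(frags, regions)
        assert table["count"].tolist() == oracle_midpoint_counts(frags, regions)


def _midpoint_cols(mids):
    n = len(mids)
    starts = [m - 10 for m in mids]
    ends = [m + 10 for m in mids]
    return np.full(n, "chr1", dtype=object), starts, ends, ["+"] * n
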