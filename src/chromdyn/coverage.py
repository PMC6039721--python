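"""Fragment libraries -> normalized coverage tracks.

The pipeline mirrors standard ChIP-seq track generation: fragments are
optionally extended from their 5' end (or re-centered) to a nominal
fragment length, binned as mean per-base coverage, scaled to 1x genome
coverage (RPGC), and then combined by depth-normalized input subtraction
or by ratio against a reference track (e.g. histone H3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import CoverageTrack, FragmentSet, GenomeModel

#: nominal fragment lengths used for extension: transcription-factor ChIP
#: libraries vs PolII ChIP libraries.
FRAGMENT_LENGTH_TF = 200
FRAGMENT_LENGTH_POLII = 250


@dataclass(frozen=True)
class ExtensionRule:
    """How raw fragments are transformed before binning.

    ``as_is`` leaves spans untouched; ``extend_to`` spans ``fragment_length``
    bp from the fragment's 5' end in the strand direction (paired-end style
    extension); ``center_at`` places a ``fragment_length``-bp window on the
    fragment midpoint (single-end centering).
    """

    mode: str = "as_is"
    fragment_length: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("as_is", "extend_to", "center_at"):
            raise ValueError(f"unknown extension mode {self.mode!r}")
        if self.mode != "as_is" and self.fragment_length <= 0:
            raise ValueError("fragment_length must be positive for extension modes")


def transform_fragments(starts: np.ndarray, ends: np.ndarray, strands: np.ndarray,
                        rule: ExtensionRule, chrom_length: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Apply an extension rule and clip to ``[0, chrom_length)``.

    Fragments running past a chromosome end are clipped, not dropped, so
    depth is preserved near the boundaries of small chromosomes.
    """
    if rule.mode == "as_is":
        s, e = starts.copy(), ends.copy()
    elif rule.mode == "extend_to":
        minus = strands == "-"
        s = np.where(minus, ends - rule.fragment_length, starts)
        e = np.where(minus, ends, starts + rule.fragment_length)
    else:  # center_at
        mid = (starts + ends) // 2
        s = mid - rule.fragment_length // 2
        e = s + rule.fragment_length
    s = np.clip(s, 0, chrom_length)
    e = np.clip(e, 0, chrom_length)
    return s.astype(np.int64), e.astype(np.int64)


def fragments_to_coverage(frags: FragmentSet, genome: GenomeModel, binsize: int = 1,
                          rule: ExtensionRule = ExtensionRule()) -> CoverageTrack:
    """Bin transformed fragments into mean per-base coverage.

    Each bin's value is the mean per-base count of overlapping transformed
    fragments over the bases the bin actually covers (the last bin of a
    chromosome may be partial).
    """
    if binsize < 1:
        raise ValueError("binsize must be >= 1")
    track = CoverageTrack.zeros(genome, binsize)
    for chrom, (starts, ends, strands) in frags.by_chrom().items():
        if chrom not in genome:
            raise ValueError(f"fragment on unknown chromosome {chrom!r}")
        length = genome.length(chrom)
        s, e = transform_fragments(starts, ends, strands, rule, length)
        keep = e > s
        s, e = s[keep], e[keep]
        # difference array -> per-base coverage -> per-bin means
        diff = np.bincount(s, minlength=length + 1).astype(np.float64)
        diff -= np.bincount(e, minlength=length + 1)
        per_base = np.cumsum(diff[:length])
        edges = np.arange(0, length, binsize)
        sums = np.add.reduceat(per_base, edges)
        track.data[chrom] = sums / track.bin_widths(chrom)
    return track


def rpgc_normalize(track: CoverageTrack, effective_genome_size: int) -> CoverageTrack:
    """Scale a raw track so mean coverage over the effective genome is 1x.

    Reads-per-genomic-content scaling: every value is multiplied by
    ``effective_genome_size / total_base_coverage``, so the track's total
    base coverage afterwards equals the effective genome size.
    """
    if track.state != "raw":
        raise ValueError(f"RPGC normalization expects a raw track, got {track.state!r}")
    total = track.total_base_coverage()
    if total == 0:
        raise ValueError("cannot RPGC-normalize an all-zero track")
    scale = effective_genome_size / total
    data = {c: v * scale for c, v in track.data.items()}
    return track.with_data(data, "rpgc")


def subtract_input(chip: CoverageTrack, input_track: CoverageTrack) -> CoverageTrack:
    """Bin-wise ``chip - input`` on depth-normalized (RPGC) tracks.

    Negative values are preserved: a bin where input exceeds ChIP is
    genuinely depleted, and flooring here would bias profile baselines.
    """
    _require_rpgc(chip, "chip")
    _require_rpgc(input_track, "input")
    chip.compatible_with(input_track)
    data = {c: chip.data[c] - input_track.data[c] for c in chip.data}
    return chip.with_data(data, "input_subtracted")


def ratio_normalize(num: CoverageTrack, den: CoverageTrack,
                    pseudocount: float = 0.1) -> CoverageTrack:
    """Bin-wise ``(num + pc) / (den + pc)`` on RPGC tracks (e.g. mark vs H3).

    The pseudocount (default 0.1 RPGC units) bounds the ratio where the
    denominator track has no signal without washing out enriched bins.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    _require_rpgc(num, "numerator")
    _require_rpgc(den, "denominator")
    num.compatible_with(den)
    data = {c: (num.data[c] + pseudocount) / (den.data[c] + pseudocount) for c in num.data}
    return num.with_data(data, "ratio")


def _require_rpgc(track: CoverageTrack, name: str) -> None:
    if track.state != "rpgc":
        raise ValueError(f"{name} track must be RPGC-normalized, got {track.state!r}")
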