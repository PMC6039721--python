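"""Coordinate model and domain types shared by every pipeline stage.

All coordinates are 0-based half-open (BED-native). GTF input is converted
on read, so no other module ever handles 1-based closed intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

#: Mouse (GRCm38/mm10) effective genome size used for 1x (RPGC) scaling.
EFFECTIVE_GENOME_SIZE_MM10 = 2_150_570_000

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome names and lengths; the coordinate frame for everything else."""

    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "GenomeModel":
        return cls(tuple(d.items()))

    @classmethod
    def from_file(cls, path) -> "GenomeModel":
        """Read a two-column chrom-sizes file (UCSC style)."""
        chroms = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
                chroms.append((parts[0], int(parts[1])))
        return cls(tuple(chroms))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chroms:
                fh.write(f"{name}\t{length}\n")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chroms)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chroms)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chroms)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths


@dataclass
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand, label and score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def validate_against(self, genome: GenomeModel) -> None:
        if self.end > genome.length(self.chrom):
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {genome.length(self.chrom)}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene span with a strand-aware TSS and TES (polyA-addition end)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not 0 <= self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: bad span [{self.start},{self.end})")

    @property
    def tss(self) -> int:
        """5' end of the gene: ``start`` on +, ``end - 1`` on -."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """3' end (polyA addition site): ``end - 1`` on +, ``start`` on -."""
        return self.end - 1 if self.strand == "+" else self.start

    def __len__(self) -> int:
        return self.end - self.start


class FragmentSet:
    """Aligned sequenced fragments of one library, stored columnar for speed.

    Parameters
    ----------
    library_id
        Free-text identifier of the library (e.g. ``"chip_rep1"``).
    chroms, starts, ends, strands
        Parallel arrays; strands are ``'+'``/``'-'`` (``'.'`` is rejected:
        a fragment always has an orientation once aligned).
    """

    def __init__(self, library_id: str, chroms, starts, ends, strands) -> None:
        self.library_id = library_id
        self.chroms = np.asarray(chroms, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.strands = np.asarray(strands, dtype="U1")
        n = len(self.chroms)
        if not (len(self.starts) == len(self.ends) == len(self.strands) == n):
            raise ValueError("fragment columns have unequal lengths")
        if n:
            if np.any(self.starts < 0) or np.any(self.starts >= self.ends):
                raise ValueError("fragments must satisfy 0 <= start < end")
            bad = ~np.isin(self.strands, ("+", "-"))
            if bad.any():
                raise ValueError("fragment strands must be '+' or '-'")

    @classmethod
    def from_intervals(cls, library_id: str, intervals: Iterable[GenomicInterval]) -> "FragmentSet":
        ivs = list(intervals)
        return cls(
            library_id,
            [iv.chrom for iv in ivs],
            [iv.start for iv in ivs],
            [iv.end for iv in ivs],
            [iv.strand for iv in ivs],
        )

    @classmethod
    def empty(cls, library_id: str) -> "FragmentSet":
        return cls(library_id, [], [], [], [])

    @property
    def library_size(self) -> int:
        return len(self.chroms)

    def __len__(self) -> int:
        return len(self.chroms)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for c, s, e, st in zip(self.chroms, self.starts, self.ends, self.strands):
            yield GenomicInterval(str(c), int(s), int(e), str(st))

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Group into per-chromosome (starts, ends, strands) triples."""
        out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in np.unique(self.chroms.astype(str)) if len(self) else []:
            m = self.chroms.astype(str) == chrom
            out[str(chrom)] = (self.starts[m], self.ends[m], self.strands[m])
        return out

    def validate_against(self, genome: GenomeModel) -> None:
        for chrom, (starts, ends, _) in self.by_chrom().items():
            length = genome.length(chrom)
            if ends.size and int(ends.max()) > length:
                raise ValueError(
                    f"library {self.library_id}: fragment exceeds {chrom} length {length}"
                )

    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2


@dataclass
class CoverageTrack:
    """Binned per-base-equivalent signal with normalization provenance.

    ``data[chrom]`` holds ``ceil(chrom_length / binsize)`` values; each value
    is the mean per-base coverage within the bin, so the track's semantics do
    not change with ``binsize``. ``provenance`` is the normalization history;
    the last entry is the current state (``raw``, ``rpgc``,
    ``input_subtracted`` or ``ratio``).
    """

    binsize: int
    data: dict[str, np.ndarray]
    genome: GenomeModel
    provenance: tuple[str, ...] = ("raw",)

    def __post_init__(self) -> None:
        if self.binsize < 1:
            raise ValueError("binsize must be >= 1")
        for chrom in self.data:
            expected = self.n_bins(chrom)
            if len(self.data[chrom]) != expected:
                raise ValueError(
                    f"{chrom}: expected {expected} bins, got {len(self.data[chrom])}"
                )
            self.data[chrom] = np.asarray(self.data[chrom], dtype=np.float64)

    @property
    def state(self) -> str:
        return self.provenance[-1]

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.genome.length(chrom) / self.binsize)

    def bin_widths(self, chrom: str) -> np.ndarray:
        """Number of genomic bases in each bin (the last bin may be partial)."""
        length = self.genome.length(chrom)
        n = self.n_bins(chrom)
        widths = np.full(n, self.binsize, dtype=np.int64)
        if n:
            widths[-1] = length - (n - 1) * self.binsize
        return widths

    def total_base_coverage(self) -> float:
        """Sum of per-base coverage over the whole genome."""
        return float(
            sum(
                np.dot(self.data[c], self.bin_widths(c))
                for c in self.data
            )
        )

    def with_data(self, data: dict[str, np.ndarray], step: str) -> "CoverageTrack":
        return CoverageTrack(self.binsize, data, self.genome, self.provenance + (step,))

    def compatible_with(self, other: "CoverageTrack") -> None:
        if self.binsize != other.binsize:
            raise ValueError("binsize mismatch between tracks")
        if self.genome.chroms != other.genome.chroms:
            raise ValueError("genome mismatch between tracks")

    @classmethod
    def zeros(cls, genome: GenomeModel, binsize: int) -> "CoverageTrack":
        data = {
            name: np.zeros(math.ceil(length / binsize))
            for name, length in genome.chroms
        }
        return cls(binsize, data, genome)
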