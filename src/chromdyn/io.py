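"""Readers and writers for the text formats the pipeline touches.

BED (3- or 6-column) carries peaks, blacklists and fragment libraries;
bedGraph is the canonical on-disk coverage format; GTF (Ensembl dialect)
carries gene models. bigWig and BAM are optional adapters behind the same
in-memory types, so nothing downstream depends on binary formats.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

from .genome import CoverageTrack, FragmentSet, GeneModel, GenomeModel, GenomicInterval


class ParseError(ValueError):
    """A malformed record, attributed to file and line number."""

    def __init__(self, path, lineno: int, message: str) -> None:
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


# ---------------------------------------------------------------------------
# BED

def read_bed(path, genome: GenomeModel | None = None) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals sorted by (chrom, start, end).

    Strand is ``'.'`` when the file has fewer than six columns. With a
    genome attached, intervals beyond the chromosome end are rejected.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(path, lineno, "fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            label = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = None
            if len(parts) > 4 and parts[4] not in (".", ""):
                try:
                    score = float(parts[4])
                except ValueError:
                    raise ParseError(path, lineno, "non-numeric score") from None
            strand = parts[5] if len(parts) > 5 else "."
            try:
                iv = GenomicInterval(chrom, start, end, strand, label, score)
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            if genome is not None:
                if chrom not in genome:
                    raise ParseError(path, lineno, f"unknown chromosome {chrom!r}")
                try:
                    iv.validate_against(genome)
                except ValueError as exc:
                    raise ParseError(path, lineno, str(exc)) from None
            intervals.append(iv)
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write BED6; label and score default to '.'/0 when absent."""
    with open(path, "w") as fh:
        for iv in intervals:
            label = iv.label if iv.label is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "0"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\t{score}\t{iv.strand}\n")


def read_fragments_bed(path, library_id: str | None = None,
                       genome: GenomeModel | None = None) -> FragmentSet:
    """Read a fragment library from BED6 (strand column required)."""
    intervals = read_bed(path, genome)
    for iv in intervals:
        if iv.strand == ".":
            raise ValueError(f"{path}: fragment records need an explicit strand")
    return FragmentSet.from_intervals(library_id or str(path), intervals)


def write_fragments_bed(frags: FragmentSet, path) -> None:
    with open(path, "w") as fh:
        for c, s, e, st in zip(frags.chroms, frags.starts, frags.ends, frags.strands):
            fh.write(f"{c}\t{s}\t{e}\t.\t0\t{st}\n")


# ---------------------------------------------------------------------------
# GTF

def read_gtf_genes(path, feature: str = "gene") -> list[GeneModel]:
    """Read gene-level GTF records into 0-based half-open :class:`GeneModel`.

    GTF is 1-based closed; a record ``start..end`` becomes span
    ``[start-1, end)``. TSS/TES are derived strand-aware by the model.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(path, lineno, f"expected 9 columns, got {len(parts)}")
            if parts[2] != feature:
                continue
            try:
                start1, end1 = int(parts[3]), int(parts[4])
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if end1 < start1:
                raise ParseError(path, lineno, f"end {end1} < start {start1}")
            strand = parts[6]
            if strand not in ("+", "-"):
                raise ParseError(path, lineno, f"bad strand {strand!r}")
            gene_id = _gtf_attribute(parts[8], "gene_id")
            if gene_id is None:
                raise ParseError(path, lineno, "missing gene_id attribute")
            genes.append(GeneModel(gene_id, parts[0], strand, start1 - 1, end1))
    return genes


def _gtf_attribute(attrs: str, key: str) -> str | None:
    for field in attrs.split(";"):
        field = field.strip()
        if field.startswith(key + " "):
            return field[len(key):].strip().strip('"')
    return None


def write_gtf_genes(genes: Iterable[GeneModel], path, source: str = "chromdyn") -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f'gene_id "{g.gene_id}";\n'
            )


# ---------------------------------------------------------------------------
# bedGraph

def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a coverage track, run-length merging equal-valued adjacent bins.

    Values are serialized with 6 significant digits, so a round trip is
    lossless at that precision.
    """
    with open(path, "w") as fh:
        for chrom in track.genome.names:
            if chrom not in track.data:
                continue
            values = track.data[chrom]
            length = track.genome.length(chrom)
            if values.size == 0:
                continue
            # run-length encode equal adjacent bins
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [values.size]))
            for b0, b1 in zip(starts, ends):
                g0 = int(b0) * track.binsize
                g1 = min(int(b1) * track.binsize, length)
                fh.write(f"{chrom}\t{g0}\t{g1}\t{values[b0]:.6g}\n")


def read_bedgraph(path, binsize: int, genome: GenomeModel) -> CoverageTrack:
    """Read a bedGraph whose intervals align to ``binsize``; gaps read as 0."""
    track = CoverageTrack.zeros(genome, binsize)
    filled = {c: np.zeros(track.n_bins(c), dtype=bool) for c in genome.names}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(path, lineno, "expected 4 columns")
            chrom, value = parts[0], float(parts[3])
            start, end = int(parts[1]), int(parts[2])
            if chrom not in genome:
                raise ParseError(path, lineno, f"unknown chromosome {chrom!r}")
            length = genome.length(chrom)
            if start % binsize != 0:
                raise ParseError(path, lineno, f"start {start} not aligned to binsize {binsize}")
            if end % binsize != 0 and end != length:
                raise ParseError(path, lineno, f"end {end} not aligned to binsize {binsize}")
            b0 = start // binsize
            b1 = math.ceil(end / binsize)
            if filled[chrom][b0:b1].any():
                raise ParseError(path, lineno, "overlapping bedGraph intervals")
            track.data[chrom][b0:b1] = value
            filled[chrom][b0:b1] = True
    return track


# ---------------------------------------------------------------------------
# Optional binary adapters

def write_bigwig(track: CoverageTrack, path) -> None:
    """bigWig export via pyBigWig (optional dependency)."""
    import pyBigWig  # deferred: binary formats are optional

    bw = pyBigWig.open(str(path), "w")
    bw.addHeader([(c, l) for c, l in track.genome.chroms])
    for chrom in track.genome.names:
        values = track.data[chrom]
        length = track.genome.length(chrom)
        starts = np.arange(values.size, dtype=np.int64) * track.binsize
        ends = np.minimum(starts + track.binsize, length)
        bw.addEntries([chrom] * values.size, starts.tolist(),
                      ends=ends.tolist(), values=values.tolist())
    bw.close()


def read_bigwig(path, binsize: int, genome: GenomeModel) -> CoverageTrack:
    import pyBigWig

    bw = pyBigWig.open(str(path))
    data = {}
    for chrom, length in genome.chroms:
        n = math.ceil(length / binsize)
        vals = np.array(bw.stats(chrom, 0, length, nBins=n, type="mean"), dtype=float)
        data[chrom] = np.nan_to_num(vals)
    bw.close()
    return CoverageTrack(binsize, data, genome)


def read_bam_fragments(path, library_id: str | None = None) -> FragmentSet:
    """BAM adapter via pysam: proper pairs become fragment spans (from the
    leftmost mate only, to avoid double-counting); single-end reads become
    read-span fragments whose extension is handled by the coverage module."""
    import pysam

    chroms, starts, ends, strands = [], [], [], []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for read in bam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_paired:
                if not read.is_proper_pair or read.is_reverse:
                    continue
                span = abs(read.template_length)
                if span == 0:
                    continue
                chroms.append(read.reference_name)
                starts.append(read.reference_start)
                ends.append(read.reference_start + span)
                strands.append("+")
            else:
                chroms.append(read.reference_name)
                starts.append(read.reference_start)
                ends.append(read.reference_end)
                strands.append("-" if read.is_reverse else "+")
    return FragmentSet(library_id or str(path), chroms, starts, ends, strands)
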