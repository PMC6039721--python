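"""Seeded synthetic genomes, gene models, peak sets and fragment libraries.

The generators emulate the statistical structure of the sequencing assays
the pipeline analyses, on a small genome so every stage runs at desk scale:

* ChIP libraries — a uniform-background / peak-centered-enrichment mixture
  with matched input libraries and negative-binomial replicate depth noise;
* MNase libraries — ~147-bp fragments jittered around positioned nucleosome
  dyads, with per-condition occupancy deltas;
* PolII S5P libraries — per-gene fragments split between the promoter
  window and the gene body in a ratio implying a known true traveling
  ratio;
* nascent RNA libraries — strand-specific reads whose 5' ends decay
  exponentially from the TSS, mixed with a uniform gene-body component.

Determinism: every (library, replicate) pair draws from its own RNG stream
derived from the master seed by stable hashing, so adding one library never
perturbs another, and identical configs yield byte-identical fixtures.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import io as cio
from .genome import FragmentSet, GeneModel, GenomeModel, GenomicInterval
from .travelratio import gene_windows


@dataclass(frozen=True)
class SimulationConfig:
    """All tunables of the synthetic cohort; identical configs reproduce
    identical output byte-for-byte."""

    seed: int = 0
    chrom_lengths: tuple[tuple[str, int], ...] = (("chr1", 2_000_000), ("chr2", 2_000_000))
    n_genes: int = 50
    n_peaks: int = 40
    peak_width: int = 1000
    depth: int = 100_000
    replicates: int = 3
    dispersion: float = 0.1  # negative-binomial replicate-depth dispersion; 0 -> Poisson
    fragment_length: int = 200
    read_length: int = 50
    gene_length_range: tuple[int, int] = (3000, 8000)
    mnase_background: float = 0.05
    mnase_jitter_sd: float = 20.0
    mnase_length_sd: float = 12.0
    polii_fragments_per_gene: int = 2000
    nascent_reads_per_gene: int = 500
    nascent_five_prime_weight: float = 0.7

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_peaks", "depth", "replicates", "peak_width",
                     "fragment_length", "read_length"):
            if getattr(self, name) < 0 or (name in ("replicates",) and getattr(self, name) < 1):
                raise ValueError(f"{name} must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def genome(self) -> GenomeModel:
        return GenomeModel(self.chrom_lengths)


def stream_rng(seed: int, *stream: str) -> np.random.Generator:
    """Independent RNG stream keyed by a stable hash of the stream name."""
    key = zlib.crc32("/".join(stream).encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _library_depth(rng: np.random.Generator, mean: int, dispersion: float) -> int:
    """Replicate library size: NB(mean, dispersion), Poisson in the limit."""
    if mean == 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    n = 1.0 / dispersion
    return int(rng.negative_binomial(n, n / (n + mean)))


# ---------------------------------------------------------------------------
# genome and genes

def make_genome_and_genes(config: SimulationConfig
                          ) -> tuple[GenomeModel, list[GeneModel]]:
    """Non-overlapping genes on both strands, lengths within configured bounds."""
    genome = config.genome()
    rng = stream_rng(config.seed, "genes")
    lo, hi = config.gene_length_range
    if lo < 3000:
        raise ValueError("gene lengths must be >= 3000 bp for promoter/body windows")
    # apportion genes to chromosomes by length (largest remainder)
    total = genome.total_length
    quotas = {c: config.n_genes * l / total for c, l in genome.chroms}
    counts = {c: int(q) for c, q in quotas.items()}
    for c, _ in sorted(quotas.items(), key=lambda kv: kv[1] - int(kv[1]), reverse=True):
        if sum(counts.values()) >= config.n_genes:
            break
        counts[c] += 1
    genes: list[GeneModel] = []
    gid = 0
    for chrom, length in genome.chroms:
        n = counts.get(chrom, 0)
        if n == 0:
            continue
        lens = rng.integers(lo, hi + 1, size=n)
        slack = length - int(lens.sum())
        if slack < 0:
            raise ValueError(
                f"genome too small: cannot place {n} genes on {chrom} ({length} bp)"
            )
        gaps = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
        pos = 0
        for i in range(n):
            pos += int(gaps[i])
            start = pos
            end = start + int(lens[i])
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            genes.append(GeneModel(f"gene{gid:04d}", chrom, strand, start, end))
            pos = end
    return genome, genes


def make_peaks(config: SimulationConfig, label: str = "peak") -> list[GenomicInterval]:
    """Random fixed-width, non-overlapping peak intervals."""
    genome = config.genome()
    rng = stream_rng(config.seed, "peaks", label)
    peaks: list[GenomicInterval] = []
    total = genome.total_length
    cum = np.cumsum([l for _, l in genome.chroms])
    names = genome.names
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    attempts = 0
    while len(peaks) < config.n_peaks and attempts < config.n_peaks * 100:
        attempts += 1
        g = int(rng.integers(0, total - config.peak_width))
        ci = int(np.searchsorted(cum, g, side="right"))
        offset = g - (int(cum[ci - 1]) if ci else 0)
        chrom = names[ci]
        if offset + config.peak_width > genome.length(chrom):
            continue
        span = (offset, offset + config.peak_width)
        if any(span[0] < e and span[1] > s for s, e in taken[chrom]):
            continue
        taken[chrom].append(span)
        peaks.append(GenomicInterval(chrom, span[0], span[1],
                                     label=f"{label}{len(peaks) + 1:03d}"))
    if len(peaks) < config.n_peaks:
        raise ValueError("genome too crowded to place the requested peaks")
    return sorted(peaks, key=lambda iv: (iv.chrom, iv.start))


# ---------------------------------------------------------------------------
# fragment assembly helpers

def _genome_uniform(rng: np.random.Generator, genome: GenomeModel, n: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """n uniform genomic midpoints -> (chrom index array, position array)."""
    cum = np.cumsum([l for _, l in genome.chroms])
    g = rng.integers(0, genome.total_length, size=n)
    ci = np.searchsorted(cum, g, side="right")
    offs = g - np.concatenate(([0], cum[:-1]))[ci]
    return ci, offs


def _build_fragments(library_id: str, genome: GenomeModel, chrom_idx: np.ndarray,
                     mids: np.ndarray, lengths, strands: np.ndarray) -> FragmentSet:
    names = np.array(genome.names, dtype=object)
    chrom_lens = np.array([genome.length(c) for c in genome.names], dtype=np.int64)
    lens = np.broadcast_to(np.asarray(lengths, dtype=np.int64), mids.shape)
    starts = np.maximum(mids - lens // 2, 0)
    ends = np.minimum(starts + lens, chrom_lens[chrom_idx])
    starts = np.minimum(starts, ends - 1)
    return FragmentSet(library_id, names[chrom_idx], starts, ends, strands)


def _random_strands(rng: np.random.Generator, n: int) -> np.ndarray:
    return np.where(rng.random(n) < 0.5, "+", "-").astype("U1")


# ---------------------------------------------------------------------------
# ChIP

def simulate_chip(peaks: Sequence[GenomicInterval], enrichment: float,
                  config: SimulationConfig, genome: GenomeModel | None = None,
                  library: str = "chip") -> tuple[list[FragmentSet], FragmentSet]:
    """Replicate ChIP libraries plus one matched input library.

    Fragment midpoints are a mixture of genome-uniform background and
    Gaussian peak-centered enrichment: the per-base rate is 1 outside peaks
    and ~``enrichment`` at peaks, so ``enrichment=1`` is indistinguishable
    from input.
    """
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    genome = genome or config.genome()
    peaks = list(peaks)
    names = list(genome.names)
    extra = np.array([(enrichment - 1.0) * len(p) for p in peaks])
    total_extra = float(extra.sum())
    p_bg = genome.total_length / (genome.total_length + total_extra)

    def one_library(rng: np.random.Generator, lib_id: str, background_only: bool
                    ) -> FragmentSet:
        n_total = _library_depth(rng, config.depth, config.dispersion)
        if n_total == 0:
            return FragmentSet.empty(lib_id)
        if background_only or total_extra == 0:
            n_bg, n_pk = n_total, 0
        else:
            n_bg = int(rng.binomial(n_total, p_bg))
            n_pk = n_total - n_bg
        ci, mids = _genome_uniform(rng, genome, n_bg)
        ci_parts, mid_parts = [ci], [mids]
        if n_pk:
            counts = rng.multinomial(n_pk, extra / total_extra)
            for pk, c in zip(peaks, counts):
                if c == 0:
                    continue
                center = (pk.start + pk.end) / 2
                pos = rng.normal(center, len(pk) / 6, size=c)
                pos = np.clip(np.rint(pos), pk.start, pk.end - 1).astype(np.int64)
                ci_parts.append(np.full(c, names.index(pk.chrom)))
                mid_parts.append(pos)
        ci_all = np.concatenate(ci_parts)
        mids_all = np.concatenate(mid_parts)
        strands = _random_strands(rng, mids_all.size)
        return _build_fragments(lib_id, genome, ci_all, mids_all,
                                config.fragment_length, strands)

    reps = [
        one_library(stream_rng(config.seed, library, f"rep{r}"),
                    f"{library}_rep{r}", background_only=False)
        for r in range(1, config.replicates + 1)
    ]
    input_lib = one_library(stream_rng(config.seed, library, "input"),
                            f"{library}_input", background_only=True)
    return reps, input_lib


# ---------------------------------------------------------------------------
# MNase

@dataclass
class NucleosomeMap:
    """Positioned nucleosome dyads with occupancies and per-condition deltas.

    ``dyads[chrom]`` is a sorted position array; ``occupancy[chrom]`` the
    matching probabilities in [0, 1]; ``deltas[condition][chrom]`` the
    occupancy change applied in that condition (sampling weight becomes
    ``occupancy * (1 + delta)``, floored at 0).
    """

    dyads: dict[str, np.ndarray]
    occupancy: dict[str, np.ndarray]
    deltas: dict[str, dict[str, np.ndarray]]

    def __post_init__(self) -> None:
        for chrom, pos in self.dyads.items():
            pos = np.asarray(pos, dtype=np.int64)
            self.dyads[chrom] = pos
            if np.any(np.diff(pos) < 147):
                raise ValueError(f"{chrom}: dyad spacing below 147 bp")
            occ = np.asarray(self.occupancy[chrom], dtype=float)
            if occ.shape != pos.shape:
                raise ValueError(f"{chrom}: occupancy shape mismatch")
            if np.any((occ < 0) | (occ > 1)):
                raise ValueError(f"{chrom}: occupancy outside [0, 1]")
            self.occupancy[chrom] = occ

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.deltas)

    def weights(self, condition: str) -> dict[str, np.ndarray]:
        if condition not in self.deltas:
            raise ValueError(
                f"unknown condition {condition!r}; have {sorted(self.deltas)}"
            )
        return {
            c: np.maximum(self.occupancy[c] * (1.0 + self.deltas[condition][c]), 0.0)
            for c in self.dyads
        }


def nucleosome_array_map(genome: GenomeModel, site_centers: dict[str, Sequence[int]],
                         conditions: dict[str, float], n_flanking: int = 2,
                         spacing: int = 180, occupancy: float = 0.8,
                         delta_scope: str = "center") -> NucleosomeMap:
    """Regular nucleosome arrays around site centers.

    Each site gets ``2*n_flanking + 1`` dyads at ``spacing`` bp; each
    condition's delta is applied to the central dyad only
    (``delta_scope='center'``) or to the whole array (``'all'``).
    """
    dyads: dict[str, np.ndarray] = {}
    occ: dict[str, np.ndarray] = {}
    center_mask: dict[str, np.ndarray] = {}
    for chrom, centers in site_centers.items():
        pos, is_center = [], []
        for c in sorted(centers):
            for k in range(-n_flanking, n_flanking + 1):
                pos.append(c + k * spacing)
                is_center.append(k == 0)
        dyads[chrom] = np.array(pos, dtype=np.int64)
        occ[chrom] = np.full(len(pos), occupancy)
        center_mask[chrom] = np.array(is_center)
    deltas = {}
    for name, delta in conditions.items():
        deltas[name] = {
            chrom: np.where(center_mask[chrom] if delta_scope == "center" else True,
                            delta, 0.0)
            for chrom in dyads
        }
    return NucleosomeMap(dyads, occ, deltas)


def simulate_mnase(nmap: NucleosomeMap, condition: str, config: SimulationConfig,
                   genome: GenomeModel | None = None) -> list[FragmentSet]:
    """Replicate MNase libraries for one condition.

    ~147-bp fragments are centered on dyads with Gaussian positional jitter,
    sampled proportionally to ``occupancy * (1 + delta)``, plus a uniform
    background fraction.
    """
    genome = genome or config.genome()
    weights = nmap.weights(condition)
    chroms = list(nmap.dyads)
    flat_w = np.concatenate([weights[c] for c in chroms]) if chroms else np.array([])
    flat_d = np.concatenate([nmap.dyads[c] for c in chroms]) if chroms else np.array([])
    flat_ci = np.concatenate(
        [np.full(len(nmap.dyads[c]), list(genome.names).index(c)) for c in chroms]
    ) if chroms else np.array([], dtype=int)
    wsum = float(flat_w.sum())

    out = []
    for r in range(1, config.replicates + 1):
        rng = stream_rng(config.seed, "mnase", condition, f"rep{r}")
        lib_id = f"mnase_{condition}_rep{r}"
        n_total = _library_depth(rng, config.depth, config.dispersion)
        if n_total == 0 or (wsum == 0 and config.mnase_background == 0):
            out.append(FragmentSet.empty(lib_id))
            continue
        n_bg = int(rng.binomial(n_total, config.mnase_background))
        n_nuc = n_total - n_bg if wsum > 0 else 0
        parts_ci, parts_mid = [], []
        if n_nuc:
            counts = rng.multinomial(n_nuc, flat_w / wsum)
            reps_idx = np.repeat(np.arange(flat_d.size), counts)
            mids = flat_d[reps_idx] + np.rint(
                rng.normal(0, config.mnase_jitter_sd, reps_idx.size)
            ).astype(np.int64)
            parts_ci.append(flat_ci[reps_idx])
            parts_mid.append(mids)
        if n_bg:
            ci, mids = _genome_uniform(rng, genome, n_bg)
            parts_ci.append(ci)
            parts_mid.append(mids)
        ci_all = np.concatenate(parts_ci)
        mid_all = np.concatenate(parts_mid)
        lens = np.clip(
            np.rint(rng.normal(147, config.mnase_length_sd, mid_all.size)), 100, 250
        ).astype(np.int64)
        chrom_lens = np.array([genome.length(c) for c in genome.names])
        mid_all = np.clip(mid_all, 0, chrom_lens[ci_all] - 1)
        strands = _random_strands(rng, mid_all.size)
        out.append(_build_fragments(lib_id, genome, ci_all, mid_all, lens, strands))
    return out


# ---------------------------------------------------------------------------
# PolII

@dataclass
class PausingSpec:
    """Per-gene promoter and body densities; implies true TR = d_p/(d_p+d_b)."""

    densities: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for gid, (d_p, d_b) in self.densities.items():
            if d_p < 0 or d_b < 0 or d_p + d_b <= 0:
                raise ValueError(f"{gid}: densities must be >= 0 with positive sum")

    def true_tr(self, gene_id: str) -> float:
        d_p, d_b = self.densities[gene_id]
        return d_p / (d_p + d_b)

    @classmethod
    def uniform(cls, genes: Iterable[GeneModel], tr: float) -> "PausingSpec":
        """Same true traveling ratio for every gene."""
        if not 0 <= tr <= 1:
            raise ValueError("tr must be in [0, 1]")
        return cls({g.gene_id: (tr, 1.0 - tr) for g in genes})


def simulate_polii(genes: Sequence[GeneModel], pausing: PausingSpec,
                   config: SimulationConfig, genome: GenomeModel | None = None
                   ) -> list[FragmentSet]:
    """Replicate PolII S5P libraries with known per-gene pausing.

    Each gene's fragments split between the promoter window and the body in
    proportion ``d_p * len_p : d_b * len_b``, with midpoints uniform inside
    each window — so uniform density within windows, by construction.
    """
    genome = genome or config.genome()
    names = list(genome.names)
    missing = [g.gene_id for g in genes if g.gene_id not in pausing.densities]
    if missing:
        raise ValueError(f"genes missing from pausing spec: {missing[:5]}")
    windows = {g.gene_id: gene_windows(g, genome) for g in genes}

    out = []
    for r in range(1, config.replicates + 1):
        rng = stream_rng(config.seed, "polii", f"rep{r}")
        parts_ci, parts_mid, parts_strand = [], [], []
        for g in genes:
            w = windows[g.gene_id]
            if w is None:
                continue
            promoter, body = w
            d_p, d_b = pausing.densities[g.gene_id]
            n_g = _library_depth(rng, config.polii_fragments_per_gene, config.dispersion)
            if n_g == 0:
                continue
            mass_p = d_p * len(promoter)
            mass_b = d_b * len(body)
            n_p = int(rng.binomial(n_g, mass_p / (mass_p + mass_b)))
            mids = np.concatenate([
                rng.integers(promoter.start, promoter.end, size=n_p),
                rng.integers(body.start, body.end, size=n_g - n_p),
            ])
            parts_ci.append(np.full(mids.size, names.index(g.chrom)))
            parts_mid.append(mids)
            parts_strand.append(np.full(mids.size, g.strand, dtype="U1"))
        if not parts_mid:
            out.append(FragmentSet.empty(f"polii_rep{r}"))
            continue
        out.append(_build_fragments(
            f"polii_rep{r}", genome, np.concatenate(parts_ci),
            np.concatenate(parts_mid), config.read_length,
            np.concatenate(parts_strand),
        ))
    return out


# ---------------------------------------------------------------------------
# nascent RNA

def simulate_nascent(genes: Sequence[GeneModel], decay_length: float,
                     config: SimulationConfig, genome: GenomeModel | None = None,
                     five_prime_weight: float | None = None) -> list[FragmentSet]:
    """Strand-specific nascent-RNA replicate libraries with a 5' excess.

    A fraction ``five_prime_weight`` of each gene's reads start at
    TSS-relative offsets drawn from a truncated exponential with scale
    ``decay_length``; the rest are uniform along the gene. Read strand
    equals gene strand. With weight 0 the profile is uniform regardless of
    the decay length.
    """
    if decay_length <= 0:
        raise ValueError("decay_length must be positive")
    genome = genome or config.genome()
    names = list(genome.names)
    w5 = config.nascent_five_prime_weight if five_prime_weight is None else five_prime_weight
    if not 0 <= w5 <= 1:
        raise ValueError("five_prime_weight must be in [0, 1]")

    out = []
    for r in range(1, config.replicates + 1):
        rng = stream_rng(config.seed, "nascent", f"rep{r}")
        parts_ci, parts_pos, parts_strand = [], [], []
        for g in genes:
            gene_len = len(g)
            n = _library_depth(rng, config.nascent_reads_per_gene, config.dispersion)
            if n == 0:
                continue
            n5 = int(rng.binomial(n, w5))
            if n5 and np.isfinite(decay_length):
                u = rng.random(n5)
                trunc = -np.expm1(-gene_len / decay_length)  # 1 - exp(-L/lambda)
                off5 = np.floor(-decay_length * np.log1p(-u * trunc)).astype(np.int64)
                off5 = np.clip(off5, 0, gene_len - 1)
            else:
                off5 = rng.integers(0, gene_len, size=n5)
            offs = np.concatenate([off5, rng.integers(0, gene_len, size=n - n5)])
            five_prime = g.tss + offs if g.strand == "+" else g.tss - offs
            parts_ci.append(np.full(offs.size, names.index(g.chrom)))
            parts_pos.append(five_prime)
            parts_strand.append(np.full(offs.size, g.strand, dtype="U1"))
        if not parts_pos:
            out.append(FragmentSet.empty(f"nascent_rep{r}"))
            continue
        pos = np.concatenate(parts_pos)
        ci = np.concatenate(parts_ci)
        strands = np.concatenate(parts_strand)
        chrom_lens = np.array([genome.length(c) for c in genome.names])
        rl = config.read_length
        starts = np.where(strands == "+", pos, pos - rl + 1)
        starts = np.clip(starts, 0, None)
        ends = np.minimum(np.where(strands == "+", pos + rl, pos + 1),
                          chrom_lens[ci])
        starts = np.minimum(starts, ends - 1)
        out.append(FragmentSet(f"nascent_rep{r}", np.array(names, dtype=object)[ci],
                               starts, ends, strands))
    return out


# ---------------------------------------------------------------------------
# fixture tree

def write_fixture_tree(config: SimulationConfig, outdir,
                       chip_enrichment: float = 8.0,
                       true_tr: float = 0.75,
                       mnase_conditions: dict[str, float] | None = None,
                       nascent_decay_length: float = 750.0) -> dict:
    """Generate a full fixture directory (chrom sizes, GTF, peak BED, and
    BED6 fragment libraries) and return a manifest of what was written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes = make_genome_and_genes(config)
    genome.to_file(outdir / "genome.chrom.sizes")
    cio.write_gtf_genes(genes, outdir / "genes.gtf")
    peaks = make_peaks(config)
    cio.write_bed(peaks, outdir / "peaks.bed")

    manifest: dict = {
        "seed": config.seed,
        "n_genes": len(genes),
        "n_peaks": len(peaks),
        "libraries": {},
    }

    def dump(libs: Iterable[FragmentSet], subdir: str) -> None:
        d = outdir / subdir
        d.mkdir(exist_ok=True)
        for lib in libs:
            path = d / f"{lib.library_id}.bed"
            cio.write_fragments_bed(lib, path)
            manifest["libraries"][lib.library_id] = {
                "path": str(path.relative_to(outdir)),
                "library_size": lib.library_size,
            }

    chip_reps, chip_input = simulate_chip(peaks, chip_enrichment, config, genome)
    dump(chip_reps + [chip_input], "chip")

    if mnase_conditions is None:
        mnase_conditions = {"t0": 0.0, "t30": 0.6}
    # keep only TSSs far enough apart that neighbouring nucleosome arrays
    # cannot violate the 147-bp dyad-spacing invariant
    min_sep = 2 * 2 * 180 + 147
    centers: dict[str, list[int]] = {}
    for chrom in genome.names:
        kept: list[int] = []
        for tss in sorted(g.tss for g in genes if g.chrom == chrom):
            if tss >= 400 and (not kept or tss - kept[-1] >= min_sep):
                kept.append(tss)
        if kept:
            centers[chrom] = kept
    nmap = nucleosome_array_map(genome, centers, mnase_conditions)
    for condition in mnase_conditions:
        dump(simulate_mnase(nmap, condition, config, genome), f"mnase_{condition}")

    pausing = PausingSpec.uniform(genes, true_tr)
    dump(simulate_polii(genes, pausing, config, genome), "polii")
    dump(simulate_nascent(genes, nascent_decay_length, config, genome), "nascent")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
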