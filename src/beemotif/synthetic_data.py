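"""Synthetic genomes with planted regulatory motifs.

Emulates the study design downstream modules are tested against: a contig of
low-order Markov background sequence, non-overlapping gene models on both
strands with configurable intergenic spacing, a foreground ("upregulated")
gene set whose upstream control regions carry planted motif instances at a
stated per-sequence occupancy, gene categories (cuticular-protein / muscle /
other), and a small TRANSFAC-format motif library containing the planted
motif plus decoys. Every output is a pure function of the configuration,
including the seed.

Default conditions mirror an AT-rich insect genome (67% AT, the honeybee
regime) with a third of genes in the foreground and per-UCR occupancy 0.9.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_ucr import GeneModel, UCRRecord, extract_ucr
from .pssm_core import BASES, PSSM, pssm_from_iupac, information_content, reverse_complement

log = logging.getLogger(__name__)

#: FTZ-F1 binding-site consensus, the default planted motif
DEFAULT_PLANTED_CONSENSUS = "YCAAGGTCR"


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic dataset.

    ``intergenic_length_distribution`` is a mapping with a ``name`` key:
    ``{"name": "fixed", "length": L}``, ``{"name": "uniform", "low": a,
    "high": b}`` or ``{"name": "geometric", "mean": m}``.
    """

    seed: int = 0
    n_genes: int = 60
    contig_length: int = 150_000
    gene_length_range: tuple[int, int] = (300, 900)
    intergenic_length_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"name": "fixed", "length": 500}
    )
    background_markov_order: int = 1
    background_base_composition: tuple[float, float, float, float] = (
        0.335, 0.165, 0.165, 0.335,  # AT-rich insect regime
    )
    planted_motif: PSSM | str = DEFAULT_PLANTED_CONSENSUS
    foreground_fraction: float = 1 / 3
    occupancy: float = 0.9
    decoy_motif_count: int = 5
    #: persistence of the order>=1 background chain (mixture weight on
    #: repeating the previous base; stationary composition is preserved)
    background_persistence: float = 0.2

    def __post_init__(self) -> None:
        comp = np.asarray(self.background_base_composition, dtype=float)
        if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("background_base_composition must be a 4-vector summing to 1")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError("occupancy must be in [0, 1]")
        if not (0.0 <= self.foreground_fraction <= 1.0):
            raise ValueError("foreground_fraction must be in [0, 1]")
        if self.background_markov_order not in (0, 1, 2):
            raise ValueError("background_markov_order must be 0, 1 or 2")
        if self.n_genes < 0 or self.decoy_motif_count < 0:
            raise ValueError("counts must be nonnegative")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid gene_length_range")

    def planted_pssm(self) -> PSSM:
        m = self.planted_motif
        if isinstance(m, PSSM):
            return m
        return pssm_from_iupac(m, name="planted")


@dataclass(frozen=True)
class PlantedSite:
    """One planted motif instance, in UCR coordinates.

    ``offset`` and ``strand`` are relative to the UCR sequence orientation
    (5'->3' toward the gene); ``word`` is the planted word in that
    orientation read on the given strand.
    """

    gene_id: str
    offset: int
    strand: str
    word: str


@dataclass
class GroundTruth:
    """What was planted where, and which genes belong to which group."""

    planted_occurrences: list[PlantedSite] = field(default_factory=list)
    foreground_genes: set[str] = field(default_factory=set)
    category_map: dict[str, str] = field(default_factory=dict)

    def validate(self, gene_ids: Iterable[str]) -> None:
        ids = set(gene_ids)
        if not self.foreground_genes <= ids:
            raise ValueError("foreground_genes not a subset of gene ids")


class InfeasiblePackingError(ValueError):
    """Genes plus intergenic spacers exceed the contig length."""


def _draw_intergenic(rng: np.random.Generator, dist: Mapping[str, float], n: int) -> np.ndarray:
    name = dist.get("name", "fixed")
    if name == "fixed":
        return np.full(n, int(dist["length"]), dtype=int)
    if name == "uniform":
        return rng.integers(int(dist["low"]), int(dist["high"]) + 1, size=n)
    if name == "geometric":
        return rng.geometric(1.0 / float(dist["mean"]), size=n)
    raise ValueError(f"unknown intergenic distribution {name!r}")


def _sample_background(
    rng: np.random.Generator,
    length: int,
    composition: np.ndarray,
    order: int,
    persistence: float,
) -> str:
    """Sample background sequence with the configured stationary composition.

    Order 0 draws i.i.d. bases. Orders 1 and 2 use a sticky chain: with
    probability ``persistence`` the previous base repeats (order 2 splits
    that weight between the two preceding bases), otherwise a fresh draw from
    the stationary composition is taken — so the marginal composition is the
    configured one at any order.
    """
    if length <= 0:
        return ""
    if order == 0 or persistence == 0.0:
        idx = rng.choice(4, size=length, p=composition)
        return "".join(BASES[i] for i in idx)
    fresh = rng.choice(4, size=length, p=composition)
    sticky = rng.random(length)
    pick_prev = rng.random(length)  # order-2 only: which history base repeats
    out = np.empty(length, dtype=np.int8)
    out[0] = fresh[0]
    for i in range(1, length):
        if sticky[i] < persistence:
            if order == 2 and i >= 2 and pick_prev[i] < 0.5:
                out[i] = out[i - 2]
            else:
                out[i] = out[i - 1]
        else:
            out[i] = fresh[i]
    return "".join(BASES[i] for i in out)


def simulate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], GroundTruth]:
    """Lay out genes on a background contig and assign groups and categories.

    Genes alternate with intergenic spacers drawn from the configured
    distribution; strands are uniform. Gene bodies are filled with background
    sequence too — only the coordinates distinguish them. The contig ends
    after the final spacer, so every intergenic stretch — including the
    flanks — follows the configured distribution; ``contig_length`` is the
    feasibility cap (and the emitted length when there are no genes).
    Raises :class:`InfeasiblePackingError` naming the shortfall when the
    layout does not fit. No motifs are planted here; see :func:`plant_motifs`.
    """
    rng = np.random.default_rng(config.seed)
    comp = np.asarray(config.background_base_composition, dtype=float)
    contig_id = "contig_1"

    n = config.n_genes
    gaps = _draw_intergenic(rng, config.intergenic_length_distribution, n + 1)
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    needed = int(gaps[: n + 1].sum() + lengths.sum()) if n else int(gaps[0])
    if needed > config.contig_length:
        raise InfeasiblePackingError(
            f"genes + spacers need {needed} bases but contig_length is "
            f"{config.contig_length} (short by {needed - config.contig_length})"
        )

    genes: list[GeneModel] = []
    pos = 0
    for i in range(n):
        pos += int(gaps[i])
        start, end = pos, pos + int(lengths[i])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i + 1:03d}", contig_id, start, end, strand))
        pos = end

    emitted_length = needed if n else config.contig_length
    seq = _sample_background(
        rng, emitted_length, comp,
        config.background_markov_order, config.background_persistence,
    )
    contigs = {contig_id: seq}

    truth = GroundTruth()
    n_fg = int(round(config.foreground_fraction * n))
    order = rng.permutation(n)
    fg_idx = sorted(order[:n_fg])
    truth.foreground_genes = {genes[i].id for i in fg_idx}
    # foreground genes alternate CP / muscle; the rest are "other"
    for rank, i in enumerate(fg_idx):
        truth.category_map[genes[i].id] = "CP" if rank % 2 == 0 else "muscle"
    for g in genes:
        truth.category_map.setdefault(g.id, "other")
    truth.validate(g.id for g in genes)
    return contigs, genes, truth


def sample_word(pssm: PSSM, rng: np.random.Generator) -> str:
    """Sample one word from a PSSM, column by column."""
    return "".join(BASES[rng.choice(4, p=pssm.frequencies[i])] for i in range(pssm.width))


def plant_motifs(
    contigs: Mapping[str, str],
    annotation: Sequence[GeneModel],
    truth: GroundTruth,
    motif: PSSM,
    occupancy: float,
    seed: int,
    requested_length: int = 3000,
) -> tuple[dict[str, str], GroundTruth]:
    """Plant sampled motif instances into foreground UCRs.

    Each foreground gene's UCR receives, with probability ``occupancy``, one
    instance sampled from the PSSM at a uniform offset and uniform strand.
    Occurrences are recorded in UCR coordinates so that mapping them through
    UCR extraction recovers the planted word exactly; since adjacent genes on
    opposite strands share an intergenic stretch, offsets already covered by
    an earlier instance are excluded so no plant overwrites another.
    Foreground genes with no valid offset left are skipped with a logged
    warning.
    """
    rng = np.random.default_rng(seed)
    occupied: dict[str, list[tuple[int, int]]] = {}
    mutable = {cid: list(seq) for cid, seq in contigs.items()}
    new_truth = GroundTruth(
        planted_occurrences=list(truth.planted_occurrences),
        foreground_genes=set(truth.foreground_genes),
        category_map=dict(truth.category_map),
    )
    w = motif.width
    for gene in annotation:
        if gene.id not in truth.foreground_genes:
            continue
        if rng.random() >= occupancy:
            continue
        ucr = extract_ucr(gene, annotation, contigs, requested_length, min_length=1)
        if ucr is None or ucr.actual_length < w:
            log.warning("no valid offset for motif in UCR of %s; skipped", gene.id)
            continue

        def genomic_start(off: int) -> int:
            return ucr.start + off if gene.strand == "+" else ucr.end - off - w

        taken = occupied.setdefault(gene.contig, [])
        free = [
            off
            for off in range(ucr.actual_length - w + 1)
            if not any(genomic_start(off) < e and genomic_start(off) + w > s for s, e in taken)
        ]
        if not free:
            log.warning("no valid offset for motif in UCR of %s; skipped", gene.id)
            continue
        offset = int(free[rng.integers(0, len(free))])
        strand = "+" if rng.random() < 0.5 else "-"
        word = sample_word(motif, rng)
        ucr_sub = word if strand == "+" else reverse_complement(word)
        # map the UCR-oriented subsequence back to forward genomic coordinates
        g_start = genomic_start(offset)
        genomic = ucr_sub if gene.strand == "+" else reverse_complement(ucr_sub)
        mutable[gene.contig][g_start : g_start + w] = list(genomic)
        taken.append((g_start, g_start + w))
        new_truth.planted_occurrences.append(PlantedSite(gene.id, offset, strand, word))
    return {cid: "".join(chars) for cid, chars in mutable.items()}, new_truth


def random_motif(
    width: int,
    rng: np.random.Generator | int,
    min_ic_per_column: float = 1.3,
    name: str = "decoy",
) -> PSSM:
    """A random PSSM with one dominant base per column and bounded information.

    Dominant-base frequencies are drawn in [0.9, 1.0) with the remainder split
    evenly, which keeps every column above ~1.37 bits — informative enough to
    behave like a genuine binding-site matrix rather than background.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    while True:
        freq = np.empty((width, 4))
        for i in range(width):
            p = rng.uniform(0.9, 1.0)
            freq[i] = (1.0 - p) / 3.0
            freq[i, rng.integers(0, 4)] = p
        pssm = PSSM(name, freq)
        per_col, _ = information_content(pssm)
        if per_col.min() >= min_ic_per_column:
            return pssm


def make_decoy_library(
    planted: PSSM, n_decoys: int, seed: int, width: int | None = None
) -> list[PSSM]:
    """The planted motif plus ``n_decoys`` random decoys, ready for writing."""
    rng = np.random.default_rng(seed)
    width = width or planted.width
    motifs = [dataclasses.replace(planted, name="planted")]
    for i in range(n_decoys):
        motifs.append(random_motif(width, rng, name=f"decoy_{i + 1}"))
    return motifs


def write_motif_library(
    motifs: Sequence[PSSM], path: str | Path, names: Sequence[str] | None = None
) -> None:
    """Write motifs as a TRANSFAC flat file (AC/ID/P0 rows, // terminators).

    Matrix rows carry frequencies at full precision so the file round-trips
    through the TRANSFAC reader to within 1e-9.
    """
    if names is None:
        names = [m.name for m in motifs]
    if len(names) != len(motifs):
        raise ValueError("names and motifs differ in length")
    if len(set(names)) != len(names):
        raise ValueError("duplicate motif names in library")
    lines: list[str] = []
    for name, motif in zip(names, motifs):
        lines += [f"AC {name}", "XX", f"ID {name}", "XX",
                  "P0      A      C      G      T"]
        for i, row in enumerate(motif.frequencies, start=1):
            vals = "  ".join(f"{v:.10f}" for v in row)
            lines.append(f"{i:02d}  {vals}  {motif.consensus()[i - 1]}")
        lines += ["XX", "//"]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def benchmark_config(
    seed: int,
    motif_seed: int = 11,
    occupancy: float = 0.9,
    width: int = 8,
    n_genes: int = 60,
    ucr_length: int = 400,
    gene_length_range: tuple[int, int] = (300, 600),
    foreground_fraction: float = 1 / 3,
) -> SimulationConfig:
    """The standard planted-motif benchmark conditions.

    60 genes with fixed 400 bp intergenic spacers (so every UCR is exactly
    400 bp), a third of them in the foreground group, and a random 8-mer
    planted motif of >= 1.3 bits per column at occupancy 0.9. The contig is
    sized to fit the layout exactly.
    """
    planted = random_motif(width, motif_seed, name="planted")
    cap = (n_genes + 1) * ucr_length + n_genes * gene_length_range[1]
    return SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        contig_length=cap,
        intergenic_length_distribution={"name": "fixed", "length": ucr_length},
        gene_length_range=gene_length_range,
        foreground_fraction=foreground_fraction,
        occupancy=occupancy,
        planted_motif=planted,
    )


def simulate_dataset(config: SimulationConfig) -> dict:
    """One-call convenience: genome + planting + UCR-ready pieces.

    Returns a dict with keys ``contigs``, ``annotation``, ``truth``,
    ``planted`` (the planted PSSM) and ``library`` (planted + decoys).
    """
    contigs, genes, truth = simulate_genome(config)
    planted = config.planted_pssm()
    rng = np.random.default_rng(config.seed)
    plant_seed = int(rng.integers(0, 2**31 - 1))
    lib_seed = int(rng.integers(0, 2**31 - 1))
    contigs, truth = plant_motifs(contigs, genes, truth, planted, config.occupancy, plant_seed)
    library = make_decoy_library(planted, config.decoy_motif_count, lib_seed)
    return {
        "contigs": contigs,
        "annotation": genes,
        "truth": truth,
        "planted": planted,
        "library": library,
    }
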