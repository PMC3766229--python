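"""Position-specific scoring matrices and the matching currency of the pipeline.

A motif is represented as a per-column base-frequency matrix over (A, C, G, T).
Two distinct percent scales are defined here and used consistently downstream:

* ``site_similarity`` — how well a single word matches a PSSM, normalised by
  the column maxima so that a consensus-built PSSM yields the intuitive
  "fraction of matching positions" reading (a word violating k of w degenerate
  consensus positions scores ``100 * (w - k) / w``).
* ``pssm_identity`` — ungapped alignment of two PSSMs scored by average
  allele sharing per column (one minus half the L1 distance), maximised over
  relative offsets and reverse complement.

Coordinates are 0-based half-open throughout; strand labels are ``+``/``-``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC nucleotide codes -> allowed bases
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_COL_TOL = 1e-9


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A,C,G,T as 0..3 and any other character (N) as 4."""
    out = np.full(len(seq), 4, dtype=np.int8)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass(frozen=True)
class PSSM:
    """A position-specific scoring matrix.

    ``frequencies`` has shape (width, 4) over (A, C, G, T); every row sums to
    one. ``source_counts`` retains the aligned-site counts the matrix was
    built from, when it was built from counts at all.
    """

    name: str
    frequencies: np.ndarray
    source_counts: np.ndarray | None = None
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        freq = np.asarray(self.frequencies, dtype=float)
        if freq.ndim != 2 or freq.shape[1] != 4 or freq.shape[0] < 1:
            raise ValueError(f"PSSM {self.name!r}: frequencies must be (width, 4) with width >= 1")
        if (freq < 0).any():
            raise ValueError(f"PSSM {self.name!r}: negative frequency entries")
        sums = freq.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"PSSM {self.name!r}: columns do not sum to 1 (sums={sums})")
        object.__setattr__(self, "frequencies", freq / sums[:, None])

    @property
    def width(self) -> int:
        return self.frequencies.shape[0]

    def reverse_complement(self) -> "PSSM":
        rc = self.frequencies[::-1, ::-1]
        counts = None if self.source_counts is None else self.source_counts[::-1, ::-1]
        return PSSM(self.name, rc, counts, self.pseudocount)

    def consensus(self) -> str:
        """Majority base per column (ties broken toward A<C<G<T order)."""
        return "".join(BASES[i] for i in self.frequencies.argmax(axis=1))

    def __eq__(self, other: object) -> bool:  # frozen dataclass with arrays
        if not isinstance(other, PSSM):
            return NotImplemented
        return self.name == other.name and np.array_equal(self.frequencies, other.frequencies)

    def __hash__(self) -> int:
        return hash((self.name, self.frequencies.tobytes()))


@dataclass(frozen=True)
class SiteHit:
    """A scored motif occurrence in one sequence.

    ``offset`` is the forward-strand coordinate of the window start regardless
    of ``strand``; ``word`` is the matched word in the motif's orientation.
    """

    sequence_id: str
    offset: int
    strand: str
    similarity: float
    word: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0.0 <= self.similarity <= 100.0 + 1e-9):
            raise ValueError(f"similarity out of [0, 100]: {self.similarity}")


def pssm_from_counts(
    counts: Sequence[Sequence[float]] | np.ndarray,
    alpha: float = 0.25,
    name: str = "pssm",
) -> PSSM:
    """Build a PSSM from per-column base counts with additive pseudocount.

    ``f[i, b] = (c[i, b] + alpha) / (sum_b c[i, b] + 4 * alpha)``.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[1] != 4 or c.shape[0] < 1:
        raise ValueError("counts must be a (width, 4) matrix with width >= 1")
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = c.sum(axis=1) + 4.0 * alpha
    if (totals <= 0).any():
        bad = int(np.argmin(totals))
        raise ValueError(f"all-zero count column {bad} with alpha=0")
    freq = (c + alpha) / totals[:, None]
    return PSSM(name, freq, source_counts=c, pseudocount=alpha)


def pssm_from_iupac(consensus: str, name: str | None = None) -> PSSM:
    """Convert an IUPAC consensus into a PSSM, uniform over each code's bases."""
    if not consensus:
        raise ValueError("empty consensus string")
    freq = np.zeros((len(consensus), 4))
    for i, ch in enumerate(consensus.upper()):
        allowed = IUPAC_CODES.get(ch)
        if allowed is None:
            raise ValueError(f"non-IUPAC character {ch!r} at position {i}")
        for b in allowed:
            freq[i, BASE_INDEX[b]] = 1.0 / len(allowed)
    return PSSM(name or consensus.upper(), freq)


def _similarity_table(pssm: PSSM) -> np.ndarray:
    """(width, 5) table of f[i,b]/max_b f[i,:]; the fifth row (N) contributes 0."""
    f = pssm.frequencies
    colmax = f.max(axis=1)
    table = np.zeros((pssm.width, 5))
    table[:, :4] = f / colmax[:, None]
    return table


def site_similarity(pssm: PSSM, word: str) -> float:
    """Percent similarity of one word to a PSSM.

    Mean over columns of ``f[b_i, i] / max_b f[b, i]`` times 100; a column
    holding an N contributes 0.
    """
    if len(word) != pssm.width:
        raise ValueError(f"word length {len(word)} != PSSM width {pssm.width}")
    enc = encode_sequence(word)
    table = _similarity_table(pssm)
    return float(100.0 * table[np.arange(pssm.width), enc].mean())


def _window_similarities(table: np.ndarray, enc: np.ndarray) -> np.ndarray:
    """Similarity (0-100) of every window of ``enc`` against a similarity table."""
    w = table.shape[0]
    n = len(enc) - w + 1
    if n <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    per_col = table[np.arange(w)[None, :], windows]
    return 100.0 * per_col.mean(axis=1)


def scan(
    pssm: PSSM,
    sequence: str,
    threshold_percent: float,
    sequence_id: str = "seq",
    both_strands: bool = True,
) -> list[SiteHit]:
    """All windows with ``site_similarity >= threshold`` on one or both strands.

    Reverse-strand hits are reported at the forward coordinate of the window
    start; hits are sorted by offset, forward strand first on ties. Sequences
    shorter than the motif yield an empty list.
    """
    if not (0.0 <= threshold_percent <= 100.0):
        raise ValueError("threshold must be in [0, 100]")
    seq = sequence.upper()
    w = pssm.width
    if len(seq) < w:
        return []
    enc = encode_sequence(seq)
    hits: list[SiteHit] = []
    strands = [("+", pssm)] + ([("-", pssm.reverse_complement())] if both_strands else [])
    for strand, mat in strands:
        sims = _window_similarities(_similarity_table(mat), enc)
        for off in np.flatnonzero(sims >= threshold_percent - 1e-9):
            word = seq[off : off + w]
            if strand == "-":
                word = reverse_complement(word)
            hits.append(SiteHit(sequence_id, int(off), strand, float(sims[off]), word))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def best_similarity(pssm: PSSM, sequence: str, both_strands: bool = True) -> float:
    """Best window similarity of a PSSM in a sequence (0 if shorter than width)."""
    seq = sequence.upper()
    if len(seq) < pssm.width:
        return 0.0
    enc = encode_sequence(seq)
    best = _window_similarities(_similarity_table(pssm), enc).max()
    if both_strands:
        rc = _window_similarities(_similarity_table(pssm.reverse_complement()), enc).max()
        best = max(best, rc)
    return float(best)


class NoAdmissibleOverlapError(ValueError):
    """No ungapped offset satisfies the minimum-overlap requirement."""


def pssm_identity(
    a: PSSM,
    b: PSSM,
    min_overlap_fraction: float = 0.75,
    min_overlap: int | None = None,
) -> tuple[float, int, str]:
    """Best ungapped percent identity between two PSSMs.

    Per overlapping column the identity is the allele-sharing coefficient
    ``1 - 0.5 * sum_b |fa[b] - fb[b]|`` in [0, 1]; the reported identity is
    100 times its mean over the overlap, maximised over all offsets with
    overlap >= ``max(4, ceil(min_overlap_fraction * min(widths)))`` (or the
    explicit ``min_overlap``) and over b's reverse complement.

    Returns ``(percent, offset, orientation)`` where ``offset`` is the
    position of b's first column relative to a's first column (may be
    negative) and orientation is ``+`` (b as given) or ``-`` (b reverse
    complemented). Ties resolve toward the forward orientation, then the
    smallest offset.
    """
    if min_overlap is None:
        min_overlap = max(4, math.ceil(min_overlap_fraction * min(a.width, b.width)))
    if min_overlap > min(a.width, b.width):
        raise NoAdmissibleOverlapError(
            f"min overlap {min_overlap} exceeds the shorter width "
            f"min({a.width}, {b.width})"
        )
    fa = a.frequencies
    best: tuple[float, int, str] | None = None
    for orient, fb in (("+", b.frequencies), ("-", b.frequencies[::-1, ::-1])):
        wb = fb.shape[0]
        for offset in range(-(wb - min_overlap), a.width - min_overlap + 1):
            lo_a, hi_a = max(0, offset), min(a.width, offset + wb)
            if hi_a - lo_a < min_overlap:
                continue
            seg_a = fa[lo_a:hi_a]
            seg_b = fb[lo_a - offset : hi_a - offset]
            ci = 1.0 - 0.5 * np.abs(seg_a - seg_b).sum(axis=1)
            score = 100.0 * float(ci.mean())
            if best is None or score > best[0] + 1e-12:
                best = (score, offset, orient)
    assert best is not None
    return best


def information_content(pssm: PSSM) -> tuple[np.ndarray, float]:
    """Per-column information content in bits and its total.

    ``IC_i = 2 + sum_b f log2 f`` with the convention ``0 * log 0 = 0``.
    """
    f = pssm.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
    per_col = 2.0 + term.sum(axis=1)
    return per_col, float(per_col.sum())
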