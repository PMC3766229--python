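"""De novo motif discovery over UCR sets.

A seeded ZOOPS-style Gibbs sampler provides the detection stage: per restart,
sites are initialised at random (one candidate per sequence), then each
sequence in turn has its site resampled from the posterior over all windows
on both strands — proportional to the likelihood ratio of the leave-one-out
PSSM against a background model — with a "no site" option so sequences
lacking the motif can drop out. The best configuration per restart is kept by
MAP score and results are deduplicated by PSSM identity.

Significance for internally discovered motifs is a Monte-Carlo proxy: the
discovery run is repeated on dinucleotide-shuffled copies of the input and
the observed MAP score is ranked among the shuffled optima. Externally
discovered motifs (MEME minimal format) are imported with their genuine
E-values instead.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .pssm_core import BASES, PSSM, pssm_from_counts, pssm_identity

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.int8)
_LOG_FLOOR = 1e-9


@dataclass
class DiscoveredMotif:
    """A motif produced by discovery or imported from an external finder."""

    pssm: PSSM
    sites: list[tuple[str, int, str]] = field(default_factory=list)
    map_score: float | None = None
    evalue: float | None = None
    finder: str = "internal"
    meta: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        return self.pssm.name

    @property
    def width(self) -> int:
        return self.pssm.width


@dataclass(frozen=True)
class Background:
    """Order-0 or order-1 nucleotide background model."""

    order: int
    composition: np.ndarray  # (4,)
    transition: np.ndarray | None = None  # (4, 4), rows sum to 1 (order 1)

    def log_prob_words(self, words: np.ndarray) -> np.ndarray:
        """Log probability of each encoded word (rows of an int matrix)."""
        w = np.asarray(words)
        safe = np.clip(w, 0, 3)
        logc = np.log(np.clip(self.composition, _LOG_FLOOR, None))
        if self.order == 0:
            ll = logc[safe].sum(axis=-1)
        else:
            logt = np.log(np.clip(self.transition, _LOG_FLOOR, None))
            ll = logc[safe[..., 0]] + logt[safe[..., :-1], safe[..., 1:]].sum(axis=-1)
        return np.where((w == 4).any(axis=-1), -np.inf, ll)


def fit_background(ucrs: Mapping[str, str], order: int = 0) -> Background:
    """Fit a background model on the UCR set (mononucleotide or first-order)."""
    if order not in (0, 1):
        raise ValueError("background order must be 0 or 1")
    from .pssm_core import encode_sequence

    counts = np.zeros(4)
    trans = np.zeros((4, 4))
    for seq in ucrs.values():
        enc = encode_sequence(seq)
        valid = enc[enc < 4]
        counts += np.bincount(valid, minlength=4)
        if order == 1 and len(enc) > 1:
            a, b = enc[:-1], enc[1:]
            ok = (a < 4) & (b < 4)
            np.add.at(trans, (a[ok], b[ok]), 1.0)
    comp = counts / counts.sum() if counts.sum() else np.full(4, 0.25)
    if order == 0:
        return Background(0, comp)
    row = trans.sum(axis=1, keepdims=True)
    trans = np.where(row > 0, trans / np.where(row > 0, row, 1.0), 0.25)
    return Background(1, comp, trans)


class _SeqWindows:
    """Precomputed candidate-site windows for one sequence, both strands."""

    def __init__(self, seq_id: str, enc: np.ndarray, width: int, background: Background):
        self.seq_id = seq_id
        n = len(enc) - width + 1
        fwd = np.lib.stride_tricks.sliding_window_view(enc, width)
        rev = _COMP[fwd[:, ::-1]]
        self.words = np.vstack([fwd, rev]).astype(np.int64)  # (2n, width)
        self.n_forward = n
        self.bg_ll = background.log_prob_words(self.words)
        self.valid = ~np.isinf(self.bg_ll)

    def option_site(self, idx: int) -> tuple[int, str]:
        if idx < self.n_forward:
            return idx, "+"
        return idx - self.n_forward, "-"


def map_score(
    motif: DiscoveredMotif,
    ucrs: Mapping[str, str],
    background: Background | None = None,
) -> float:
    """MAP score of a motif's site set against a background model.

    ``MAP = (1/ln 2) * sum_sites ln[P(site|PSSM)/P(site|bg)]
    - n_sites * log2(total admissible positions)`` where admissible positions
    count every window on both strands of every sequence. Zero sites score 0.
    """
    if not motif.sites:
        return 0.0
    from .pssm_core import encode_sequence, reverse_complement

    bg = background or fit_background(ucrs, order=1)
    w = motif.width
    total_positions = sum(
        2 * max(0, len(s) - w + 1) for s in ucrs.values()
    )
    logf = np.log(np.clip(motif.pssm.frequencies, _LOG_FLOOR, None))
    total_llr = 0.0
    for seq_id, offset, strand in motif.sites:
        seq = ucrs[seq_id]
        word = seq[offset : offset + w]
        if strand == "-":
            word = reverse_complement(word)
        enc = encode_sequence(word)
        if (enc == 4).any():
            continue
        site_ll = logf[np.arange(w), enc].sum()
        bg_ll = bg.log_prob_words(enc[None, :])[0]
        total_llr += site_ll - bg_ll
    return total_llr / math.log(2) - len(motif.sites) * math.log2(total_positions)


def gibbs_discover(
    ucrs: Mapping[str, str],
    width: int,
    n_restarts: int = 10,
    iterations: int = 500,
    seed: int | None = None,
    pseudocount: float = 0.25,
    occupancy_prior: float = 0.8,
    background: Background | None = None,
    dedup_identity: float = 95.0,
) -> list[DiscoveredMotif]:
    """ZOOPS Gibbs sampling motif discovery, deterministic under a fixed seed.

    Returns motifs sorted by MAP score descending, deduplicated at
    ``dedup_identity`` percent PSSM identity (best representative kept).
    """
    from .pssm_core import encode_sequence

    if len(ucrs) < 2:
        raise ValueError("need at least 2 sequences")
    shortest = min(len(s) for s in ucrs.values())
    if width > shortest:
        raise ValueError(f"width {width} exceeds shortest sequence ({shortest})")

    bg = background or fit_background(ucrs, order=1)
    seq_ids = sorted(ucrs)
    seqs = [_SeqWindows(sid, encode_sequence(ucrs[sid]), width, bg) for sid in seq_ids]
    total_positions = sum(s.words.shape[0] for s in seqs)
    log_tp = math.log2(total_positions)
    rng = np.random.default_rng(seed)

    def build_counts(assign: list[int]) -> tuple[np.ndarray, int]:
        counts = np.zeros((width, 4))
        n = 0
        for s, idx in zip(seqs, assign):
            if idx >= 0:
                np.add.at(counts, (np.arange(width), s.words[idx]), 1.0)
                n += 1
        return counts, n

    def state_map(assign: list[int]) -> float:
        counts, n = build_counts(assign)
        if n == 0:
            return 0.0
        freqs = (counts + pseudocount) / (n + 4 * pseudocount)
        logf = np.log(np.clip(freqs, _LOG_FLOOR, None))
        total = 0.0
        for s, idx in zip(seqs, assign):
            if idx < 0:
                continue
            word = s.words[idx]
            total += logf[np.arange(width), word].sum() - s.bg_ll[idx]
        return total / math.log(2) - n * log_tp

    results: list[DiscoveredMotif] = []
    log_q = math.log(occupancy_prior)
    log_noq = math.log(1.0 - occupancy_prior)
    for restart in range(n_restarts):
        assign = [int(rng.integers(0, s.words.shape[0])) for s in seqs]
        for i, s in enumerate(seqs):  # never start on an N-containing window
            if not s.valid[assign[i]]:
                choices = np.flatnonzero(s.valid)
                assign[i] = int(rng.choice(choices)) if len(choices) else -1
        counts, n_assigned = build_counts(assign)
        best_map, best_assign = -np.inf, list(assign)
        for _ in range(iterations):
            for i, s in enumerate(seqs):
                if assign[i] >= 0:
                    np.subtract.at(counts, (np.arange(width), s.words[assign[i]]), 1.0)
                    n_assigned -= 1
                freqs = (counts + pseudocount) / (max(n_assigned, 0) + 4 * pseudocount)
                logf = np.log(np.clip(freqs, _LOG_FLOOR, None))
                motif_ll = logf[np.arange(width)[None, :], np.clip(s.words, 0, 3)].sum(axis=1)
                logw = log_q - math.log(s.words.shape[0]) + motif_ll - s.bg_ll
                logw[~s.valid] = -np.inf
                all_logw = np.append(logw, log_noq)
                all_logw -= all_logw.max()
                p = np.exp(all_logw)
                p /= p.sum()
                choice = int(rng.choice(len(p), p=p))
                assign[i] = -1 if choice == len(p) - 1 else choice
                if assign[i] >= 0:
                    np.add.at(counts, (np.arange(width), s.words[assign[i]]), 1.0)
                    n_assigned += 1
            current = state_map(assign)
            if current > best_map:
                best_map, best_assign = current, list(assign)
        b_counts, b_n = build_counts(best_assign)
        if b_n == 0:
            continue
        pssm = pssm_from_counts(b_counts, pseudocount, name=f"motif_r{restart}")
        sites = []
        for s, idx in zip(seqs, best_assign):
            if idx >= 0:
                off, strand = s.option_site(idx)
                sites.append((s.seq_id, off, strand))
        results.append(
            DiscoveredMotif(
                pssm=pssm,
                sites=sites,
                map_score=best_map,
                finder="internal",
                meta={"width": width, "seed": seed, "restarts": n_restarts,
                      "iterations": iterations, "restart": restart},
            )
        )

    results.sort(key=lambda m: -(m.map_score or 0.0))
    kept: list[DiscoveredMotif] = []
    for cand in results:
        dup = False
        for ref in kept:
            ident, _, _ = pssm_identity(cand.pssm, ref.pssm)
            if ident >= dedup_identity:
                dup = True
                break
        if not dup:
            kept.append(cand)
    for rank, m in enumerate(kept, start=1):
        m.pssm = dataclasses.replace(m.pssm, name=f"motif_{rank}")
    return kept


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its dinucleotide counts exactly.

    Altschul–Erickson edge shuffling: the sequence is an Eulerian path in the
    graph whose edges are its dinucleotides; a random last-edge arborescence
    toward the final character is drawn, remaining out-edges are permuted,
    and a new Eulerian walk is read off. First and last characters are fixed.
    """
    if len(seq) <= 2:
        return seq
    chars = list(seq)
    first, last = chars[0], chars[-1]
    edges: dict[str, list[str]] = {}
    for a, b in zip(chars, chars[1:]):
        edges.setdefault(a, []).append(b)
        edges.setdefault(b, [])
    verts = list(edges)
    while True:
        lastedge = {}
        for v in verts:
            if v == last or not edges[v]:
                continue
            lastedge[v] = edges[v][int(rng.integers(len(edges[v])))]
        ok = True
        for v in lastedge:
            seen, u = set(), v
            while u != last:
                if u in seen or u not in lastedge:
                    ok = False
                    break
                seen.add(u)
                u = lastedge[u]
            if not ok:
                break
        if ok:
            break
    shuffled: dict[str, list[str]] = {}
    for v in verts:
        pool = list(edges[v])
        if v in lastedge:
            pool.remove(lastedge[v])
        perm = [pool[i] for i in rng.permutation(len(pool))]
        if v in lastedge:
            perm.append(lastedge[v])
        shuffled[v] = perm
    out = [first]
    ptr = {v: 0 for v in verts}
    u = first
    for _ in range(len(chars) - 1):
        nxt = shuffled[u][ptr[u]]
        ptr[u] += 1
        out.append(nxt)
        u = nxt
    return "".join(out)


def empirical_significance(
    motif: DiscoveredMotif,
    ucrs: Mapping[str, str],
    n_shuffles: int = 19,
    seed: int | None = None,
    background: Background | None = None,
    **gibbs_kwargs,
) -> float:
    """Monte-Carlo significance proxy for an internally discovered motif.

    Reruns discovery at the motif's width on dinucleotide-shuffled copies of
    the UCR set; the proxy is ``(1 + #{shuffled best MAP >= observed}) /
    (n_shuffles + 1)``, so its floor is ``1/(n_shuffles + 1)``. The shuffle
    count is recorded in ``motif.meta["n_shuffles"]`` so the filter cascade
    can recover the floor; assign the returned proxy to ``motif.evalue`` to
    have the cascade apply it.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    observed = motif.map_score
    if observed is None:
        observed = map_score(motif, ucrs, background)
    rng = np.random.default_rng(seed)
    gibbs_kwargs.setdefault("n_restarts", motif.meta.get("restarts", 5))
    gibbs_kwargs.setdefault("iterations", motif.meta.get("iterations", 200))
    exceed = 0
    for _ in range(n_shuffles):
        shuffled = {sid: dinucleotide_shuffle(s, rng) for sid, s in ucrs.items()}
        child_seed = int(rng.integers(0, 2**31 - 1))
        found = gibbs_discover(shuffled, motif.width, seed=child_seed, **gibbs_kwargs)
        best = max((m.map_score or -np.inf) for m in found) if found else -np.inf
        if best >= observed:
            exceed += 1
    motif.meta["n_shuffles"] = n_shuffles
    return (1 + exceed) / (n_shuffles + 1)


def import_meme_motifs(path: str | Path) -> list[DiscoveredMotif]:
    """Import motifs from a MEME minimal-format file.

    Letter-probability matrices become PSSMs at full printed precision and
    the header's ``E=`` token is kept as the motif's E-value; malformed
    matrix rows (not 4 numbers, or not summing to ~1) raise with their line
    number. An empty file yields an empty list.
    """
    text = Path(path).read_text()
    if not text.strip():
        return []
    out: list[DiscoveredMotif] = []
    name: str | None = None
    evalue: float | None = None
    rows: list[list[float]] = []
    in_matrix = False

    def flush() -> None:
        nonlocal name, evalue, rows, in_matrix
        if name is not None and rows:
            freq = np.asarray(rows)
            out.append(
                DiscoveredMotif(
                    pssm=PSSM(name, freq),
                    sites=[],
                    map_score=None,
                    evalue=evalue,
                    finder="imported",
                    meta={"width": freq.shape[0], "source": str(path)},
                )
            )
        name, evalue, rows, in_matrix = None, None, [], False

    for lineno, line in enumerate(text.splitlines(), 1):
        stripped = line.strip()
        first = stripped.split()[0].upper() if stripped else ""
        if first == "MOTIF":
            flush()
            tokens = stripped.split()
            name = tokens[1] if len(tokens) > 1 else f"imported_{len(out) + 1}"
            continue
        if stripped.lower().startswith("letter-probability matrix"):
            in_matrix = True
            tokens = stripped.replace("=", "= ").split()
            if "E=" in tokens:
                evalue = float(tokens[tokens.index("E=") + 1])
            continue
        if in_matrix:
            if not stripped or first in ("URL",):
                in_matrix = False
                continue
            try:
                row = [float(x) for x in stripped.split()]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric matrix row") from None
            if len(row) != 4:
                raise ValueError(f"{path}:{lineno}: matrix row has {len(row)} values, expected 4")
            if abs(sum(row) - 1.0) > 0.01:
                raise ValueError(f"{path}:{lineno}: matrix row sums to {sum(row):.4f}, expected ~1")
            rows.append(row)
    flush()
    return out


def write_meme_minimal(
    motifs: Sequence[DiscoveredMotif], path: str | Path,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> None:
    """Write motifs in MEME minimal format (letter-probability matrices)."""
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: + -", "",
             "Background letter frequencies",
             " ".join(f"{b} {f:.4f}" for b, f in zip(BASES, background)), ""]
    for m in motifs:
        lines.append(f"MOTIF {m.name}")
        ev = f" E= {m.evalue:g}" if m.evalue is not None else ""
        lines.append(
            f"letter-probability matrix: alength= 4 w= {m.width} "
            f"nsites= {max(len(m.sites), 1)}{ev}"
        )
        for row in m.pssm.frequencies:
            lines.append(" " + " ".join(f"{v:.6f}" for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_site_table(motifs: Sequence[DiscoveredMotif], path: str | Path) -> None:
    """TSV of discovered sites: motif, sequence id, offset, strand."""
    import pandas as pd

    rows = [
        {"motif": m.name, "sequence_id": sid, "offset": off, "strand": strand}
        for m in motifs
        for sid, off, strand in m.sites
    ]
    pd.DataFrame(rows, columns=["motif", "sequence_id", "offset", "strand"]).to_csv(
        path, sep="\t", index=False
    )
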