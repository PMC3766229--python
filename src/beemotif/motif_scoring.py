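"""Specificity statistics and the two-stage filter cascade.

Three per-motif statistics decide whether a discovered motif is
overrepresented in a gene group relative to the promoter universe:

* Church score — group specificity: the hypergeometric upper tail
  ``P(K >= x)`` for ``K ~ Hypergeom(N, X, s)``, where x of the s group
  sequences and X of the N universe sequences contain the motif.
* ROC-AUC — discrimination: the probability that a random group sequence
  outscores a random background sequence, i.e. the normalised Mann-Whitney U
  with ties credited half.
* Enrichment score — the binomial upper tail ``P(B >= x)`` for
  ``B ~ Binomial(s, X/N)``.

"Contains the motif" means at least one scan hit at the scanning threshold —
presence per sequence, not occurrence counts, which keeps the hypergeometric
model exact. The cascade applies a detection-quality filter (MAP score and,
for imported motifs, the finder's E-value) followed by the specificity
filter; thresholds are configurable and raw values are always reported so
users may apply their own multiple-testing correction downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motif_discovery import Background, DiscoveredMotif
from .pssm_core import PSSM, best_similarity, scan


@dataclass
class MotifScoreReport:
    """The three specificity statistics plus presence counts for one motif."""

    motif_name: str
    church_p: float
    roc_auc: float
    enrichment_p: float
    x: int  # group sequences containing the motif
    s: int  # group size
    X: int  # universe sequences containing the motif
    N: int  # universe size
    filter1_pass: bool | None = None
    filter2_pass: bool | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.church_p <= 1.0 and 0.0 <= self.enrichment_p <= 1.0):
            raise ValueError("p-values must lie in [0, 1]")
        if not (0.0 <= self.roc_auc <= 1.0):
            raise ValueError("ROC-AUC must lie in [0, 1]")
        if not (0 <= self.x <= min(self.X, self.s) and self.s <= self.N):
            raise ValueError(f"inconsistent counts x={self.x} s={self.s} X={self.X} N={self.N}")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the two-stage cascade."""

    map_min: float = 5.0
    evalue_max: float = 1e-05  # imported motifs carrying a genuine E-value
    internal_proxy_max: float | None = None  # None: proxy must sit at its floor
    church_max: float = 1e-04
    roc_auc_min: float = 0.7
    enrichment_p_max: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.evalue_max and 0 < self.church_max <= 1
                and 0 <= self.roc_auc_min <= 1 and 0 < self.enrichment_p_max <= 1):
            raise ValueError("filter thresholds out of range")


def presence_counts(
    pssm: PSSM,
    group_ucrs: Mapping[str, str],
    universe_ucrs: Mapping[str, str],
    scan_threshold: float,
) -> tuple[int, int, int, int]:
    """(x, s, X, N): per-sequence motif presence in group and universe.

    Presence means at least one scan hit at the threshold, on either strand.
    The group must be a subset of the universe.
    """
    if not set(group_ucrs) <= set(universe_ucrs):
        raise ValueError("group sequences must be a subset of the universe")
    present = {
        sid: best_similarity(pssm, seq) >= scan_threshold - 1e-9
        for sid, seq in universe_ucrs.items()
    }
    X = sum(present.values())
    x = sum(present[sid] for sid in group_ucrs)
    return int(x), len(group_ucrs), int(X), len(universe_ucrs)


def church_score(x: int, s: int, X: int, N: int) -> float:
    """Hypergeometric upper tail P(K >= x), K ~ Hypergeom(N, X, s)."""
    _check_counts(x, s, X, N)
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, X, s))


def enrichment_score(x: int, s: int, X: int, N: int) -> float:
    """Binomial upper tail P(B >= x), B ~ Binomial(s, X/N)."""
    _check_counts(x, s, X, N)
    if x == 0:
        return 1.0
    if X == 0:
        raise ValueError("X = 0 with x > 0: motif present in group but absent from universe")
    return float(stats.binom.sf(x - 1, s, X / N))


def _check_counts(x: int, s: int, X: int, N: int) -> None:
    if not (0 <= x <= min(X, s) and 0 <= X <= N and 0 < s <= N):
        raise ValueError(f"invalid presence counts x={x} s={s} X={X} N={N}")


def roc_auc(group_scores: Sequence[float], background_scores: Sequence[float]) -> float:
    """Normalised Mann-Whitney U: P(group score > background score) + ties/2."""
    g = np.asarray(group_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if g.size == 0 or b.size == 0:
        raise ValueError("both score lists must be nonempty")
    ranks = stats.rankdata(np.concatenate([g, b]))
    u = ranks[: g.size].sum() - g.size * (g.size + 1) / 2.0
    return float(u / (g.size * b.size))


def score_motif(
    motif: DiscoveredMotif | PSSM,
    group_ucrs: Mapping[str, str],
    universe_ucrs: Mapping[str, str],
    scan_threshold: float = 85.0,
) -> MotifScoreReport:
    """Compute all three statistics for one motif against a universe.

    ROC-AUC compares best-window similarities of group sequences against the
    non-group remainder of the universe. The default presence threshold (85)
    is stricter than the 70 used for consensus-site scanning because
    count-derived matrices admit partial credit at every column; at 70 an
    informative 8-mer is "present" in nearly every kilobase of background,
    which would void the presence statistics.
    """
    pssm = motif.pssm if isinstance(motif, DiscoveredMotif) else motif
    x, s, X, N = presence_counts(pssm, group_ucrs, universe_ucrs, scan_threshold)
    group_scores = [best_similarity(pssm, seq) for seq in group_ucrs.values()]
    bg_scores = [
        best_similarity(pssm, seq)
        for sid, seq in universe_ucrs.items()
        if sid not in group_ucrs
    ]
    auc = roc_auc(group_scores, bg_scores) if bg_scores else 0.5
    return MotifScoreReport(
        motif_name=pssm.name,
        church_p=church_score(x, s, X, N),
        roc_auc=auc,
        enrichment_p=enrichment_score(x, s, X, N) if X > 0 or x == 0 else 1.0,
        x=x, s=s, X=X, N=N,
    )


def filter_cascade(
    motifs: Sequence[DiscoveredMotif],
    reports: Mapping[str, MotifScoreReport],
    config: FilterConfig | None = None,
) -> tuple[list[DiscoveredMotif], pd.DataFrame]:
    """Apply both filters; return retained motifs and a verdict table.

    Filter 1 (detection quality): MAP score above ``map_min`` and, when the
    motif carries a significance value, that value at or below its threshold
    (the finder E-value for imported motifs; the Monte-Carlo proxy for
    internal ones — by default required to sit at its attainable floor
    ``1/(n_shuffles + 1)``).
    Filter 2 (specificity): Church <= ``church_max``, ROC-AUC >=
    ``roc_auc_min`` and enrichment p <= ``enrichment_p_max``.
    """
    config = config or FilterConfig()
    rows = []
    retained: list[DiscoveredMotif] = []
    for m in motifs:
        report = reports.get(m.name)
        if report is None:
            raise KeyError(f"no score report for motif {m.name!r}")
        if m.map_score is None:
            raise ValueError(f"motif {m.name!r} has no MAP score")
        f1 = m.map_score > config.map_min
        if m.evalue is not None:
            if m.finder == "imported":
                f1 = f1 and m.evalue <= config.evalue_max
            else:
                proxy_max = config.internal_proxy_max
                if proxy_max is None:
                    n_shuffles = m.meta.get("n_shuffles")
                    proxy_max = (
                        1.0 / (n_shuffles + 1) + 1e-12 if n_shuffles else config.evalue_max
                    )
                f1 = f1 and m.evalue <= proxy_max
        f2 = (
            report.church_p <= config.church_max
            and report.roc_auc >= config.roc_auc_min
            and report.enrichment_p <= config.enrichment_p_max
        )
        report.filter1_pass, report.filter2_pass = bool(f1), bool(f2)
        if f1 and f2:
            retained.append(m)
        rows.append(
            {
                "motif": m.name, "finder": m.finder, "map_score": m.map_score,
                "evalue": m.evalue, "church_p": report.church_p,
                "roc_auc": report.roc_auc, "enrichment_p": report.enrichment_p,
                "x": report.x, "s": report.s, "X": report.X, "N": report.N,
                "filter1_pass": bool(f1), "filter2_pass": bool(f2),
                "retained": bool(f1 and f2),
            }
        )
    columns = ["motif", "finder", "map_score", "evalue", "church_p", "roc_auc",
               "enrichment_p", "x", "s", "X", "N", "filter1_pass",
               "filter2_pass", "retained"]
    return retained, pd.DataFrame(rows, columns=columns)


def write_score_table(reports: Sequence[MotifScoreReport], path) -> None:
    """MotifScoreReport table as TSV, one row per motif."""
    pd.DataFrame(
        [
            {
                "motif": r.motif_name, "church_p": r.church_p, "roc_auc": r.roc_auc,
                "enrichment_p": r.enrichment_p, "x": r.x, "s": r.s, "X": r.X,
                "N": r.N, "filter1_pass": r.filter1_pass, "filter2_pass": r.filter2_pass,
            }
            for r in reports
        ]
    ).to_csv(path, sep="\t", index=False)
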