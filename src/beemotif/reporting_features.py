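"""Small quantitative side-procedures around the core pipeline.

Covers the bookkeeping a microarray/RT-qPCR integument study reports next to
its motif analysis: summarising differential-expression spot tables into
counts and percentages, cross-platform concordance between microarray and
RT-qPCR calls, qPCR amplification efficiency from a standard-curve slope,
and sequence features of candidate cuticular proteins (glycine content,
GGYGG/GGY motifs, molecular mass, mature-form recomputation from a supplied
signal-peptide span).

Rounding deliberately reproduces how such studies print their numbers:
array percentages to one decimal, gene-set shares to two, and concordance
truncated (floored) to one decimal.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.SeqUtils import molecular_weight

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
DIRECTIONS = {"up", "down", "unchanged"}


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence plus optional signal-peptide span (input metadata).

    The span is 0-based half-open over the precursor; it is never predicted
    here, only applied.
    """

    id: str
    sequence: str
    signal_peptide: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id}: empty sequence")
        bad = set(self.sequence.upper()) - AMINO_ACIDS
        if bad:
            raise ValueError(f"protein {self.id}: non-amino-acid characters {sorted(bad)}")
        if self.signal_peptide is not None:
            a, b = self.signal_peptide
            if not (0 <= a < b <= len(self.sequence)):
                raise ValueError(f"protein {self.id}: invalid signal-peptide span")

    @property
    def mature_sequence(self) -> str | None:
        if self.signal_peptide is None:
            return None
        a, b = self.signal_peptide
        return self.sequence[:a] + self.sequence[b:]


def deg_summary(
    spots: pd.DataFrame,
    array_size: int,
    per_comparison_unique_gene_sets: Mapping[str, Iterable[str]],
) -> dict:
    """Summarise spot-level differential-expression calls.

    ``spots`` needs columns spot_id, gene_id (empty/NaN for non-OGS spots),
    comparison, direction in {up, down}, significant (bool). Per comparison
    the summary reports significant-spot counts, their percent of the array
    (one decimal) and the OGS share (two decimals); across comparisons it
    reports unique-gene counts, the union size, and up/down gene counts.
    """
    if spots.empty:
        raise ValueError("empty spot table")
    required = {"spot_id", "gene_id", "comparison", "direction", "significant"}
    if not required <= set(spots.columns):
        raise ValueError(f"spot table missing columns {sorted(required - set(spots.columns))}")
    bad = set(spots["direction"]) - {"up", "down"}
    if bad:
        raise ValueError(f"invalid directions {sorted(bad)}")
    per_comparison = {}
    for comp, sub in spots.groupby("comparison", sort=True):
        if sub["spot_id"].duplicated().any():
            raise ValueError(f"duplicate spot ids in comparison {comp!r}")
        sig = sub[sub["significant"]]
        n_sig = len(sig)
        if n_sig > array_size:
            raise ValueError("more significant spots than array positions")
        ogs = sig[sig["gene_id"].notna() & (sig["gene_id"].astype(str) != "")]
        genes = set(per_comparison_unique_gene_sets.get(comp, set(ogs["gene_id"])))
        per_comparison[comp] = {
            "n_significant_spots": n_sig,
            "percent_of_array": round(100.0 * n_sig / array_size, 1),
            "n_ogs_spots": len(ogs),
            "percent_ogs": round(100.0 * len(ogs) / n_sig, 2) if n_sig else 0.0,
            "n_unique_genes": len(genes),
            "n_up_genes": len(set(ogs.loc[ogs["direction"] == "up", "gene_id"])),
            "n_down_genes": len(set(ogs.loc[ogs["direction"] == "down", "gene_id"])),
        }
    union: set[str] = set()
    for genes in per_comparison_unique_gene_sets.values():
        union |= set(genes)
    return {"per_comparison": per_comparison, "n_union_genes": len(union)}


def concordance(table: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Percent agreement between two platforms' direction calls.

    ``table`` needs columns gene_id, comparison, direction_platform1,
    direction_platform2 with values in {up, down, unchanged}. Agreement is
    rows with equal directions over total, times 100, floored to one decimal
    (58/72 reports as 80.5). Returns the percent and the table with a
    per-row ``agree`` column.
    """
    if table.empty:
        raise ValueError("empty concordance table")
    for col in ("direction_platform1", "direction_platform2"):
        bad = set(table[col]) - DIRECTIONS
        if bad:
            raise ValueError(f"invalid direction labels {sorted(bad)} in {col}")
    out = table.copy()
    out["agree"] = out["direction_platform1"] == out["direction_platform2"]
    percent = math.floor(1000.0 * out["agree"].sum() / len(out)) / 10.0
    return percent, out


def pcr_efficiency(slope: float) -> float:
    """Amplification efficiency from a standard-curve slope: E = 10^(-1/slope).

    A slope of -3.3219 (perfect doubling per cycle) gives E = 2. Nonnegative
    slopes are rejected as non-physical standard curves.
    """
    if slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    return 10.0 ** (-1.0 / slope)


def _find_overlapping(sequence: str, motif: str) -> list[int]:
    return [m.start() for m in re.finditer(f"(?={re.escape(motif)})", sequence)]


def _sequence_features(seq: str, monoisotopic: bool) -> dict:
    comp = {
        aa: round(100.0 * seq.count(aa) / len(seq), 1) for aa in sorted(AMINO_ACIDS)
    }
    return {
        "length": len(seq),
        "composition_percent": comp,
        "glycine_percent": comp["G"],
        "mass_da": float(molecular_weight(seq, seq_type="protein", monoisotopic=monoisotopic)),
        "ggygg_positions": _find_overlapping(seq, "GGYGG"),
        "ggy_positions": _find_overlapping(seq, "GGY"),
        "has_cysteine": "C" in seq,
    }


def protein_features(record: ProteinRecord, monoisotopic: bool = False) -> dict:
    """Sequence features of a candidate cuticular protein.

    Reports per-residue composition (one decimal), molecular mass in Da
    (average residue masses plus one water, or monoisotopic on request),
    positions of the glycine-rich GGYGG and GGY amino-acid motifs (overlaps
    allowed), a below-30-kDa flag, and — when a signal-peptide span was
    supplied as metadata — the same features for the mature form.
    """
    seq = record.sequence.upper()
    out = {"id": record.id, "precursor": _sequence_features(seq, monoisotopic)}
    out["precursor"]["below_30kda"] = out["precursor"]["mass_da"] < 30_000.0
    out["has_signal_peptide"] = record.signal_peptide is not None
    mature = record.mature_sequence
    if mature:
        out["mature"] = _sequence_features(mature.upper(), monoisotopic)
        out["mature"]["below_30kda"] = out["mature"]["mass_da"] < 30_000.0
    return out


def protein_feature_table(records: Sequence[ProteinRecord], monoisotopic: bool = False) -> pd.DataFrame:
    """Flat per-protein feature table (precursor and, where known, mature form)."""
    rows = []
    for rec in records:
        feats = protein_features(rec, monoisotopic)
        form = feats.get("mature", feats["precursor"])
        rows.append(
            {
                "id": rec.id,
                "length": feats["precursor"]["length"],
                "glycine_percent_precursor": feats["precursor"]["glycine_percent"],
                "glycine_percent_mature": feats.get("mature", {}).get("glycine_percent"),
                "mass_da": form["mass_da"],
                "below_30kda": form["below_30kda"],
                "n_ggygg": len(form["ggygg_positions"]),
                "n_ggy": len(form["ggy_positions"]),
                "has_signal_peptide": feats["has_signal_peptide"],
            }
        )
    return pd.DataFrame(rows)
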