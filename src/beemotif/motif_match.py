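"""Known-motif libraries and matching of discovered motifs to TF binding sites.

Reads TRANSFAC flat-file libraries (records delimited by ``//``, AC/ID lines,
a ``P0`` column header over A C G T, numbered matrix rows, optional BF lines
naming the binding factor), matches retained motifs against them at a
percent-identity threshold (70 by default, exhaustively above threshold so a
single motif may resemble several factors), and runs the FTZ-F1 consensus
analysis: the nuclear-receptor binding-site consensus YCAAGGTCR is converted
to a PSSM, scanned across a gene group's UCRs, and scored with the same
Church / ROC-AUC / enrichment statistics as discovered motifs.

The parser handles the flat-file *dialect* only; no proprietary matrix data
is bundled — libraries are supplied by the user or generated synthetically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motif_discovery import DiscoveredMotif
from .motif_scoring import MotifScoreReport, score_motif
from .pssm_core import (
    PSSM,
    NoAdmissibleOverlapError,
    SiteHit,
    pssm_from_counts,
    pssm_from_iupac,
    pssm_identity,
    scan,
)

log = logging.getLogger(__name__)

FTZF1_CONSENSUS = "YCAAGGTCR"


@dataclass(frozen=True)
class KnownMotif:
    """One library record: a TF binding-site count matrix with identifiers."""

    accession: str
    identifier: str
    tf_names: tuple[str, ...]
    pssm: PSSM

    @property
    def display_name(self) -> str:
        return self.tf_names[0] if self.tf_names else (self.identifier or self.accession)


@dataclass
class KnownMotifLibrary:
    records: list[KnownMotif] = field(default_factory=list)

    def __post_init__(self) -> None:
        idents = [r.identifier for r in self.records]
        if len(set(idents)) != len(idents):
            raise ValueError("duplicate identifiers in motif library")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, identifier: str) -> KnownMotif:
        for r in self.records:
            if r.identifier == identifier:
                return r
        raise KeyError(identifier)


@dataclass(frozen=True)
class MotifMatch:
    """A discovered-motif <-> known-motif alignment above threshold."""

    motif_name: str
    known_identifier: str
    tf_name: str
    identity: float
    offset: int
    orientation: str


def read_transfac(path: str | Path, alpha: float = 0.0) -> KnownMotifLibrary:
    """Parse a TRANSFAC flat-file motif library.

    Matrix rows may hold integer or real counts; each record's matrix is
    normalised into a PSSM via ``pssm_from_counts`` (no pseudocount by
    default, so frequency matrices round-trip exactly). A missing terminating
    ``//`` on the final record is tolerated with a logged warning; a matrix
    row without exactly four values raises, naming the record and line.
    """
    records: list[KnownMotif] = []
    acc = ident = None
    tf_names: list[str] = []
    rows: list[list[float]] = []
    in_matrix = False
    saw_record_data = False

    def flush(lineno: int) -> None:
        nonlocal acc, ident, tf_names, rows, in_matrix, saw_record_data
        if not saw_record_data:
            return
        if not rows:
            raise ValueError(f"record {ident or acc!r} before line {lineno} has no matrix")
        name = ident or acc or f"record_{len(records) + 1}"
        counts = np.asarray(rows, dtype=float)
        pssm = pssm_from_counts(counts, alpha=alpha, name=name)
        records.append(KnownMotif(acc or name, name, tuple(tf_names), pssm))
        acc = ident = None
        tf_names, rows = [], []
        in_matrix = saw_record_data = False

    lines = Path(path).read_text().splitlines()
    terminated = True
    for lineno, raw in enumerate(lines, 1):
        line = raw.rstrip()
        if not line.strip():
            continue
        tag = line[:2].upper()
        if line.strip() == "//":
            flush(lineno)
            terminated = True
            continue
        terminated = False
        if tag == "XX":
            in_matrix = False
            continue
        if tag == "AC":
            acc = line[2:].strip()
            saw_record_data = True
        elif tag == "ID":
            ident = line[2:].strip()
            saw_record_data = True
        elif tag in ("BF", "NA"):
            name = line[2:].strip()
            # TRANSFAC BF lines look like "T00123 factor name; species"
            parts = name.split(";")[0].split(None, 1)
            tf_names.append(parts[1] if len(parts) == 2 and parts[0].startswith("T0") else name)
            saw_record_data = True
        elif tag == "P0" or line.split()[0].upper() == "P0":
            in_matrix = True
            saw_record_data = True
        elif in_matrix and line.split()[0].rstrip(".").isdigit():
            fields = line.split()[1:]
            # trailing consensus letter is optional
            if fields and not _is_number(fields[-1]):
                fields = fields[:-1]
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: record {ident or acc!r} matrix row has "
                    f"{len(fields)} values, expected 4"
                )
            rows.append([float(v) for v in fields])
            saw_record_data = True
    if not terminated and saw_record_data:
        log.warning("%s: final record not terminated by //; accepted", path)
        flush(len(lines) + 1)
    return KnownMotifLibrary(records)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def match_to_known(
    retained_motifs: Sequence[DiscoveredMotif | PSSM],
    library: KnownMotifLibrary,
    identity_threshold: float = 70.0,
) -> list[MotifMatch]:
    """All (discovered, known) pairs at or above the identity threshold.

    Matches are reported exhaustively — one discovered motif may resemble
    several factors — sorted by identity descending.
    """
    if len(library) == 0:
        raise ValueError("motif library is empty")
    matches: list[MotifMatch] = []
    for m in retained_motifs:
        pssm = m.pssm if isinstance(m, DiscoveredMotif) else m
        for rec in library:
            try:
                ident, offset, orient = pssm_identity(pssm, rec.pssm)
            except NoAdmissibleOverlapError:
                continue
            if ident >= identity_threshold:
                matches.append(
                    MotifMatch(pssm.name, rec.identifier, rec.display_name,
                               ident, offset, orient)
                )
    matches.sort(key=lambda mm: -mm.identity)
    return matches


def ftzf1_site_analysis(
    ucrs: Mapping[str, str],
    group_ids: Sequence[str],
    threshold: float = 70.0,
    consensus: str = FTZF1_CONSENSUS,
) -> tuple[list[SiteHit], MotifScoreReport]:
    """Scan a gene group for FTZ-F1-like binding sites and score specificity.

    Builds a PSSM from the consensus, reports every site at least
    ``threshold`` percent similar in the group's UCRs, and computes the
    Church / ROC-AUC / enrichment statistics of the consensus motif for the
    group against the whole UCR universe.
    """
    missing = set(group_ids) - set(ucrs)
    if missing:
        raise KeyError(f"group ids not in UCR set: {sorted(missing)}")
    pssm = pssm_from_iupac(consensus, name="FTZ-F1")
    hits: list[SiteHit] = []
    for gid in group_ids:
        hits.extend(scan(pssm, ucrs[gid], threshold, sequence_id=gid))
    group = {gid: ucrs[gid] for gid in group_ids}
    report = score_motif(pssm, group, ucrs, scan_threshold=threshold)
    return hits, report


def write_matches(matches: Sequence[MotifMatch], path: str | Path) -> None:
    """Match table as TSV."""
    pd.DataFrame(
        [
            {
                "motif": m.motif_name, "known_motif": m.known_identifier,
                "tf_name": m.tf_name, "identity_percent": m.identity,
                "offset": m.offset, "orientation": m.orientation,
            }
            for m in matches
        ],
        columns=["motif", "known_motif", "tf_name", "identity_percent",
                 "offset", "orientation"],
    ).to_csv(path, sep="\t", index=False)


def write_hits(hits: Sequence[SiteHit], tsv_path: str | Path, bed_path: str | Path | None = None) -> None:
    """Site hits as TSV and optionally BED (0-based half-open)."""
    pd.DataFrame(
        [
            {
                "sequence_id": h.sequence_id, "offset": h.offset, "strand": h.strand,
                "similarity": h.similarity, "word": h.word,
            }
            for h in hits
        ],
        columns=["sequence_id", "offset", "strand", "similarity", "word"],
    ).to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for h in hits:
                end = h.offset + len(h.word)
                fh.write(
                    f"{h.sequence_id}\t{h.offset}\t{end}\tsite\t"
                    f"{h.similarity:.1f}\t{h.strand}\n"
                )
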