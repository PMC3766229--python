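"""Upstream control region (UCR) extraction.

For every gene the region upstream of its 5' end is taken as a promoter
proxy, capped at a requested length (3 kb by default) and trimmed back
whenever another annotated gene lies closer than the cap — neighbours on
either strand trim, since an open reading frame interrupts the intergenic
stretch regardless of its orientation. Gene boundaries stand in for ORF/TSS
coordinates because the gene sets targeted here carry no UTR annotation.

The emitted sequence is oriented promoter-to-gene (5'->3' toward the gene),
i.e. reverse complemented for minus-strand genes. Regions shorter than a
minimum length are excluded with a logged reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pssm_core import reverse_complement

log = logging.getLogger(__name__)

DEFAULT_UCR_LENGTH = 3000
DEFAULT_MIN_LENGTH = 30


@dataclass(frozen=True)
class GeneModel:
    """A gene locus in 0-based half-open coordinates."""

    id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.id}: invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class UCRRecord:
    """A gene's upstream control region with trimming provenance."""

    gene_id: str
    sequence: str
    requested_length: int
    trimmed_by: str | None
    contig: str
    start: int
    end: int
    strand: str

    @property
    def actual_length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if self.actual_length > self.requested_length:
            raise ValueError(f"UCR {self.gene_id}: longer than requested")
        if set(self.sequence.upper()) - set("ACGTN"):
            raise ValueError(f"UCR {self.gene_id}: alphabet outside ACGTN")


def read_annotation(
    path: str | Path,
    fmt: str | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> list[GeneModel]:
    """Read gene models from GFF3 or BED into 0-based half-open coordinates.

    Only ``gene`` features are taken from GFF3. Models are returned sorted by
    (contig, start); duplicate gene ids raise, as do coordinates outside the
    contig when ``contig_lengths`` is supplied.
    """
    path = Path(path)
    if fmt is None:
        fmt = "bed" if path.suffix.lower() == ".bed" else "gff3"
    fmt = fmt.lower()
    genes: list[GeneModel] = []
    if fmt == "bed":
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 6 fields")
            contig, start, end, name, _score, strand = fields[:6]
            genes.append(GeneModel(name, contig, int(start), int(end), strand))
    elif fmt in ("gff", "gff3"):
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        for feat in db.features_of_type("gene"):
            gid = feat.attributes.get("ID", [feat.id])[0]
            # GFF3 is 1-based inclusive; shift start to half-open convention
            genes.append(GeneModel(gid, feat.seqid, feat.start - 1, feat.end, feat.strand))
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")

    seen: set[str] = set()
    for g in genes:
        if g.id in seen:
            raise ValueError(f"duplicate gene id {g.id!r} in {path}")
        seen.add(g.id)
    if contig_lengths is not None:
        for g in genes:
            if g.contig not in contig_lengths:
                raise ValueError(f"gene {g.id}: unknown contig {g.contig!r}")
            if g.end > contig_lengths[g.contig]:
                raise ValueError(f"gene {g.id}: end {g.end} outside contig {g.contig}")
    genes.sort(key=lambda g: (g.contig, g.start, g.id))
    return genes


def extract_ucr(
    gene: GeneModel,
    annotation: Sequence[GeneModel],
    sequences: Mapping[str, str],
    requested_length: int = DEFAULT_UCR_LENGTH,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> UCRRecord | None:
    """Extract one gene's UCR, trimming at the nearest flanking gene.

    Plus strand: the interval ``[max(0, nearest upstream end, start - L), start)``.
    Minus strand: ``[end, min(contig end, nearest downstream start, end + L))``
    reverse complemented. ``trimmed_by`` names the neighbour when the
    neighbour — not the length cap or the contig edge — bounds the region.
    Returns None (with a logged reason) when the region is shorter than
    ``min_length``.
    """
    ids = {g.id for g in annotation}
    if gene.id not in ids:
        raise KeyError(f"gene {gene.id!r} not present in annotation")
    if gene.contig not in sequences:
        raise KeyError(f"contig {gene.contig!r} not in sequences")
    contig_seq = sequences[gene.contig]
    clen = len(contig_seq)

    neighbours = [g for g in annotation if g.contig == gene.contig and g.id != gene.id]
    trimmed_by: str | None = None
    if gene.strand == "+":
        cap = gene.start - requested_length
        bound = max(cap, 0)
        for g in neighbours:
            if g.end <= gene.start and g.end > bound:
                bound, trimmed_by = g.end, g.id
        if trimmed_by is not None and bound <= cap:
            trimmed_by = None
        start, end = bound, gene.start
        seq = contig_seq[start:end]
    else:
        cap = gene.end + requested_length
        bound = min(cap, clen)
        for g in neighbours:
            if g.start >= gene.end and g.start < bound:
                bound, trimmed_by = g.start, g.id
        if trimmed_by is not None and bound >= cap:
            trimmed_by = None
        start, end = gene.end, bound
        seq = reverse_complement(contig_seq[start:end])

    if len(seq) < min_length:
        log.info("UCR for %s excluded: too short (%d < %d)", gene.id, len(seq), min_length)
        return None
    return UCRRecord(
        gene_id=gene.id,
        sequence=seq.upper(),
        requested_length=requested_length,
        trimmed_by=trimmed_by,
        contig=gene.contig,
        start=start,
        end=end,
        strand=gene.strand,
    )


def build_ucr_database(
    annotation: Sequence[GeneModel],
    sequences: Mapping[str, str],
    requested_length: int = DEFAULT_UCR_LENGTH,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[UCRRecord]:
    """UCRs for every gene in the annotation, short regions excluded."""
    records = []
    for gene in annotation:
        rec = extract_ucr(gene, annotation, sequences, requested_length, min_length)
        if rec is not None:
            records.append(rec)
    return records


def write_ucr_database(
    records: Iterable[UCRRecord], fasta_path: str | Path, tsv_path: str | Path | None = None
) -> None:
    """Write UCRs as FASTA (ids = gene ids) plus a TSV provenance sidecar."""
    records = list(records)
    seqs = [SeqRecord(Seq(r.sequence), id=r.gene_id, description="") for r in records]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    if tsv_path is not None:
        pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in records],
                "contig": [r.contig for r in records],
                "start": [r.start for r in records],
                "end": [r.end for r in records],
                "strand": [r.strand for r in records],
                "requested_length": [r.requested_length for r in records],
                "actual_length": [r.actual_length for r in records],
                "trimmed_by": [r.trimmed_by or "" for r in records],
            }
        ).to_csv(tsv_path, sep="\t", index=False)


def read_ucr_fasta(path: str | Path) -> dict[str, str]:
    """Read a UCR FASTA back into an id -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
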