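"""UCR extraction: the 3 kb cap, ORF trimming, strand handling, file IO."""

import numpy as np
import pytest

from beemotif.genome_ucr import (
    GeneModel,
    build_ucr_database,
    extract_ucr,
    read_annotation,
    read_ucr_fasta,
    write_ucr_database,
)
from beemotif.pssm_core import reverse_complement


def make_contig(length, seed=0):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


def test_read_annotation_bed(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text("chr1\t100\t400\tg1\t0\t+\nchr1\t600\t900\tg2\t0\t-\n")
    genes = read_annotation(bed)
    assert genes[0] == GeneModel("g1", "chr1", 100, 400, "+")
    assert genes[1].strand == "-"


def test_read_annotation_gff3_coordinate_shift(tmp_path):
    gff = tmp_path / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t200\t400\t.\t+\t.\tID=g1\n"
        "chr1\tsrc\tmRNA\t200\t400\t.\t+\t.\tID=t1;Parent=g1\n"
    )
    genes = read_annotation(gff)
    assert genes == [GeneModel("g1", "chr1", 199, 400, "+")]


def test_read_annotation_duplicate_id_rejected(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text("chr1\t100\t400\tg1\t0\t+\nchr1\t600\t900\tg1\t0\t+\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_annotation(bed)


def test_read_annotation_coordinate_outside_contig(tmp_path):
    bed = tmp_path / "genes.bed"
    bed.write_text("chr1\t100\t4000\tg1\t0\t+\n")
    with pytest.raises(ValueError, match="g1"):
        read_annotation(bed, contig_lengths={"chr1": 1000})


def test_extract_trimmed_by_upstream_neighbour():
    contig = {"c": make_contig(6000)}
    genes = [
        GeneModel("up", "c", 2000, 2800, "+"),
        GeneModel("g", "c", 4000, 4500, "+"),
    ]
    ucr = extract_ucr(genes[1], genes, contig)
    assert (ucr.start, ucr.end) == (2800, 4000)
    assert ucr.actual_length == 1200
    assert ucr.trimmed_by == "up"
    assert ucr.sequence == contig["c"][2800:4000]


def test_extract_isolated_gene_capped_at_requested_length():
    contig = {"c": make_contig(8000)}
    genes = [GeneModel("g", "c", 4000, 4500, "+")]
    ucr = extract_ucr(genes[0], genes, contig)
    assert ucr.actual_length == 3000
    assert ucr.trimmed_by is None
    assert (ucr.start, ucr.end) == (1000, 4000)


def test_extract_minus_strand_reverse_complemented():
    contig = {"c": make_contig(6000)}
    genes = [
        GeneModel("g", "c", 1000, 1500, "-"),
        GeneModel("down", "c", 2700, 3000, "+"),  # opposite strand still trims
    ]
    ucr = extract_ucr(genes[0], genes, contig)
    assert (ucr.start, ucr.end) == (1500, 2700)
    assert ucr.trimmed_by == "down"
    assert ucr.sequence == reverse_complement(contig["c"][1500:2700])


def test_extract_short_region_excluded():
    contig = {"c": make_contig(1000)}
    genes = [GeneModel("g", "c", 10, 500, "+")]
    assert extract_ucr(genes[0], genes, contig, min_length=30) is None


def test_extract_unknown_gene_errors():
    contig = {"c": make_contig(1000)}
    genes = [GeneModel("g", "c", 100, 500, "+")]
    with pytest.raises(KeyError):
        extract_ucr(GeneModel("other", "c", 600, 700, "+"), genes, contig)


def _oracle_interval(gene, genes, clen, requested):
    """Brute-force interval computation straight from the trimming rule."""
    others = [g for g in genes if g.id != gene.id and g.contig == gene.contig]
    if gene.strand == "+":
        lo = max([0, gene.start - requested] + [g.end for g in others if g.end <= gene.start])
        return lo, gene.start
    hi = min([clen, gene.end + requested] + [g.start for g in others if g.start >= gene.end])
    return gene.end, hi


def test_extraction_agrees_with_interval_oracle(rng):
    """Randomised annotations: extraction equals the brute-force intervals."""
    contig = {"c": make_contig(20_000, seed=9)}
    for trial in range(100):
        starts = np.sort(rng.choice(19_000, size=8, replace=False))
        genes = []
        pos = 0
        for i, s in enumerate(starts):
            start = max(int(s), pos)
            end = start + int(rng.integers(50, 400))
            if end > 20_000:
                break
            genes.append(GeneModel(f"g{i}", "c", start, end,
                                   "+" if rng.random() < 0.5 else "-"))
            pos = end
        for gene in genes:
            rec = extract_ucr(gene, genes, contig, requested_length=1500, min_length=1)
            lo, hi = _oracle_interval(gene, genes, 20_000, 1500)
            if hi - lo < 1:
                assert rec is None
            else:
                assert (rec.start, rec.end) == (lo, hi)


def test_minus_strand_mirrors_forward_extraction():
    """Extraction on the reverse-complemented contig with mirrored coordinates
    must reproduce minus-strand extraction on the forward contig."""
    clen = 5000
    contig = {"c": make_contig(clen, seed=4)}
    genes = [
        GeneModel("a", "c", 500, 900, "+"),
        GeneModel("b", "c", 1500, 2100, "-"),
        GeneModel("d", "c", 3000, 3400, "+"),
    ]
    mirrored_contig = {"c": reverse_complement(contig["c"])}
    mirrored = [
        GeneModel(g.id, "c", clen - g.end, clen - g.start,
                  "+" if g.strand == "-" else "-")
        for g in genes
    ]
    for gene, mgene in zip(genes, mirrored):
        rec = extract_ucr(gene, genes, contig, requested_length=1000, min_length=1)
        mrec = extract_ucr(mgene, mirrored, mirrored_contig, requested_length=1000, min_length=1)
        assert rec.sequence == mrec.sequence
        assert rec.trimmed_by == mrec.trimmed_by


def test_ucr_never_overlaps_gene_bodies(planted_dataset):
    records = build_ucr_database(planted_dataset["annotation"], planted_dataset["contigs"])
    bodies = [(g.start, g.end) for g in planted_dataset["annotation"]]
    for rec in records:
        for start, end in bodies:
            assert rec.end <= start or rec.start >= end


def test_total_ucr_length_invariant_to_annotation_order(rng):
    contig = {"c": make_contig(10_000, seed=2)}
    genes = [
        GeneModel("a", "c", 1000, 1400, "+"),
        GeneModel("b", "c", 2000, 2500, "-"),
        GeneModel("d", "c", 4000, 4800, "+"),
    ]
    total = sum(r.actual_length for r in build_ucr_database(genes, contig))
    shuffled = [genes[i] for i in rng.permutation(3)]
    assert total == sum(r.actual_length for r in build_ucr_database(shuffled, contig))


def test_ucr_database_roundtrip(tmp_path, planted_dataset):
    records = build_ucr_database(planted_dataset["annotation"], planted_dataset["contigs"])
    fasta = tmp_path / "ucrs.fasta"
    write_ucr_database(records, fasta, tmp_path / "ucrs.tsv")
    back = read_ucr_fasta(fasta)
    assert back == {r.gene_id: r.sequence for r in records}
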