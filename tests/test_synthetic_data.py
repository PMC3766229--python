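"""Synthetic genome generation, motif planting and the TRANSFAC writer."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from beemotif.genome_ucr import build_ucr_database, extract_ucr
from beemotif.motif_match import read_transfac
from beemotif.pssm_core import information_content, pssm_from_iupac, reverse_complement
from beemotif.synthetic_data import (
    InfeasiblePackingError,
    SimulationConfig,
    plant_motifs,
    random_motif,
    simulate_dataset,
    simulate_genome,
    write_motif_library,
)


def test_empty_genome():
    contigs, genes, truth = simulate_genome(SimulationConfig(seed=1, n_genes=0))
    assert genes == []
    assert truth.foreground_genes == set()
    assert len(contigs["contig_1"]) == 150_000


def test_determinism_same_seed_byte_identical():
    cfg = SimulationConfig(seed=42, n_genes=20, contig_length=40_000)
    a = simulate_dataset(cfg)
    b = simulate_dataset(cfg)
    assert a["contigs"] == b["contigs"]
    assert a["annotation"] == b["annotation"]
    assert a["truth"].planted_occurrences == b["truth"].planted_occurrences
    assert a["truth"].category_map == b["truth"].category_map


def test_different_seed_differs():
    a = simulate_dataset(SimulationConfig(seed=1, n_genes=20, contig_length=40_000))
    b = simulate_dataset(SimulationConfig(seed=2, n_genes=20, contig_length=40_000))
    assert a["contigs"] != b["contigs"]


def test_fixed_spacing_bounds_ucr_length():
    cfg = SimulationConfig(
        seed=3, n_genes=10, contig_length=20_000,
        intergenic_length_distribution={"name": "fixed", "length": 500},
        gene_length_range=(300, 500),
    )
    contigs, genes, _ = simulate_genome(cfg)
    records = build_ucr_database(genes, contigs, requested_length=3000, min_length=1)
    assert len(records) == 10
    assert all(r.actual_length <= 500 for r in records)


def test_infeasible_packing_names_shortfall():
    cfg = SimulationConfig(
        seed=1, n_genes=50, contig_length=1000,
        intergenic_length_distribution={"name": "fixed", "length": 500},
    )
    with pytest.raises(InfeasiblePackingError, match="short by"):
        simulate_genome(cfg)


def test_genes_non_overlapping_both_strands():
    cfg = SimulationConfig(seed=7, n_genes=50, contig_length=100_000)
    _, genes, _ = simulate_genome(cfg)
    for g1, g2 in zip(genes, genes[1:]):
        assert g1.end <= g2.start
    assert {g.strand for g in genes} == {"+", "-"}


def test_plant_occupancy_zero_changes_nothing():
    cfg = SimulationConfig(seed=4, n_genes=10, contig_length=20_000)
    contigs, genes, truth = simulate_genome(cfg)
    motif = pssm_from_iupac("ACGTACGT")
    new_contigs, new_truth = plant_motifs(contigs, genes, truth, motif, 0.0, seed=1)
    assert new_contigs == contigs
    assert new_truth.planted_occurrences == []


def test_plant_occupancy_one_plants_every_foreground_gene():
    cfg = SimulationConfig(seed=4, n_genes=60, contig_length=100_000,
                           foreground_fraction=1 / 3)
    contigs, genes, truth = simulate_genome(cfg)
    motif = random_motif(8, 0)
    _, new_truth = plant_motifs(contigs, genes, truth, motif, 1.0, seed=1)
    assert len(new_truth.planted_occurrences) == 20
    assert {s.gene_id for s in new_truth.planted_occurrences} == truth.foreground_genes


def test_plant_count_within_binomial_interval():
    """Occupancy 0.5 over 500 foreground genes: count inside the central
    99% binomial interval (exact bounds from the binomial ppf)."""
    cfg = SimulationConfig(
        seed=8, n_genes=500, contig_length=600_000,
        intergenic_length_distribution={"name": "fixed", "length": 300},
        gene_length_range=(300, 400), foreground_fraction=1.0,
    )
    contigs, genes, truth = simulate_genome(cfg)
    motif = random_motif(8, 0)
    _, new_truth = plant_motifs(contigs, genes, truth, motif, 0.5, seed=9)
    n = len(new_truth.planted_occurrences)
    lo, hi = stats.binom.ppf([0.005, 0.995], 500, 0.5)
    assert lo <= n <= hi


def test_planted_occurrences_recoverable_through_ucr_extraction(planted_dataset):
    truth = planted_dataset["truth"]
    ucrs = planted_dataset["ucrs"]
    assert truth.planted_occurrences, "dataset should contain planted sites"
    for site in truth.planted_occurrences:
        seq = ucrs[site.gene_id]
        sub = seq[site.offset : site.offset + len(site.word)]
        expected = site.word if site.strand == "+" else reverse_complement(site.word)
        assert sub == expected


def test_background_composition_within_three_standard_errors():
    comp = (0.335, 0.165, 0.165, 0.335)
    cfg = SimulationConfig(seed=6, n_genes=0, contig_length=100_000,
                           background_markov_order=0,
                           background_base_composition=comp)
    contigs, _, _ = simulate_genome(cfg)
    seq = contigs["contig_1"]
    n = len(seq)
    for base, p in zip("ACGT", comp):
        observed = seq.count(base) / n
        se = np.sqrt(p * (1 - p) / n)
        assert abs(observed - p) <= 3 * se


def test_order1_background_preserves_marginal_composition():
    comp = (0.335, 0.165, 0.165, 0.335)
    cfg = SimulationConfig(seed=6, n_genes=0, contig_length=100_000,
                           background_markov_order=1,
                           background_base_composition=comp)
    contigs, _, _ = simulate_genome(cfg)
    seq = contigs["contig_1"]
    for base, p in zip("ACGT", comp):
        assert abs(seq.count(base) / len(seq) - p) < 0.02


def test_random_motif_information_floor():
    motif = random_motif(8, 5, min_ic_per_column=1.3)
    per_col, _ = information_content(motif)
    assert per_col.min() >= 1.3


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        SimulationConfig(background_base_composition=(0.5, 0.5, 0.1, 0.1))
    with pytest.raises(ValueError):
        SimulationConfig(occupancy=1.5)


def test_write_motif_library_roundtrip(tmp_path):
    motifs = [pssm_from_iupac("YCAAGGTCR", name="ftzf1"), random_motif(6, 1, name="decoy")]
    path = tmp_path / "lib.transfac"
    write_motif_library(motifs, path)
    text = path.read_text()
    assert text.count("//") == 2
    assert "P0" in text and "01" in text and "09" in text
    lib = read_transfac(path)
    assert [r.identifier for r in lib] == ["ftzf1", "decoy"]
    for motif, rec in zip(motifs, lib):
        np.testing.assert_allclose(rec.pssm.frequencies, motif.frequencies, atol=1e-9)


def test_write_motif_library_rejects_duplicate_names(tmp_path):
    m = pssm_from_iupac("ACGT", name="m")
    with pytest.raises(ValueError, match="duplicate"):
        write_motif_library([m, m], tmp_path / "lib.transfac")


def test_write_empty_library(tmp_path):
    path = tmp_path / "empty.transfac"
    write_motif_library([], path)
    assert len(read_transfac(path)) == 0
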