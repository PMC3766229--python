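"""Gibbs discovery, the MAP score, the shuffle null and MEME import."""

import math
from collections import Counter

import numpy as np
import pytest

from beemotif.motif_discovery import (
    Background,
    DiscoveredMotif,
    dinucleotide_shuffle,
    empirical_significance,
    fit_background,
    gibbs_discover,
    import_meme_motifs,
    map_score,
    write_meme_minimal,
)
from beemotif.pssm_core import PSSM, pssm_from_iupac, pssm_identity

UNIFORM_BG = Background(0, np.full(4, 0.25))


def test_map_score_zero_sites_is_zero():
    motif = DiscoveredMotif(pssm=pssm_from_iupac("ACGTACGT"))
    assert map_score(motif, {"s1": "ACGT" * 20}) == 0.0


def test_map_score_perfectly_conserved_sites_matches_hand_formula():
    """Ten exact sites of a 1.0-frequency 8-mer in 4 kb total sequence."""
    word = "ACGTACGT"
    seqs = {}
    for i in range(10):
        filler = "TTCTTCTT" * 49
        seqs[f"s{i}"] = word + filler[: 400 - 8]
    pssm = PSSM("m", np.eye(4)[[0, 1, 2, 3, 0, 1, 2, 3]])
    motif = DiscoveredMotif(pssm=pssm, sites=[(f"s{i}", 0, "+") for i in range(10)])
    total_positions = sum(2 * (len(s) - 8 + 1) for s in seqs.values())
    expected = 10 * 16.0 - 10 * math.log2(total_positions)
    assert map_score(motif, seqs, UNIFORM_BG) == pytest.approx(expected, rel=1e-9)


def test_map_score_increases_when_adding_strong_site():
    word = "ACGTACGT"
    seqs = {f"s{i}": word + "T" * 92 for i in range(5)}
    pssm = PSSM("m", np.eye(4)[[0, 1, 2, 3, 0, 1, 2, 3]])
    base = DiscoveredMotif(pssm=pssm, sites=[("s0", 0, "+"), ("s1", 0, "+")])
    more = DiscoveredMotif(pssm=pssm, sites=base.sites + [("s2", 0, "+")])
    assert map_score(more, seqs, UNIFORM_BG) > map_score(base, seqs, UNIFORM_BG)


def test_map_score_invariant_under_sequence_relabeling():
    seqs = {"a": "ACGTACGT" + "T" * 50, "b": "ACGTACGT" + "G" * 50}
    pssm = PSSM("m", np.eye(4)[[0, 1, 2, 3, 0, 1, 2, 3]])
    motif = DiscoveredMotif(pssm=pssm, sites=[("a", 0, "+"), ("b", 0, "+")])
    relabeled = {"x": seqs["a"], "y": seqs["b"]}
    motif2 = DiscoveredMotif(pssm=pssm, sites=[("x", 0, "+"), ("y", 0, "+")])
    assert map_score(motif, seqs, UNIFORM_BG) == pytest.approx(
        map_score(motif2, relabeled, UNIFORM_BG)
    )


def test_gibbs_requires_feasible_width():
    with pytest.raises(ValueError):
        gibbs_discover({"a": "ACGT", "b": "ACGTACGT"}, width=6, seed=0)
    with pytest.raises(ValueError):
        gibbs_discover({"a": "ACGTACGT"}, width=4, seed=0)


def test_gibbs_deterministic_under_seed(planted_dataset):
    group = planted_dataset["group"]
    kwargs = dict(width=8, n_restarts=2, iterations=40, seed=17)
    a = gibbs_discover(group, **kwargs)
    b = gibbs_discover(group, **kwargs)
    assert len(a) == len(b)
    for ma, mb in zip(a, b):
        np.testing.assert_array_equal(ma.pssm.frequencies, mb.pssm.frequencies)
        assert ma.sites == mb.sites
        assert ma.map_score == pytest.approx(mb.map_score)


def test_gibbs_recovers_planted_motif_in_most_seeds():
    """Planted 8-mer at occupancy 0.9: recovered at >= 70% identity in >= 8/10 seeds."""
    from conftest import make_planted_dataset

    hits = 0
    planted_scores = []
    for seed in range(10):
        data = make_planted_dataset(seed=100 + seed)
        motifs = gibbs_discover(data["group"], 8, n_restarts=5, iterations=200, seed=seed)
        ident, _, _ = pssm_identity(motifs[0].pssm, data["planted"])
        planted_scores.append(motifs[0].map_score)
        hits += ident >= 70.0
    assert hits >= 8
    # paired comparison: unplanted data scores below the planted runs
    data = make_planted_dataset(seed=100, occupancy=0.0)
    null_motifs = gibbs_discover(data["group"], 8, n_restarts=5, iterations=200, seed=0)
    assert null_motifs[0].map_score < np.median(planted_scores)


def test_dinucleotide_shuffle_preserves_counts(rng):
    for length in (3, 10, 57, 200):
        seq = "".join(rng.choice(list("ACGT"), size=length))
        shuffled = dinucleotide_shuffle(seq, rng)
        assert len(shuffled) == len(seq)
        assert Counter(zip(seq, seq[1:])) == Counter(zip(shuffled, shuffled[1:]))
        assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]


def test_dinucleotide_shuffle_actually_shuffles(rng):
    seq = "ACGTTGCAACGTAGCTAGGCTTAACGGATCGATTACGA" * 4
    outcomes = {dinucleotide_shuffle(seq, rng) for _ in range(10)}
    assert len(outcomes) > 1


def test_empirical_significance_bounds(planted_dataset):
    group = dict(list(planted_dataset["group"].items())[:8])
    motifs = gibbs_discover(group, 8, n_restarts=2, iterations=60, seed=3)
    top = motifs[0]
    proxy = empirical_significance(
        top, group, n_shuffles=4, seed=5, n_restarts=2, iterations=60
    )
    assert 1 / 5 <= proxy <= 1.0
    # an absurdly strong observed MAP can never be matched by shuffles
    unbeatable = DiscoveredMotif(pssm=top.pssm, sites=top.sites, map_score=1e9,
                                 meta=dict(top.meta))
    assert empirical_significance(
        unbeatable, group, n_shuffles=4, seed=5, n_restarts=1, iterations=20
    ) == pytest.approx(1 / 5)


MEME_TEXT = """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF test_motif
letter-probability matrix: alength= 4 w= 4 nsites= 20 E= 1e-07
 0.800000 0.100000 0.050000 0.050000
 0.100000 0.700000 0.100000 0.100000
 0.250000 0.250000 0.250000 0.250000
 0.000000 0.000000 0.000000 1.000000
"""


def test_import_meme_motifs(tmp_path):
    path = tmp_path / "motifs.meme"
    path.write_text(MEME_TEXT)
    motifs = import_meme_motifs(path)
    assert len(motifs) == 1
    m = motifs[0]
    assert m.finder == "imported"
    assert m.evalue == pytest.approx(1e-07)
    np.testing.assert_allclose(m.pssm.frequencies[0], [0.8, 0.1, 0.05, 0.05], atol=1e-6)


def test_import_meme_empty_file(tmp_path):
    path = tmp_path / "empty.meme"
    path.write_text("")
    assert import_meme_motifs(path) == []


def test_import_meme_malformed_row_reports_line(tmp_path):
    path = tmp_path / "bad.meme"
    path.write_text(MEME_TEXT.replace(" 0.100000 0.700000 0.100000 0.100000",
                                      " 0.100000 0.700000 0.100000"))
    with pytest.raises(ValueError, match=r"matrix row has 3 values"):
        import_meme_motifs(path)


def test_meme_roundtrip(tmp_path):
    pssm = pssm_from_iupac("YCAAGGTCR", name="ftzf1")
    motif = DiscoveredMotif(pssm=pssm, evalue=1e-6, finder="internal")
    path = tmp_path / "rt.meme"
    write_meme_minimal([motif], path)
    back = import_meme_motifs(path)
    assert len(back) == 1
    np.testing.assert_allclose(back[0].pssm.frequencies, pssm.frequencies, atol=1e-6)


def test_fit_background_orders():
    seqs = {"a": "AAAACCCC", "b": "GGGGTTTT"}
    bg0 = fit_background(seqs, order=0)
    np.testing.assert_allclose(bg0.composition, [0.25] * 4)
    bg1 = fit_background(seqs, order=1)
    # A->A occurs 3 times, A->C once within "AAAACCCC"
    assert bg1.transition[0, 0] == pytest.approx(0.75)
    assert bg1.transition[0, 1] == pytest.approx(0.25)
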