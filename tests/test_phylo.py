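"""p-distance, neighbor joining, Newick round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from estmir import (distance_matrix, nj_tree, pairwise_distance, read_newick,
                    same_topology, to_newick)


class TestPairwiseDistance:
    def test_identical_sequences(self):
        assert pairwise_distance("UGAUGCUGAUGAUGAGGA",
                                 "UGAUGCUGAUGAUGAGGA") == 0.0

    def test_one_substitution_in_18(self):
        a = "UGAUGCUGAUGAUGAGGA"
        b = "UGAUGCUGCUGAUGAGGA"
        assert pairwise_distance(a, b) == pytest.approx(1 / 18)

    def test_single_indel(self):
        a = "UGAUGCUGAUGAUGAGGA"
        assert pairwise_distance(a, a + "U") == pytest.approx(1 / 19)

    @given(a=st.text(alphabet="ACGU", min_size=1, max_size=25),
           b=st.text(alphabet="ACGU", min_size=1, max_size=25))
    @settings(derandomize=True, max_examples=100)
    def test_symmetric_and_bounded(self, a, b):
        d = pairwise_distance(a, b)
        assert d == pytest.approx(pairwise_distance(b, a))
        assert 0.0 <= d <= 1.0


class TestNJTree:
    def test_four_taxon_additive_recovery(self):
        # tree ((A,B),(C,D)) with internal edge 2: classic additive matrix
        labels = ["A", "B", "C", "D"]
        m = np.array([[0, 2, 7, 7],
                      [2, 0, 7, 7],
                      [7, 7, 0, 2],
                      [7, 7, 2, 0]], dtype=float)
        tree = nj_tree(m, labels)
        ab = tree.lca(["A", "B"])
        assert {t.name for t in ab.tips()} in ({"A", "B"}, {"C", "D"})

    def test_three_taxa_closed_form(self):
        # d(A,B)=3, d(A,C)=4, d(B,C)=5 -> x=1, y=2, z=3
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(m, ["A", "B", "C"])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_ultrametric_matrix_reproduced(self):
        labels = ["A", "B", "C", "D"]
        m = np.array([[0, 2, 8, 8],
                      [2, 0, 8, 8],
                      [8, 8, 0, 4],
                      [8, 8, 4, 0]], dtype=float)
        tree = nj_tree(m, labels)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    d = tree.find(a).distance(tree.find(b))
                    assert d == pytest.approx(m[i, j], abs=1e-9)

    def test_branch_lengths_nonnegative(self, rng):
        n = 8
        m = rng.uniform(0.1, 1.0, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        tree = nj_tree(m, [f"t{i}" for i in range(n)])
        assert all((node.length or 0) >= 0 for node in tree.traverse())

    def test_rejects_asymmetric_matrix(self):
        m = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            nj_tree(m, ["a", "b", "c"])

    def test_rejects_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])

    def test_topology_invariant_under_row_permutation(self, rng):
        labels = ["A", "B", "C", "D", "E"]
        m = np.array([[0, 2, 7, 7, 8],
                      [2, 0, 7, 7, 8],
                      [7, 7, 0, 2, 5],
                      [7, 7, 2, 0, 5],
                      [8, 8, 5, 5, 0]], dtype=float)
        perm = rng.permutation(5)
        t1 = nj_tree(m, labels)
        t2 = nj_tree(m[np.ix_(perm, perm)], [labels[i] for i in perm])
        assert same_topology(t1, t2)


class TestNewick:
    def test_three_leaf_shape(self):
        m = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        nwk = to_newick(nj_tree(m, ["A", "B", "C"]))
        assert nwk.startswith("(") and nwk.endswith(";")
        assert "A:1.000000" in nwk and "C:3.000000" in nwk

    def test_round_trip_is_identical(self):
        m = np.array([[0, 2, 7, 7],
                      [2, 0, 7, 7],
                      [7, 7, 0, 2],
                      [7, 7, 2, 0]], dtype=float)
        nwk = to_newick(nj_tree(m, ["A", "B", "C", "D"]))
        assert to_newick(read_newick(nwk)) == nwk

    def test_hyphenated_mirna_labels_survive(self):
        labels = ["jcu-miR7805-3p", "rgl-miR7805-3p", "ath-miR5658"]
        m = np.array([[0, 1, 4], [1, 0, 5], [4, 5, 0]], dtype=float)
        nwk = to_newick(nj_tree(m, labels))
        tree = read_newick(nwk)
        assert {t.name for t in tree.tips()} == set(labels)
        assert to_newick(tree) == nwk


class TestDistanceMatrixFromSequences:
    def test_matrix_matches_pairwise_calls(self):
        seqs = ["UGAUGCUGAUGAUGAGGA", "UGAUGCUGCUGAUGAGGA",
                "ACCCAUGCAUGGGGGGGG"]
        dm = distance_matrix(seqs, ["a", "b", "c"])
        assert dm["a", "b"] == pytest.approx(pairwise_distance(seqs[0],
                                                               seqs[1]))
        assert dm["a", "a"] == 0.0


def test_phylip_writer_square_matrix(tmp_path):
    from estmir import write_phylip
    dm = distance_matrix(["AAAA", "AAAU", "GGGG"], ["a", "b", "c"])
    out = tmp_path / "dm.phy"
    write_phylip(dm, out)
    lines = out.read_text().splitlines()
    assert lines[0] == "3"
    assert lines[1].startswith("a  0.000000 0.250000 1.000000")
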