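"""Protein distances, neighbor joining, bootstrap, Newick I/O, clades."""

import numpy as np
import pytest

from baculoscan.homology import MsaResult
from baculoscan.phylogeny import (DistanceMatrix, SaturatedDistanceError,
                                  bootstrap_support, clade_membership,
                                  neighbor_joining, protein_distance,
                                  read_newick, write_newick)
from baculoscan.synthetic_data import evolve_along_tree, random_protein


def make_msa(rows, labels=None):
    labels = labels or [f"t{i}" for i in range(len(rows))]
    return MsaResult(labels=labels, rows=rows)


class TestProteinDistance:
    def test_identical_rows_distance_zero(self):
        dm = protein_distance(make_msa(["ACDEF", "ACDEF"]))
        assert dm.matrix[0, 1] == 0.0

    def test_half_different_poisson_closed_form(self):
        a = "A" * 100
        b = "A" * 50 + "C" * 50
        dm_p = protein_distance(make_msa([a, b]), model="p")
        assert dm_p.matrix[0, 1] == pytest.approx(0.5)
        dm = protein_distance(make_msa([a, b]), model="poisson")
        assert dm.matrix[0, 1] == pytest.approx(-np.log(0.5), abs=1e-9)

    def test_pairwise_deletion_excludes_gap_columns(self):
        # 4-column hand example: column 3 has a gap, so 3 compared columns
        # with 1 mismatch
        dm = protein_distance(make_msa(["AC-D", "AAED"]), model="p")
        assert dm.matrix[0, 1] == pytest.approx(1 / 3)

    def test_saturated_pair_flagged(self):
        dm = protein_distance(make_msa(["AAAA", "CCCC"]), model="poisson")
        assert dm.saturated == [("t0", "t1")]
        assert np.isinf(dm.matrix[0, 1])

    def test_poisson_at_least_p(self, rng):
        rows = [random_protein(rng, 80) for _ in range(4)]
        p = protein_distance(make_msa(rows), model="p").matrix
        poisson = protein_distance(make_msa(rows), model="poisson").matrix
        assert np.all(poisson >= p - 1e-12)


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> pairwise path distances
        labels = list("ABCD")
        D = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels=labels, matrix=D,
                                               model="p"))
        assert tree.bipartitions() == {
            frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})}
        # branch lengths recovered exactly from additivity
        newick = tree.newick()
        assert "A:1.000000" in newick and "B:2.000000" in newick
        assert "C:3.000000" in newick and "D:4.000000" in newick

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(labels=list("ABC"), matrix=D,
                                               model="p"))
        assert "A:0.000000" in tree.newick()
        assert "B:2.000000" in tree.newick()
        assert "C:3.000000" in tree.newick()

    def test_ultrametric_eight_taxa_topology(self):
        # balanced ultrametric tree: distances = 2 * depth to MRCA
        labels = [f"t{i}" for i in range(8)]
        D = np.zeros((8, 8))
        for i in range(8):
            for j in range(8):
                if i != j:
                    depth = 1 if i // 2 == j // 2 else (2 if i // 4 == j // 4
                                                        else 3)
                    D[i, j] = 2.0 * depth
        tree = neighbor_joining(DistanceMatrix(labels=labels, matrix=D,
                                               model="p"))
        cherries = {frozenset({f"t{2 * k}", f"t{2 * k + 1}"})
                    for k in range(4)}
        sides = {s for bp in tree.bipartitions() for s in bp if len(s) == 2}
        assert cherries <= sides

    def test_needs_three_taxa(self):
        D = np.array([[0, 1], [1, 0]], dtype=float)
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(labels=["a", "b"], matrix=D))

    def test_saturated_matrix_rejected(self):
        dm = protein_distance(make_msa(["AAAA", "CCCC", "AAAC"]),
                              model="poisson")
        with pytest.raises(SaturatedDistanceError):
            neighbor_joining(dm)


class TestBootstrap:
    def _signal_msa(self):
        # strong clade signal: (A,B) vs (C,D) differ in half the columns
        block1 = "A" * 30 + "C" * 30
        block2 = "A" * 30 + "W" * 30
        return make_msa([block1, block1, block2, block2],
                        labels=list("ABCD"))

    def test_strong_signal_high_support(self):
        tree = bootstrap_support(self._signal_msa(), n_replicates=100, seed=5)
        supports = tree.supports()
        bp = frozenset({frozenset({"A", "B"}), frozenset({"C", "D"})})
        assert supports[bp] >= 95

    def test_single_replicate_supports_are_binary(self):
        tree = bootstrap_support(self._signal_msa(), n_replicates=1, seed=2)
        assert set(tree.supports().values()) <= {0.0, 100.0}

    def test_same_seed_reproducible(self):
        from baculoscan.synthetic_data import mutate_protein
        root = random_protein(np.random.default_rng(31), 60)
        rows = [mutate_protein(root, 0.6, seed=i) for i in range(5)]
        msa = make_msa(rows)
        s1 = bootstrap_support(msa, n_replicates=25, seed=9).supports()
        s2 = bootstrap_support(msa, n_replicates=25, seed=9).supports()
        assert s1 == s2

    def test_supports_invariant_to_taxon_order(self):
        msa = self._signal_msa()
        reordered = make_msa([msa.rows[i] for i in (2, 0, 3, 1)],
                             labels=["C", "A", "D", "B"])
        s1 = bootstrap_support(msa, n_replicates=50, seed=7).supports()
        s2 = bootstrap_support(reordered, n_replicates=50, seed=7).supports()
        assert s1 == s2


class TestNewick:
    def test_round_trips(self, tmp_path):
        cases = [
            "(A:0.100000,B:0.200000,(C:0.300000,D:0.400000):0.050000);",
            "(A:0.100000,B:0.200000,(C:0.300000,D:0.400000)87:0.050000);",
            "(A:0.000000,B:0.200000,(C:0.300000,D:0.400000):0.000000);",
        ]
        for i, text in enumerate(cases):
            path = tmp_path / f"t{i}.nwk"
            path.write_text(text + "\n")
            tree = read_newick(path)
            out = tmp_path / f"o{i}.nwk"
            write_newick(tree, out)
            assert out.read_text().strip() == text


class TestCladeMembership:
    def _tree(self, tmp_path):
        path = tmp_path / "clade.nwk"
        path.write_text("((A:1,(B:1,C:1):1):1,((D:1,E:1):1,F:1):1);\n")
        return read_newick(path)

    def test_member_inside_clade(self, tmp_path):
        tree = self._tree(tmp_path)
        inside, clade = clade_membership(tree, "B", ["A", "C"])
        assert inside and clade <= {"A", "B", "C"}

    def test_outgroup_taxon_outside(self, tmp_path):
        tree = self._tree(tmp_path)
        inside, _ = clade_membership(tree, "F", ["A", "B", "C"])
        assert not inside

    def test_simulated_tree_matches_generating_clade(self):
        tree_str = ("(((X:0.1,Y:0.1):0.1,(Z:0.1,W:0.1):0.1):0.4,"
                    "((P:0.1,Q:0.1):0.1,(R:0.1,(S:0.1,T:0.1):0.05):0.1):0.4);")
        root = random_protein(np.random.default_rng(13), 250)
        leaves = evolve_along_tree(tree_str, root, rate=1.0, seed=13)
        labels = sorted(leaves)
        msa = make_msa([leaves[k] for k in labels], labels=labels)
        nj = neighbor_joining(protein_distance(msa, "poisson"))
        inside, _ = clade_membership(nj, "X", ["Y", "Z", "W"])
        assert inside
        outside, _ = clade_membership(nj, "P", ["X", "Y", "Z", "W"])
        assert not outside
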