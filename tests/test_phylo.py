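"""Supermatrix building, K2P distances, NJ, bootstrap, and tree comparison."""

import math

import dendropy
import numpy as np
import pytest

from mitochar.phylo import (
    SaturationError,
    Supermatrix,
    bootstrap,
    concatenate,
    is_monophyletic,
    k2p_distance,
    k2p_matrix,
    mask_gappy_columns,
    nj,
    nj_from_supermatrix,
    p_distance,
    rf_distance,
    ts_tv_table,
)
from mitochar.synthetic_data import EvolutionSpec, evolve_on_tree


def _tree_distances(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(t.label for t in tree.taxon_namespace)
    lookup = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(lookup[taxa[i]], lookup[taxa[j]])
    return taxa, d


class TestConcatenate:
    def test_two_genes_three_taxa(self):
        aln = {
            "g1": {"A": "ACGTACGTA", "B": "ACGTACGTT", "C": "ACGTACGTC"},
            "g2": {"A": "TTTTTT", "B": "TTTTTA", "C": "TTTTTC"},
        }
        sm = concatenate(aln)
        assert sm.n_columns == 15
        assert sm.partitions == {"g1": (0, 9), "g2": (9, 15)}

    def test_missing_taxon_gap_filled(self):
        aln = {"g1": {"A": "ACG", "B": "ACT"}, "g2": {"A": "TTTTTT"}}
        sm = concatenate(aln)
        assert sm.rows["B"][3:] == "------"

    def test_input_order_irrelevant(self):
        a = {"g1": {"A": "ACG", "B": "ACT"}, "g2": {"A": "TTT", "B": "TTA"}}
        b = {"g2": {"B": "TTA", "A": "TTT"}, "g1": {"B": "ACT", "A": "ACG"}}
        assert concatenate(a).rows == concatenate(b).rows

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            concatenate({"g": {"A": "ACG", "B": "AC"}})

    def test_partition_file_format(self):
        sm = concatenate({"g1": {"A": "ACG"}, "g2": {"A": "TTTTTT"}})
        assert sm.partition_text() == "DNA, g1 = 1-3\nDNA, g2 = 4-9\n"

    def test_gappy_column_mask(self):
        sm = concatenate({"g": {"A": "AC-T", "B": "A--T", "C": "AC-T"}})
        masked = mask_gappy_columns(sm, 0.5)
        assert masked.n_columns == 3 and masked.rows["B"] == "A-T"


class TestK2P:
    def test_identical_rows(self):
        assert k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_formula_hand_evaluation(self):
        # 100 sites: 10 transitions, 5 transversions -> P=0.1, Q=0.05
        a = "A" * 100
        b = "G" * 10 + "C" * 5 + "A" * 85
        expect = -0.5 * math.log((1 - 2 * 0.1 - 0.05) * math.sqrt(1 - 2 * 0.05))
        assert k2p_distance(a, b) == pytest.approx(expect)

    def test_correction_exceeds_p_distance(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), 500))
            idx = rng.choice(500, 60, replace=False)
            b = list(a)
            for i in idx:
                b[i] = rng.choice([c for c in "ACGT" if c != a[i]])
            b = "".join(b)
            assert k2p_distance(a, b) >= p_distance(a, b)

    def test_gaps_excluded_pairwise(self):
        assert k2p_distance("ACGT--", "ACGTAA") == 0.0

    def test_saturation(self):
        with pytest.raises(SaturationError):
            k2p_distance("A" * 50, "G" * 50)


class TestNJ:
    def test_additive_four_taxon_recovery(self):
        true = "((A:0.1,B:0.2):0.05,C:0.15,D:0.3);"
        taxa, d = _tree_distances(true)
        tree = nj(taxa, d)
        assert rf_distance(tree, true) == 0
        # branch lengths are recovered exactly on additive input
        built = {}
        for leaf in tree.leaf_node_iter():
            built[leaf.taxon.label] = leaf.edge.length
        assert built["A"] == pytest.approx(0.1, abs=1e-9)
        assert built["D"] == pytest.approx(0.3, abs=1e-9)

    def test_three_taxa_star(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        tree = nj(["A", "B", "C"], d)
        assert len(tree.leaf_nodes()) == 3

    def test_taxon_order_invariance(self):
        true = "(((A:0.1,B:0.1):0.1,C:0.2):0.05,(D:0.1,E:0.2):0.1);"
        taxa, d = _tree_distances(true)
        tree1 = nj(taxa, d)
        perm = [3, 1, 4, 0, 2]
        tree2 = nj([taxa[i] for i in perm], d[np.ix_(perm, perm)])
        assert rf_distance(tree1, tree2) == 0

    def test_fixed_point_on_own_distances(self):
        true = "(((A:0.1,B:0.15):0.12,C:0.2):0.07,(D:0.1,E:0.2):0.1,F:0.3);"
        taxa, d = _tree_distances(true)
        t1 = nj(taxa, d)
        taxa2, d2 = _tree_distances(t1.as_string(schema="newick"))
        assert rf_distance(t1, nj(taxa2, d2)) == 0

    def test_agrees_with_independent_nj(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        true = "(((A:0.11,B:0.14):0.1,C:0.22):0.06,(D:0.13,E:0.21):0.09,F:0.25);"
        taxa, d = _tree_distances(true)
        ours = nj(taxa, d)
        theirs = skbio_nj(DistanceMatrix(d, taxa))
        assert rf_distance(ours, str(theirs)) == 0


class TestBootstrap:
    def _structured_matrix(self, seed=1):
        tree = "((A:0.05,B:0.05):0.1,(C:0.05,D:0.05):0.1);"
        seqs, _ = evolve_on_tree(EvolutionSpec(tree=tree, n_sites=3000, seed=seed))
        return concatenate({"all": seqs})

    def test_deep_split_high_support(self):
        sm = self._structured_matrix()
        _, support = bootstrap(sm, B=100, seed=0)
        assert max(support.values()) >= 95.0

    def test_seed_reproducibility(self):
        sm = self._structured_matrix()
        t1, s1 = bootstrap(sm, B=50, seed=9)
        t2, s2 = bootstrap(sm, B=50, seed=9)
        assert s1 == s2
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_signal_free_matrix_handled(self):
        rows = {t: "ACGT" * 50 for t in "ABCD"}
        sm = Supermatrix(taxa=list("ABCD"), rows=rows, partitions={"all": (0, 200)})
        tree, support = bootstrap(sm, B=20, seed=0)
        assert len(tree.leaf_nodes()) == 4
        assert all(0.0 <= v <= 100.0 for v in support.values())


class TestTreeComparison:
    def test_identical_trees(self):
        t = "((A,B),(C,D));"
        assert rf_distance(t, t) == 0

    def test_conflicting_four_taxon_resolutions(self):
        assert rf_distance("((A,B),(C,D));", "((A,C),(B,D));") == 2

    def test_monophyly_after_outgroup_rooting(self):
        t = "((A:1,B:1):1,C:1,D:1);"
        assert is_monophyletic(t, {"A", "B"}, outgroup="D")
        assert not is_monophyletic(t, {"A", "C"}, outgroup="D")

    def test_ts_tv_table(self):
        sm = concatenate({"g": {"A": "AAAA", "B": "AGAT"}})
        rows = ts_tv_table(sm)
        assert rows[0]["P_transition"] == 0.25 and rows[0]["Q_transversion"] == 0.25


class TestPipelineRecovery:
    TREE = "(((A:0.1,B:0.1):0.15,C:0.2):0.05,((D:0.1,E:0.1):0.15,F:0.2):0.05);"

    def test_k2p_nj_recovers_simulated_topology(self):
        ok = 0
        for rep in range(20):
            seqs, _ = evolve_on_tree(
                EvolutionSpec(tree=self.TREE, n_sites=5000, seed=9000 + rep)
            )
            sm = concatenate({"all": seqs})
            if rf_distance(nj_from_supermatrix(sm), self.TREE) == 0:
                ok += 1
        assert ok >= 19

    def test_star_branch_distance_expectation(self):
        seqs, _ = evolve_on_tree(
            EvolutionSpec(tree="(A:0.15,B:0.15,C:0.15);", n_sites=10_000, seed=4)
        )
        d = k2p_distance(seqs["A"], seqs["B"])
        assert d == pytest.approx(0.30, rel=0.10)
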