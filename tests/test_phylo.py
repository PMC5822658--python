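"""Neighbor joining, bootstrap supports and Robinson-Foulds congruence."""

from __future__ import annotations

import numpy as np
import pytest

from teratornscan import simulate as sim
from teratornscan._seq import decode
from teratornscan.divergence import k2p_distance
from teratornscan.phylo import (
    CONCAT_ORDER,
    DistanceMatrix,
    bootstrap_support,
    concatenate_alignments,
    congruence_test,
    distance_matrix,
    neighbor_joining,
    read_newick,
    robinson_foulds,
    write_newick,
)


def tree_path_distances(tree):
    """Leaf-to-leaf path-length matrix from a dendropy tree."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    n = len(labels)
    d = np.zeros((n, n))
    tx = {t.label: t for t in tree.taxon_namespace}
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(tx[labels[i]], tx[labels[j]])
    return DistanceMatrix(labels, d)


class TestDistanceMatrix:
    def test_identical_triplet_zero(self):
        aln = {k: "ACGT" * 50 for k in "abc"}
        dm = distance_matrix(aln)
        assert (dm.d == 0).all()

    def test_entries_match_pairwise_k2p(self):
        rng = np.random.default_rng(0)
        base = decode(rng.choice(4, size=600).astype(np.uint8))
        aln = {
            f"t{i}": sim.evolve_sequence(base, 0.05 * (i + 1), seed=i) for i in range(4)
        }
        dm = distance_matrix(aln)
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                if i < j:
                    assert dm.d[i, j] == pytest.approx(
                        k2p_distance((aln[a], aln[b])).d, abs=1e-12
                    )

    def test_saturated_pair_named(self):
        aln = {"a": "A" * 100, "b": "G" * 60 + "C" * 40, "c": "A" * 100}
        with pytest.raises(Exception, match="a.*b|b.*a"):
            distance_matrix(aln)


class TestNeighborJoining:
    def test_three_leaf_closed_form(self):
        dm = DistanceMatrix(
            ["A", "B", "C"],
            np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]]),
        )
        tree = neighbor_joining(dm)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(1.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_too_few_taxa_raises(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_ultrametric_four_leaf_split(self):
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0.0, 0.2, 1.0, 1.0],
                [0.2, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.2],
                [1.0, 1.0, 0.2, 0.0],
            ]
        )
        tree = neighbor_joining(DistanceMatrix(labels, d))
        from teratornscan.phylo import _splits

        assert frozenset({"C", "D"}) in _splits(tree) or frozenset({"A", "B"}) in _splits(tree)

    def test_additive_recovery_many_random_trees(self):
        # NJ is consistent on additive distances: exact topology recovery
        for n in range(4, 13):
            for rep in range(4):
                true = sim.random_tree(n, seed=n * 100 + rep)
                dm = tree_path_distances(true)
                est = neighbor_joining(dm)
                assert robinson_foulds(true, est).rf == 0, (n, rep)

    def test_matches_skbio_topology(self):
        import skbio

        rng = np.random.default_rng(1)
        base = decode(rng.choice(4, size=2000).astype(np.uint8))
        tree_true = sim.random_tree(7, seed=3)
        seqs = sim.evolve_along_tree(base, tree_true, seed=4)
        dm = distance_matrix(seqs)
        mine = neighbor_joining(dm)
        sk_dm = skbio.DistanceMatrix(dm.d, ids=dm.labels)
        sk_tree = skbio.tree.nj(sk_dm)
        import dendropy

        sk_dendro = dendropy.Tree.get(data=str(sk_tree), schema="newick")
        assert robinson_foulds(mine, sk_dendro).rf == 0

    def test_branch_lengths_non_negative(self):
        rng = np.random.default_rng(5)
        # noisy matrix that can induce negative NJ estimates
        d = rng.uniform(0.1, 0.2, size=(6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = neighbor_joining(DistanceMatrix([f"t{i}" for i in range(6)], d))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0


class TestRobinsonFoulds:
    def test_self_distance_zero(self):
        t = sim.random_tree(8, seed=1)
        assert robinson_foulds(t, t).rf == 0

    def test_maximally_different_quartets(self):
        import dendropy

        t1 = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        t2 = dendropy.Tree.get(data="((A,C),(B,D));", schema="newick")
        res = robinson_foulds(t1, t2)
        assert res.rf == 2
        assert res.rf_normalized == 1.0

    def test_symmetric(self):
        t1 = sim.random_tree(7, seed=2)
        t2 = sim.random_tree(7, seed=3)
        assert robinson_foulds(t1, t2).rf == robinson_foulds(t2, t1).rf

    def test_too_few_shared_leaves_raises(self):
        t1 = sim.random_tree(4, seed=4)
        t2 = sim.random_tree(3, seed=5)
        with pytest.raises(ValueError):
            robinson_foulds(t1, t2)


class TestNewick:
    def test_round_trip(self, tmp_path):
        t = sim.random_tree(9, seed=6)
        path = tmp_path / "t.nwk"
        write_newick(t, path)
        back = read_newick(path)
        assert robinson_foulds(t, back).rf == 0
        orig = sorted(l.edge.length for l in t.leaf_node_iter())
        again = sorted(l.edge.length for l in back.leaf_node_iter())
        assert np.allclose(orig, again, atol=1e-9)


class TestBootstrap:
    def make_two_clade_alignment(self, seed=0):
        rng = np.random.default_rng(seed)
        base = decode(rng.choice(4, size=2000).astype(np.uint8))
        cladeA = sim.evolve_sequence(base, 0.25, seed=1)
        cladeB = sim.evolve_sequence(base, 0.25, seed=2)
        aln = {}
        for i in range(3):
            aln[f"a{i}"] = sim.evolve_sequence(cladeA, 0.005, seed=10 + i)
            aln[f"b{i}"] = sim.evolve_sequence(cladeB, 0.005, seed=20 + i)
        return aln

    def test_clear_split_high_support(self):
        aln = self.make_two_clade_alignment()
        tree, supports = bootstrap_support(aln, n_replicates=200, seed=7)
        key = frozenset({"b0", "b1", "b2"})
        central = supports.get(key) or supports.get(frozenset({"a0", "a1", "a2"}))
        assert central is not None and central >= 99

    def test_supports_bounded_and_deterministic(self):
        aln = self.make_two_clade_alignment(seed=1)
        _, s1 = bootstrap_support(aln, n_replicates=50, seed=9)
        _, s2 = bootstrap_support(aln, n_replicates=50, seed=9)
        assert s1 == s2
        assert all(0 <= v <= 100 for v in s1.values())


class TestCongruence:
    def co_simulate(self, seed, n_taxa=8):
        rng = np.random.default_rng(seed)
        species = sim.random_tree(n_taxa, seed=seed)
        tp_root = decode(rng.choice(4, size=1200).astype(np.uint8))
        tp_aln = sim.evolve_along_tree(tp_root, species, seed=seed + 1)
        gene_alns = {}
        for gi, gene in enumerate(CONCAT_ORDER):
            root = decode(rng.choice(4, size=900).astype(np.uint8))
            gene_alns[gene] = sim.evolve_along_tree(root, species, seed=seed + 2 + gi)
        taxa = sorted(tp_aln)
        return tp_aln, gene_alns, taxa

    def test_identical_alignments_rf_zero(self):
        tp_aln, gene_alns, taxa = self.co_simulate(31)
        same_genes = {g: tp_aln for g in CONCAT_ORDER}
        res, *_ = congruence_test(tp_aln, same_genes, taxa)
        assert res.rf == 0

    def test_co_simulated_histories_congruent(self):
        hits = 0
        for seed in range(10):
            tp_aln, gene_alns, taxa = self.co_simulate(100 + seed * 7)
            res, *_ = congruence_test(tp_aln, gene_alns, taxa)
            if res.rf == 0:
                hits += 1
        assert hits >= 9

    def test_label_shuffling_breaks_congruence(self):
        rfs = []
        for seed in range(8):
            tp_aln, gene_alns, taxa = self.co_simulate(500 + seed * 11)
            rng = np.random.default_rng(seed)
            perm = list(taxa)
            rng.shuffle(perm)
            shuffled = {new: tp_aln[old] for new, old in zip(taxa, perm)}
            res, *_ = congruence_test(shuffled, gene_alns, taxa)
            rfs.append(res.rf)
        assert np.median(rfs) > 0

    def test_missing_taxon_named(self):
        tp_aln, gene_alns, taxa = self.co_simulate(77)
        del gene_alns["pol"]["t1"]
        with pytest.raises(KeyError, match="t1"):
            congruence_test(tp_aln, gene_alns, taxa)

    def test_ds_comparability_on_cosimulated_cds(self):
        # under a shared history, per-pair synonymous divergence of the
        # transposase tracks that of the concatenated viral genes
        from scipy.stats import spearmanr

        from teratornscan.divergence import ng_dnds

        rng = np.random.default_rng(13)
        species = sim.random_tree(10, seed=42, min_bl=0.01, max_bl=0.06)
        tp_root = sim._back_translate(rng, sim._random_protein(rng, 250))[:-3]
        v_root = sim._back_translate(rng, sim._random_protein(rng, 500))[:-3]
        tp = sim.evolve_cds_along_tree(tp_root, species, seed=1)
        vg = sim.evolve_cds_along_tree(v_root, species, seed=2)
        taxa = sorted(tp)
        ds_tp, ds_vg = [], []
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                a, b = taxa[i], taxa[j]
                try:
                    e1 = ng_dnds((tp[a], tp[b]))
                    e2 = ng_dnds((vg[a], vg[b]))
                except ValueError:
                    continue  # stop codon created by neutral evolution
                ds_tp.append(e1.dS)
                ds_vg.append(e2.dS)
        rho = spearmanr(ds_tp, ds_vg).statistic
        assert len(ds_tp) >= 20
        assert rho > 0.8


class TestConcatenate:
    def test_column_wise_join(self):
        genes = {
            "pol": {"x": "AAA", "y": "CCC"},
            "hel": {"x": "GGG", "y": "TTT"},
        }
        out = concatenate_alignments(genes, ["x", "y"])
        assert out == {"x": "AAAGGG", "y": "CCCTTT"}

    def test_fixed_order(self):
        genes = {g: {"x": g[:1].upper() * 3} for g in CONCAT_ORDER}
        out = concatenate_alignments(genes, ["x"])
        assert out["x"] == "".join(g[:1].upper() * 3 for g in CONCAT_ORDER)
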