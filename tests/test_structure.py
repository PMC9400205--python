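"""IBS distances, neighbor joining against additive-matrix oracles and an
independent library implementation, Newick round-trips, and PCA properties."""
import io

import numpy as np
import pytest

from invasweep import (AdmixedSpec, ChromSpec, DistanceMatrix, PopSpec,
                       SimConfig, ibs_distance, nj_tree, pca,
                       simulate_genotypes, to_newick)

from conftest import make_gm


class TestIbsDistance:
    def test_identical_samples_distance_zero(self):
        d = np.array([[0, 0], [1, 1], [2, 2]], dtype=np.int8)
        dm = ibs_distance(make_gm(d))
        assert dm.matrix[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        d = np.array([[0, 2], [0, 2]], dtype=np.int8)
        assert ibs_distance(make_gm(d)).matrix[0, 1] == 1.0

    def test_het_vs_hom_half(self):
        d = np.array([[0, 1]], dtype=np.int8)
        assert ibs_distance(make_gm(d)).matrix[0, 1] == 0.5

    def test_missing_sites_excluded_pairwise(self):
        d = np.array([[0, 2], [-1, 2], [0, -1]], dtype=np.int8)
        dm = ibs_distance(make_gm(d))
        assert dm.matrix[0, 1] == 1.0
        assert dm.pair_sites[0, 1] == 1

    def test_no_shared_sites_raises(self):
        d = np.array([[0, -1], [-1, 2]], dtype=np.int8)
        with pytest.raises(ValueError, match="share"):
            ibs_distance(make_gm(d))


def tree_from_newick_skbio(newick):
    from skbio import TreeNode
    return TreeNode.read(io.StringIO(newick))


def random_additive_matrix(rng, n_leaves):
    """Random unrooted binary tree with positive lengths; returns its
    leaf names and patristic distance matrix (the additive oracle)."""
    from skbio import TreeNode
    names = [f"L{i}" for i in range(n_leaves)]
    nodes = [TreeNode(name=nm) for nm in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        for x in (a, b):
            x.length = float(rng.uniform(0.1, 2.0))
        parent = TreeNode(children=[b, a])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    for x in nodes:
        x.length = float(rng.uniform(0.1, 2.0))
    root = TreeNode(children=nodes)
    dm = root.tip_tip_distances()
    order = [dm.ids.index(nm) for nm in names]
    return names, np.asarray(dm.data)[np.ix_(order, order)]


class TestNeighborJoining:
    def test_three_taxon_formulas(self):
        d = np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], d, np.ones((3, 3), int)))
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths == {"A": 0.0, "B": 2.0, "C": 4.0}

    def test_four_taxon_additive_recovery(self):
        # distances from tree ((A:1,B:2):1,(C:3,D:4)) with internal edge 1
        names = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(names, d, np.ones((4, 4), int)))
        got_names, got = tree.leaf_path_lengths()
        order = [got_names.index(n) for n in names]
        np.testing.assert_allclose(got[np.ix_(order, order)], d, atol=1e-9)
        # topology AB|CD: A and B must be sisters
        for child in tree.root.children:
            leaves = sorted(l.name for l in child.leaves())
            assert leaves not in (["A", "C"], ["A", "D"], ["B", "C"],
                                  ["B", "D"])

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 8])
    def test_additive_matrices_recovered_exactly(self, n_leaves):
        """On any additive matrix, NJ reproduces the generating patristic
        distances (hence the topology) exactly."""
        rng = np.random.default_rng(n_leaves)
        for rep in range(5):
            names, d = random_additive_matrix(rng, n_leaves)
            tree = nj_tree(DistanceMatrix(names, d, np.ones_like(d, int)))
            got_names, got = tree.leaf_path_lengths()
            order = [got_names.index(n) for n in names]
            np.testing.assert_allclose(got[np.ix_(order, order)], d,
                                       atol=1e-8)

    def test_matches_library_nj_topology(self):
        """Cross-check against an independent NJ implementation on a noisy
        (non-additive) matrix: same unrooted topology."""
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj
        rng = np.random.default_rng(123)
        names, d = random_additive_matrix(rng, 7)
        noise = rng.uniform(0, 0.01, size=d.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        d = d + noise
        ours = nj_tree(DistanceMatrix(names, d, np.ones_like(d, int)))
        theirs = sk_nj(SkDM(d, ids=names))
        ours_sk = tree_from_newick_skbio(to_newick(ours))
        assert ours_sk.compare_rfd(theirs) == 0.0

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(5)
        names, d = random_additive_matrix(rng, 6)
        perm = rng.permutation(6)
        t1 = nj_tree(DistanceMatrix(names, d, np.ones_like(d, int)))
        t2 = nj_tree(DistanceMatrix([names[i] for i in perm],
                                    d[np.ix_(perm, perm)],
                                    np.ones_like(d, int)))
        a = tree_from_newick_skbio(to_newick(t1))
        b = tree_from_newick_skbio(to_newick(t2))
        assert a.compare_rfd(b) == 0.0

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B", "C"], d, np.ones((3, 3), int)))


class TestNewick:
    def test_three_taxon_string(self):
        d = np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["A", "B", "C"], d, np.ones((3, 3), int)))
        s = to_newick(tree)
        assert s.endswith(");")
        assert "A:0" in s and "B:2" in s and "C:4" in s

    def test_round_trip_preserves_topology_and_lengths(self):
        rng = np.random.default_rng(9)
        names, d = random_additive_matrix(rng, 6)
        tree = nj_tree(DistanceMatrix(names, d, np.ones_like(d, int)))
        parsed = tree_from_newick_skbio(to_newick(tree))
        dm = parsed.tip_tip_distances()
        order = [dm.ids.index(n) for n in names]
        np.testing.assert_allclose(np.asarray(dm.data)[np.ix_(order, order)],
                                   d, atol=1e-6)

    def test_names_with_spaces_quoted(self):
        d = np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["tax on A", "B", "C"], d,
                                      np.ones((3, 3), int)))
        assert "'tax on A'" in to_newick(tree)


class TestPca:
    def test_duplicated_sample_identical_coordinates(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, (60, 5)).astype(np.int8)
        d = np.column_stack([d, d[:, 0]])  # sample 6 duplicates sample 1
        res = pca(make_gm(d), k=2)
        np.testing.assert_allclose(res.coordinates[0], res.coordinates[5],
                                   atol=1e-9)

    def test_fixed_groups_separate_on_pc1(self):
        d = np.zeros((40, 8), dtype=np.int8)
        d[:, 4:] = 2
        res = pca(make_gm(d), k=2)
        pc1 = res.coordinates[:, 0]
        assert np.allclose(pc1[:4], pc1[0]) and np.allclose(pc1[4:], pc1[4])
        assert abs(pc1[0] - pc1[4]) > 0.1

    def test_eigenvalues_nonnegative_descending_and_sum_to_total(self):
        rng = np.random.default_rng(4)
        d = rng.integers(0, 3, (100, 10)).astype(np.int8)
        res = pca(make_gm(d), k=3)
        ev = res.eigenvalues
        assert (ev >= 0).all()
        assert (np.diff(ev) <= 1e-9).all()
        assert res.variance_explained.sum() <= 1.0 + 1e-9

    def test_sample_order_invariance_up_to_sign(self):
        rng = np.random.default_rng(6)
        d = rng.integers(0, 3, (80, 6)).astype(np.int8)
        perm = rng.permutation(6)
        r1 = pca(make_gm(d), k=2)
        r2 = pca(make_gm(d[:, perm],
                         samples=[f"S{j + 1}" for j in perm]), k=2)
        back = {s: i for i, s in enumerate(r2.sample_ids)}
        reord = np.array([back[s] for s in r1.sample_ids])
        for comp in range(2):
            a, b = r1.coordinates[:, comp], r2.coordinates[reord, comp]
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)

    def test_k_too_large_rejected(self):
        d = np.zeros((10, 3), dtype=np.int8)
        d[::2, 0] = 1
        with pytest.raises(ValueError):
            pca(make_gm(d), k=3)


def test_admixed_samples_fall_between_source_clusters():
    """Individuals with ancestry split between two sources must project
    strictly between the source-population centroids on the PC1-PC2 plane."""
    cfg = SimConfig(
        seed=21,
        chromosomes=[ChromSpec("chr1", 400_000)],
        populations=[PopSpec("P1", 8, 0.15), PopSpec("P2", 8, 0.15),
                     PopSpec("P3", 8, 0.15)],
        site_density=0.01,
        admixed=[AdmixedSpec(f"MIX_{i}", {"P1": 0.5, "P2": 0.5}, "F")
                 for i in range(3)],
    )
    gm, meta, _ = simulate_genotypes(cfg)
    res = pca(gm, k=2)
    coords = {s: res.coordinates[i] for i, s in enumerate(res.sample_ids)}
    c1 = np.mean([coords[m.sample_id] for m in meta
                  if m.population == "P1"], axis=0)
    c2 = np.mean([coords[m.sample_id] for m in meta
                  if m.population == "P2"], axis=0)
    axis = c2 - c1
    denom = axis @ axis
    for m in meta:
        if m.population == "ADMIXED":
            t = ((coords[m.sample_id] - c1) @ axis) / denom
            assert 0.0 < t < 1.0
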