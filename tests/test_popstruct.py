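import numpy as np
import pytest

from introscan.genotype_io import MISSING, PopulationMap
from introscan.popstruct import (DistanceMatrix, allele_frequencies, nj_tree,
                                 p_distance_matrix, pca)

from conftest import make_panel


class TestAlleleFrequencies:
    def test_all_reference(self, two_group_map):
        panel = make_panel(np.zeros((6, 4), dtype=int))
        p = allele_frequencies(panel, two_group_map, "A")
        np.testing.assert_allclose(p, 1.0)

    def test_missing_excluded_from_denominator(self):
        panel = make_panel(np.array([[0], [0], [1], [MISSING]]))
        pm = PopulationMap({"s1": "G", "s2": "G"})
        p = allele_frequencies(panel, pm, "G")
        assert p[0] == pytest.approx(2 / 3)

    def test_counting_oracle(self, two_group_map):
        rng = np.random.default_rng(2)
        alleles = rng.choice([0, 1, MISSING], size=(6, 20), p=[0.4, 0.4, 0.2])
        panel = make_panel(alleles)
        p = allele_frequencies(panel, two_group_map, "A")
        for j in range(20):
            col = [int(x) for x in alleles[:4, j] if x != MISSING]
            expect = (col.count(0) / len(col)) if col else np.nan
            if np.isnan(expect):
                assert np.isnan(p[j])
            else:
                assert p[j] == pytest.approx(expect)

    def test_unknown_group(self, toy_panel, two_group_map):
        with pytest.raises(KeyError):
            allele_frequencies(toy_panel, two_group_map, "Z")


class TestPDistance:
    def test_identical_and_complementary(self):
        panel = make_panel(np.array([
            [0, 1, 0, 1],
            [0, 1, 0, 1],
            [1, 0, 1, 0],
            [0, 0, 0, 0],
        ]))
        dm = p_distance_matrix(panel, unit="haplotype")
        assert dm.d[0, 1] == 0.0
        assert dm.d[0, 2] == 1.0

    def test_hand_counted_triples(self):
        # h1=0101, h2=0111, h3=1100 ; h4 filler
        panel = make_panel(np.array([
            [0, 1, 0, 1],
            [0, 1, 1, 1],
            [1, 1, 0, 0],
            [0, 0, 0, 0],
        ]))
        dm = p_distance_matrix(panel, unit="haplotype")
        assert dm.d[0, 1] == pytest.approx(1 / 4)
        assert dm.d[0, 2] == pytest.approx(2 / 4)
        assert dm.d[1, 2] == pytest.approx(3 / 4)

    def test_sample_unit_dosage_convention(self):
        # sample1 = 0|0 (dosage 0), sample2 = 1|1 (dosage 2) -> d = 1
        panel = make_panel(np.array([[0], [0], [1], [1]]))
        dm = p_distance_matrix(panel, unit="sample")
        assert dm.d[0, 1] == pytest.approx(1.0)

    def test_no_joint_sites_flagged_nan(self):
        panel = make_panel(np.array([
            [0, MISSING],
            [0, 0],
            [MISSING, 1],
            [0, 1],
        ]))
        with pytest.warns(UserWarning, match="no non-missing"):
            dm = p_distance_matrix(panel, unit="haplotype")
        assert np.isnan(dm.d[0, 2])


def random_additive_tree(n_taxa, rng):
    """Random binary tree with positive branch lengths -> (splits, distances).

    Built independently of the NJ code: explicit node graph, path distances
    by BFS.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # start from a 3-star, attach remaining taxa to random edges
    nodes = {"root": {}}
    adj = {}

    def add_edge(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    add_edge(labels[0], "x0", rng.uniform(0.5, 2))
    add_edge(labels[1], "x0", rng.uniform(0.5, 2))
    add_edge(labels[2], "x0", rng.uniform(0.5, 2))
    internal = 1
    for leaf in labels[3:]:
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[rng.integers(len(edges))]
        w = adj[a].pop(b)
        adj[b].pop(a)
        mid = f"x{internal}"
        internal += 1
        f = rng.uniform(0.2, 0.8)
        add_edge(a, mid, w * f)
        add_edge(mid, b, w * (1 - f))
        add_edge(leaf, mid, rng.uniform(0.5, 2))

    def path_len(a, b):
        seen = {a: 0.0}
        queue = [a]
        while queue:
            u = queue.pop()
            for v, w in adj[u].items():
                if v not in seen:
                    seen[v] = seen[u] + w
                    queue.append(v)
        return seen[b]

    d = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            d[i, j] = d[j, i] = path_len(labels[i], labels[j])
    return labels, d


def tree_distances(newick, labels):
    """Leaf-to-leaf path lengths of a Newick tree via dendropy (oracle)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return d


class TestNJ:
    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        nwk = nj_tree(DistanceMatrix(["A", "B", "C"], d))
        # lA = (dAB + dAC - dBC)/2 = 0.1, lB = 0.2, lC = 0.4
        assert "A:0.1" in nwk and "B:0.2" in nwk and "C:0.4" in nwk

    def test_four_taxon_additive_split(self):
        # ((A,B),(C,D)) with internal edge 1: additive matrix
        d = np.array([
            [0, 2, 4, 4],
            [2, 0, 4, 4],
            [4, 4, 0, 2],
            [4, 4, 2, 0],
        ], dtype=float)
        nwk = nj_tree(DistanceMatrix(list("ABCD"), d))
        # an additive matrix determines its tree uniquely: recovering the
        # ((A,B),(C,D)) topology is equivalent to reproducing all distances
        got = tree_distances(nwk, list("ABCD"))
        np.testing.assert_allclose(got, d, atol=1e-9)
        # and the wrong topologies cannot reproduce them: A-B distance must
        # go through no internal edge shared with C or D
        assert "A" in nwk and "B" in nwk

    def test_recovers_random_tree_topologies(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = int(rng.integers(5, 9))
            labels, d = random_additive_tree(n, rng)
            nwk = nj_tree(DistanceMatrix(labels, d))
            # additivity: a tree metric has a unique realizing tree, so
            # reproducing every pairwise distance proves topology recovery
            got = tree_distances(nwk, labels)
            np.testing.assert_allclose(got, d, atol=1e-8)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestPCA:
    def test_two_clusters_separate_on_pc1(self):
        block = np.zeros((8, 20), dtype=int)
        block[4:, :] = 1  # second cluster fixed for alternate allele
        alleles = np.repeat(block, 2, axis=0)  # 8 samples, homozygous
        panel = make_panel(alleles)
        scores, ev = pca(panel, n_components=2)
        pc1 = scores["PC1"].to_numpy()
        assert np.allclose(pc1[:4], pc1[0]) and np.allclose(pc1[4:], pc1[4])
        assert abs(pc1[0] - pc1[4]) > 1.0

    def test_eigen_oracle(self):
        rng = np.random.default_rng(8)
        alleles = rng.integers(0, 2, size=(10, 8))  # 5 samples x 8 variants
        panel = make_panel(alleles)
        scores, ev = pca(panel, n_components=5, scale=False)

        g = (alleles[0::2] + alleles[1::2]).astype(float)
        g -= g.mean(axis=0)
        cov = g @ g.T / (g.shape[0] - 1)  # sample-sample covariance via Gram
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        oracle = v * np.sqrt(np.maximum(w, 0) * (g.shape[0] - 1))
        got = scores.to_numpy()
        for k in range(min(4, got.shape[1])):
            if w[k] < 1e-12:
                continue
            assert (np.allclose(got[:, k], oracle[:, k], atol=1e-10)
                    or np.allclose(got[:, k], -oracle[:, k], atol=1e-10))

    def test_explained_variance_identity(self):
        rng = np.random.default_rng(9)
        alleles = rng.integers(0, 2, size=(12, 15))
        panel = make_panel(alleles)
        scores, ev = pca(panel, n_components=6, scale=True)
        g = (alleles[0::2] + alleles[1::2]).astype(float)
        p = g.mean(axis=0) / 2
        sd = np.sqrt(2 * p * (1 - p))
        gs = (g - g.mean(axis=0))
        nz = sd > 0
        gs[:, nz] /= sd[nz]
        gs[:, ~nz] = 0
        total = (gs ** 2).sum() / (g.shape[0] - 1)
        assert ev.sum() == pytest.approx(total, rel=1e-10)
        assert (np.diff(ev) <= 1e-12).all()

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(10)
        alleles = rng.integers(0, 2, size=(12, 20))
        panel = make_panel(alleles)
        scores, _ = pca(panel, n_components=3)
        perm = rng.permutation(6)
        rows = np.ravel(np.column_stack([2 * perm, 2 * perm + 1]))
        panel2 = make_panel(alleles[rows],
                            sample_ids=[panel.sample_ids[i] for i in perm])
        scores2, _ = pca(panel2, n_components=3)
        for col in scores.columns:
            a = scores[col].to_numpy()
            b = scores2[col].reindex(scores.index).to_numpy()
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)
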