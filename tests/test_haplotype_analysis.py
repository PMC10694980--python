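import itertools

import numpy as np
import pytest

from introscan.genotype_io import MISSING, PopulationMap
from introscan.haplotype_analysis import (NoTagSnpError, build_haplotype_set,
                                          call_Qq, haplotype_network,
                                          heatmap_matrix, informative_snps,
                                          major_haplotype, tag_snps)
from introscan.synthetic_data import SimConfig, simulate_panel

from conftest import make_panel


def two_group_panel(rows_a, rows_b):
    """rows_a / rows_b: lists of haplotype allele lists (even counts)."""
    alleles = np.array(rows_a + rows_b)
    na, nb = len(rows_a) // 2, len(rows_b) // 2
    ids = [f"a{i}" for i in range(na)] + [f"b{i}" for i in range(nb)]
    panel = make_panel(alleles, sample_ids=ids)
    pm = PopulationMap({f"a{i}": "A" for i in range(na)}
                       | {f"b{i}": "B" for i in range(nb)})
    return panel, pm


class TestInformativeSnps:
    def test_fixed_difference_kept(self):
        panel, pm = two_group_panel([[1, 0], [1, 0]], [[0, 0], [0, 0]])
        idx = informative_snps(panel, pm, "A", "B", 0.8)
        assert list(idx) == [0]

    def test_half_difference_dropped(self):
        panel, pm = two_group_panel([[1, 0], [0, 0]], [[0, 0], [0, 0]])
        idx = informative_snps(panel, pm, "A", "B", 0.8)
        assert list(idx) == []

    def test_brute_force(self):
        rng = np.random.default_rng(1)
        alleles = rng.integers(0, 2, size=(12, 30))
        panel, pm = two_group_panel(
            [list(r) for r in alleles[:6]], [list(r) for r in alleles[6:]])
        idx = informative_snps(panel, pm, "A", "B", 0.3)
        for j in range(30):
            pa = np.mean(alleles[:6, j] == 0)
            pb = np.mean(alleles[6:, j] == 0)
            assert (j in idx) == (abs(pa - pb) > 0.3)


class TestBuildHaplotypeSet:
    def test_all_identical(self):
        panel, pm = two_group_panel([[0, 1]] * 4, [[0, 1]] * 2)
        hset = build_haplotype_set(panel, pm)
        assert hset.labels == ["hap_1"]
        assert hset.total_counts[0] == 6

    def test_disjoint_group_haplotypes(self):
        panel, pm = two_group_panel([[0, 0]] * 4, [[1, 1]] * 2)
        hset = build_haplotype_set(panel, pm)
        assert hset.n_haplotypes == 2
        assert hset.group_counts.loc["hap_1", "A"] == 4
        assert hset.group_counts.loc["hap_1", "B"] == 0
        assert hset.group_counts.loc["hap_2", "B"] == 2

    def test_labels_by_descending_frequency(self):
        panel, pm = two_group_panel(
            [[0, 0], [1, 1], [1, 1], [1, 1]], [[0, 1], [0, 1]])
        hset = build_haplotype_set(panel, pm)
        assert hset.allele_string("hap_1") == "11"
        assert list(hset.total_counts) == [3, 2, 1]

    def test_missing_haplotypes_excluded_and_counted(self):
        panel, pm = two_group_panel(
            [[0, MISSING], [1, 1]], [[1, 1], [0, 0]])
        hset = build_haplotype_set(panel, pm)
        assert hset.n_excluded_missing == 1
        assert hset.total_counts.sum() == 3

    def test_counts_sum_invariant(self):
        rng = np.random.default_rng(2)
        alleles = rng.choice([0, 1], size=(16, 6))
        panel, pm = two_group_panel(
            [list(r) for r in alleles[:8]], [list(r) for r in alleles[8:]])
        hset = build_haplotype_set(panel, pm)
        assert hset.group_counts.loc[:, "A"].sum() == 8
        assert hset.group_counts.loc[:, "B"].sum() == 8

    def test_simulated_tract_collapses_with_source(self):
        cfg = SimConfig(n_source=10, n_control=10, n_recipient=10,
                        chrom_lengths={"1": 500_000},
                        tracts=[("1", 100_001, 400_001, 1.0)],
                        tract_source_sweep=1.0, tract_mut_rate=0.0, seed=3)
        panel, popmap, _ = simulate_panel(cfg)
        region = ("1", 100_001, 400_001)
        hset = build_haplotype_set(panel, popmap, region=region)
        top = major_haplotype(hset, "source")
        # swept source + all carriers share one haplotype
        assert hset.group_counts.loc[top, "source"] == 10
        assert hset.group_counts.loc[top, "recipient"] == 10


class TestHeatmap:
    def test_reference_fixed_rows_major(self):
        panel, pm = two_group_panel([[0, 1], [0, 1]], [[1, 0], [1, 0]])
        hset = build_haplotype_set(panel, pm)
        coded = heatmap_matrix(hset, "A")
        ref_hap = "hap_1" if hset.group_counts.loc["hap_1", "A"] else "hap_2"
        assert (coded.loc[ref_hap] == 0).all()

    def test_complementary_group_all_minor(self):
        panel, pm = two_group_panel([[0, 1], [0, 1]], [[1, 0], [1, 0]])
        hset = build_haplotype_set(panel, pm)
        coded = heatmap_matrix(hset, "A")
        other = [l for l in hset.labels
                 if hset.group_counts.loc[l, "B"] > 0][0]
        assert (coded.loc[other] == 1).all()

    def test_recode_oracle(self):
        rng = np.random.default_rng(4)
        alleles = rng.integers(0, 2, size=(10, 5))
        panel, pm = two_group_panel(
            [list(r) for r in alleles[:6]], [list(r) for r in alleles[6:]])
        hset = build_haplotype_set(panel, pm)
        coded = heatmap_matrix(hset, "A")
        # oracle: weighted majority among group-A haplotype copies per site
        a_rows = alleles[:6]
        for j in range(5):
            maj = 1 if (a_rows[:, j] == 1).sum() * 2 > 6 else 0
            for k, lab in enumerate(hset.labels):
                assert coded.loc[lab].iloc[j] == int(hset.alleles[k, j] != maj)


def mst_weight_bruteforce(dist):
    """Exhaustive minimum over all spanning trees (union-find per subset)."""
    n = dist.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = None
    for combo in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for i, j in combo:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            w = sum(dist[i, j] for i, j in combo)
            best = w if best is None else min(best, w)
    return best


class TestNetwork:
    def test_two_haplotypes_single_edge(self):
        panel, pm = two_group_panel([[0, 0, 0], [0, 0, 0]],
                                    [[1, 1, 1], [1, 1, 1]])
        hset = build_haplotype_set(panel, pm)
        net = haplotype_network(hset)
        assert len(net.edges) == 1
        assert net.edges[0][2] == 3

    def test_unique_mst_three_haplotypes(self):
        # h1=000, h2=001, h3=011: d12=1, d23=1, d13=2
        panel, pm = two_group_panel(
            [[0, 0, 0], [0, 0, 0], [0, 0, 1], [0, 0, 1]],
            [[0, 1, 1], [0, 1, 1]])
        hset = build_haplotype_set(panel, pm)
        net = haplotype_network(hset)
        weights = sorted(w for _, _, w in net.edges)
        assert weights == [1, 1]

    def test_mst_weight_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(5)
        # 8 distinct haplotypes over 10 sites
        haps = set()
        while len(haps) < 8:
            haps.add(tuple(rng.integers(0, 2, size=10)))
        haps = [list(h) for h in haps]
        panel, pm = two_group_panel(haps[:4] * 2, haps[4:] * 2)
        hset = build_haplotype_set(panel, pm)
        assert hset.n_haplotypes == 8
        net = haplotype_network(hset)
        dist = np.array([[sum(x != y for x, y in zip(a, b))
                          for b in hset.alleles] for a in hset.alleles])
        assert net.total_weight == mst_weight_bruteforce(dist)
        assert len(net.edges) == hset.n_haplotypes - 1


class TestTagSnps:
    def _hset(self):
        # Q haplotypes (hap with allele 1 at sites 0..9) vs others (allele 0)
        q = [1] * 10 + [0, 1]
        other1 = [0] * 10 + [0, 1]
        other2 = [0] * 10 + [1, 1]
        panel, pm = two_group_panel([q] * 6, [other1] * 2 + [other2] * 2)
        return build_haplotype_set(panel, pm)

    def test_selected_tags_are_separating(self):
        hset = self._hset()
        q_lab = major_haplotype(hset, "A")
        tags = tag_snps(hset, {q_lab}, n_tags=2, seed=1)
        assert len(tags) == 2
        assert all(t < 10 for t in tags)

    def test_identical_sets_error(self):
        panel, pm = two_group_panel([[0, 1]] * 4, [[0, 1]] * 2)
        hset = build_haplotype_set(panel, pm)
        with pytest.raises(ValueError, match="strict subset"):
            tag_snps(hset, set(hset.labels))

    def test_no_separating_site_error(self):
        panel, pm = two_group_panel(
            [[0, 0], [0, 0], [0, 1], [0, 1]], [[1, 0], [1, 0]])
        hset = build_haplotype_set(panel, pm)
        labs = sorted(hset.labels)
        with pytest.raises(NoTagSnpError):
            tag_snps(hset, {labs[0]}, n_tags=2)

    def test_seeded_determinism(self):
        hset = self._hset()
        q_lab = major_haplotype(hset, "A")
        t1 = tag_snps(hset, {q_lab}, n_tags=2, seed=42)
        t2 = tag_snps(hset, {q_lab}, n_tags=2, seed=42)
        np.testing.assert_array_equal(t1, t2)

    def test_calls_invariant_to_tag_choice(self):
        hset = self._hset()
        q_lab = major_haplotype(hset, "A")
        panel, pm = two_group_panel([[1] * 10 + [0, 1]] * 6,
                                    [[0] * 10 + [0, 1]] * 2
                                    + [[0] * 10 + [1, 1]] * 2)
        results = []
        for seed in (1, 2, 3, 4):
            tags = tag_snps(hset, {q_lab}, n_tags=2, seed=seed)
            pattern = hset.alleles[hset.labels.index(q_lab), tags]
            calls = call_Qq(panel, hset.variant_idx[tags], pattern)
            results.append(tuple(calls["genotype"]))
        assert len(set(results)) == 1


class TestCallQq:
    def test_basic_genotypes(self):
        alleles = np.array([
            [1, 1],  # s1 hap1: Q
            [1, 1],  # s1 hap2: Q  -> QQ
            [1, 1],  # s2 hap1: Q
            [0, 1],  # s2 hap2: q  -> Qq
            [0, 0],  # s3: qq
            [0, 1],
        ])
        panel = make_panel(alleles)
        calls = call_Qq(panel, np.array([0, 1]), np.array([1, 1]))
        assert list(calls["genotype"]) == ["QQ", "Qq", "qq"]

    def test_missing_tag_no_call(self):
        alleles = np.array([[1, 1], [MISSING, 1]])
        panel = make_panel(alleles)
        calls = call_Qq(panel, np.array([0, 1]), np.array([1, 1]))
        assert calls["genotype"].isna().all()

    def test_simulated_carriers_called_q(self):
        cfg = SimConfig(n_source=10, n_control=10, n_recipient=10,
                        chrom_lengths={"1": 500_000},
                        tracts=[("1", 100_001, 400_001, 0.5)],
                        tract_source_sweep=1.0, tract_mut_rate=0.0, seed=6)
        panel, popmap, truth = simulate_panel(cfg)
        region_panel = panel.restrict("1", 100_001, 400_001)
        hset = build_haplotype_set(region_panel, popmap)
        q_lab = major_haplotype(hset, "source")
        tags = tag_snps(hset, {q_lab}, n_tags=2, seed=1)
        pattern = hset.alleles[hset.labels.index(q_lab), tags]
        calls = call_Qq(region_panel, hset.variant_idx[tags], pattern)
        carriers = set(truth.carriers("1", 100_001, 400_001))
        calls = calls.set_index("individual")
        for i, sample in enumerate(region_panel.sample_ids):
            if not sample.startswith("RCP"):
                continue
            n_q = sum(f"{sample}_{h}" in carriers for h in (1, 2))
            assert calls.loc[sample, "genotype"] == ("qq", "Qq", "QQ")[n_q]
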