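"""Proximity, separation, exposure classification and tissue filtering."""

import math
import warnings

import networkx as nx
import numpy as np
import pytest

from combiscreen.network import (
    DegreeMatchedSampler,
    ProteinSet,
    classify_exposure,
    closest_distance,
    proximity_zscore,
    separation_score,
    tissue_filter,
)
from combiscreen.simulate import NetworkConfig, gen_ppi_with_modules


class TestClosestDistance:
    def test_identity_sets_give_zero(self):
        g = nx.cycle_graph(6)
        s = ProteinSet("s", [0, 2, 4])
        assert closest_distance(g, s, s) == 0.0

    def test_path_graph(self, path_graph4):
        assert closest_distance(
            path_graph4, ProteinSet("x", ["a"]), ProteinSet("y", ["c"])
        ) == 2.0

    def test_star_example(self):
        g = nx.star_graph(4)  # center 0, leaves 1..4
        x = ProteinSet("x", [1, 2])
        y = ProteinSet("y", [0, 3])
        # y=0 at distance 1 from either leaf; y=3 at distance 2
        assert closest_distance(g, x, y) == pytest.approx(1.5)

    def test_asymmetry(self, path_graph4):
        x = ProteinSet("x", ["a"])
        y = ProteinSet("y", ["c", "d"])
        assert closest_distance(path_graph4, x, y) == pytest.approx(2.5)
        assert closest_distance(path_graph4, y, x) == pytest.approx(2.0)

    def test_members_outside_component_dropped_with_warning(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("z1", "z2")])
        with pytest.warns(UserWarning, match="outside the largest"):
            d = closest_distance(g, ProteinSet("x", ["a"]), ProteinSet("y", ["c", "z1"]))
        assert d == 2.0

    def test_empty_after_filtering_raises(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("z1", "z2")])
        with pytest.raises(ValueError, match="largest component"):
            closest_distance(g, ProteinSet("x", ["z9"]), ProteinSet("y", ["a"]))

    def test_matches_floyd_warshall_oracle_sample(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            g = nx.gnp_random_graph(25, 0.12, seed=int(rng.integers(2**31)))
            comp = max(nx.connected_components(g), key=len)
            nodes = sorted(comp)
            if len(nodes) < 6:
                continue
            fw = nx.floyd_warshall_numpy(g.subgraph(nodes), nodelist=nodes)
            xi = rng.choice(len(nodes), 3, replace=False)
            yi = rng.choice(len(nodes), 4, replace=False)
            expected = fw[np.ix_(xi, yi)].min(axis=0).mean()
            got = closest_distance(
                g,
                ProteinSet("x", [nodes[i] for i in xi]),
                ProteinSet("y", [nodes[i] for i in yi]),
            )
            assert got == pytest.approx(expected)


class TestSeparation:
    def test_identical_modules_overlap(self):
        g = nx.Graph([("a", "b")])
        s = ProteinSet("s", ["a", "b"])
        res = separation_score(g, s, s)
        assert res.d_ab == 0.0 and res.d_aa == 1.0
        assert res.s_ab == -1.0

    def test_singleton_convention(self, path_graph4):
        res = separation_score(
            path_graph4, ProteinSet("a", ["a"]), ProteinSet("b", ["d"])
        )
        assert res.s_ab == 3.0

    def test_adjacent_pairs(self, path_graph4):
        res = separation_score(
            path_graph4, ProteinSet("a", ["a", "b"]), ProteinSet("b", ["c", "d"])
        )
        assert res.d_ab == pytest.approx(1.5)
        assert res.s_ab == pytest.approx(0.5)

    def test_self_separation_never_positive_on_random_sets(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            g = nx.gnp_random_graph(30, 0.15, seed=int(rng.integers(2**31)))
            comp = sorted(max(nx.connected_components(g), key=len))
            if len(comp) < 5:
                continue
            members = rng.choice(comp, size=4, replace=False)
            s = ProteinSet("s", members.tolist())
            assert separation_score(g, s, s).s_ab <= 0.0

    def test_empty_set_raises(self, path_graph4):
        with pytest.raises(ValueError):
            separation_score(path_graph4, ProteinSet("a", []), ProteinSet("b", ["a"]))


class TestProximityNull:
    def test_fixed_seed_bit_reproducible(self):
        g, dis, a, _, _ = gen_ppi_with_modules(NetworkConfig(n_nodes=120), seed=4)
        r1 = proximity_zscore(g, a, dis, n_permutations=50, seed=11)
        r2 = proximity_zscore(g, a, dis, n_permutations=50, seed=11)
        assert (r1.d, r1.mu, r1.sigma, r1.z) == (r2.d, r2.mu, r2.sigma, r2.z)
        r3 = proximity_zscore(g, a, dis, n_permutations=50, seed=12)
        assert r3.mu != r1.mu

    def test_hub_self_proximity_is_negative(self):
        g = nx.barabasi_albert_graph(50, 2, seed=1)
        hubs = [n for n, _ in sorted(g.degree, key=lambda kv: -kv[1])[:5]]
        s = ProteinSet("hubs", hubs)
        res = proximity_zscore(g, s, s, n_permutations=100, seed=1)
        assert res.d == 0.0
        if res.sigma > 0:
            assert res.z < 0

    def test_single_permutation_flagged(self):
        g = nx.barabasi_albert_graph(40, 2, seed=2)
        s = ProteinSet("s", [0, 1])
        with pytest.warns(UserWarning, match="sigma"):
            res = proximity_zscore(g, s, s, n_permutations=1, seed=3)
        assert res.flagged and math.isnan(res.z)

    def test_standard_error_shrinks_with_permutations(self):
        # empirical sd of mu over replicates should shrink ~1/sqrt(n)
        g = nx.barabasi_albert_graph(60, 2, seed=5)
        x = ProteinSet("x", [0, 5, 9])
        y = ProteinSet("y", [3, 7])
        mus_small = [
            proximity_zscore(g, x, y, n_permutations=25, seed=s).mu for s in range(20)
        ]
        mus_big = [
            proximity_zscore(g, x, y, n_permutations=100, seed=s + 500).mu
            for s in range(20)
        ]
        ratio = np.std(mus_small) / np.std(mus_big)
        assert 1.1 < ratio < 4.0  # expect ~2, generous sampling tolerance


class TestDegreeMatchedSampler:
    def test_samples_preserve_bin_composition(self):
        g = nx.barabasi_albert_graph(200, 3, seed=7)
        sampler = DegreeMatchedSampler(g)
        rng = np.random.default_rng(0)
        template = [0, 1, 50, 150]
        for _ in range(20):
            sample = sampler.sample_like(template, rng)
            assert len(sample) == len(template)
            want = sorted(sampler.node_bin[n] for n in template)
            got = sorted(sampler.node_bin[n] for n in sample)
            assert want == got

    def test_small_bins_are_widened(self):
        g = nx.star_graph(30)  # hub degree 30, alone in its raw bin
        sampler = DegreeMatchedSampler(g, min_bin_size=10)
        assert all(len(ns) >= 10 for ns in sampler.bin_nodes.values())


class TestExposure:
    def test_identical_drugs_never_complementary(self):
        g, dis, a, _, _ = gen_ppi_with_modules(NetworkConfig(n_nodes=150), seed=9)
        call = classify_exposure(g, dis, a, a, n_permutations=50, seed=9)
        assert call.s_ab <= 0
        assert call.category != "complementary"

    def test_planted_scenarios_recovered(self):
        for scenario in ("complementary", "overlapping", "single", "non"):
            g, dis, a, b, planted = gen_ppi_with_modules(
                NetworkConfig(), scenario=scenario, seed=5
            )
            call = classify_exposure(g, dis, a, b, n_permutations=100, seed=5)
            assert call.category == planted

    def test_drug_without_targets_raises(self):
        g, dis, a, _, _ = gen_ppi_with_modules(NetworkConfig(n_nodes=150), seed=2)
        with pytest.raises(ValueError, match="no target proteins"):
            classify_exposure(g, dis, a, ProteinSet("empty", []))


class TestTissueFilter:
    def test_all_expressed_unchanged(self, path_graph4):
        expr = {n: 5.0 for n in path_graph4}
        out = tissue_filter(path_graph4, expr)
        assert set(out.edges()) == set(path_graph4.edges())

    def test_boundary_tpm_excluded_strictly(self, path_graph4):
        expr = {n: 1.0 for n in path_graph4}
        with pytest.raises(ValueError, match="removes every node"):
            tissue_filter(path_graph4, expr, threshold=1.0)

    def test_induced_subgraph_matches_direct_enumeration(self):
        rng = np.random.default_rng(77)
        g = nx.gnp_random_graph(10, 0.4, seed=77)
        expr = {n: float(rng.uniform(0, 3)) for n in g}
        out = tissue_filter(g, expr, threshold=1.0)
        keep = {n for n in g if expr[n] > 1.0}
        expected_edges = {(u, v) for u, v in g.edges() if u in keep and v in keep}
        assert out.number_of_edges() == len(expected_edges)
        assert out.graph["n_edges_before"] == g.number_of_edges()

    def test_missing_nodes_treated_as_unexpressed(self, path_graph4):
        out = tissue_filter(path_graph4, {"a": 5.0, "b": 5.0}, threshold=1.0)
        assert set(out.nodes()) == {"a", "b"}
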