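"""Dense module search: weight transform, greedy growth, permutation null."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from modbridge import (
    ModuleRecord,
    SearchConfig,
    dense_module_search,
    grow_module,
    module_score,
    permute_and_normalize,
    pvals_to_weights,
    select_top_modules,
)


def _weights_frame(p):
    return pd.DataFrame({"p_value": p}, index=[f"g{i}" for i in range(len(p))])


class TestWeights:
    def test_p_half_maps_to_zero(self):
        w = pvals_to_weights(_weights_frame([0.5]))
        assert w["g0"] == pytest.approx(0.0, abs=1e-12)

    def test_p_005_maps_to_1_6449(self):
        w = pvals_to_weights(_weights_frame([0.05]))
        assert w["g0"] == pytest.approx(1.6449, abs=1e-4)

    def test_p_one_clipped(self):
        # p=1 clipped to 1-1e-16; z = Phi^-1(1e-16) ~ -8.2221
        w = pvals_to_weights(_weights_frame([1.0]))
        assert w["g0"] == pytest.approx(-8.2221, abs=1e-3)

    def test_monotone_decreasing_in_p(self):
        w = pvals_to_weights(_weights_frame([0.001, 0.01, 0.5, 0.99]))
        z = [w[f"g{i}"] for i in range(4)]
        assert z == sorted(z, reverse=True)

    def test_missing_p_excluded_and_empty_rejected(self):
        w = pvals_to_weights(_weights_frame([0.1, np.nan]))
        assert set(w) == {"g0"}
        with pytest.raises(ValueError, match="empty"):
            pvals_to_weights(_weights_frame([]))


class TestModuleScore:
    def test_single_node(self):
        assert module_score(["a"], {"a": 2.0}) == pytest.approx(2.0)

    def test_two_nodes(self):
        assert module_score(["a", "b"], {"a": 3.0, "b": 1.0}) == pytest.approx(
            4 / math.sqrt(2), abs=1e-6)

    def test_equal_weights_closed_form(self):
        for k in (1, 3, 9):
            members = [f"m{i}" for i in range(k)]
            w = {m: 1.7 for m in members}
            assert module_score(members, w) == pytest.approx(1.7 * math.sqrt(k))

    def test_unweighted_member_rejected(self):
        with pytest.raises(ValueError, match="without weight"):
            module_score(["a", "b"], {"a": 1.0})


class TestGrowModule:
    def test_path_example_rejects_expansion(self):
        # A-B-C, z={A:2,B:0.5,C:3}: from A, adding B gives 2.5/sqrt(2)=1.77
        # which fails 2*1.1, so the module stays {A}.
        g = nx.path_graph(["A", "B", "C"])
        w = {"A": 2.0, "B": 0.5, "C": 3.0}
        rec = grow_module("A", g, w, SearchConfig(r=0.1, d=1))
        assert rec.members == frozenset({"A"})
        assert rec.raw_score == pytest.approx(2.0)

    def test_star_example_absorbs_all_leaves(self):
        # center z=1, three leaves z=3: scores 1 -> 2.8284 -> 4.0415 -> 5.0
        g = nx.star_graph(["c", "l1", "l2", "l3"])
        w = {"c": 1.0, "l1": 3.0, "l2": 3.0, "l3": 3.0}
        rec, trace = grow_module("c", g, w, SearchConfig(r=0.1, d=1), return_trace=True)
        assert rec.members == frozenset({"c", "l1", "l2", "l3"})
        assert rec.raw_score == pytest.approx(5.0, abs=1e-6)
        np.testing.assert_allclose(
            [s for _, s in trace], [1.0, 4 / math.sqrt(2), 7 / math.sqrt(3), 5.0],
            atol=1e-6)

    def test_negative_neighbors_leave_seed_alone(self):
        g = nx.star_graph(["c", "l1", "l2"])
        w = {"c": 2.0, "l1": -5.0, "l2": -5.0}
        rec = grow_module("c", g, w)
        assert rec.members == frozenset({"c"})

    def test_every_step_satisfies_improvement_rule(self, rng):
        g = nx.erdos_renyi_graph(30, 0.15, seed=5)
        g = nx.relabel_nodes(g, {i: f"g{i:02d}" for i in range(30)})
        w = {n: float(rng.normal()) for n in g}
        cfg = SearchConfig(r=0.1, d=1)
        for seed_gene in list(g)[:10]:
            rec, trace = grow_module(seed_gene, g, w, cfg, return_trace=True)
            for (_, prev), (_, nxt) in zip(trace, trace[1:]):
                assert nxt > prev * 1.1
            assert rec.raw_score == pytest.approx(trace[-1][1])

    def test_modules_are_connected_subgraphs(self, rng):
        g = nx.erdos_renyi_graph(40, 0.1, seed=9)
        g = nx.relabel_nodes(g, {i: f"g{i:02d}" for i in range(40)})
        w = {n: float(rng.normal(1, 1)) for n in g}
        for seed_gene in list(g):
            rec = grow_module(seed_gene, g, w, SearchConfig(d=2))
            assert nx.is_connected(g.subgraph(rec.members))


def naive_grow(seed, graph, weights, r, d):
    """Independent brute-force re-implementation of the expansion rule:
    exhaustive candidate scan each step, shortest linker paths enumerated
    via nx.all_shortest_paths and chosen lexicographically."""
    graph = graph.subgraph([n for n in graph if n in weights])
    members = {seed}
    score = sum(weights[m] for m in members) / math.sqrt(len(members))
    while True:
        additions = {}
        for node in graph:
            if node in members:
                continue
            dists = [nx.shortest_path_length(graph, node, m)
                     for m in members if nx.has_path(graph, node, m)]
            if not dists or min(dists) > d:
                continue
            dmin = min(dists)
            paths = []
            for m in members:
                if nx.has_path(graph, node, m):
                    for p in nx.all_shortest_paths(graph, node, m):
                        if len(p) - 1 == dmin:
                            paths.append(p[:-1])  # drop the member endpoint
            additions[node] = min(paths)
        best, best_score = None, -math.inf
        for c in sorted(additions):
            trial = members | set(additions[c])
            s = sum(weights[m] for m in trial) / math.sqrt(len(trial))
            if s > best_score:
                best, best_score = c, s
        if best is not None and best_score > score * (1 + r):
            members |= set(additions[best])
            score = best_score
        else:
            return members, score


@pytest.mark.parametrize("d", [1, 2])
def test_grow_matches_naive_oracle(d):
    """Greedy growth equals the brute-force candidate-scan oracle on
    random graphs (<=25 nodes) over many weight draws."""
    rng = np.random.default_rng(99 + d)
    for trial in range(25):
        n = int(rng.integers(5, 26))
        g = nx.gnp_random_graph(n, 0.2, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {i: f"g{i:02d}" for i in range(n)})
        w = {node: float(rng.normal()) for node in g}
        seed_gene = sorted(g)[int(rng.integers(n))]
        rec = grow_module(seed_gene, g, w, SearchConfig(r=0.1, d=d))
        members, score = naive_grow(seed_gene, g, w, 0.1, d)
        assert rec.members == frozenset(members)
        assert rec.raw_score == pytest.approx(score, abs=1e-10)


class TestPermutationNull:
    def _modules(self, weights, sizes):
        genes = sorted(weights)
        mods = []
        for i, k in enumerate(sizes):
            members = genes[i:i + k]
            mods.append(ModuleRecord(f"m{i}", members[0], frozenset(members),
                                     module_score(members, weights)))
        return mods

    def test_score_above_all_nulls_gets_boundary_p(self, rng):
        """Add-one estimator: p = 1/(n_perm+1) when no null draw reaches Z_m."""
        from modbridge.module_search import NullDistribution
        null = NullDistribution({3: rng.normal(size=1000)})
        assert null.empirical_p(50.0, 3) == pytest.approx(1 / 1001)
        # and within-module draws keep p strictly positive
        assert null.empirical_p(-50.0, 3) == 1.0

    def test_degenerate_equal_weights(self, caplog):
        weights = {f"g{i}": 2.0 for i in range(30)}
        mod = ModuleRecord("m", "g0", frozenset({"g0", "g1"}),
                           module_score(["g0", "g1"], weights))
        with caplog.at_level("WARNING"):
            out, _ = permute_and_normalize([mod], weights, SearchConfig(n_perm=100))
        assert out[0].normalized_score == 0.0

    def test_null_p_uniform_under_exchangeable_weights(self):
        """Random size-k modules under exchangeable weights get uniform
        empirical p (KS < 0.1 over 200 modules)."""
        rng = np.random.default_rng(21)
        weights = {f"g{i:03d}": float(rng.normal()) for i in range(300)}
        genes = sorted(weights)
        mods = []
        for i in range(200):
            members = rng.choice(genes, size=8, replace=False)
            mods.append(ModuleRecord(f"m{i}", members[0], frozenset(members),
                                     module_score(members, weights)))
        out, _ = permute_and_normalize(
            mods, weights, SearchConfig(n_perm=1000, seed=3))
        ks = stats.kstest([m.perm_p for m in out], "uniform").statistic
        assert ks < 0.1


class TestSelectTop:
    def _mods(self, n, rng):
        mods = []
        for i in range(n):
            mods.append(ModuleRecord(
                f"m{i:03d}", f"g{i}", frozenset({f"g{i}", f"h{i}"}),
                raw_score=1.0, normalized_score=float(rng.normal()),
                perm_p=float(rng.uniform(0.001, 0.04))))
        return mods

    def test_top_fraction_counting(self, rng):
        mods = self._mods(100, rng)
        kept = select_top_modules(mods, SearchConfig(top_fraction=0.01))
        assert len(kept) <= 1

    def test_duplicate_member_sets_deduplicated(self):
        shared = frozenset({"a", "b"})
        m1 = ModuleRecord("m1", "a", shared, 1.0, 2.0, 0.01)
        m2 = ModuleRecord("m2", "b", shared, 1.0, 3.0, 0.01)
        kept = select_top_modules([m1, m2], SearchConfig(top_fraction=1.0))
        assert len(kept) == 1
        assert kept[0].normalized_score == 3.0

    def test_invariant_to_input_order(self, rng):
        mods = self._mods(50, rng)
        a = select_top_modules(mods, SearchConfig(top_fraction=0.1))
        b = select_top_modules(mods[::-1], SearchConfig(top_fraction=0.1))
        assert [m.module_id for m in a] == [m.module_id for m in b]

    def test_insignificant_modules_filtered(self):
        m = ModuleRecord("m1", "a", frozenset({"a"}), 1.0, 5.0, perm_p=0.5)
        assert select_top_modules([m], SearchConfig(top_fraction=1.0)) == []


def test_unweighted_network_genes_removed(rng):
    g = nx.path_graph(["a", "b", "c", "d"])
    w = {"a": 3.0, "b": 2.0, "c": 1.0}  # d unweighted
    mods, _ = permute_and_normalize(
        [grow_module("a", g, w)], w, SearchConfig(n_perm=100))
    modules, _ = dense_module_search(g, w, SearchConfig(n_perm=100, top_fraction=1.0),
                                     select=False)
    assert all("d" not in m.members for m in modules)


def test_search_config_validation():
    with pytest.raises(ValueError):
        SearchConfig(r=0.0)
    with pytest.raises(ValueError):
        SearchConfig(d=0)
    with pytest.raises(ValueError):
        SearchConfig(n_perm=50)
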