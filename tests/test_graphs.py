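"""Graph metrics: worked examples, brute-force oracle equivalence, sweeps."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netprog.exceptions import DomainError, UndefinedMetricError
from netprog.graphs import (
    DEFAULT_GRID,
    assortativity,
    characteristic_path_length,
    clustering_coefficient,
    compare_metrics,
    degree_centrality,
    metric_sweep,
    small_worldness,
    threshold_graph,
)

# ---------------------------------------------------------------- oracles


def oracle_degree_centrality(g):
    return g.number_of_edges() / g.number_of_nodes() if g.number_of_nodes() else 0.0


def oracle_clustering(g):
    """Onnela geometric-mean weighted clustering, written out edge by edge."""
    if g.number_of_edges() == 0:
        return 0.0
    wmax = max(d["weight"] for _, _, d in g.edges(data=True))
    total = 0.0
    for u in g.nodes():
        nbrs = list(g[u])
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for v, w in itertools.combinations(nbrs, 2):
            if g.has_edge(v, w):
                s += (
                    (g[u][v]["weight"] / wmax)
                    * (g[u][w]["weight"] / wmax)
                    * (g[v][w]["weight"] / wmax)
                ) ** (1.0 / 3.0)
        total += 2.0 * s / (k * (k - 1))
    return total / g.number_of_nodes()


def oracle_path_length(g):
    """Floyd-Warshall on lengths 1/w; mean over connected pairs."""
    nodes = list(g.nodes())
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v, data in g.edges(data=True):
        d[idx[u], idx[v]] = d[idx[v], idx[u]] = 1.0 / data["weight"]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    iu = np.triu_indices(n, 1)
    vals = d[iu]
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return None
    return float(finite.mean())


def oracle_assortativity(g):
    xs, ys = [], []
    deg = dict(g.degree())
    for u, v in g.edges():
        xs += [deg[u], deg[v]]
        ys += [deg[v], deg[u]]
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    if sxx == 0 or syy == 0:
        return None
    return sxy / math.sqrt(sxx * syy)


def random_weighted_graph(rng, n):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                g.add_edge(i, j, weight=float(rng.uniform(0.1, 1.0)))
    return g


class TestOracleEquivalence:
    def test_all_metrics_match_brute_force_on_small_graphs(self):
        """Exhaustive brute-force implementations agree to 1e-10 on 100
        random weighted graphs of <= 6 nodes."""
        rng = np.random.default_rng(12345)
        checked = {"dc": 0, "cc": 0, "pl": 0, "as": 0}
        for _ in range(100):
            n = int(rng.integers(2, 7))
            g = random_weighted_graph(rng, n)
            assert degree_centrality(g) == pytest.approx(
                oracle_degree_centrality(g), abs=1e-10
            )
            checked["dc"] += 1
            if g.number_of_nodes():
                assert clustering_coefficient(g) == pytest.approx(
                    oracle_clustering(g), abs=1e-10
                )
                checked["cc"] += 1
            opl = oracle_path_length(g)
            if opl is not None:
                assert characteristic_path_length(g) == pytest.approx(opl, abs=1e-10)
                checked["pl"] += 1
            oas = oracle_assortativity(g) if g.number_of_edges() >= 2 else None
            if oas is not None:
                assert assortativity(g) == pytest.approx(oas, abs=1e-10)
                checked["as"] += 1
            else:
                with pytest.raises(UndefinedMetricError):
                    assortativity(g)
        assert min(checked.values()) > 20  # every metric exercised many times

    def test_small_worldness_identity_with_its_null(self):
        """S equals (C/C_null)/(L/L_null) recomputed from the returned null
        ensemble means (C and L verified against oracles above)."""
        rng = np.random.default_rng(7)
        g = random_weighted_graph(rng, 6)
        while g.number_of_edges() < 4:
            g = random_weighted_graph(rng, 6)
        s, info = small_worldness(g, n_null=20, seed=3, return_null=True)
        expected = (info["C"] / info["C_null_mean"]) / (info["L"] / info["L_null_mean"])
        assert s == pytest.approx(expected, abs=1e-12)


class TestWorkedExamples:
    def test_degree_centrality_examples(self):
        tri = nx.Graph([(0, 1), (1, 2), (0, 2)])
        path4 = nx.path_graph(4)
        empty = nx.Graph()
        assert degree_centrality(tri) == 1.0
        assert degree_centrality(path4) == 0.75
        assert degree_centrality(empty) == 0.0
        assert degree_centrality(tri, convention="mean_degree") == 2.0

    def test_clustering_examples(self):
        tri = nx.Graph()
        tri.add_weighted_edges_from([(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)])
        star = nx.star_graph(4)
        for u, v in star.edges():
            star[u][v]["weight"] = 1.0
        assert clustering_coefficient(tri) == pytest.approx(1.0)
        assert clustering_coefficient(star) == 0.0

    def test_path_length_examples(self):
        p = nx.Graph()
        p.add_weighted_edges_from([(0, 1, 1.0), (1, 2, 1.0)])
        assert characteristic_path_length(p) == pytest.approx(4.0 / 3.0)
        k = nx.complete_graph(5)
        for u, v in k.edges():
            k[u][v]["weight"] = 1.0
        assert characteristic_path_length(k) == pytest.approx(1.0)
        w = nx.Graph()
        w.add_weighted_edges_from([(0, 1, 0.5), (1, 2, 0.5)])
        assert characteristic_path_length(w) == pytest.approx(8.0 / 3.0)

    def test_disconnected_pairs_reported(self):
        g = nx.Graph()
        g.add_weighted_edges_from([(0, 1, 1.0)])
        g.add_node(2)
        L, n_excl = characteristic_path_length(g, with_info=True)
        assert L == 1.0 and n_excl == 2

    def test_assortativity_degenerate_cases(self):
        with pytest.raises(UndefinedMetricError):
            assortativity(nx.complete_graph(4))
        assert assortativity(nx.complete_graph(4), degenerate="neg_one") == -1.0
        # a star is not degenerate: both-orientation Pearson gives exactly -1
        star = nx.star_graph(3)
        assert assortativity(star) == pytest.approx(-1.0)
        assert assortativity(star) == pytest.approx(
            nx.degree_assortativity_coefficient(star)
        )


class TestThresholdGraph:
    def _adj(self, m, labels):
        return pd.DataFrame(m, index=labels, columns=labels)

    def test_complete_and_empty(self):
        labels = list("abcd")
        hi = self._adj(np.full((4, 4), 0.9), labels)
        lo = self._adj(np.full((4, 4), 0.2), labels)
        assert threshold_graph(hi, 0.5).density == 1.0
        tg = threshold_graph(lo, 0.5)
        assert tg.density == 0.0 and len(tg.isolated) == 4

    def test_counting_density(self):
        labels = list("abcd")
        m = np.zeros((4, 4))
        for i, j, r in [(0, 1, 0.8), (1, 2, 0.7), (2, 3, 0.9)]:
            m[i, j] = m[j, i] = r
        tg = threshold_graph(self._adj(m, labels), 0.5)
        assert tg.density == pytest.approx(0.5)

    def test_signed_mode_drops_negative_correlations(self):
        labels = list("abc")
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = -0.9
        m[1, 2] = m[2, 1] = 0.9
        assert threshold_graph(self._adj(m, labels), 0.5).graph.number_of_edges() == 1
        assert (
            threshold_graph(self._adj(m, labels), 0.5, mode="abs").graph.number_of_edges()
            == 2
        )

    def test_monotone_in_threshold(self, rng):
        n = 12
        a = rng.uniform(-1, 1, (n, n))
        a = (a + a.T) / 2
        labels = [f"R{i}" for i in range(n)]
        dens, dc = [], []
        for thr in DEFAULT_GRID:
            tg = threshold_graph(self._adj(a, labels), thr)
            dens.append(tg.density)
            dc.append(degree_centrality(tg))
        assert all(x >= y for x, y in zip(dens, dens[1:]))
        assert all(x >= y for x, y in zip(dc, dc[1:]))


class TestSmallWorldness:
    def test_watts_strogatz_is_small_world(self):
        g = nx.watts_strogatz_graph(50, 6, 0.05, seed=1)
        for u, v in g.edges():
            g[u][v]["weight"] = 1.0
        assert small_worldness(g, n_null=30, seed=2) > 1.5

    def test_random_graph_close_to_its_null(self):
        g = nx.erdos_renyi_graph(50, 0.3, seed=3)
        for u, v in g.edges():
            g[u][v]["weight"] = 1.0
        assert 0.8 <= small_worldness(g, n_null=30, seed=4) <= 1.2

    def test_deterministic_given_seed(self):
        g = nx.erdos_renyi_graph(20, 0.3, seed=5)
        for u, v in g.edges():
            g[u][v]["weight"] = 1.0
        assert small_worldness(g, n_null=10, seed=9) == small_worldness(
            g, n_null=10, seed=9
        )


class TestSweepAndCompare:
    def _iterates(self, rng, b, n, shift=0.0):
        out = np.empty((b, n, n))
        for i in range(b):
            x = rng.normal(0, 1, (40, n)) + shift * rng.normal(0, 1, (40, 1))
            out[i] = np.corrcoef(x, rowvar=False)
        return out

    def test_sweep_bookkeeping(self, rng):
        it = self._iterates(rng, 3, 8, shift=0.8)
        ms = metric_sweep(it, grid=(0.3, 0.4, 0.5), n_null=5, seed=0,
                          metrics=("degree_centrality", "clustering"))
        assert set(ms.values["threshold"]) == {0.3, 0.4, 0.5}
        assert len(ms.values) == 3 * 3 * 2

    def test_identical_iterates_zero_bootstrap_variance(self, rng):
        one = self._iterates(rng, 1, 6, shift=0.8)
        it = np.repeat(one, 3, axis=0)
        ms = metric_sweep(it, grid=(0.3,), n_null=3, seed=0,
                          metrics=("degree_centrality",))
        assert ms.summarize()["sd"].iloc[0] == 0.0

    def test_identical_sets_compare_to_p_one(self, rng):
        it = self._iterates(rng, 4, 6, shift=0.8)
        ms = metric_sweep(it, grid=(0.3, 0.4), n_null=3, seed=0,
                          metrics=("degree_centrality", "clustering"))
        out = compare_metrics(ms, ms)
        assert (out["p_corr"] == 1.0).all()

    def test_separation_detected_and_bonferroni_arithmetic(self, rng):
        lo = self._iterates(rng, 6, 6, shift=0.0)
        hi = self._iterates(rng, 6, 6, shift=1.0)
        a = metric_sweep(lo, grid=(0.3, 0.4), n_null=3, seed=0,
                         metrics=("degree_centrality",))
        b = metric_sweep(hi, grid=(0.3, 0.4), n_null=3, seed=0,
                         metrics=("degree_centrality",))
        out = compare_metrics(a, b)
        assert (out["p_corr"] < 0.001).any()
        finite = out[np.isfinite(out["p_raw"])]
        assert np.allclose(
            finite["p_corr"], np.minimum(1.0, finite["p_raw"] * finite["bonferroni_m"])
        )

    def test_grid_mismatch_rejected(self, rng):
        it = self._iterates(rng, 3, 6, shift=0.8)
        a = metric_sweep(it, grid=(0.3,), n_null=3, metrics=("degree_centrality",))
        b = metric_sweep(it, grid=(0.4,), n_null=3, metrics=("degree_centrality",))
        with pytest.raises(DomainError):
            compare_metrics(a, b)

    def test_planted_clustering_difference_consistent_across_thresholds(self, rng):
        """A group with genuinely denser, more clustered graphs exceeds the
        other at every threshold in the sweep."""
        lo = self._iterates(rng, 5, 10, shift=0.35)
        hi = self._iterates(rng, 5, 10, shift=1.2)
        a = metric_sweep(lo, grid=(0.3, 0.4, 0.5), n_null=3, seed=1,
                         metrics=("clustering",))
        b = metric_sweep(hi, grid=(0.3, 0.4, 0.5), n_null=3, seed=1,
                         metrics=("clustering",))
        sa = a.summarize().set_index("threshold")["mean"]
        sb = b.summarize().set_index("threshold")["mean"]
        assert (sb > sa).all()
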