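"""Weighted graph metrics on thresholded correlation networks.

Five metrics characterise network architecture on weighted undirected graphs
built by retaining correlations at or above a threshold:

* degree centrality — edge count divided by node count (overall connectivity
  of the network space; a ``mean_degree`` convention, 2E/N, is available),
* clustering coefficient — mean Onnela geometric-mean-of-triangles weighted
  clustering (segregation),
* characteristic path length — mean shortest-path distance over connected
  node pairs with edge length 1/weight (integration),
* small-worldness — clustering/path-length ratio normalised by the means of
  a degree-preserving rewired null ensemble,
* assortativity — Pearson correlation of endpoint degrees over edges.

Metrics are swept over a threshold grid on bootstrap adjacency iterates and
compared between groups with a linear model plus Bonferroni-corrected
per-threshold contrasts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import AdjacencyMatrix
from .exceptions import DomainError, UndefinedMetricError

__all__ = [
    "ThresholdedGraph",
    "GraphMetricSet",
    "threshold_graph",
    "degree_centrality",
    "clustering_coefficient",
    "characteristic_path_length",
    "small_worldness",
    "assortativity",
    "metric_sweep",
    "compare_metrics",
    "DEFAULT_GRID",
    "METRICS",
]

DEFAULT_GRID = tuple(float(t) for t in np.round(np.arange(0.30, 0.651 + 1e-9, 0.05), 2))
METRICS = (
    "degree_centrality",
    "clustering",
    "path_length",
    "small_worldness",
    "assortativity",
)


@dataclass
class ThresholdedGraph:
    """Weighted undirected graph retaining correlations >= a threshold."""

    graph: nx.Graph
    threshold: float
    density: float
    isolated: list[str]
    mode: str = "signed"


def threshold_graph(adj, r_thresh: float, mode: str = "signed") -> ThresholdedGraph:
    """Retain edges with r >= ``r_thresh`` (or |r| >= in ``"abs"`` mode).

    Edge weights are the retained correlation values (absolute values in
    ``"abs"`` mode) so weights lie in (0, 1].  Empty graphs are allowed; the
    density and any isolated nodes are reported on the result.
    """
    if not 0 < r_thresh < 1:
        raise DomainError("r_thresh must be in (0, 1)")
    if isinstance(adj, AdjacencyMatrix):
        mat = adj.r
    else:
        mat = adj
    labels = list(mat.columns)
    arr = mat.to_numpy(dtype=float)
    g = nx.Graph()
    g.add_nodes_from(labels)
    n = len(labels)
    kept = 0
    for i in range(n):
        for j in range(i + 1, n):
            r = arr[i, j]
            if not np.isfinite(r):
                continue
            val = abs(r) if mode == "abs" else r
            if val >= r_thresh:
                g.add_edge(labels[i], labels[j], weight=abs(r) if mode == "abs" else r)
                kept += 1
    possible = n * (n - 1) // 2
    density = kept / possible if possible else 0.0
    isolated = [v for v in g.nodes if g.degree(v) == 0]
    return ThresholdedGraph(graph=g, threshold=r_thresh, density=density, isolated=isolated, mode=mode)


def _as_graph(g) -> nx.Graph:
    return g.graph if isinstance(g, ThresholdedGraph) else g


def _weight_matrix(graph: nx.Graph) -> np.ndarray:
    return nx.to_numpy_array(graph, weight="weight")


def degree_centrality(g, convention: str = "edges_per_node") -> float:
    """Edge count divided by node count (``"mean_degree"`` gives 2E/N)."""
    graph = _as_graph(g)
    n = graph.number_of_nodes()
    if n == 0:
        return 0.0
    e = graph.number_of_edges()
    if convention == "edges_per_node":
        return e / n
    if convention == "mean_degree":
        return 2.0 * e / n
    raise DomainError(f"unknown convention {convention!r}")


def clustering_coefficient(g) -> float:
    """Mean weighted clustering (Onnela geometric-mean triangle form).

    Weights are normalised by the maximum edge weight in the graph; nodes
    with degree < 2 contribute 0 to the mean.
    """
    graph = _as_graph(g)
    if graph.number_of_nodes() == 0:
        raise UndefinedMetricError("clustering undefined on the empty graph")
    if graph.number_of_edges() == 0:
        return 0.0
    W = _weight_matrix(graph)
    Wn = np.cbrt(W / W.max())
    tri = np.diagonal(Wn @ Wn @ Wn)
    k = (W > 0).sum(axis=1)
    denom = k * (k - 1)
    c = np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)
    return float(c.mean())


def characteristic_path_length(g, with_info: bool = False):
    """Mean shortest-path distance over connected node pairs (length = 1/w).

    Disconnected pairs are excluded; their count is available via
    ``with_info=True``.  A graph with no connected pair at all has no defined
    path length and raises :class:`UndefinedMetricError`.
    """
    from scipy.sparse import csr_array
    from scipy.sparse.csgraph import dijkstra

    graph = _as_graph(g)
    n = graph.number_of_nodes()
    if n == 0:
        raise UndefinedMetricError("path length undefined on the empty graph")
    W = _weight_matrix(graph)
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), 0.0)
    dist = dijkstra(csr_array(lengths), directed=False)
    iu = np.triu_indices(n, k=1)
    d = dist[iu]
    finite = np.isfinite(d)
    n_connected = int(finite.sum())
    n_excluded = d.size - n_connected
    if n_connected == 0:
        raise UndefinedMetricError("no connected node pair: path length undefined")
    L = float(d[finite].mean())
    return (L, n_excluded) if with_info else L


def assortativity(g, degenerate: str = "error") -> float:
    """Degree assortativity: Pearson correlation of endpoint degrees.

    Computed over the edge list with both orientations (a star therefore
    evaluates to exactly -1).  Degree-regular graphs (zero endpoint-degree
    variance, e.g. complete graphs or cycles) make the correlation a 0/0;
    ``degenerate="error"`` raises while ``degenerate="neg_one"`` adopts the
    convention of returning -1 for that case.
    """
    graph = _as_graph(g)
    if graph.number_of_edges() < 2:
        raise UndefinedMetricError("assortativity requires >= 2 edges")
    deg = dict(graph.degree())
    x, y = [], []
    for u, v in graph.edges():
        x.extend((deg[u], deg[v]))
        y.extend((deg[v], deg[u]))
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        if degenerate == "neg_one":
            return -1.0
        raise UndefinedMetricError("zero degree variance: assortativity undefined")
    return float(np.corrcoef(x, y)[0, 1])


def _shuffled_weight_null(graph: nx.Graph, rng: np.random.Generator, seed: int) -> nx.Graph:
    """Degree-preserving rewiring with the weight multiset shuffled on top."""
    h = nx.Graph()
    h.add_nodes_from(graph.nodes())
    h.add_edges_from(graph.edges())
    e = h.number_of_edges()
    if e >= 2:
        try:
            nx.double_edge_swap(h, nswap=2 * e, max_tries=50 * e, seed=seed)
        except nx.NetworkXException:
            pass  # too few swappable edges; keep whatever rewiring was achieved
    weights = [d.get("weight", 1.0) for _, _, d in graph.edges(data=True)]
    rng.shuffle(weights)
    for (u, v), w in zip(h.edges(), weights):
        h[u][v]["weight"] = w
    return h


def small_worldness(
    g,
    n_null: int = 100,
    seed: int | None = None,
    return_null: bool = False,
):
    """S = (C/C_null) / (L/L_null) against a rewired null ensemble.

    C and L are computed on the giant component.  The null ensemble consists
    of ``n_null`` degree-preserving rewirings with the original weight
    multiset shuffled onto the rewired topology; C_null and L_null are the
    ensemble means.  Raises :class:`UndefinedMetricError` when the null
    clustering mean is zero or no path length is defined.
    """
    graph = _as_graph(g)
    if graph.number_of_edges() == 0:
        raise UndefinedMetricError("small-worldness undefined without edges")
    giant = graph.subgraph(max(nx.connected_components(graph), key=len)).copy()
    C = clustering_coefficient(giant)
    L = characteristic_path_length(giant)
    rng = np.random.default_rng(seed)
    c_null, l_null = [], []
    for k in range(n_null):
        h = _shuffled_weight_null(giant, rng, seed=int(rng.integers(2**31)))
        hg = h.subgraph(max(nx.connected_components(h), key=len))
        c_null.append(clustering_coefficient(hg))
        try:
            l_null.append(characteristic_path_length(hg))
        except UndefinedMetricError:
            continue
    c_bar = float(np.mean(c_null))
    if c_bar == 0 or not l_null:
        raise UndefinedMetricError("null ensemble has zero clustering or no path length")
    l_bar = float(np.mean(l_null))
    s = (C / c_bar) / (L / l_bar)
    if return_null:
        return s, {
            "C": C,
            "L": L,
            "C_null_mean": c_bar,
            "L_null_mean": l_bar,
            "C_null_sd": float(np.std(c_null, ddof=1)) if len(c_null) > 1 else 0.0,
            "L_null_sd": float(np.std(l_null, ddof=1)) if len(l_null) > 1 else 0.0,
        }
    return s


@dataclass
class GraphMetricSet:
    """Long-format bootstrap metric distributions over a threshold grid.

    ``values`` columns: group, timepoint, threshold, metric, iterate, value.
    """

    values: pd.DataFrame
    grid: tuple[float, ...]
    group: str = ""
    timepoint: float = 0.0

    def summarize(self) -> pd.DataFrame:
        g = (
            self.values.dropna(subset=["value"])
            .groupby(["group", "timepoint", "threshold", "metric"])["value"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )
        return g.rename(columns={"std": "sd", "count": "n_boot"})


def metric_sweep(
    iterates,
    region_labels: list[str] | None = None,
    grid=DEFAULT_GRID,
    group: str = "",
    timepoint: float = 0.0,
    mode: str = "signed",
    n_null: int = 20,
    metrics=METRICS,
    seed: int | None = None,
) -> GraphMetricSet:
    """Compute every metric per bootstrap iterate per threshold.

    ``iterates`` is a B x R x R array (or an :class:`AdjacencyMatrix` with
    stored iterates).  Metrics undefined on a particular thresholded iterate
    (e.g. assortativity of a degree-regular graph) are recorded as NaN so the
    distributions stay aligned.
    """
    if isinstance(iterates, AdjacencyMatrix):
        if iterates.iterates is None:
            raise DomainError("AdjacencyMatrix carries no bootstrap iterates")
        region_labels = iterates.region_labels
        group = group or iterates.group
        timepoint = iterates.timepoint
        iterates = iterates.iterates
    arr = np.asarray(iterates, dtype=float)
    if arr.ndim != 3 or arr.shape[0] < 2:
        raise DomainError("need >= 2 bootstrap iterates")
    grid = tuple(float(t) for t in grid)
    if any(not 0 < t < 1 for t in grid):
        raise DomainError("thresholds must lie in (0, 1)")
    if region_labels is None:
        region_labels = [f"n{i}" for i in range(arr.shape[1])]
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(arr.shape[0]):
        mat = pd.DataFrame(arr[b], index=region_labels, columns=region_labels)
        for thr in grid:
            tg = threshold_graph(mat, thr, mode=mode)
            vals = {}
            if "degree_centrality" in metrics:
                vals["degree_centrality"] = degree_centrality(tg)
            if "clustering" in metrics:
                try:
                    vals["clustering"] = clustering_coefficient(tg)
                except UndefinedMetricError:
                    vals["clustering"] = math.nan
            if "path_length" in metrics:
                try:
                    vals["path_length"] = characteristic_path_length(tg)
                except UndefinedMetricError:
                    vals["path_length"] = math.nan
            if "small_worldness" in metrics:
                try:
                    vals["small_worldness"] = small_worldness(
                        tg, n_null=n_null, seed=int(rng.integers(2**31))
                    )
                except UndefinedMetricError:
                    vals["small_worldness"] = math.nan
            if "assortativity" in metrics:
                try:
                    vals["assortativity"] = assortativity(tg)
                except UndefinedMetricError:
                    vals["assortativity"] = math.nan
            for metric, v in vals.items():
                rows.append((group, timepoint, thr, metric, b, v))
    values = pd.DataFrame(
        rows, columns=["group", "timepoint", "threshold", "metric", "iterate", "value"]
    )
    return GraphMetricSet(values=values, grid=grid, group=group, timepoint=timepoint)


def compare_metrics(
    set_a: GraphMetricSet,
    set_b: GraphMetricSet,
    bonferroni_family: int | None = None,
) -> pd.DataFrame:
    """Group comparison of bootstrap metric distributions across thresholds.

    For each metric a linear model ``value ~ group + threshold`` (threshold
    categorical) on the pooled bootstrap values gives an overall group-effect
    p; per-threshold two-sample contrasts follow, Bonferroni-corrected over
    the declared family (default: thresholds x metrics for this comparison).
    """
    if set_a.grid != set_b.grid:
        raise DomainError("threshold grids differ between metric sets")
    import statsmodels.formula.api as smf

    metrics = sorted(set(set_a.values["metric"]) & set(set_b.values["metric"]))
    m = bonferroni_family if bonferroni_family is not None else len(set_a.grid) * len(metrics)
    out = []
    for metric in metrics:
        a = set_a.values[set_a.values["metric"] == metric].dropna(subset=["value"])
        b = set_b.values[set_b.values["metric"] == metric].dropna(subset=["value"])
        pooled = pd.concat(
            [a.assign(grp="A"), b.assign(grp="B")], ignore_index=True
        )
        if pooled["value"].nunique() <= 1:
            overall_p = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = smf.ols("value ~ C(grp) + C(threshold)", data=pooled).fit()
            overall_p = float(fit.pvalues.get("C(grp)[T.B]", 1.0))
        for thr in set_a.grid:
            va = a[a["threshold"] == thr]["value"].to_numpy()
            vb = b[b["threshold"] == thr]["value"].to_numpy()
            if len(va) < 2 or len(vb) < 2:
                t = p = math.nan
            elif np.array_equal(np.sort(va), np.sort(vb)) or (
                np.std(va, ddof=1) == 0 and np.std(vb, ddof=1) == 0
            ):
                t, p = (0.0, 1.0) if va.mean() == vb.mean() else (math.inf, 0.0)
            else:
                t, p = stats.ttest_ind(va, vb, equal_var=True)
                t, p = float(t), float(p)
            out.append(
                (
                    metric,
                    thr,
                    float(np.mean(va)) if len(va) else math.nan,
                    float(np.mean(vb)) if len(vb) else math.nan,
                    t,
                    p,
                    min(1.0, p * m) if np.isfinite(p) else p,
                    overall_p,
                    m,
                )
            )
    return pd.DataFrame(
        out,
        columns=[
            "metric",
            "threshold",
            "mean_a",
            "mean_b",
            "t",
            "p_raw",
            "p_corr",
            "p_group_overall",
            "bonferroni_m",
        ],
    )
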