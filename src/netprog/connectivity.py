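"""Gain and loss of metabolic connections between network nodes.

Group-level adjacency matrices are estimated as the entrywise median of
pairwise Pearson correlations over subject-level bootstrap resamples.  An
edge is *gained* in the case group when its correlation magnitude reaches the
edge threshold (|r| >= tau_r, default 0.6) in cases but not in controls and
the between-group difference exceeds the difference threshold (|dr| > tau_dr,
default 0.4, calibrated by label permutation on the healthy graph); *lost*
edges satisfy the mirrored predicate.  Detected changes are confirmed by
paired bootstrap re-detection, restricted to anatomically plausible pairs
(<= 2 hops along a pathway graph), and tallied by network category
(within-motor RR, bridging RC, within-cognitive CC).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, DomainError, LabelMismatchError
from .expression import NetworkPattern, RegionalProfileSet

__all__ = [
    "AdjacencyMatrix",
    "ConnectionChange",
    "PermutationNull",
    "bootstrap_adjacency",
    "permutation_dr_threshold",
    "detect_gain_loss",
    "confirm_changes",
    "filter_anatomical",
    "categorize_changes",
    "classify_nodes",
    "detect_connection_changes",
]

logger = logging.getLogger(__name__)


@dataclass
class AdjacencyMatrix:
    """Symmetric region x region correlation matrix with provenance.

    ``r`` is a square DataFrame (diagonal masked to NaN).  ``iterates`` holds
    the per-bootstrap correlation matrices (B x R x R) when requested.
    """

    r: pd.DataFrame
    group: str = ""
    timepoint: float = 0.0
    n_bootstrap: int = 0
    seed: int | None = None
    iterates: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = self.r.to_numpy(dtype=float)
        if arr.shape[0] != arr.shape[1]:
            raise DomainError("adjacency matrix must be square")
        off = arr[~np.eye(arr.shape[0], dtype=bool)]
        finite = off[np.isfinite(off)]
        if finite.size and (np.abs(finite) > 1 + 1e-9).any():
            raise DomainError("correlations must lie in [-1, 1]")

    @property
    def region_labels(self) -> list[str]:
        return list(self.r.columns)


@dataclass
class ConnectionChange:
    """One gained or lost edge with its correlation evidence."""

    region_a: str
    region_b: str
    status: str  # "gained" | "lost"
    r_case: float
    r_hc: float
    abs_dr: float
    category: str | None = None  # "RR" | "RC" | "CC"
    timepoint: float = 0.0
    anatomical_ok: bool | None = None
    confirmation_frac: float | None = None


@dataclass
class PermutationNull:
    """Label-permutation null distribution of |dr| and its derived cutoff."""

    n_permutations: int
    alpha: float
    null_abs_dr: np.ndarray
    threshold: float
    seed: int | None = None


def _corr(values: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.corrcoef(values, rowvar=False)


def bootstrap_adjacency(
    profiles: RegionalProfileSet,
    B: int = 100,
    seed: int | None = None,
    keep_iterates: bool = False,
) -> AdjacencyMatrix:
    """Median-of-bootstraps adjacency matrix for one group/timepoint.

    Subjects (rows) are resampled with replacement B times at the original
    sample size; entry (i, j) is the median Pearson correlation over the
    iterates.  An iterate in which a region has zero variance produces NaN
    for that region's entries and is excluded from the median (deterministic
    given the seed); an entry undefined in every iterate stays NaN.
    """
    if profiles.n_subjects < 5:
        raise DegenerateDataError("bootstrap_adjacency requires >= 5 subjects")
    if B < 1:
        raise DomainError("B must be >= 1")
    rng = np.random.default_rng(seed)
    vals = profiles.values.to_numpy(dtype=float)
    n = vals.shape[0]
    stack = np.empty((B, vals.shape[1], vals.shape[1]))
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        stack[b] = _corr(vals[idx])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(stack, axis=0)
    med = np.clip(med, -1.0, 1.0)
    np.fill_diagonal(med, np.nan)
    r = pd.DataFrame(med, index=profiles.region_labels, columns=profiles.region_labels)
    return AdjacencyMatrix(
        r=r,
        group=profiles.group,
        timepoint=profiles.timepoint,
        n_bootstrap=B,
        seed=seed,
        iterates=stack if keep_iterates else None,
    )


def permutation_dr_threshold(
    hc_profiles: RegionalProfileSet,
    P: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> PermutationNull:
    """Calibrate the |dr| cutoff by permuting region labels of the HC graph.

    Each permutation relabels the nodes of the observed healthy correlation
    matrix, pairing every edge with a pseudorandom one; the pooled |dr|
    between observed and permuted correlations forms the null, and the cutoff
    is its (1 - alpha) empirical quantile.
    """
    if P <= 0:
        raise DomainError("P must be positive")
    if P < 100:
        warnings.warn("P < 100 permutations: quantile estimate is unstable", stacklevel=2)
    if hc_profiles.n_subjects < 5:
        raise DegenerateDataError("permutation_dr_threshold requires >= 5 subjects")
    rng = np.random.default_rng(seed)
    c = _corr(hc_profiles.values.to_numpy(dtype=float))
    nr = c.shape[0]
    iu = np.triu_indices(nr, k=1)
    null = np.empty((P, iu[0].size))
    for p in range(P):
        perm = rng.permutation(nr)
        null[p] = np.abs(c[iu] - c[np.ix_(perm, perm)][iu])
    null = null[np.isfinite(null)]
    threshold = float(np.quantile(null, 1.0 - alpha))
    return PermutationNull(
        n_permutations=P, alpha=alpha, null_abs_dr=null, threshold=threshold, seed=seed
    )


def _dr(rc: np.ndarray, rh: np.ndarray, mode: str) -> np.ndarray:
    if mode == "signed":
        return np.abs(rc - rh)
    if mode == "magnitude":
        return np.abs(np.abs(rc) - np.abs(rh))
    raise DomainError(f"unknown dr mode {mode!r}")


def detect_gain_loss(
    adj_case: AdjacencyMatrix,
    adj_hc: AdjacencyMatrix,
    tau_r: float = 0.6,
    tau_dr: float = 0.4,
    dr_mode: str = "signed",
) -> list[ConnectionChange]:
    """Threshold logic for gained and lost edges.

    gained: |r_case| >= tau_r and |r_hc| < tau_r and |dr| > tau_dr
    lost:   |r_hc| >= tau_r and |r_case| < tau_r and |dr| > tau_dr

    The two predicates are mutually exclusive, so the gained and lost sets
    are disjoint by construction.
    """
    if not (0 < tau_r < 1 and 0 < tau_dr < 1):
        raise DomainError("thresholds must lie in (0, 1)")
    if adj_case.region_labels != adj_hc.region_labels:
        only_case = set(adj_case.region_labels) - set(adj_hc.region_labels)
        only_hc = set(adj_hc.region_labels) - set(adj_case.region_labels)
        raise LabelMismatchError(
            f"region sets differ (case-only: {sorted(only_case)[:5]}, "
            f"hc-only: {sorted(only_hc)[:5]})"
        )
    labels = adj_case.region_labels
    rc = adj_case.r.to_numpy(dtype=float)
    rh = adj_hc.r.to_numpy(dtype=float)
    dr = _dr(rc, rh, dr_mode)
    changes: list[ConnectionChange] = []
    iu = zip(*np.triu_indices(len(labels), k=1))
    for i, j in iu:
        if not (np.isfinite(rc[i, j]) and np.isfinite(rh[i, j])):
            continue
        gained = abs(rc[i, j]) >= tau_r and abs(rh[i, j]) < tau_r and dr[i, j] > tau_dr
        lost = abs(rh[i, j]) >= tau_r and abs(rc[i, j]) < tau_r and dr[i, j] > tau_dr
        if gained or lost:
            changes.append(
                ConnectionChange(
                    region_a=labels[i],
                    region_b=labels[j],
                    status="gained" if gained else "lost",
                    r_case=float(rc[i, j]),
                    r_hc=float(rh[i, j]),
                    abs_dr=float(dr[i, j]),
                    timepoint=adj_case.timepoint,
                )
            )
    return changes


def confirm_changes(
    changes: list[ConnectionChange],
    case_profiles: RegionalProfileSet,
    hc_profiles: RegionalProfileSet,
    tau_r: float = 0.6,
    tau_dr: float = 0.4,
    dr_mode: str = "signed",
    n_iter: int = 100,
    vote: float = 0.65,
    seed: int | None = None,
) -> list[ConnectionChange]:
    """Bootstrap confirmation: keep a change re-detected in > ``vote`` of
    ``n_iter`` paired subject resamples (both groups resampled jointly each
    iteration, full-sample correlations recomputed).  The default retention
    fraction (about two thirds) is stricter than a bare majority: at n ~ 17 a
    sample-level fluke that passed detection is reproduced by roughly half of
    the bootstrap replicates, so majority voting does not control the false
    discovery rate; two-thirds retention does while keeping recall."""
    if not changes:
        return []
    rng = np.random.default_rng(seed)
    labels = case_profiles.region_labels
    if labels != hc_profiles.region_labels:
        raise LabelMismatchError("case and HC profiles must share region labels")
    lab_idx = {lab: k for k, lab in enumerate(labels)}
    pairs = [(lab_idx[ch.region_a], lab_idx[ch.region_b]) for ch in changes]
    cv = case_profiles.values.to_numpy(dtype=float)
    hv = hc_profiles.values.to_numpy(dtype=float)
    hits = np.zeros(len(changes))
    for _ in range(n_iter):
        rc = _corr(cv[rng.integers(0, len(cv), size=len(cv))])
        rh = _corr(hv[rng.integers(0, len(hv), size=len(hv))])
        for k, ((i, j), ch) in enumerate(zip(pairs, changes)):
            a, b = rc[i, j], rh[i, j]
            if not (np.isfinite(a) and np.isfinite(b)):
                continue
            d = _dr(np.array(a), np.array(b), dr_mode)
            if ch.status == "gained":
                ok = abs(a) >= tau_r and abs(b) < tau_r and d > tau_dr
            else:
                ok = abs(b) >= tau_r and abs(a) < tau_r and d > tau_dr
            hits[k] += ok
    frac = hits / n_iter
    kept = [
        replace(ch, confirmation_frac=float(f))
        for ch, f in zip(changes, frac)
        if f > vote
    ]
    return kept


def filter_anatomical(
    changes: list[ConnectionChange],
    anatomy_edges,
    max_hops: int = 2,
) -> list[ConnectionChange]:
    """Retain changes whose endpoints are <= ``max_hops`` apart in the
    anatomical pathway graph; endpoints absent from the graph drop the change
    (logged)."""
    g = anatomy_edges if isinstance(anatomy_edges, nx.Graph) else nx.Graph(list(anatomy_edges))
    kept = []
    n_dropped = 0
    for ch in changes:
        if ch.region_a not in g or ch.region_b not in g:
            logger.info(
                "dropping %s-%s: endpoint absent from anatomy graph", ch.region_a, ch.region_b
            )
            n_dropped += 1
            continue
        reach = nx.single_source_shortest_path_length(g, ch.region_a, cutoff=max_hops)
        if ch.region_b in reach:
            kept.append(replace(ch, anatomical_ok=True))
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("anatomical filter dropped %d of %d changes", n_dropped, len(changes))
    return kept


def _category(region_a: str, region_b: str, pdrp: NetworkPattern, pdcp: NetworkPattern):
    in_r = {r: r in pdrp.weights.index for r in (region_a, region_b)}
    in_c = {r: r in pdcp.weights.index for r in (region_a, region_b)}
    if not all(in_r[r] or in_c[r] for r in (region_a, region_b)):
        return None
    if in_r[region_a] and in_r[region_b]:
        return "RR"
    if in_c[region_a] and in_c[region_b]:
        return "CC"
    return "RC"


def categorize_changes(
    changes: list[ConnectionChange],
    pdrp: NetworkPattern,
    pdcp: NetworkPattern,
) -> pd.DataFrame:
    """Category percentage table per (timepoint, status).

    Categories: RR (both endpoints motor-pattern nodes), CC (both cognitive),
    RC (bridging).  A node belonging to both memberships counts toward the
    within-network category first (precedence RR, then CC).  Changes with an
    endpoint in neither membership are excluded (logged).  Percentages over
    RR/RC/CC sum to 100 within each (timepoint, status) cell; an empty change
    list yields an empty table.
    """
    rows = []
    for ch in changes:
        cat = _category(ch.region_a, ch.region_b, pdrp, pdcp)
        if cat is None:
            logger.info(
                "excluding %s-%s: endpoint in neither pattern", ch.region_a, ch.region_b
            )
            continue
        ch.category = cat
        rows.append((ch.timepoint, ch.status, cat))
    if not rows:
        return pd.DataFrame(columns=["timepoint", "status", "category", "count", "pct"])
    df = pd.DataFrame(rows, columns=["timepoint", "status", "category"])
    out = []
    for (tp, status), grp in df.groupby(["timepoint", "status"]):
        total = len(grp)
        for cat in ("RR", "RC", "CC"):
            n = int((grp["category"] == cat).sum())
            out.append((tp, status, cat, n, 100.0 * n / total))
    return pd.DataFrame(out, columns=["timepoint", "status", "category", "count", "pct"])


def classify_nodes(
    case_profiles: RegionalProfileSet,
    hc_profiles: RegionalProfileSet,
    pattern: NetworkPattern,
    core_quantile: float = 0.5,
) -> NetworkPattern:
    """Label membership nodes active/underactive and core/periphery.

    A node is *active* when the case group's mean normalised activity exceeds
    the healthy mean; *core* when its |weight| is at or above the
    ``core_quantile`` quantile of membership |weights| (>= rule, so ties and
    all-equal weights classify as core).  Returns a copy of the pattern with
    the labels attached.
    """
    for r in pattern.membership:
        if r not in case_profiles.values.columns or r not in hc_profiles.values.columns:
            raise LabelMismatchError(f"region {r!r} missing from profiles")
    case_mean = case_profiles.values[pattern.membership].mean(axis=0)
    hc_mean = hc_profiles.values[pattern.membership].mean(axis=0)
    active = frozenset(case_mean.index[case_mean > hc_mean])
    absw = pattern.weights.abs()
    cut = absw.quantile(core_quantile)
    core = frozenset(absw.index[absw >= cut])
    return replace(pattern, active=active, core=core)


def detect_connection_changes(
    case_profiles: RegionalProfileSet,
    hc_profiles: RegionalProfileSet,
    pdrp: NetworkPattern,
    pdcp: NetworkPattern,
    anatomy_edges=None,
    tau_r: float = 0.6,
    tau_dr: float = 0.4,
    dr_mode: str = "signed",
    B: int = 100,
    n_confirm: int = 100,
    max_hops: int = 2,
    seed: int | None = None,
) -> tuple[list[ConnectionChange], pd.DataFrame]:
    """Full edge-change pipeline for one timepoint.

    Bootstrap-median adjacency for both groups, threshold detection,
    restriction to pattern-member pairs, anatomical filtering (when an
    anatomy graph is supplied), bootstrap confirmation, and category
    percentages.  Returns the confirmed changes and the category table.
    """
    ss = np.random.SeedSequence(seed)
    s_case, s_hc, s_conf = (np.random.default_rng(c).integers(2**31) for c in ss.spawn(3))
    adj_case = bootstrap_adjacency(case_profiles, B=B, seed=int(s_case))
    adj_hc = bootstrap_adjacency(hc_profiles, B=B, seed=int(s_hc))
    changes = detect_gain_loss(adj_case, adj_hc, tau_r=tau_r, tau_dr=tau_dr, dr_mode=dr_mode)
    changes = [
        ch for ch in changes if _category(ch.region_a, ch.region_b, pdrp, pdcp) is not None
    ]
    if anatomy_edges is not None:
        changes = filter_anatomical(changes, anatomy_edges, max_hops=max_hops)
    changes = confirm_changes(
        changes,
        case_profiles,
        hc_profiles,
        tau_r=tau_r,
        tau_dr=tau_dr,
        dr_mode=dr_mode,
        n_iter=n_confirm,
        seed=int(s_conf),
    )
    table = categorize_changes(changes, pdrp, pdcp)
    return changes, table
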