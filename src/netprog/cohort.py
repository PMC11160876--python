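"""Synthetic longitudinal cohort generator.

Generates healthy-control (HC) and prodromal-case cohorts with the statistical
structure every downstream pipeline stage assumes, so the whole analysis is
testable without patient scans:

* a parcellation of ``n_regions`` regions with two embedded covariance
  patterns (a motor-like "PDRP" and a cognitive-like "PDCP") whose subject
  expression drifts upward over time at a configured rate (z-points/year),
* regional log-activity with a strong shared metabolic factor plus block
  structure, giving the widespread positive inter-regional correlations seen
  in global-ratio-normalised metabolic data,
* planted edge-level connectivity edits (gained/lost correlations) applied to
  the case covariance before sampling, with ground truth recorded,
* linearly declining dopamine-transporter (DAT) binding expressed as % of the
  healthy mean, with per-subject random intercepts/slopes.

Case profiles are generated in log space (pattern expression is added to the
log activity), which makes the topographic scoring in
:mod:`netprog.expression` the exact matched inverse and turns parameter
recovery into a well-posed test.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError, InfeasibleEditError, InvalidConfigError
from .expression import NetworkPattern, RegionalProfileSet

__all__ = [
    "PlantedEdge",
    "CohortConfig",
    "SyntheticCohort",
    "generate_patterns",
    "generate_cohort",
    "plant_connection_changes",
    "example_planted_edges",
    "default_anatomy",
    "generate_cross_sectional",
    "region_labels",
]

_BLOCK_SIZE = 10
_HOST_BLOCK_LOADING = 0.15
_LOSS_PAIR_LOADING = 0.93


def region_labels(n_regions: int) -> list[str]:
    width = max(3, len(str(n_regions)))
    return [f"R{i + 1:0{width}d}" for i in range(n_regions)]


@dataclass(frozen=True)
class PlantedEdge:
    """One ground-truth connectivity edit.

    ``r_case`` is the target case-group correlation; ``r_hc`` (optional)
    overrides the healthy-group correlation for the same pair.  ``kind`` is
    ``"gain"`` (edge present in cases only) or ``"loss"`` (present in HC
    only).  ``timepoints`` restricts the case edit to a subset of timepoint
    indices (``None`` = all).
    """

    region_a: str
    region_b: str
    r_case: float
    r_hc: float | None = None
    kind: str = "gain"
    timepoints: tuple[int, ...] | None = None


@dataclass
class CohortConfig:
    """Study-design and generative parameters for one synthetic cohort.

    Rates mirror the prodromal-parkinsonism study conditions: pattern
    expression drifting at ~0.23 z-points/year and putamen DAT binding
    declining at ~4.8 percentage points of the healthy mean per year.
    """

    n_regions: int = 95
    n_hc: int = 17
    n_case: int = 13
    timepoints: tuple[float, ...] = (0.0, 2.0, 4.0)
    # pattern expression dynamics (z-score scale)
    pattern_score_slope: float = 0.23
    pdcp_score_slope: float = 0.21
    pdrp_baseline_z: float = 0.8
    pdcp_baseline_z: float = 0.3
    baseline_z_sd: float = 0.5
    slope_sd: float = 0.05
    z_noise_sd: float = 0.3
    # latent correlation between the two patterns' trajectory noise; combined
    # with the shared upward trend this puts the measured within-subject
    # change correlation near 0.89
    pattern_noise_corr: float = 0.60
    # DAT binding dynamics (% of healthy mean)
    dat_putamen_rate: float = -4.8
    dat_caudate_rate: float = -4.4
    dat_baseline_mean: float = 100.0
    dat_baseline_sd: float = 5.0
    dat_slope_sd: float = 0.3
    dat_noise_sd: float = 3.0
    n_hc2: int = 10
    hc_putamen_sor: float = 2.0
    hc_caudate_sor: float = 2.2
    dat_sor_sd: float = 0.12
    # regional profile noise (log-activity scale)
    noise_sd: float = 0.08
    subject_global_sd: float = 0.115
    overlap_fraction: float = 0.0
    planted_gains: tuple[PlantedEdge, ...] = ()
    planted_losses: tuple[PlantedEdge, ...] = ()
    case_n_by_timepoint: tuple[int, ...] | None = None
    dat_n_by_timepoint: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 4:
            raise InvalidConfigError("n_regions must be >= 4")
        tps = tuple(float(t) for t in self.timepoints)
        if any(t < 0 for t in tps) or any(
            b <= a for a, b in zip(tps, tps[1:])
        ):
            raise InvalidConfigError("timepoints must be non-negative and strictly increasing")
        object.__setattr__(self, "timepoints", tps)
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be > 0")
        if not 0 <= self.overlap_fraction < 1:
            raise InvalidConfigError("overlap_fraction must be in [0, 1)")
        for attr in ("case_n_by_timepoint", "dat_n_by_timepoint"):
            sched = getattr(self, attr)
            if sched is not None:
                sched = tuple(int(n) for n in sched)
                if len(sched) != len(tps):
                    raise InvalidConfigError(f"{attr} must match the number of timepoints")
                if any(n < 1 or n > self.n_case for n in sched):
                    raise InvalidConfigError(f"{attr} entries must be in [1, n_case]")
                object.__setattr__(self, attr, sched)

    @classmethod
    def paper_longitudinal(cls, **overrides) -> "CohortConfig":
        """Preset mirroring the longitudinal study arm: 17 HC vs 13 cases
        scanned at 0/2/4 years with attrition 13/12/10 (FDG) and 13/10/6 (DAT)."""
        base = dict(
            n_hc=17,
            n_case=13,
            case_n_by_timepoint=(13, 12, 10),
            dat_n_by_timepoint=(13, 10, 6),
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def null(cls, **overrides) -> "CohortConfig":
        """Preset with every planted effect removed: cases and HC are drawn
        from the same generative law (false-positive calibration runs)."""
        base = dict(
            pattern_score_slope=0.0,
            pdcp_score_slope=0.0,
            pdrp_baseline_z=0.0,
            pdcp_baseline_z=0.0,
            baseline_z_sd=0.0,
            slope_sd=0.0,
            z_noise_sd=0.0,
            dat_putamen_rate=0.0,
            dat_caudate_rate=0.0,
            dat_slope_sd=0.0,
            planted_gains=(),
            planted_losses=(),
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth needed for self-scoring tests."""

    config: CohortConfig
    patterns: dict[str, NetworkPattern]
    hc_profiles: RegionalProfileSet
    case_profiles_by_timepoint: list[RegionalProfileSet]
    trajectories: pd.DataFrame  # columns: subject, measure, timepoint_years, value
    dat_counts: pd.DataFrame
    hc2_dat_counts: pd.DataFrame
    truth: dict


def generate_patterns(
    n_regions: int,
    overlap_fraction: float = 0.0,
    seed: int = 0,
    membership_size: int | None = None,
) -> tuple[NetworkPattern, NetworkPattern]:
    """Build two region-weighted patterns with zero-mean unit-norm weights.

    Each pattern occupies a contiguous membership of ~30% of the parcellation;
    the two memberships overlap by ``overlap_fraction`` of their size.  Core
    nodes carry positive weights (overactive under expression), periphery
    nodes negative weights, and the periphery magnitudes are rescaled so the
    weight vector sums to zero before unit normalisation.
    """
    if not 0 <= overlap_fraction < 1:
        raise InvalidConfigError("overlap_fraction must be in [0, 1)")
    labels = region_labels(n_regions)
    m = membership_size if membership_size is not None else max(4, int(round(0.3 * n_regions)))
    if m < 4:
        raise InvalidConfigError("membership size must be >= 4")
    k = int(round(overlap_fraction * m))
    if 2 * m - k > n_regions:
        raise InvalidConfigError(
            f"n_regions={n_regions} too small for two patterns of {m} regions "
            f"with overlap {k}"
        )
    rng = np.random.default_rng(seed)
    memberships = [labels[:m], labels[m - k : 2 * m - k]]
    names = ["PDRP", "PDCP"]
    patterns = []
    for name, mem in zip(names, memberships):
        n_core = (m + 1) // 2
        core_idx = rng.choice(m, size=n_core, replace=False)
        is_core = np.zeros(m, dtype=bool)
        is_core[core_idx] = True
        mags = rng.uniform(0.5, 1.5, size=m)
        w = np.where(is_core, mags, -mags)
        w[~is_core] *= w[is_core].sum() / mags[~is_core].sum()
        w /= np.linalg.norm(w)
        patterns.append(
            NetworkPattern(
                name=name,
                weights=pd.Series(w, index=mem),
                core=frozenset(np.asarray(mem)[is_core]),
            )
        )
    return patterns[0], patterns[1]


def plant_connection_changes(
    cov: np.ndarray,
    edits: list[tuple[int, int, float]],
    tol: float = 0.02,
    allow_repair: bool = True,
    max_iter: int = 500,
) -> np.ndarray:
    """Impose target pairwise correlations on a covariance matrix.

    Edits are ``(i, j, target_r)`` index triples.  The matrix is converted to
    correlation form, the requested entries are set, and if the result is not
    positive definite it is repaired by alternating eigenvalue clipping and
    edit re-imposition (a Higham-style nearest-correlation projection with
    fixed entries).  The returned covariance satisfies every edit within
    ``tol`` and has smallest eigenvalue > 0; otherwise
    :class:`~netprog.exceptions.InfeasibleEditError` is raised.
    """
    cov = np.asarray(cov, dtype=float)
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise DomainError("covariance must be symmetric")
    if not edits:
        return cov.copy()
    sd = np.sqrt(np.diag(cov))
    if (sd <= 0).any():
        raise DomainError("covariance has non-positive diagonal")
    corr = cov / np.outer(sd, sd)
    n = corr.shape[0]
    for i, j, r in edits:
        if not (0 <= i < n and 0 <= j < n) or i == j:
            raise InvalidConfigError(f"invalid edit indices ({i}, {j})")
        if not -1 < r < 1:
            raise InvalidConfigError(f"target correlation {r} outside (-1, 1)")

    def impose(c: np.ndarray) -> np.ndarray:
        c = c.copy()
        for i, j, r in edits:
            c[i, j] = c[j, i] = r
        np.fill_diagonal(c, 1.0)
        return c

    eps = 1e-8
    c = impose(corr)
    evals = np.linalg.eigvalsh(c)
    if evals[0] <= 0:
        if not allow_repair:
            raise InfeasibleEditError(
                f"edited matrix not positive definite (min eigenvalue "
                f"{evals[0]:.3g}) and repair is disabled"
            )
        for _ in range(max_iter):
            w, v = np.linalg.eigh(c)
            if w[0] >= eps:
                break
            w = np.clip(w, eps, None)
            c = (v * w) @ v.T
            d = np.sqrt(np.diag(c))
            c = c / np.outer(d, d)
            c = impose(c)
        evals = np.linalg.eigvalsh(c)
    err = max(abs(c[i, j] - r) for i, j, r in edits)
    if evals[0] <= 0 or err > tol:
        raise InfeasibleEditError(
            f"could not realise edits as a positive-definite correlation matrix "
            f"(min eigenvalue {evals[0]:.3g}, max edit error {err:.3g} > tol {tol})"
        )
    return c * np.outer(sd, sd)


def _structure(
    config: CohortConfig,
    labels: list[str],
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Base inter-regional correlation matrix (unit diagonal) plus role record.

    Regions load on the factor of their anatomical block (loadings
    0.82-0.92), giving strong within-block correlations that survive global
    ratio normalisation (a near-uniform factor would not).  Regions hosting
    planted *gains* load only weakly on their block so their mutual
    correlation is low in HC and can be raised in cases; regions hosting
    planted *losses* additionally share a strong pair factor (mutual r ~ 0.86
    in HC) that the case edit removes.
    """
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    block = np.arange(n) // _BLOCK_SIZE
    n_blocks = int(block.max()) + 1
    edges = list(config.planted_gains) + list(config.planted_losses)
    roles: dict[str, str] = {}
    for e in edges:
        for lab in (e.region_a, e.region_b):
            if lab not in idx:
                raise InvalidConfigError(f"planted edge references unknown region {lab!r}")
            if lab in roles:
                raise InvalidConfigError(
                    f"region {lab!r} hosts more than one planted edge"
                )
            roles[lab] = e.kind
    b = rng.uniform(0.82, 0.92, size=n)
    n_pairs = sum(1 for e in edges if e.kind == "loss")
    pair_load = np.zeros((n, n_pairs))
    p = 0
    for e in edges:
        hosts = (e.region_a, e.region_b)
        for lab in hosts:
            b[idx[lab]] = _HOST_BLOCK_LOADING
        if e.kind == "loss":
            for lab in hosts:
                pair_load[idx[lab], p] = _LOSS_PAIR_LOADING
            p += 1
    load = np.zeros((n, n_blocks + n_pairs))
    for r in range(n):
        load[r, block[r]] = b[r]
    load[:, n_blocks:] = pair_load
    resid = 1.0 - (load**2).sum(axis=1)
    if (resid <= 0.01).any():
        raise InvalidConfigError("factor loadings leave no residual variance")
    omega = load @ load.T
    np.fill_diagonal(omega, 1.0)
    return omega, {"roles": roles, "block": block.tolist()}


def _edit_indices(edges, labels, attr):
    idx = {lab: i for i, lab in enumerate(labels)}
    return [(idx[e.region_a], idx[e.region_b], getattr(e, attr)) for e in edges]


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic longitudinal cohort (deterministic per seed)."""
    labels = region_labels(config.n_regions)
    ss = np.random.SeedSequence(config.seed)
    keys = ["patterns", "structure", "mu", "traj", "dat", "hc", "case", "hc2"]
    rngs = {k: np.random.default_rng(s) for k, s in zip(keys, ss.spawn(len(keys)))}

    pdrp, pdcp = generate_patterns(
        config.n_regions, config.overlap_fraction, seed=config.seed
    )
    omega, structure_info = _structure(config, labels, rngs["structure"])

    # healthy-group covariance: optional r_hc overrides on planted pairs
    hc_edits = [
        (i, j, r)
        for (i, j, r) in _edit_indices(
            [e for e in (*config.planted_gains, *config.planted_losses) if e.r_hc is not None],
            labels,
            "r_hc",
        )
    ]
    omega_hc = plant_connection_changes(omega, hc_edits) if hc_edits else omega

    # case covariance per timepoint: r_case edits active at that timepoint
    omegas_case = []
    achieved = []
    for t_idx in range(len(config.timepoints)):
        active = [
            e
            for e in (*config.planted_gains, *config.planted_losses)
            if e.timepoints is None or t_idx in e.timepoints
        ]
        edits = _edit_indices(active, labels, "r_case")
        om = plant_connection_changes(omega_hc, edits) if edits else omega_hc
        omegas_case.append(om)
        for e, (i, j, _) in zip(active, edits):
            achieved.append(
                {
                    "region_a": e.region_a,
                    "region_b": e.region_b,
                    "kind": e.kind,
                    "timepoint_index": t_idx,
                    "r_case_target": e.r_case,
                    "r_case_achieved": float(om[i, j]),
                    "r_hc": float(omega_hc[i, j]),
                }
            )

    # analytic raw-score SD under the healthy law, used to scale expression
    w_full = {}
    sig = {}
    for pat in (pdrp, pdcp):
        w = np.zeros(config.n_regions)
        for lab, wv in pat.weights.items():
            w[labels.index(lab)] = wv
        w_full[pat.name] = w
        sig[pat.name] = config.noise_sd * float(np.sqrt(w @ omega_hc @ w))

    # per-subject z-score trajectories for the two patterns (correlated noise)
    rho = config.pattern_noise_corr
    cmat = np.array([[1.0, rho], [rho, 1.0]])
    croot = np.linalg.cholesky(cmat) if abs(rho) < 1 else np.array([[1.0, 0.0], [1.0, 0.0]])
    tr = rngs["traj"]
    n_case, tps = config.n_case, config.timepoints
    b0 = config.baseline_z_sd * (tr.standard_normal((n_case, 2)) @ croot.T)
    b1 = config.slope_sd * (tr.standard_normal((n_case, 2)) @ croot.T)
    eps = config.z_noise_sd * (tr.standard_normal((n_case, len(tps), 2)) @ croot.T)
    base = np.array([config.pdrp_baseline_z, config.pdcp_baseline_z])
    slope = np.array([config.pattern_score_slope, config.pdcp_score_slope])
    tarr = np.asarray(tps)
    # z[subject, timepoint, pattern]
    z = (
        base[None, None, :]
        + b0[:, None, :]
        + (slope[None, None, :] + b1[:, None, :]) * tarr[None, :, None]
        + eps
    )

    # DAT %-of-normal trajectories
    dt = rngs["dat"]
    rates = np.array([config.dat_putamen_rate, config.dat_caudate_rate])
    u0 = config.dat_baseline_sd * dt.standard_normal((n_case, 2))
    u1 = config.dat_slope_sd * dt.standard_normal((n_case, 2))
    de = config.dat_noise_sd * dt.standard_normal((n_case, len(tps), 2))
    pct = (
        config.dat_baseline_mean
        + u0[:, None, :]
        + (rates[None, None, :] + u1[:, None, :]) * tarr[None, :, None]
        + de
    )
    pct = np.clip(pct, 1.0, None)

    case_ids = [f"case{i + 1:02d}" for i in range(n_case)]
    hc_ids = [f"hc{i + 1:02d}" for i in range(config.n_hc)]
    mu = np.log(100.0) + 0.15 * rngs["mu"].standard_normal(config.n_regions)

    # orthonormal basis of the two pattern directions; case residual noise is
    # drawn orthogonal to it so the planted z-trajectories are exactly the
    # expression statistics downstream scoring recovers
    wmat = np.column_stack([w_full["PDRP"], w_full["PDCP"]])
    qbasis, _ = np.linalg.qr(wmat)

    def sample_profiles(rng, ids, om, extra=None, deflate_patterns=False):
        from scipy.stats import norm

        root = np.linalg.cholesky(om + 1e-10 * np.eye(config.n_regions))
        resid = config.noise_sd * (rng.standard_normal((len(ids), config.n_regions)) @ root.T)
        if deflate_patterns:
            resid = resid - (resid @ qbasis) @ qbasis.T
        # stratified (quantile-spaced) global scaling: the between-subject
        # spread of the global metabolic rate is then stable at small n
        q = norm.ppf((np.arange(len(ids)) + 0.5) / len(ids))
        g = config.subject_global_sd * rng.permutation(q)
        logx = mu[None, :] + g[:, None] + resid
        if extra is not None:
            logx = logx + extra
        return pd.DataFrame(np.exp(logx), index=ids, columns=labels)

    hc_profiles = RegionalProfileSet(
        sample_profiles(rngs["hc"], hc_ids, omega_hc), group="HC", timepoint=0.0
    )

    case_sets = []
    crng = rngs["case"]
    for t_idx, t in enumerate(tps):
        n_t = (
            config.case_n_by_timepoint[t_idx]
            if config.case_n_by_timepoint is not None
            else n_case
        )
        extra = (
            z[:n_t, t_idx, 0:1] * sig["PDRP"] * w_full["PDRP"][None, :]
            + z[:n_t, t_idx, 1:2] * sig["PDCP"] * w_full["PDCP"][None, :]
        )
        case_sets.append(
            RegionalProfileSet(
                sample_profiles(
                    crng, case_ids[:n_t], omegas_case[t_idx], extra, deflate_patterns=True
                ),
                group="case",
                timepoint=t,
            )
        )

    # long-format trajectory table (the generator's own measurement record)
    rows = []
    for s, sid in enumerate(case_ids):
        for t_idx, t in enumerate(tps):
            if config.case_n_by_timepoint is None or s < config.case_n_by_timepoint[t_idx]:
                rows.append((sid, "PDRP_z", t, z[s, t_idx, 0]))
                rows.append((sid, "PDCP_z", t, z[s, t_idx, 1]))
            if config.dat_n_by_timepoint is None or s < config.dat_n_by_timepoint[t_idx]:
                rows.append((sid, "putamen_pct", t, pct[s, t_idx, 0]))
                rows.append((sid, "caudate_pct", t, pct[s, t_idx, 1]))
    trajectories = pd.DataFrame(
        rows, columns=["subject", "measure", "timepoint_years", "value"]
    )

    # DAT count tables: striatal and occipital counts reproducing the planted
    # %-of-normal values through the (striatum - occipital)/occipital ratio
    drows = []
    for s, sid in enumerate(case_ids):
        for t_idx, t in enumerate(tps):
            if (
                config.dat_n_by_timepoint is not None
                and s >= config.dat_n_by_timepoint[t_idx]
            ):
                continue
            occ = 1.0 + 0.05 * dt.standard_normal()
            sor_put = pct[s, t_idx, 0] / 100.0 * config.hc_putamen_sor
            sor_cau = pct[s, t_idx, 1] / 100.0 * config.hc_caudate_sor
            drows.append((sid, t, occ * (1 + sor_put), occ * (1 + sor_cau), occ))
    dat_counts = pd.DataFrame(
        drows,
        columns=[
            "subject",
            "timepoint_years",
            "putamen_counts",
            "caudate_counts",
            "occipital_counts",
        ],
    )
    h2 = rngs["hc2"]
    hrows = []
    for i in range(config.n_hc2):
        occ = 1.0 + 0.05 * h2.standard_normal()
        sor_put = config.hc_putamen_sor + config.dat_sor_sd * h2.standard_normal()
        sor_cau = config.hc_caudate_sor + config.dat_sor_sd * h2.standard_normal()
        hrows.append((f"hc2_{i + 1:02d}", 0.0, occ * (1 + sor_put), occ * (1 + sor_cau), occ))
    hc2_dat_counts = pd.DataFrame(hrows, columns=dat_counts.columns)

    truth = {
        "pdrp_slope": config.pattern_score_slope,
        "pdcp_slope": config.pdcp_score_slope,
        "dat_putamen_rate": config.dat_putamen_rate,
        "dat_caudate_rate": config.dat_caudate_rate,
        "score_sd": dict(sig),
        "planted_edges": achieved,
        "structure": structure_info,
        "seed": config.seed,
    }
    return SyntheticCohort(
        config=config,
        patterns={"PDRP": pdrp, "PDCP": pdcp},
        hc_profiles=hc_profiles,
        case_profiles_by_timepoint=case_sets,
        trajectories=trajectories,
        dat_counts=dat_counts,
        hc2_dat_counts=hc2_dat_counts,
        truth=truth,
    )


def example_planted_edges(
    pdrp: NetworkPattern,
    pdcp: NetworkPattern,
    n_gain: tuple[int, int, int] = (3, 2, 1),
    n_loss: tuple[int, int, int] = (2, 1, 1),
    r_gain: float = 0.90,
    r_loss: float = 0.05,
    seed: int = 0,
) -> tuple[tuple[PlantedEdge, ...], tuple[PlantedEdge, ...]]:
    """Build a default planted-edge set across categories.

    ``n_gain``/``n_loss`` give counts per category ``(RR, RC, CC)`` where R/C
    denote endpoints in the motor/cognitive pattern membership.  Host regions
    are drawn without replacement so each region hosts one edge.  Gains leave
    the healthy correlation at its (low) structural baseline and set the case
    correlation to ``r_gain``; losses do the reverse via a structural pair
    factor removed in cases (case correlation ``r_loss``).
    """
    rng = np.random.default_rng(seed)
    pool_r = [r for r in pdrp.membership if r not in pdcp.membership]
    pool_c = [r for r in pdcp.membership if r not in pdrp.membership]
    rng.shuffle(pool_r)
    rng.shuffle(pool_c)
    pool_r, pool_c = list(pool_r), list(pool_c)

    def take(cat):
        need = {"RR": (pool_r, pool_r), "CC": (pool_c, pool_c),
                "RC": (pool_r, pool_c)}[cat]
        if len(need[0]) < (2 if need[0] is need[1] else 1) or not need[1]:
            return None
        return need[0].pop(), need[1].pop()

    gains, losses = [], []
    for counts, out, kind, r in ((n_gain, gains, "gain", r_gain), (n_loss, losses, "loss", r_loss)):
        for cat, k in zip(("RR", "RC", "CC"), counts):
            for _ in range(k):
                pair = take(cat)
                if pair is None:
                    logging.getLogger(__name__).info(
                        "host pool exhausted; skipping a planted %s %s edge", cat, kind
                    )
                    continue
                out.append(PlantedEdge(pair[0], pair[1], r_case=r, kind=kind))
    return tuple(gains), tuple(losses)


def default_anatomy(
    n_regions: int,
    planted_edges: tuple[PlantedEdge, ...] = (),
    block_size: int = _BLOCK_SIZE,
) -> list[tuple[str, str]]:
    """Sparse synthetic anatomical pathway graph.

    Within each block consecutive regions are chained (short association
    pathways); consecutive blocks are bridged by their boundary regions;
    planted edges are added as direct pathways so that ground-truth
    connections always lie along the anatomy.
    """
    labels = region_labels(n_regions)
    edges = set()
    for i in range(n_regions):
        j = i + 1
        if j < n_regions and j // block_size == i // block_size:
            edges.add((labels[i], labels[j]))
    for b in range((n_regions - 1) // block_size):
        i = (b + 1) * block_size - 1
        j = (b + 1) * block_size
        if j < n_regions:
            edges.add((labels[i], labels[j]))
    for e in planted_edges:
        key = tuple(sorted((e.region_a, e.region_b)))
        edges.add(key)
    return sorted(edges)


def generate_cross_sectional(
    n_subjects: int = 17,
    n_converters: int = 12,
    score_time_corr: float = -0.58,
    time_mean: float = 4.8,
    time_sd: float = 3.9,
    score_mean: float = 1.2,
    score_sd: float = 0.9,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic cross-sectional cohort: baseline pattern scores vs conversion.

    Emulates a single-timepoint perfusion-imaging cohort followed clinically:
    converters' times to phenoconversion correlate inversely with baseline
    motor-pattern expression at the configured Pearson correlation; age and
    motor ratings carry weaker inverse associations, sex and disease duration
    none.  Non-converters receive no conversion time.
    """
    if n_converters > n_subjects or n_converters < 3:
        raise InvalidConfigError("need 3 <= n_converters <= n_subjects")
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(n_subjects)
    times = np.clip(time_mean + time_sd * u, 0.2, None)
    conv = np.zeros(n_subjects, dtype=bool)
    conv[:n_converters] = True
    t_std = (times - times[conv].mean()) / times[conv].std(ddof=1)
    rho = score_time_corr
    v = rng.standard_normal(n_subjects)
    score = score_mean + score_sd * (rho * t_std + np.sqrt(1 - rho**2) * v)
    age = 70.0 + 5.0 * (-0.3 * t_std + np.sqrt(1 - 0.09) * rng.standard_normal(n_subjects))
    updrs = np.clip(
        5.0 + 3.0 * (-0.25 * t_std + np.sqrt(1 - 0.0625) * rng.standard_normal(n_subjects)),
        0.0,
        None,
    )
    duration = np.abs(rng.normal(9.6, 6.7, size=n_subjects))
    sex = (rng.random(n_subjects) < 0.75).astype(int)
    # keep both sexes represented among converters so the covariate is never
    # constant (and hence collinear with the intercept) in adjusted models
    if sex[:n_converters].min() == sex[:n_converters].max():
        sex[0] = 1 - sex[0]
    return pd.DataFrame(
        {
            "subject": [f"xs{i + 1:02d}" for i in range(n_subjects)],
            "pdrp_z": score,
            "converted": conv,
            "time_to_conversion": np.where(conv, times, np.nan),
            "age": age,
            "sex": sex,
            "irbd_duration": duration,
            "updrs_motor": updrs,
        }
    )
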