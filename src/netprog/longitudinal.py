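"""Longitudinal progression statistics.

Progression rates are estimated with individual growth models (IGM): linear
mixed-effects models with subject-level random intercepts and slopes, fitted
by maximum likelihood.  Supporting statistics mirror classical longitudinal
biomarker practice: one-way repeated-measures ANOVA with paired Bonferroni
post-hocs, pooled-variance two-sample t-tests, the Bland-Altman
within-subject (repeated-measures) correlation, and a noncentral-t power /
sample-size routine for two-arm trial planning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConvergenceError, DegenerateDataError, DomainError

__all__ = [
    "SubjectTrajectory",
    "RateEstimate",
    "fit_igm",
    "compare_rates",
    "rmanova",
    "bland_altman_rm_corr",
    "two_sample_t",
    "power_sample_size",
]


@dataclass
class SubjectTrajectory:
    """Timestamped observations of one measure for one subject."""

    subject_id: str
    times: np.ndarray
    values: np.ndarray
    measure: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size == 0 or t.size != v.size:
            raise DomainError("trajectory needs matching, non-empty times and values")
        if (t < 0).any() or (np.diff(t) <= 0).any():
            raise DomainError("times must be non-negative and strictly increasing")
        self.times, self.values = t, v


@dataclass
class RateEstimate:
    """Fixed-effect progression rate from a growth model."""

    slope: float
    intercept: float
    slope_se: float
    p_value: float
    n_subjects: int
    n_observations: int
    model: str


def _as_long(trajectories) -> pd.DataFrame:
    if isinstance(trajectories, pd.DataFrame):
        df = trajectories.rename(
            columns={"timepoint_years": "time", "timepoint": "time"}
        )
        need = {"subject", "time", "value"}
        if not need <= set(df.columns):
            raise DomainError(f"long-format data needs columns {sorted(need)}")
        return df[["subject", "time", "value"]].dropna().copy()
    rows = []
    for tr in trajectories:
        for t, v in zip(tr.times, tr.values):
            rows.append((tr.subject_id, t, v))
    return pd.DataFrame(rows, columns=["subject", "time", "value"])


def fit_igm(trajectories, reml: bool = False) -> RateEstimate:
    """Individual growth model: value = (b0 + u0_i) + (b1 + u1_i) t + e.

    Fitted as a linear mixed model (ML by default; ``reml=True`` for REML)
    with unstructured random intercept/slope covariance.  When the
    random-slope variance is degenerate or the fit fails, the model falls
    back to random-intercept-only, and finally to pooled ordinary least
    squares on exactly collinear (noise-free) data; the path taken is
    recorded in ``model``.
    """
    df = _as_long(trajectories)
    counts = df.groupby("subject")["time"].count()
    if (counts >= 2).sum() == 0:
        raise DegenerateDataError("all subjects have a single timepoint")
    if counts.size < 3:
        raise DegenerateDataError("need >= 3 subjects")
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    def _mixed(re_formula, tag):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm("value ~ time", df, groups=df["subject"], re_formula=re_formula)
            res = md.fit(reml=reml, method=["lbfgs", "powell"])
            if not res.converged:
                raise ConvergenceError(f"{tag} mixed model did not converge")
            se = float(res.bse_fe["time"])
            if not np.isfinite(se) or se <= 0:
                raise ConvergenceError(f"{tag} slope SE not estimable")
            return RateEstimate(
                slope=float(res.fe_params["time"]),
                intercept=float(res.fe_params["Intercept"]),
                slope_se=se,
                p_value=float(res.pvalues["time"]),
                n_subjects=int(counts.size),
                n_observations=int(len(df)),
                model=tag,
            )

    # exactly collinear data defeat variance estimation; detect and use OLS
    X = np.column_stack([np.ones(len(df)), df["time"].to_numpy()])
    beta, res_ss, _, _ = np.linalg.lstsq(X, df["value"].to_numpy(), rcond=None)
    pooled_resid = float(res_ss[0]) if res_ss.size else 0.0
    # only subjects with >= 3 distinct times can witness exact linearity
    witnesses = [g for _, g in df.groupby("subject") if g["time"].nunique() >= 3]
    subj_perfect = bool(witnesses)
    for g in witnesses:
        b = np.polyfit(g["time"], g["value"], 1)
        if not np.allclose(np.polyval(b, g["time"]), g["value"], atol=1e-10):
            subj_perfect = False
            break
    if subj_perfect or pooled_resid < 1e-24:
        ols = sm.OLS(df["value"], X).fit()
        se = float(ols.bse.iloc[1])
        return RateEstimate(
            slope=float(beta[1]),
            intercept=float(beta[0]),
            slope_se=se if se > 0 else math.nan,
            p_value=float(ols.pvalues.iloc[1]) if se > 0 else math.nan,
            n_subjects=int(counts.size),
            n_observations=int(len(df)),
            model="ols-pooled (noise-free data)",
        )
    try:
        return _mixed("~time", "mixed (random intercept+slope, "
                      + ("REML" if reml else "ML") + ")")
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        pass
    try:
        return _mixed("1", "mixed (random intercept only — slope variance degenerate, "
                      + ("REML" if reml else "ML") + ")")
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        pass
    # last resort: pooled OLS with subject-clustered standard errors
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ols = sm.OLS(df["value"].to_numpy(), X).fit(
            cov_type="cluster", cov_kwds={"groups": df["subject"].to_numpy()}
        )
        return RateEstimate(
            slope=float(ols.params[1]),
            intercept=float(ols.params[0]),
            slope_se=float(ols.bse[1]),
            p_value=float(ols.pvalues[1]),
            n_subjects=int(counts.size),
            n_observations=int(len(df)),
            model="ols-pooled (cluster-robust SE; mixed model failed)",
        )


def compare_rates(trajectories_a, trajectories_b, labels=("a", "b"), reml: bool = False):
    """Joint two-measure growth model with a measure x time interaction.

    Tests whether two progression rates differ (e.g. caudate vs putamen
    decline) by adding fixed ``measure`` and ``measure:time`` terms to a
    mixed model with per-subject random intercepts and slopes.  Returns
    ``(rate_difference, p_interaction)``.
    """
    da = _as_long(trajectories_a).assign(measure=labels[0])
    db = _as_long(trajectories_b).assign(measure=labels[1])
    df = pd.concat([da, db], ignore_index=True)
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm(
            "value ~ time * C(measure)", df, groups=df["subject"], re_formula="~time"
        )
        res = md.fit(reml=reml, method=["lbfgs", "powell"])
    terms = [t for t in res.fe_params.index if t.startswith("time:C(measure)")]
    if len(terms) != 1:
        raise ConvergenceError(f"interaction term not identified among {list(res.fe_params.index)}")
    return float(res.fe_params[terms[0]]), float(res.pvalues[terms[0]])


def rmanova(wide: pd.DataFrame) -> dict:
    """One-way repeated-measures ANOVA over timepoints (subjects x columns).

    Rows with any missing value are dropped (complete cases; count recorded).
    Returns F with df = (k-1, (n-1)(k-1)), the p-value, and paired t post-hocs
    with Bonferroni-multiplied p-values.  If the error variance is exactly
    zero the F ratio is undefined; the degenerate case is reported with
    ``F = nan`` and ``p = 1`` when the condition means are equal.
    """
    if wide.shape[1] < 2:
        raise DegenerateDataError("need >= 2 timepoints")
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    n, k = complete.shape
    if n < 3:
        raise DegenerateDataError("need >= 3 complete-case subjects")
    vals = complete.to_numpy(dtype=float)
    grand = vals.mean()
    ss_time = n * ((vals.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((vals.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((vals - grand) ** 2).sum()
    ss_err = ss_tot - ss_time - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_time = ss_time / df1
    ms_err = ss_err / df2
    if ms_err <= 1e-300:
        F = math.nan if ms_time <= 1e-300 else math.inf
        p = 1.0 if ms_time <= 1e-300 else 0.0
    else:
        F = ms_time / ms_err
        p = float(stats.f.sf(F, df1, df2))
    pairs = []
    n_pairs = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            a, b = vals[:, i], vals[:, j]
            if np.allclose(a, b):
                t, praw = 0.0, 1.0
            else:
                t, praw = stats.ttest_rel(a, b)
            pairs.append(
                {
                    "pair": (wide.columns[i], wide.columns[j]),
                    "t": float(t),
                    "p_raw": float(praw),
                    "p_bonferroni": min(1.0, float(praw) * n_pairs),
                }
            )
    return {
        "F": F,
        "df": (df1, df2),
        "p": p,
        "n_subjects": n,
        "n_dropped_incomplete": n_dropped,
        "posthoc": pairs,
    }


def bland_altman_rm_corr(x, y, subject_ids) -> tuple[float, float]:
    """Within-subject (repeated-measures) correlation of two paired measures.

    Both variables are centred within subject and the Pearson correlation is
    computed on the pooled residuals with df = N_obs - n_subjects - 1.
    Subjects with fewer than two paired observations contribute nothing;
    if no subject contributes, the correlation is undefined.
    """
    df = pd.DataFrame({"x": x, "y": y, "s": subject_ids}).dropna()
    parts = []
    for _, g in df.groupby("s"):
        if len(g) < 2:
            continue
        parts.append(g[["x", "y"]] - g[["x", "y"]].mean())
    if not parts:
        raise DegenerateDataError("no subject has >= 2 paired observations")
    resid = pd.concat(parts, ignore_index=True)
    n_subj = sum(1 for _, g in df.groupby("s") if len(g) >= 2)
    dof = len(resid) - n_subj - 1
    if dof < 1:
        raise DegenerateDataError("insufficient degrees of freedom for rm correlation")
    sx, sy = resid["x"].std(ddof=0), resid["y"].std(ddof=0)
    if sx == 0 or sy == 0:
        raise DegenerateDataError("zero within-subject variance in one variable")
    r = float(np.corrcoef(resid["x"], resid["y"])[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt(dof / (1 - r**2))
    p = 2 * float(stats.t.sf(abs(t), dof))
    return r, p


def two_sample_t(a, b) -> tuple[float, float]:
    """Pooled-variance two-tailed Student's t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DegenerateDataError("need n >= 2 per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise DegenerateDataError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def _power_two_sample(n_per_arm: int, d: float, alpha: float) -> float:
    df = 2 * n_per_arm - 2
    nc = d * math.sqrt(n_per_arm / 2.0)
    crit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(crit, df, nc) + stats.nct.cdf(-crit, df, nc))


def power_sample_size(
    effect_size_d: float,
    alpha: float = 0.05,
    power: float = 0.80,
    max_n: int = 10_000_000,
) -> int:
    """Total sample size (two equal arms) for a two-sided two-sample t-test.

    Finds the smallest per-arm n whose exact noncentral-t power reaches the
    target and returns 2n.
    """
    if effect_size_d <= 0:
        raise DomainError("effect size must be > 0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise DomainError("alpha and power must lie in (0, 1)")
    # bracket by doubling, then bisect (power is monotone in n)
    lo, hi = 2, 2
    while _power_two_sample(hi, effect_size_d, alpha) < power:
        lo = hi
        hi *= 2
        if hi > max_n:
            raise DomainError("required sample size exceeds max_n")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _power_two_sample(mid, effect_size_d, alpha) >= power:
            hi = mid
        else:
            lo = mid
    if _power_two_sample(lo, effect_size_d, alpha) >= power:
        hi = lo
    return 2 * hi
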