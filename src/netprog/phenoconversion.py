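"""Time-to-phenoconversion prediction and baseline-expression correlations.

Dopamine-transporter (DAT) binding is quantified as the striatal-to-occipital
ratio SOR = (striatum - occipital)/occipital and expressed as a percentage of
the healthy-control mean.  The dual-threshold predictor extrapolates a
subject's motor-pattern expression upward at the cohort progression rate and
putamen DAT binding downward at the cohort decline rate, and predicts
phenoconversion at the time *both* early-disease thresholds are crossed
(expression z >= +1.5 and putamen DAT <= 40% of normal mean); subjects are
classed into high / intermediate / low risk zones by which measures are
already abnormal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, DomainError, InvalidConfigError

__all__ = [
    "DATMeasure",
    "PredictorConfig",
    "PredictionResult",
    "dat_sor",
    "dat_percent_normal",
    "predict_conversion_time",
    "risk_class",
    "summarize_predictions",
    "baseline_time_correlation",
    "conversion_percentage",
    "plot_risk_plane",
]


@dataclass
class DATMeasure:
    """Per-subject DAT binding at one timepoint."""

    subject_id: str
    timepoint: float
    putamen_sor: float
    caudate_sor: float
    putamen_pct: float | None = None
    caudate_pct: float | None = None


@dataclass
class PredictorConfig:
    """Rates and thresholds for the dual-threshold predictor.

    Rates are positive magnitudes: expression rises by ``pdrp_rate``
    z-points/year, putamen DAT falls by ``dat_rate`` %-points of the healthy
    mean per year.  ``pdrp_abnormal_z`` / ``dat_abnormal_pct`` are the softer
    cutoffs delimiting the intermediate/low risk zones.
    """

    pdrp_rate: float = 0.23
    dat_rate: float = 4.8
    pdrp_threshold: float = 1.5
    dat_threshold: float = 40.0
    pdrp_abnormal_z: float = 1.0
    dat_abnormal_pct: float = 80.0

    def __post_init__(self) -> None:
        if self.pdrp_rate <= 0 or self.dat_rate <= 0:
            raise InvalidConfigError("progression rates must be positive magnitudes")
        if not 0 < self.dat_threshold < 100:
            raise InvalidConfigError("dat_threshold must lie in (0, 100)")


@dataclass
class PredictionResult:
    """Years to each threshold plus the joint (max) prediction."""

    subject_id: str
    t_pdrp: float
    t_dat: float
    t_predicted: float
    risk_class: str


def dat_sor(striatal_counts: float, occipital_counts: float) -> float:
    """Striatal-to-occipital ratio (striatum - occipital)/occipital."""
    if occipital_counts <= 0:
        raise DomainError("occipital counts must be positive")
    return (striatal_counts - occipital_counts) / occipital_counts


def dat_percent_normal(sor: float, hc_mean_sor: float) -> float:
    """Express an SOR as a percentage of the healthy-control mean SOR."""
    if hc_mean_sor <= 0:
        raise DomainError("healthy-control mean SOR must be positive")
    return 100.0 * sor / hc_mean_sor


def predict_conversion_time(
    pdrp_z: float,
    putamen_pct: float,
    config: PredictorConfig = PredictorConfig(),
    subject_id: str = "",
) -> PredictionResult:
    """Linear extrapolation to the crossing of both early-disease thresholds.

    ``t_pdrp = max(0, (z_threshold - z)/rate_z)`` and
    ``t_dat = max(0, (pct - pct_threshold)/rate_dat)``; the predicted time is
    their maximum (both thresholds must be crossed).  Crossing is inclusive:
    a subject on either boundary needs 0 years for that measure.
    """
    if not (np.isfinite(pdrp_z) and np.isfinite(putamen_pct)):
        raise DomainError("inputs must be finite")
    t_pdrp = max(0.0, (config.pdrp_threshold - pdrp_z) / config.pdrp_rate)
    t_dat = max(0.0, (putamen_pct - config.dat_threshold) / config.dat_rate)
    return PredictionResult(
        subject_id=subject_id,
        t_pdrp=t_pdrp,
        t_dat=t_dat,
        t_predicted=max(t_pdrp, t_dat),
        risk_class=risk_class(pdrp_z, putamen_pct, config),
    )


def risk_class(
    pdrp_z: float,
    putamen_pct: float,
    config: PredictorConfig = PredictorConfig(),
) -> str:
    """high: both measures abnormal; low: neither; intermediate: exactly one."""
    ab_z = pdrp_z > config.pdrp_abnormal_z
    ab_dat = putamen_pct < config.dat_abnormal_pct
    if ab_z and ab_dat:
        return "high"
    if not ab_z and not ab_dat:
        return "low"
    return "intermediate"


def summarize_predictions(predicted, observed=None) -> dict:
    """Summary statistics of predicted (and optionally observed) times.

    Returns means/SDs and, when observed times are supplied, the per-subject
    errors (predicted - observed) and their extrema.
    """
    predicted = np.asarray(predicted, dtype=float)
    out = {
        "n": int(predicted.size),
        "predicted_mean": float(predicted.mean()),
        "predicted_sd": float(predicted.std(ddof=1)) if predicted.size > 1 else math.nan,
    }
    if observed is not None:
        observed = np.asarray(observed, dtype=float)
        if observed.size != predicted.size:
            raise DomainError("predicted and observed must have equal length")
        err = predicted - observed
        out.update(
            observed_mean=float(observed.mean()),
            observed_sd=float(observed.std(ddof=1)) if observed.size > 1 else math.nan,
            errors=err.tolist(),
            max_error=float(err.max()),
            min_error=float(err.min()),
            mean_abs_error=float(np.abs(err).mean()),
        )
    return out


def conversion_percentage(n_converted: int, n_total: int) -> float:
    """Phenoconversion proportion as a percentage."""
    if not 0 <= n_converted <= n_total or n_total <= 0:
        raise DomainError("need 0 <= n_converted <= n_total, n_total > 0")
    return 100.0 * n_converted / n_total


@dataclass
class BaselineCorrelation:
    """Baseline expression vs time-to-conversion association."""

    r: float
    p: float
    partial_r: float
    partial_p: float
    n: int
    coefficients: dict


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def baseline_time_correlation(
    scores,
    conversion_times,
    covariates: pd.DataFrame | None = None,
) -> BaselineCorrelation:
    """Pearson and covariate-adjusted partial correlation of baseline scores
    with time to phenoconversion.

    The partial correlation uses the leverage-residual form: both score and
    time are residualised on the covariates (plus intercept) and the Pearson
    correlation of the residuals is tested on n - k - 2 degrees of freedom.
    With no covariates the partial correlation equals the simple one.
    Exactly collinear covariates raise an error naming the offenders.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(conversion_times, dtype=float)
    keep = np.isfinite(s) & np.isfinite(t)
    if covariates is not None and len(covariates):
        cov = covariates.reset_index(drop=True)
        keep &= np.isfinite(cov.to_numpy(dtype=float)).all(axis=1)
        cov = cov.loc[keep]
    else:
        cov = None
    s, t = s[keep], t[keep]
    n = s.size
    if n < 5:
        raise DegenerateDataError("need >= 5 complete observations")
    r, p = stats.pearsonr(s, t)
    if cov is not None and cov.shape[1]:
        X = np.column_stack([np.ones(n), cov.to_numpy(dtype=float)])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            names = list(cov.columns)
            bad = []
            for j in range(1, X.shape[1]):
                rest = np.delete(X, j, axis=1)
                resid = _residualize(X[:, j], rest)
                if float(resid @ resid) < 1e-10 * max(1.0, float(X[:, j] @ X[:, j])):
                    bad.append(names[j - 1])
            raise DomainError(f"collinear covariates: {bad or names}")
        rs = _residualize(s, X)
        rt = _residualize(t, X)
        k = cov.shape[1]
    else:
        X = np.ones((n, 1))
        rs, rt = s - s.mean(), t - t.mean()
        k = 0
    denom = math.sqrt(float(rs @ rs) * float(rt @ rt))
    if denom == 0:
        raise DegenerateDataError("zero residual variance in partial correlation")
    pr = float(rs @ rt) / denom
    dof = n - k - 2
    if dof < 1:
        raise DegenerateDataError("insufficient df for partial correlation")
    pr = max(-1.0, min(1.0, pr))
    if abs(pr) == 1.0:
        pp = 0.0
    else:
        tt = pr * math.sqrt(dof / (1 - pr**2))
        pp = 2 * float(stats.t.sf(abs(tt), dof))
    # full multiple-regression coefficients of time on score + covariates
    Xfull = np.column_stack([np.ones(n), s] + ([cov.to_numpy(dtype=float)] if k else []))
    beta, *_ = np.linalg.lstsq(Xfull, t, rcond=None)
    names = ["intercept", "score"] + (list(cov.columns) if k else [])
    return BaselineCorrelation(
        r=float(r),
        p=float(p),
        partial_r=pr,
        partial_p=pp,
        n=n,
        coefficients=dict(zip(names, beta.tolist())),
    )


def plot_risk_plane(
    states: pd.DataFrame,
    config: PredictorConfig = PredictorConfig(),
    ax=None,
):
    """Scatter final-scan states on the (putamen DAT %, expression z) plane
    with the early-disease zone shaded.  ``states`` needs columns ``pdrp_z``
    and ``putamen_pct``; an optional boolean ``converted`` column styles the
    markers."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    conv = states.get("converted", pd.Series(False, index=states.index))
    ax.axvspan(0, config.dat_threshold, ymin=0, color="0.85", zorder=0)
    ax.axvline(config.dat_threshold, color="k", lw=1)
    ax.axhline(config.pdrp_threshold, color="k", lw=1)
    ax.scatter(
        states.loc[~conv, "putamen_pct"], states.loc[~conv, "pdrp_z"],
        facecolors="none", edgecolors="k", label="non-converter",
    )
    ax.scatter(
        states.loc[conv, "putamen_pct"], states.loc[conv, "pdrp_z"],
        color="k", label="converter",
    )
    ax.set_xlabel("putamen DAT binding (% of normal mean)")
    ax.set_ylabel("motor pattern expression (z)")
    ax.invert_xaxis()
    ax.legend(frameon=False, fontsize=8)
    return ax
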