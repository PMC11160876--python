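"""Spatial-covariance pattern expression scoring.

A *network pattern* is a region-weighted topography (for Parkinson's disease the
motor PDRP and cognitive PDCP patterns).  A subject's *expression score* is the
inner product of the pattern weights with the subject's centred log regional
metabolic profile, and scores are standardised (z-scored) against a healthy
reference group so that controls score 0 +/- 1 by construction.

The module also provides global-metabolic-rate (GMR) ratio normalisation and a
simple two-sample nodal comparison of regional activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CalibrationError, DegenerateDataError, DomainError, LabelMismatchError

__all__ = [
    "RegionalProfileSet",
    "NetworkPattern",
    "ScoreSet",
    "NodalComparison",
    "gmr_normalize",
    "compute_raw_scores",
    "calibrate_and_zscore",
    "score_profiles",
    "nodal_compare",
]


@dataclass
class RegionalProfileSet:
    """Subjects x regions table of strictly positive regional metabolic activity.

    Parameters
    ----------
    values
        DataFrame with one row per subject (index = subject ids) and one
        column per region label.  All entries must be finite and > 0.
    group
        Free-text group tag (e.g. ``"HC"`` or ``"case"``).
    timepoint
        Scan time in years from baseline.
    """

    values: pd.DataFrame
    group: str = ""
    timepoint: float = 0.0

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise DomainError(f"duplicate region labels: {dups}")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            rows, cols = np.nonzero(np.isnan(arr))
            raise DomainError(
                f"missing value at subject {self.values.index[rows[0]]!r}, "
                f"region {self.values.columns[cols[0]]!r}"
            )
        if (arr <= 0).any():
            rows, cols = np.nonzero(arr <= 0)
            raise DomainError(
                f"non-positive activity at subject {self.values.index[rows[0]]!r}, "
                f"region {self.values.columns[cols[0]]!r}"
            )

    @property
    def subject_ids(self) -> list:
        return list(self.values.index)

    @property
    def region_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.values)


@dataclass
class NetworkPattern:
    """Region-weighted covariance topography with optional reference moments.

    ``weights`` is indexed by the pattern's *membership* regions (its nodes);
    regions outside the membership carry an implicit weight of zero.  ``core``
    marks the high-|weight| core-zone nodes, ``active`` the nodes whose group
    mean activity exceeds the healthy mean (set by
    :func:`netprog.connectivity.classify_nodes`).  ``reference_mean``/``sd``
    are the raw-score moments of the healthy reference group, set during
    calibration.
    """

    name: str
    weights: pd.Series
    core: frozenset = frozenset()
    active: frozenset | None = None
    reference_mean: float | None = None
    reference_sd: float | None = None

    def __post_init__(self) -> None:
        w = self.weights.to_numpy(dtype=float)
        if not np.all(np.isfinite(w)):
            raise DomainError(f"pattern {self.name!r} has non-finite weights")
        if self.reference_sd is not None and self.reference_sd <= 0:
            raise CalibrationError(f"pattern {self.name!r}: reference sd must be > 0")

    @property
    def membership(self) -> list[str]:
        return list(self.weights.index)

    @property
    def calibrated(self) -> bool:
        return self.reference_mean is not None and self.reference_sd is not None


@dataclass
class ScoreSet:
    """Per-subject raw and z-scored expression values for one pattern/timepoint."""

    subject_ids: list
    raw: np.ndarray
    pattern: str
    timepoint: float = 0.0
    z: np.ndarray | None = None
    reference_mean: float | None = None
    reference_sd: float | None = None
    sd_convention: str = "sample (ddof=1)"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject_ids,
                "timepoint": self.timepoint,
                "pattern": self.pattern,
                "raw": self.raw,
                "z": self.z if self.z is not None else np.nan,
            }
        )


@dataclass
class NodalComparison:
    """Two-sample comparison of GMR-normalised activity in one region."""

    region: str
    mean_case: float
    mean_hc: float
    t: float
    p: float
    n_case: int
    n_hc: int


def gmr_normalize(profiles: RegionalProfileSet) -> RegionalProfileSet:
    """Divide each subject's regional values by that subject's global mean.

    After normalisation every row has mean exactly 1; this removes global
    metabolic-rate differences between subjects before nodal or connectivity
    analysis.
    """
    vals = profiles.values
    normed = vals.div(vals.mean(axis=1), axis=0)
    return replace(profiles, values=normed)


def _log_membership(profiles: RegionalProfileSet, pattern: NetworkPattern) -> pd.DataFrame:
    missing = [r for r in pattern.membership if r not in profiles.values.columns]
    if missing:
        raise LabelMismatchError(
            f"profiles lack pattern {pattern.name!r} regions: {missing[:5]}"
        )
    sub = profiles.values[pattern.membership]
    return np.log(sub)


def compute_raw_scores(
    profiles: RegionalProfileSet,
    pattern: NetworkPattern,
    reference_profiles: RegionalProfileSet,
) -> ScoreSet:
    """Topographic-profile raw expression scores for one pattern.

    For each subject the log profile over the pattern's membership regions is
    centred by its own mean (removing residual global scaling), the healthy
    reference group's mean centred log profile is subtracted, and the residual
    is projected onto the pattern weights:

    ``raw_s = sum_r w_r * (q_{s,r} - qbar_s - ref_r)``

    Because the weights are zero-mean over the membership the subject-mean
    centring leaves scores invariant to adding any constant to a subject's
    log profile.
    """
    if reference_profiles.n_subjects == 0:
        raise DomainError("reference profile set is empty")
    q = _log_membership(profiles, pattern)
    q = q.sub(q.mean(axis=1), axis=0)
    ref = _log_membership(reference_profiles, pattern)
    ref = ref.sub(ref.mean(axis=1), axis=0)
    resid = q - ref.mean(axis=0)
    w = pattern.weights.reindex(q.columns).to_numpy(dtype=float)
    raw = resid.to_numpy(dtype=float) @ w
    return ScoreSet(
        subject_ids=profiles.subject_ids,
        raw=raw,
        pattern=pattern.name,
        timepoint=profiles.timepoint,
    )


def calibrate_and_zscore(
    case_scores: ScoreSet | list[ScoreSet],
    hc_scores: ScoreSet,
    ddof: int = 1,
) -> tuple[list[ScoreSet], ScoreSet, float, float]:
    """Set reference moments from healthy raw scores and z-transform both sets.

    The healthy reference must contain at least 3 subjects with non-zero
    raw-score variance.  The sample-SD convention (``ddof=1``) is the default;
    the convention used is recorded on every returned :class:`ScoreSet`.

    Returns ``(case_sets, hc_set, reference_mean, reference_sd)``.
    """
    if len(pd.unique(np.asarray(hc_scores.subject_ids))) < 3:
        raise CalibrationError("need >= 3 healthy reference subjects")
    mean = float(np.mean(hc_scores.raw))
    sd = float(np.std(hc_scores.raw, ddof=ddof))
    if sd <= 0 or not np.isfinite(sd):
        raise CalibrationError("healthy reference raw scores have zero variance")
    single = isinstance(case_scores, ScoreSet)
    case_list = [case_scores] if single else list(case_scores)
    convention = f"sample (ddof={ddof})" if ddof else "population (ddof=0)"

    def _z(s: ScoreSet) -> ScoreSet:
        return replace(
            s,
            z=(s.raw - mean) / sd,
            reference_mean=mean,
            reference_sd=sd,
            sd_convention=convention,
        )

    return [_z(s) for s in case_list], _z(hc_scores), mean, sd


def score_profiles(
    case_profile_sets: list[RegionalProfileSet],
    hc_profiles: RegionalProfileSet,
    pattern: NetworkPattern,
    ddof: int = 1,
) -> tuple[list[ScoreSet], ScoreSet, NetworkPattern]:
    """Convenience wrapper: raw-score all sets against HC, then z-score.

    Returns the z-scored case score sets, the z-scored HC self-scores, and a
    copy of the pattern carrying the calibrated reference moments.
    """
    hc_raw = compute_raw_scores(hc_profiles, pattern, hc_profiles)
    case_raw = [compute_raw_scores(p, pattern, hc_profiles) for p in case_profile_sets]
    case_z, hc_z, mean, sd = calibrate_and_zscore(case_raw, hc_raw, ddof=ddof)
    calibrated = replace(pattern, reference_mean=mean, reference_sd=sd)
    return case_z, hc_z, calibrated


def nodal_compare(
    case_profiles: RegionalProfileSet,
    hc_profiles: RegionalProfileSet,
    region: str,
) -> NodalComparison:
    """Two-sample pooled-variance t-test of one region's normalised activity."""
    for ps, tag in ((case_profiles, "case"), (hc_profiles, "HC")):
        if region not in ps.values.columns:
            raise LabelMismatchError(f"region {region!r} absent from {tag} profiles")
        if ps.n_subjects < 2:
            raise DegenerateDataError(f"{tag} group has n < 2")
    a = case_profiles.values[region].to_numpy(dtype=float)
    b = hc_profiles.values[region].to_numpy(dtype=float)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            raise DegenerateDataError(
                f"region {region!r}: zero within-group variance with unequal means"
            )
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
        t, p = float(t), float(p)
    return NodalComparison(
        region=region,
        mean_case=float(a.mean()),
        mean_hc=float(b.mean()),
        t=t,
        p=p,
        n_case=len(a),
        n_hc=len(b),
    )
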