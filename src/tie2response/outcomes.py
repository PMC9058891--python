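"""Survival analysis and trial-design support for vascular-response groups.

Relates response categories to progression-free and overall survival with a
Cox proportional-hazards model, checking the proportional-hazards assumption
on scaled Schoenfeld residuals; when the assumption fails, the headline
effect is reported as a restricted-mean-survival-time (RMST) ratio instead of
a hazard ratio.  Also provides the median-dichotomised chi-square association
test used for baseline characteristics, and the Schoenfeld log-rank events
formula for sizing a response-stratified phase II design.

Times are handled in days internally; 1 month = 30.4375 days for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test
from scipy.stats import chi2_contingency, norm

DAYS_PER_MONTH = 30.4375


class NonEstimableError(ValueError):
    """The survival contrast cannot be estimated (no events, separation, ...)."""


class InvalidTauError(ValueError):
    """Requested RMST truncation time exceeds a group's observed follow-up."""


@dataclass(frozen=True)
class SurvivalResult:
    """Group contrast on a time-to-event endpoint.

    ``hr`` compares the non-reference group with the reference; ``ph_ok``
    reports the scaled-Schoenfeld-residual proportional-hazards check at
    alpha = 0.05.  When ``ph_ok`` is False the RMST ratio (non-reference /
    reference, truncated at ``tau_days``) is filled in as the headline
    effect, mirroring the non-proportional-hazards fallback.
    """

    hr: float
    ci_low: float
    ci_high: float
    p: float
    ph_ok: bool
    rmst_ratio: Optional[float] = None
    rmst_ci: Optional[tuple[float, float]] = None
    tau_days: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("hazard-ratio CI must bracket the estimate")
        if (self.rmst_ratio is not None) == self.ph_ok:
            raise ValueError("rmst_ratio must be present exactly when ph_ok is False")


@dataclass(frozen=True)
class SampleSizeResult:
    n_patients: int
    n_events: float
    response_prevalence: float
    hr: float
    alpha: float
    power: float
    event_fraction: float
    rounding: str = "nearest"


def cox_hr(
    records: pd.DataFrame,
    duration_col: str = "time_days",
    event_col: str = "event",
    group_col: str = "group",
    reference: Optional[str] = None,
    adjustment_covariates: Sequence[str] = (),
    ph_alpha: float = 0.05,
) -> SurvivalResult:
    """Cox partial-likelihood hazard ratio for a two-group contrast.

    Parameters
    ----------
    records : DataFrame
        One row per patient with duration, event flag (1 = event), the group
        label and any adjustment covariates (numeric).
    reference : str, optional
        Group label used as the baseline; defaults to the lexicographically
        first label.  The returned HR is non-reference vs reference.
    ph_alpha : float
        Significance level of the proportional-hazards check.

    When proportional hazards is rejected, the result carries the RMST ratio
    (non-reference / reference) at the automatic truncation time.
    """
    groups = sorted(records[group_col].astype(str).unique())
    if len(groups) != 2:
        raise NonEstimableError(f"need exactly 2 groups, got {groups}")
    ref = reference if reference is not None else groups[0]
    if ref not in groups:
        raise NonEstimableError(f"reference {ref!r} not among groups {groups}")
    other = [g for g in groups if g != ref][0]

    df = records[[duration_col, event_col, *adjustment_covariates]].copy()
    df["_group"] = (records[group_col].astype(str) == other).astype(float)
    events_per_group = records.groupby(records[group_col].astype(str))[event_col].sum()
    if (events_per_group < 1).any():
        raise NonEstimableError(f"each group needs >= 1 event, got {events_per_group.to_dict()}")

    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise NonEstimableError(f"Cox fit failed: {exc}") from exc

    row = cph.summary.loc["_group"]
    hr = float(row["exp(coef)"])
    ci_low = float(row["exp(coef) lower 95%"])
    ci_high = float(row["exp(coef) upper 95%"])
    p = float(row["p"])

    ph = proportional_hazard_test(cph, df, time_transform="rank")
    ph_p = float(np.atleast_1d(ph.summary.loc["_group", "p"]).min())
    ph_ok = bool(ph_p >= ph_alpha)

    if ph_ok:
        return SurvivalResult(hr, ci_low, ci_high, p, True)

    ratio, rmst_ci, tau = rmst_ratio(
        records, duration_col=duration_col, event_col=event_col,
        group_col=group_col, reference=ref,
    )
    return SurvivalResult(hr, ci_low, ci_high, p, False,
                          rmst_ratio=ratio, rmst_ci=rmst_ci, tau_days=tau)


def _km_rmst(durations: np.ndarray, events: np.ndarray, tau: float) -> tuple[float, float]:
    """RMST and its large-sample variance from the Kaplan-Meier curve.

    The RMST is the exact area under the KM step function up to tau; the
    variance is the standard Greenwood-type estimator
    sum_j A_j^2 d_j / (n_j (n_j - d_j)) with A_j the area under the curve
    from event time t_j to tau.
    """
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events)
    table = kmf.event_table
    times = table.index.to_numpy(float)
    observed = table["observed"].to_numpy(float)
    at_risk = table["at_risk"].to_numpy(float)

    keep = (times <= tau) & (observed > 0)
    t_ev = times[keep]
    d = observed[keep]
    n = at_risk[keep]
    surv = np.cumprod(1.0 - d / n)  # S at each event time, left-continuous steps

    # area under the step function on [0, tau]
    grid = np.concatenate([[0.0], t_ev, [tau]])
    heights = np.concatenate([[1.0], surv])
    widths = np.diff(grid)
    rmst = float(np.sum(heights * widths))

    # A_j: area from t_j to tau
    seg = heights * widths  # segment areas; seg[k] spans [grid[k], grid[k+1])
    tail = np.cumsum(seg[::-1])[::-1]
    a = tail[1:]  # area from t_ev[j] to tau
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, a**2 * d / (n * (n - d)), 0.0)
    return rmst, float(np.sum(terms))


def rmst_ratio(
    records: pd.DataFrame,
    duration_col: str = "time_days",
    event_col: str = "event",
    group_col: str = "group",
    reference: Optional[str] = None,
    tau_days: Optional[float] = None,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float], float]:
    """Ratio of restricted mean survival times (non-reference / reference).

    The RMST is the area under each group's Kaplan-Meier curve truncated at
    tau; tau defaults to the lesser of the two groups' maximum observed
    times so both curves are supported.  The CI comes from the large-sample
    RMST variance via the delta method on the log ratio.

    Raises
    ------
    InvalidTauError
        If an explicit tau exceeds either group's observed follow-up.
    """
    groups = sorted(records[group_col].astype(str).unique())
    if len(groups) != 2:
        raise NonEstimableError(f"need exactly 2 groups, got {groups}")
    ref = reference if reference is not None else groups[0]
    other = [g for g in groups if g != ref][0]

    max_obs = {
        g: float(records.loc[records[group_col].astype(str) == g, duration_col].max())
        for g in groups
    }
    tau = float(tau_days) if tau_days is not None else min(max_obs.values())
    if tau > min(max_obs.values()) + 1e-12:
        raise InvalidTauError(
            f"tau {tau} exceeds observed follow-up {min(max_obs.values())} in one group"
        )

    est: dict[str, tuple[float, float]] = {}
    for g in (ref, other):
        sub = records[records[group_col].astype(str) == g]
        est[g] = _km_rmst(sub[duration_col].to_numpy(float),
                          sub[event_col].to_numpy(float), tau)

    r_ref, v_ref = est[ref]
    r_other, v_other = est[other]
    ratio = r_other / r_ref
    # delta method on log(ratio)
    se_log = math.sqrt(v_other / r_other**2 + v_ref / r_ref**2) if r_ref > 0 and r_other > 0 else float("inf")
    z = norm.ppf(1 - alpha / 2)
    ci = (ratio * math.exp(-z * se_log), ratio * math.exp(z * se_log))
    return float(ratio), (float(ci[0]), float(ci[1])), tau


@dataclass(frozen=True)
class AssociationResult:
    statistic: float
    p: float
    table: pd.DataFrame
    unreliable: bool


def dichotomise_at_median(values: Sequence[float]) -> np.ndarray:
    """Split continuous values at their median; ties go to the lower group."""
    x = np.asarray(values, dtype=float)
    med = float(np.median(x))
    return np.where(x <= med, "low", "high")


def baseline_association(values: Sequence, characteristic: Sequence) -> AssociationResult:
    """Chi-square association after median dichotomisation of continuous input.

    ``values`` may be numeric (dichotomised at the median, ties to the lower
    group) or already categorical; ``characteristic`` is categorical.  The
    Pearson statistic is computed without continuity correction.  Any
    expected cell below 1 sets ``unreliable`` (the statistic is still
    returned).
    """
    v = np.asarray(values)
    if np.issubdtype(v.dtype, np.number):
        v = dichotomise_at_median(v)
    c = np.asarray(characteristic).astype(str)
    table = pd.crosstab(pd.Series(v, name="value"), pd.Series(c, name="characteristic"))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("association needs >= 2 categories on each axis")
    stat, p, _, expected = chi2_contingency(table.to_numpy(), correction=False)
    return AssociationResult(float(stat), float(p), table, bool((expected < 1).any()))


def schoenfeld_sample_size(
    response_prevalence: float,
    hr: float,
    alpha: float = 0.05,
    power: float = 0.80,
    event_fraction: float = 0.80,
    rounding: str = "nearest",
) -> SampleSizeResult:
    """Patients needed to compare responders vs non-responders on survival.

    Schoenfeld's log-rank events formula with allocation p : (1 - p), where
    p is the responder prevalence:

        events = (z_{1-alpha/2} + z_{power})**2 / (p (1 - p) (ln hr)**2)

    Patients = events / event_fraction, rounded per ``rounding`` ("nearest",
    the default, or "ceil"; the two differ by at most one patient).

    Raises
    ------
    ValueError
        For hr = 1 (infinite sample size) or arguments out of range.
    """
    p = response_prevalence
    if not (0 < p < 1):
        raise ValueError("response_prevalence must lie in (0, 1)")
    if hr <= 0:
        raise ValueError("hr must be positive")
    if hr == 1:
        raise ValueError("hr = 1 implies an infinite sample size")
    if not (0 < event_fraction <= 1):
        raise ValueError("event_fraction must lie in (0, 1]")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")

    z_a = norm.ppf(1 - alpha / 2)
    z_b = norm.ppf(power)
    n_events = (z_a + z_b) ** 2 / (p * (1 - p) * math.log(hr) ** 2)
    raw_patients = n_events / event_fraction
    if rounding == "nearest":
        n_patients = int(round(raw_patients))
    elif rounding == "ceil":
        n_patients = int(math.ceil(raw_patients))
    else:
        raise ValueError(f"unknown rounding {rounding!r}")
    return SampleSizeResult(
        n_patients=n_patients, n_events=float(n_events),
        response_prevalence=p, hr=hr, alpha=alpha, power=power,
        event_fraction=event_fraction, rounding=rounding,
    )
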