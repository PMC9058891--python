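"""Nadir-rise progression rules and lead-time detection.

A marker-defined progression event (vPD for the vascular marker Tie2, ePD for
an epithelial marker such as CK18 or CA125) is called at the first visit at
which the concentration has risen by a configured fraction above the running
nadir of all *strictly earlier* measurements (pre-treatment draws included).
Default rise fractions: 40% for Tie2, 50% for CK18.  The vascular and
epithelial calls combine by OR — the combined trigger is the earliest single
trigger — and a patient's progression counts as *detected at lead L* when the
trigger precedes the radiological progression day by at least L days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from statsmodels.stats.contingency_tables import mcnemar

from .trajectories import BiomarkerSeries, UnevaluableSeriesError

COMBINED = "combined"
DEFAULT_RISE = {"TIE2": 0.40, "CK18": 0.50, "CA125": 0.50}


@dataclass(frozen=True)
class ProgressionRule:
    """Rise-from-nadir rule for one marker.

    ``rise_fraction`` 0.40 means trigger at >= 1.4x the running nadir;
    ``confirmations_required`` > 1 demands that many consecutive qualifying
    visits (trigger day = first visit of the run); ``require_prior_vcr``
    gates the call on a previously attained vascular complete response.
    """

    marker: str
    rise_fraction: float = 0.40
    confirmations_required: int = 1
    require_prior_vcr: bool = False

    def __post_init__(self) -> None:
        if not self.rise_fraction > 0:
            raise ValueError("rise_fraction must be positive")
        if self.confirmations_required < 1:
            raise ValueError("confirmations_required must be >= 1")


@dataclass(frozen=True)
class ProgressionCall:
    patient_id: str
    marker: str
    triggered: bool
    trigger_day: Optional[int]
    nadir_value: float
    nadir_day: int


@dataclass(frozen=True)
class DetectionSummary:
    """Detection counts at one fixed lead before radiological progression."""

    lead_days: int
    n_progressors: int
    detected: Mapping[str, int] = field(default_factory=dict)
    fraction: Mapping[str, float] = field(default_factory=dict)


def detect_marker_progression(
    series: BiomarkerSeries,
    rule: ProgressionRule,
    response_category: Optional[str] = None,
) -> ProgressionCall:
    """Scan one series for the first sustained rise above the running nadir.

    At each visit t with at least one strictly earlier measurement, the visit
    qualifies when concentration(t) >= (1 + rise_fraction) * min(concentration
    over days < t); the boundary is inclusive (exactly 1.4x the nadir triggers
    a 40% rule).  With ``confirmations_required`` = k the call needs k
    consecutive qualifying visits and reports the first of them.

    ``response_category`` is consulted only when ``rule.require_prior_vcr``
    is set: anything other than ``"vCR"`` suppresses the call.

    Raises
    ------
    UnevaluableSeriesError
        If the series has fewer than two measurements.
    """
    days = series.days
    conc = series.concentrations
    if days.size < 2:
        raise UnevaluableSeriesError(
            f"progression scan needs >= 2 measurements for {series.patient_id}/{series.marker}"
        )

    gated = rule.require_prior_vcr and response_category != "vCR"

    running_min = np.minimum.accumulate(conc)
    overall_nadir_idx = int(np.argmin(conc))

    if not gated:
        qualifies = conc[1:] >= (1.0 + rule.rise_fraction) * running_min[:-1]
        run = 0
        for i, q in enumerate(qualifies, start=1):
            run = run + 1 if q else 0
            if run >= rule.confirmations_required:
                first = i - rule.confirmations_required + 1
                nadir_idx = int(np.argmin(conc[:first]))
                return ProgressionCall(
                    patient_id=series.patient_id,
                    marker=series.marker,
                    triggered=True,
                    trigger_day=int(days[first]),
                    nadir_value=float(conc[nadir_idx]),
                    nadir_day=int(days[nadir_idx]),
                )

    return ProgressionCall(
        patient_id=series.patient_id,
        marker=series.marker,
        triggered=False,
        trigger_day=None,
        nadir_value=float(conc[overall_nadir_idx]),
        nadir_day=int(days[overall_nadir_idx]),
    )


def combine_progression_calls(calls: Sequence[ProgressionCall]) -> ProgressionCall:
    """OR-combination across markers: triggered iff any input triggered.

    The combined trigger day is the earliest trigger among triggered inputs,
    and the nadir fields are carried from the call supplying that trigger
    (from the first input when nothing triggered).

    Raises
    ------
    UnevaluableSeriesError
        On empty input or mixed patient ids.
    """
    calls = list(calls)
    if not calls:
        raise UnevaluableSeriesError("cannot combine an empty set of progression calls")
    pids = {c.patient_id for c in calls}
    if len(pids) != 1:
        raise ValueError(f"progression calls from different patients: {sorted(pids)}")

    triggered = [c for c in calls if c.triggered]
    if triggered:
        winner = min(triggered, key=lambda c: c.trigger_day)
        return ProgressionCall(winner.patient_id, COMBINED, True, winner.trigger_day,
                               winner.nadir_value, winner.nadir_day)
    first = calls[0]
    return ProgressionCall(first.patient_id, COMBINED, False, None,
                           first.nadir_value, first.nadir_day)


def lead_time_detection(
    calls_by_set: Mapping[str, Mapping[str, ProgressionCall]],
    rad_pd_day: Mapping[str, Optional[float]],
    lead_days: int,
) -> DetectionSummary:
    """Fraction of radiological progressors detected ``lead_days`` in advance.

    Parameters
    ----------
    calls_by_set : mapping
        Marker-set label (e.g. "vascular", "epithelial", "combined") ->
        {patient_id: ProgressionCall}.  Patients absent from a set count as
        not detected by it.
    rad_pd_day : mapping
        patient_id -> radiological progression day, or None/NaN when no
        radiological progression was recorded (those patients are excluded).
    lead_days : int
        A patient is detected when trigger_day <= rad_pd_day - lead_days.
    """
    progressors = [
        pid for pid, day in rad_pd_day.items()
        if day is not None and not (isinstance(day, float) and math.isnan(day))
    ]
    n = len(progressors)
    detected: dict[str, int] = {}
    fraction: dict[str, float] = {}
    for label, calls in calls_by_set.items():
        count = 0
        for pid in progressors:
            call = calls.get(pid)
            if call is not None and call.triggered and call.trigger_day is not None:
                if call.trigger_day <= rad_pd_day[pid] - lead_days:
                    count += 1
        detected[label] = count
        fraction[label] = count / n if n else float("nan")
    return DetectionSummary(lead_days=int(lead_days), n_progressors=n,
                            detected=detected, fraction=fraction)


def detection_indicators(
    calls: Mapping[str, ProgressionCall],
    rad_pd_day: Mapping[str, Optional[float]],
    lead_days: int,
) -> dict[str, bool]:
    """Per-progressor detection indicator for one marker set at one lead."""
    out: dict[str, bool] = {}
    for pid, day in rad_pd_day.items():
        if day is None or (isinstance(day, float) and math.isnan(day)):
            continue
        call = calls.get(pid)
        out[pid] = bool(
            call is not None and call.triggered
            and call.trigger_day is not None and call.trigger_day <= day - lead_days
        )
    return out


def compare_detection_fractions(
    detected_a: Sequence[bool], detected_b: Sequence[bool]
) -> tuple[float, float, bool]:
    """Exact McNemar test on paired detection indicators.

    Returns (statistic = smaller discordant count, two-sided exact p,
    degenerate) where ``degenerate`` marks the no-discordant-pairs case
    (p fixed at 1).
    """
    a = np.asarray(detected_a, dtype=bool)
    b = np.asarray(detected_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("paired indicators must have equal length")
    n10 = int(np.sum(a & ~b))
    n01 = int(np.sum(~a & b))
    if n10 + n01 == 0:
        return 0.0, 1.0, True
    table = [[int(np.sum(a & b)), n10], [n01, int(np.sum(~a & ~b))]]
    res = mcnemar(table, exact=True)
    return float(res.statistic), float(min(res.pvalue, 1.0)), False
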