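"""Longitudinal biomarker series and per-patient change summaries.

A patient's circulating biomarker (plasma Tie2, CK18, CA125, ...) is sampled
twice before treatment and then on a roughly 3-weekly visit schedule.  All
downstream analysis works on three primitives defined here:

* the **baseline**, the geometric mean of the pre-treatment draws (day <= 0);
* the **windowed log2 change**, the log2 ratio of the on-treatment sample
  closest to a target day (default day 63, i.e. nine weeks / three cycles)
  to the baseline;
* the **running nadir**, the minimum concentration observed up to a day.

Concentrations are strictly positive (pg/ml); days are integers relative to
day 0 = first treatment administration, so pre-treatment draws have day <= 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gmean

MARKER_TIE2 = "TIE2"
MARKER_CK18 = "CK18"
MARKER_CA125 = "CA125"


class UnevaluableSeriesError(ValueError):
    """A requested summary cannot be computed from the available samples."""


@dataclass(frozen=True)
class Measurement:
    """One blood draw: integer day from first treatment, concentration in pg/ml."""

    day: int
    concentration: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.day):
            raise ValueError(f"day must be finite, got {self.day}")
        if int(self.day) != self.day:
            raise ValueError(f"day must be an integer (visit-based sampling), got {self.day}")
        if not (np.isfinite(self.concentration) and self.concentration > 0):
            raise ValueError(f"concentration must be positive and finite, got {self.concentration}")


@dataclass(frozen=True)
class BiomarkerSeries:
    """Time-ordered concentration trajectory of one marker in one patient."""

    patient_id: str
    marker: str
    measurements: tuple[Measurement, ...]

    def __post_init__(self) -> None:
        if len(self.measurements) == 0:
            raise ValueError("a series needs at least one measurement")
        days = [m.day for m in self.measurements]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(
                f"measurement days must be strictly increasing for {self.patient_id}/{self.marker}: {days}"
            )

    @property
    def days(self) -> np.ndarray:
        return np.array([m.day for m in self.measurements], dtype=int)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([m.concentration for m in self.measurements], dtype=float)

    @classmethod
    def from_arrays(cls, patient_id: str, marker: str,
                    days: Sequence[int], concentrations: Sequence[float]) -> "BiomarkerSeries":
        order = np.argsort(np.asarray(days))
        ms = tuple(Measurement(int(np.asarray(days)[i]), float(np.asarray(concentrations)[i]))
                   for i in order)
        return cls(patient_id, marker, ms)


@dataclass(frozen=True)
class ChangeSummary:
    """Per-patient on-treatment change relative to baseline.

    ``log2_change`` is log2(on-treatment / baseline); ``evaluable`` is False
    when no qualifying on-treatment sample (or no baseline) exists, in which
    case the numeric fields are NaN / undefined.
    """

    log2_change: float
    baseline: float
    evaluable: bool
    window_day_used: Optional[int] = None

    @property
    def fractional_change(self) -> float:
        """2**log2_change - 1; e.g. -0.24 is a 24% reduction."""
        return float(2.0 ** self.log2_change - 1.0) if self.evaluable else float("nan")


def baseline_value(series: BiomarkerSeries) -> float:
    """Geometric mean of all pre-treatment (day <= 0) concentrations.

    The geometric mean is the natural central value for a marker analysed on
    the log scale; with the usual two pre-treatment draws it is sqrt(c1*c2).

    Raises
    ------
    UnevaluableSeriesError
        If the series has no measurement with day <= 0.
    """
    pre = series.concentrations[series.days <= 0]
    if pre.size == 0:
        raise UnevaluableSeriesError(
            f"no pre-treatment measurement for {series.patient_id}/{series.marker}"
        )
    return float(gmean(pre))


def log2_change_over_window(
    series: BiomarkerSeries,
    target_day: int = 63,
    tolerance_days: int = 21,
    mode: str = "closest",
) -> ChangeSummary:
    """Log2 change of the on-treatment sample nearest ``target_day`` vs baseline.

    Parameters
    ----------
    target_day : int
        Nominal evaluation day; 63 is nine weeks (three 21-day cycles).
    tolerance_days : int
        A sample qualifies when 0 < day and |day - target_day| <= tolerance.
        Ties in distance resolve to the earlier day.
    mode : {"closest", "minimum"}
        "closest" uses the single qualifying sample nearest the target day;
        "minimum" instead takes the minimum concentration over on-treatment
        days in (0, target_day + tolerance_days].

    Returns an unevaluable summary (never raises) when no baseline or no
    qualifying sample exists.
    """
    try:
        base = baseline_value(series)
    except UnevaluableSeriesError:
        return ChangeSummary(float("nan"), float("nan"), False, None)

    days = series.days
    conc = series.concentrations
    if mode == "closest":
        on = (days > 0) & (np.abs(days - target_day) <= tolerance_days)
        if not on.any():
            return ChangeSummary(float("nan"), base, False, None)
        cand_days = days[on]
        cand_conc = conc[on]
        dist = np.abs(cand_days - target_day)
        # stable argmin prefers the earlier day on ties because days are sorted
        i = int(np.argmin(dist))
        sel_day, sel = int(cand_days[i]), float(cand_conc[i])
    elif mode == "minimum":
        on = (days > 0) & (days <= target_day + tolerance_days)
        if not on.any():
            return ChangeSummary(float("nan"), base, False, None)
        i = int(np.argmin(conc[on]))
        sel_day, sel = int(days[on][i]), float(conc[on][i])
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return ChangeSummary(float(np.log2(sel / base)), base, True, sel_day)


def running_nadir(series: BiomarkerSeries, upto_day: int) -> float:
    """Minimum concentration among measurements with day <= upto_day.

    Pre-treatment draws count as nadir candidates.

    Raises
    ------
    UnevaluableSeriesError
        If no measurement falls on or before ``upto_day``.
    """
    window = series.concentrations[series.days <= upto_day]
    if window.size == 0:
        raise UnevaluableSeriesError(
            f"no measurement on or before day {upto_day} for {series.patient_id}/{series.marker}"
        )
    return float(window.min())
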