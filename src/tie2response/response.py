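"""Vascular response thresholds and patient classification.

The two mixture components of the nine-week plasma-Tie2 log2-change
distribution define response cutpoints through their two-sided 95% normal
confidence bounds:

* **vCR** (vascular complete response): the fractional change is at or below
  the lower bound of the *placebo-like* component — the marker fell further
  than chemotherapy alone plausibly explains.  With placebo-like moments
  0.16 +/- 0.28 (log2) this bound is 2**(0.16 - 1.96*0.28) - 1 = -0.236,
  i.e. at least a 24% reduction after rounding.
* **vNR** (vascular no response): the change is at or above the upper bound
  of the *responder* component — the marker rose more than an effective
  anti-vascular drug plausibly allows (about a 7% increase under the default
  responder moments).
* **vPR** (vascular partial response): everything in between.

Both boundaries are inclusive toward the extreme class ("at least a 24%
reduction", "at least a 7% increase").  Classification uses unrounded cuts;
rounding to whole percent is for display only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .mixture import MixtureFit, fit_two_component_mixture
from .trajectories import BiomarkerSeries, ChangeSummary, log2_change_over_window

CATEGORIES = ("vCR", "vPR", "vNR")
UNEVALUABLE = "unevaluable"

#: Responder-component moments (log2 scale) used when no fitted responder
#: component is available.  Back-solved so that the upper 95% bound lands on
#: a +7% increase; they are a package default, not a measured quantity.
DEFAULT_RESPONDER_MEAN = -0.55
DEFAULT_RESPONDER_SD = 0.33


class InvalidThresholdsError(ValueError):
    """Component bounds cross or leave the admissible fractional-change range."""


@dataclass(frozen=True)
class ResponseThresholds:
    """Fractional-change cutpoints separating vCR / vPR / vNR.

    ``vcr_cut`` is negative (e.g. -0.24 means a 24% reduction), ``vnr_cut``
    positive (e.g. +0.07).  ``source`` records whether the placebo-like
    component came from the mixture fit or directly from placebo-arm moments.
    """

    vcr_cut: float
    vnr_cut: float
    alpha: float = 0.05
    source: str = "mixture"

    def __post_init__(self) -> None:
        if not (self.vcr_cut < self.vnr_cut):
            raise InvalidThresholdsError(
                f"vcr_cut ({self.vcr_cut}) must be below vnr_cut ({self.vnr_cut})"
            )
        if not (-1.0 < self.vcr_cut < 0.0):
            raise InvalidThresholdsError(f"vcr_cut must lie in (-1, 0), got {self.vcr_cut}")
        if not (self.vnr_cut > 0.0):
            raise InvalidThresholdsError(f"vnr_cut must be positive, got {self.vnr_cut}")
        if not (0.0 < self.alpha < 1.0):
            raise InvalidThresholdsError(f"alpha must lie in (0, 1), got {self.alpha}")

    def as_percent(self) -> tuple[int, int]:
        """(percent reduction for vCR, percent increase for vNR), display rounding."""
        return int(round(-100 * self.vcr_cut)), int(round(100 * self.vnr_cut))


@dataclass(frozen=True)
class ResponseCall:
    patient_id: str
    category: str
    fractional_change: float


def fractional_change_from_log2(log2_change: float) -> float:
    """Convert a log2 ratio to a fractional change (2**x - 1)."""
    return float(2.0 ** np.asarray(log2_change) - 1.0)


def derive_thresholds(
    mean_placebo_like: float,
    sd_placebo_like: float,
    mean_responder: float = DEFAULT_RESPONDER_MEAN,
    sd_responder: float = DEFAULT_RESPONDER_SD,
    alpha: float = 0.05,
    source: str = "mixture",
) -> ResponseThresholds:
    """Cutpoints from the two-sided (1 - alpha) normal bounds of each component.

    vcr_cut = 2**(mean_placebo_like - z * sd_placebo_like) - 1 and
    vnr_cut = 2**(mean_responder + z * sd_responder) - 1, with z the exact
    standard-normal quantile at 1 - alpha/2 (1.959964..., not 1.96).

    Raises
    ------
    InvalidThresholdsError
        If the bounds cross (pathologically overlapping components, e.g. both
        SDs zero) or fall outside the admissible range.
    """
    if sd_placebo_like < 0 or sd_responder < 0:
        raise ValueError("component SDs must be non-negative")
    z = norm.ppf(1.0 - alpha / 2.0)
    vcr = float(2.0 ** (mean_placebo_like - z * sd_placebo_like) - 1.0)
    vnr = float(2.0 ** (mean_responder + z * sd_responder) - 1.0)
    return ResponseThresholds(vcr_cut=vcr, vnr_cut=vnr, alpha=alpha, source=source)


def thresholds_from_mixture(fit: MixtureFit, alpha: float = 0.05) -> ResponseThresholds:
    """Thresholds from a fitted two-component deconvolution."""
    return derive_thresholds(
        fit.mean_placebo_like, fit.sd_placebo_like,
        fit.mean_responder, fit.sd_responder,
        alpha=alpha, source="mixture",
    )


def thresholds_from_placebo_arm(
    placebo_changes: Sequence[float],
    mean_responder: float = DEFAULT_RESPONDER_MEAN,
    sd_responder: float = DEFAULT_RESPONDER_SD,
    alpha: float = 0.05,
) -> ResponseThresholds:
    """Thresholds anchoring the placebo-like component on placebo-arm moments.

    The responder component is not observable in a placebo arm, so its
    moments must be supplied (package defaults if omitted).
    """
    x = np.asarray(list(placebo_changes), dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("placebo-arm thresholds need >= 2 finite changes")
    return derive_thresholds(
        float(x.mean()), float(x.std(ddof=1)),
        mean_responder, sd_responder,
        alpha=alpha, source="placebo_arm",
    )


def classify_response(fractional_change: float, thresholds: ResponseThresholds) -> str:
    """Map one fractional change to vCR / vPR / vNR (boundaries inclusive outward)."""
    if not np.isfinite(fractional_change):
        return UNEVALUABLE
    if fractional_change <= thresholds.vcr_cut:
        return "vCR"
    if fractional_change >= thresholds.vnr_cut:
        return "vNR"
    return "vPR"


class VascularResponseClassifier(BaseEstimator):
    """Mixture-deconvolution classifier for vascular response categories.

    ``fit`` takes the nine-week log2 changes of the VEGF-inhibitor-treated
    arm, deconvolutes them into responder and placebo-like Gaussian
    components by EM, and derives vCR/vNR cutpoints from the components'
    two-sided ``1 - alpha`` confidence bounds.  ``predict`` maps log2 changes
    to ``"vCR"``, ``"vPR"``, ``"vNR"`` (or ``"unevaluable"`` for non-finite
    input).

    Parameters
    ----------
    alpha : float, default 0.05
        Two-sided confidence level of the component bounds.
    threshold_source : {"mixture", "placebo_arm"}, default "mixture"
        Where the placebo-like component comes from.  With "mixture" the
        classifier falls back to placebo-arm moments automatically when the
        EM fit is degenerate and placebo changes were provided to ``fit``.
    n_restarts : int, default 20
        EM restarts.
    responder_mean, responder_sd : float
        Responder-component moments used whenever no usable fitted responder
        component exists (placebo_arm source, or degenerate fit).
    random_state : int, default 0
        Seed for the EM restarts.

    Attributes
    ----------
    mixture_ : MixtureFit or None
        The fitted deconvolution (None when fitted purely from placebo moments).
    thresholds_ : ResponseThresholds
        The derived cutpoints actually used by ``predict``.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        threshold_source: str = "mixture",
        n_restarts: int = 20,
        responder_mean: float = DEFAULT_RESPONDER_MEAN,
        responder_sd: float = DEFAULT_RESPONDER_SD,
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.threshold_source = threshold_source
        self.n_restarts = n_restarts
        self.responder_mean = responder_mean
        self.responder_sd = responder_sd
        self.random_state = random_state

    @staticmethod
    def _as_1d(X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise ValueError("expected a 1-d array of log2 changes (or a single column)")
        return x

    def fit(self, X, y=None, placebo_changes: Optional[Sequence[float]] = None):
        """Fit thresholds from treated-arm log2 changes ``X``.

        ``placebo_changes`` (log2 changes of a chemotherapy-only arm) is
        required for ``threshold_source="placebo_arm"`` and enables the
        degenerate-fit fallback under ``"mixture"``.
        """
        x = self._as_1d(X)
        if self.threshold_source not in ("mixture", "placebo_arm"):
            raise ValueError(f"unknown threshold_source {self.threshold_source!r}")

        self.mixture_ = None
        if self.threshold_source == "placebo_arm":
            if placebo_changes is None:
                raise ValueError("threshold_source='placebo_arm' requires placebo_changes")
            self.thresholds_ = thresholds_from_placebo_arm(
                placebo_changes, self.responder_mean, self.responder_sd, self.alpha
            )
            return self

        self.mixture_ = fit_two_component_mixture(
            x, seed=self.random_state, n_restarts=self.n_restarts
        )
        # a degenerate fit, or one whose confidence bounds leave the admissible
        # range, cannot anchor thresholds; fall back to placebo-arm moments
        usable = None
        if not self.mixture_.degenerate:
            try:
                usable = thresholds_from_mixture(self.mixture_, alpha=self.alpha)
            except InvalidThresholdsError:
                usable = None
        if usable is not None:
            self.thresholds_ = usable
        elif placebo_changes is not None:
            self.thresholds_ = thresholds_from_placebo_arm(
                placebo_changes, self.responder_mean, self.responder_sd, self.alpha
            )
        else:
            raise InvalidThresholdsError(
                "mixture fit unusable (degenerate or out-of-range bounds) and no "
                "placebo_changes supplied for fallback"
            )
        return self

    def predict(self, X) -> np.ndarray:
        """Categories for log2 changes ``X``."""
        if not hasattr(self, "thresholds_"):
            raise AttributeError("classifier is not fitted")
        x = self._as_1d(X)
        frac = 2.0**x - 1.0
        return np.array([classify_response(f, self.thresholds_) for f in frac], dtype=object)


def classify_cohort(
    series_list: Iterable[BiomarkerSeries],
    thresholds: ResponseThresholds,
    target_day: int = 63,
    tolerance_days: int = 21,
    change_mode: str = "closest",
) -> tuple[list[ResponseCall], pd.DataFrame]:
    """Classify every patient series and tabulate response rates.

    Returns the per-patient calls and a rate table with one row per category
    (vCR, vPR, vNR) giving counts and percentages among evaluable patients,
    plus an ``unevaluable`` row outside the percentage base.
    """
    calls: list[ResponseCall] = []
    for series in series_list:
        summary: ChangeSummary = log2_change_over_window(
            series, target_day=target_day, tolerance_days=tolerance_days, mode=change_mode
        )
        frac = summary.fractional_change
        calls.append(ResponseCall(series.patient_id, classify_response(frac, thresholds), frac))

    n_eval = sum(c.category in CATEGORIES for c in calls)
    rows = []
    for cat in CATEGORIES:
        count = sum(c.category == cat for c in calls)
        rows.append({
            "category": cat,
            "count": count,
            "percent": 100.0 * count / n_eval if n_eval else float("nan"),
        })
    rows.append({
        "category": UNEVALUABLE,
        "count": sum(c.category == UNEVALUABLE for c in calls),
        "percent": float("nan"),
    })
    return calls, pd.DataFrame(rows)
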