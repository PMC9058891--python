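"""Synthetic cohort generator with full ground truth.

Emulates the statistical structure the pipeline assumes, for recovery
testing: two pre-treatment draws and 3-weekly on-treatment sampling; a
nine-week Tie2 log2 change drawn from a responder component (default
N(-0.55, 0.33**2)) or a placebo-like component (N(0.16, 0.28**2), matching
the observed chemotherapy-only change distribution); a geometric ramp from
baseline to the target change by day 63; for progressors a post-nadir
exponential rise whose first rule-crossing precedes the radiological
progression day by a configured lead; multiplicative log-normal measurement
noise; and per-class exponential survival with uniform censoring.

Every generated patient carries a ``SyntheticTruth``-style record (class,
true change, planted trigger day, radiological progression day) so that
classification, progression calling and lead-time detection can be scored
against the generating labels.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .progression import ProgressionRule, detect_marker_progression
from .trajectories import BiomarkerSeries, UnevaluableSeriesError

CHANGE_RAMP_DAY = 63  # target change is fully attained by the end of cycle 3


class ConfigError(ValueError):
    """Generator configuration is invalid; the message lists offending fields."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults encode a plausible VEGFi-vs-placebo trial: half the cohort on
    the VEGF inhibitor, half of those with a true vascular response, Tie2
    changes from the responder / placebo-like components, CK18 falling
    modestly in both arms (its response to cytotoxic chemotherapy is
    class-independent), and survival medians linked to the response class.
    Concentration units are pg/ml but the absolute scale is arbitrary.
    """

    n_patients: int = 120
    arm_fraction_vegfi: float = 0.5
    responder_fraction: float = 0.5  # among VEGFi patients

    responder_mean_log2: float = -0.55
    responder_sd_log2: float = 0.33
    placebo_like_mean_log2: float = 0.16
    placebo_like_sd_log2: float = 0.28

    ck18_mean_log2: float = -0.15
    ck18_sd_log2: float = 0.25

    tie2_baseline_median: float = 18000.0
    tie2_baseline_cv: float = 0.30
    ck18_baseline_median: float = 300.0
    ck18_baseline_cv: float = 0.40

    noise_cv: float = 0.10

    pre_treatment_days: tuple[int, ...] = (-14, -1)
    visit_start: int = 21
    visit_interval: int = 21
    visit_end: int = 252

    fraction_progressing: float = 0.75
    p_vascular_rise: float = 0.65
    p_epithelial_rise: float = 0.65
    rise_onset_days: tuple[int, ...] = (105, 126, 147, 168, 189)
    growth_rate_per_day: float = 0.02
    lead_choices_days: tuple[int, ...] = (42, 84)

    tie2_rise_fraction: float = 0.40
    ck18_rise_fraction: float = 0.50

    pfs_median_days: dict = field(default_factory=lambda: {"responder": 268.0, "placebo_like": 228.0})
    os_median_days: dict = field(default_factory=lambda: {"responder": 572.0, "placebo_like": 368.0})
    censor_low_days: float = 360.0
    censor_high_days: float = 1080.0

    seed: int = 0

    def validate(self) -> None:
        bad: list[str] = []
        if self.n_patients < 1:
            bad.append("n_patients")
        for name in ("arm_fraction_vegfi", "responder_fraction", "fraction_progressing",
                     "p_vascular_rise", "p_epithelial_rise"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                bad.append(name)
        for name in ("responder_sd_log2", "placebo_like_sd_log2", "ck18_sd_log2",
                     "tie2_baseline_median", "ck18_baseline_median",
                     "growth_rate_per_day", "tie2_rise_fraction", "ck18_rise_fraction"):
            if not getattr(self, name) > 0:
                bad.append(name)
        if self.noise_cv < 0:
            bad.append("noise_cv")
        if not (self.visit_start > 0 and self.visit_interval > 0 and self.visit_end >= self.visit_start):
            bad.append("visit_start/visit_interval/visit_end")
        if min(self.lead_choices_days, default=0) <= 0:
            bad.append("lead_choices_days")
        if min(self.rise_onset_days, default=0) <= CHANGE_RAMP_DAY:
            bad.append("rise_onset_days")
        for d in (self.pfs_median_days, self.os_median_days):
            if set(d) != {"responder", "placebo_like"} or min(d.values()) <= 0:
                bad.append("pfs_median_days/os_median_days")
                break
        if not (0 < self.censor_low_days <= self.censor_high_days):
            bad.append("censor_low_days/censor_high_days")
        if bad:
            raise ConfigError(f"invalid generator config fields: {', '.join(bad)}")

    def schedule(self) -> np.ndarray:
        on = np.arange(self.visit_start, self.visit_end + 1, self.visit_interval)
        return np.concatenate([np.asarray(self.pre_treatment_days, dtype=int), on])

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown generator config keys: {sorted(unknown)}")
        for key in ("pre_treatment_days", "rise_onset_days", "lead_choices_days"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        import yaml
        data = dataclasses.asdict(self)
        for key in ("pre_treatment_days", "rise_onset_days", "lead_choices_days"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


@dataclass(frozen=True)
class SimulatedCohort:
    """Generated long-format measurements, patient table and truth labels."""

    measurements: pd.DataFrame
    patients: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig


def _lognormal_params(median: float, cv: float) -> tuple[float, float]:
    sigma = math.sqrt(math.log1p(cv**2)) if cv > 0 else 0.0
    return math.log(median), sigma


def _trajectory(days: np.ndarray, baseline: float, change_log2: float,
                rise_onset: Optional[int], growth: float) -> np.ndarray:
    """Noiseless concentration at each day: ramp, plateau, optional rise."""
    d = np.asarray(days, dtype=float)
    frac = np.clip(d, 0.0, CHANGE_RAMP_DAY) / CHANGE_RAMP_DAY
    values = baseline * 2.0 ** (change_log2 * frac)
    if rise_onset is not None:
        rising = d > rise_onset
        values[rising] *= np.exp(growth * (d[rising] - rise_onset))
    return values


def _planted_trigger(patient_id: str, marker: str, days: np.ndarray,
                     noiseless: np.ndarray, rise_fraction: float) -> Optional[int]:
    """First day the nadir-rise rule fires on the noiseless trajectory."""
    series = BiomarkerSeries.from_arrays(patient_id, marker, days, noiseless)
    try:
        call = detect_marker_progression(series, ProgressionRule(marker, rise_fraction))
    except UnevaluableSeriesError:
        return None
    return call.trigger_day if call.triggered else None


def simulate_cohort(config: GeneratorConfig) -> SimulatedCohort:
    """Generate a cohort; byte-identical output for a fixed seed.

    Returns long-format measurements (patient_id, marker, day,
    concentration), a patient table (arm, survival endpoints, radiological
    progression day, performance status) and the truth table (true class,
    true Tie2/CK18 log2 changes, planted trigger days, survival rates).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    days_all = config.schedule()
    noise_sigma = math.sqrt(math.log1p(config.noise_cv**2)) if config.noise_cv > 0 else 0.0

    mu_t, sg_t = _lognormal_params(config.tie2_baseline_median, config.tie2_baseline_cv)
    mu_c, sg_c = _lognormal_params(config.ck18_baseline_median, config.ck18_baseline_cv)

    meas_rows: list[dict] = []
    pat_rows: list[dict] = []
    truth_rows: list[dict] = []

    width = len(str(config.n_patients))
    for i in range(config.n_patients):
        pid = f"P{i + 1:0{width}d}"
        arm = "vegfi" if rng.random() < config.arm_fraction_vegfi else "placebo"
        if arm == "vegfi" and rng.random() < config.responder_fraction:
            klass = "responder"
            change_t = float(rng.normal(config.responder_mean_log2, config.responder_sd_log2))
        else:
            klass = "placebo_like"
            change_t = float(rng.normal(config.placebo_like_mean_log2, config.placebo_like_sd_log2))
        change_c = float(rng.normal(config.ck18_mean_log2, config.ck18_sd_log2))

        base_t = float(rng.lognormal(mu_t, sg_t))
        base_c = float(rng.lognormal(mu_c, sg_c))

        progressor = rng.random() < config.fraction_progressing
        rise_t: Optional[int] = None
        rise_c: Optional[int] = None
        rad_pd: Optional[int] = None
        trig_t = trig_c = trig_combined = None
        if progressor:
            onset = int(rng.choice(config.rise_onset_days))
            lead = int(rng.choice(config.lead_choices_days))
            if rng.random() < config.p_vascular_rise:
                rise_t = onset
            if rng.random() < config.p_epithelial_rise:
                rise_c = onset

        traj_t = _trajectory(days_all, base_t, change_t, rise_t, config.growth_rate_per_day)
        traj_c = _trajectory(days_all, base_c, change_c, rise_c, config.growth_rate_per_day)

        if progressor:
            trig_t = _planted_trigger(pid, "TIE2", days_all, traj_t, config.tie2_rise_fraction)
            trig_c = _planted_trigger(pid, "CK18", days_all, traj_c, config.ck18_rise_fraction)
            planted = [t for t in (trig_t, trig_c) if t is not None]
            trig_combined = min(planted) if planted else None
            rad_pd = (trig_combined if trig_combined is not None else onset) + lead

        # sampling continues until radiological progression
        keep = days_all <= rad_pd if rad_pd is not None else np.ones_like(days_all, dtype=bool)
        for marker, traj in (("TIE2", traj_t), ("CK18", traj_c)):
            noise = (np.exp(rng.normal(-noise_sigma**2 / 2, noise_sigma, size=int(keep.sum())))
                     if noise_sigma > 0 else np.ones(int(keep.sum())))
            for day, value in zip(days_all[keep], traj[keep] * noise):
                meas_rows.append({"patient_id": pid, "marker": marker,
                                  "day": int(day), "concentration": float(value)})

        pfs_rate = math.log(2) / config.pfs_median_days[klass]
        os_rate = math.log(2) / config.os_median_days[klass]
        pfs_t = float(rng.exponential(1.0 / pfs_rate))
        os_t = float(rng.exponential(1.0 / os_rate))
        pfs_c = float(rng.uniform(config.censor_low_days, config.censor_high_days))
        os_c = float(rng.uniform(config.censor_low_days, config.censor_high_days))

        pat_rows.append({
            "patient_id": pid, "arm": arm,
            "performance_status": int(rng.random() < 0.5),
            "pfs_days": round(min(pfs_t, pfs_c), 3), "pfs_event": int(pfs_t <= pfs_c),
            "os_days": round(min(os_t, os_c), 3), "os_event": int(os_t <= os_c),
            "rad_pd_day": rad_pd,
        })
        truth_rows.append({
            "patient_id": pid, "arm": arm, "true_class": klass,
            "true_change_log2": change_t, "true_change_ck18_log2": change_c,
            "rad_pd_day": rad_pd,
            "planted_trigger_day": trig_combined,
            "planted_trigger_tie2": trig_t,
            "planted_trigger_ck18": trig_c,
            "pfs_rate_per_day": pfs_rate, "os_rate_per_day": os_rate,
        })

    measurements = pd.DataFrame(meas_rows, columns=["patient_id", "marker", "day", "concentration"])
    patients = pd.DataFrame(pat_rows)
    patients["rad_pd_day"] = patients["rad_pd_day"].astype("Float64")
    truth = pd.DataFrame(truth_rows)
    for col in ("rad_pd_day", "planted_trigger_day", "planted_trigger_tie2", "planted_trigger_ck18"):
        truth[col] = truth[col].astype("Float64")
    return SimulatedCohort(measurements, patients, truth, config)


@dataclass(frozen=True)
class RecoveryReport:
    """Scores of the pipeline against the generating labels."""

    confusion: pd.DataFrame
    classification_accuracy: float
    mean_component_error: Optional[float]
    trigger_day_errors: tuple[float, ...]


def truth_recovery_report(
    response_calls,
    combined_calls,
    truth: pd.DataFrame,
    mixture=None,
    config: Optional[GeneratorConfig] = None,
) -> RecoveryReport:
    """Score classification and progression calling against the truth table.

    A vCR call is read as a *responder* prediction and vPR/vNR as
    *placebo_like* (the vPR band inevitably absorbs mild responders, so
    accuracy below 1 is expected even without noise whenever the component
    distributions overlap).  Trigger-day errors are measured minus planted
    combined trigger, for patients where both exist.
    """
    pred = {c.patient_id: ("responder" if c.category == "vCR" else "placebo_like")
            for c in response_calls if c.category in ("vCR", "vPR", "vNR")}
    t = truth.set_index("patient_id")
    rows = [(t.loc[pid, "true_class"], cls) for pid, cls in pred.items() if pid in t.index]
    if rows:
        df = pd.DataFrame(rows, columns=["true", "predicted"])
        confusion = pd.crosstab(df["true"], df["predicted"])
        accuracy = float((df["true"] == df["predicted"]).mean())
    else:
        confusion = pd.DataFrame()
        accuracy = float("nan")

    mean_err = None
    if mixture is not None and config is not None:
        mean_err = float(np.mean([
            abs(mixture.mean_responder - config.responder_mean_log2),
            abs(mixture.mean_placebo_like - config.placebo_like_mean_log2),
        ]))

    errors: list[float] = []
    by_pid = {c.patient_id: c for c in combined_calls}
    for pid, row in t.iterrows():
        planted = row["planted_trigger_day"]
        call = by_pid.get(pid)
        if pd.notna(planted) and call is not None and call.triggered:
            errors.append(float(call.trigger_day - planted))
    return RecoveryReport(confusion, accuracy, mean_err, tuple(errors))
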