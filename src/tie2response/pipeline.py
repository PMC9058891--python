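"""End-to-end pipeline: classify -> progression -> lead time -> survival.

``run_pipeline`` ties the library together for file-based use: it reads the
long-format measurements and the patient table, derives vascular response
thresholds (mixture deconvolution of the treated arm, with automatic
fallback to placebo-arm moments when the fit is unavailable or degenerate),
classifies patients, calls marker and combined progression, evaluates
detection fractions at the configured leads, contrasts survival between
complete vascular responders and the rest, and writes every stage's output
plus a deterministic JSON manifest to the output directory.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .mixture import InsufficientDataError
from .outcomes import NonEstimableError, cox_hr
from .progression import (COMBINED, ProgressionRule, combine_progression_calls,
                          compare_detection_fractions, detect_marker_progression,
                          detection_indicators, lead_time_detection)
from .response import VascularResponseClassifier, classify_cohort
from .trajectories import UnevaluableSeriesError, log2_change_over_window

logger = logging.getLogger("tie2response")

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is stage-tagged."""


@dataclass
class RunConfig:
    """File paths, marker roles and analysis settings for one pipeline run."""

    measurements_path: str
    patients_path: str
    out_dir: str
    vascular_marker: str = "TIE2"
    epithelial_marker: Optional[str] = "CK18"
    threshold_source: str = "mixture"
    alpha: float = 0.05
    rise_vascular: float = 0.40
    rise_epithelial: float = 0.50
    confirmations_required: int = 1
    target_day: int = 63
    tolerance_days: int = 21
    lead_days: tuple[int, ...] = (42, 84)
    adjustment_covariates: tuple[str, ...] = ()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.lead_days, list):
            cfg.lead_days = tuple(int(x) for x in cfg.lead_days)
        if isinstance(cfg.adjustment_covariates, list):
            cfg.adjustment_covariates = tuple(cfg.adjustment_covariates)
        return cfg

    def validate(self) -> None:
        problems = []
        if not self.vascular_marker:
            problems.append("vascular_marker must be set")
        for p in (self.measurements_path, self.patients_path):
            if not Path(p).exists():
                problems.append(f"input path does not exist: {p}")
        if self.threshold_source not in ("mixture", "placebo_arm"):
            problems.append(f"unknown threshold_source {self.threshold_source!r}")
        if problems:
            raise PipelineError("[config] " + "; ".join(problems))


@dataclass
class PipelineResult:
    out_dir: Path
    thresholds: object
    response_calls: list
    rate_table: pd.DataFrame
    detection: pd.DataFrame
    survival: dict
    manifest: dict = field(default_factory=dict)


def _patient_changes(series_list, cfg: RunConfig) -> dict[str, float]:
    changes = {}
    for s in series_list:
        if s.marker != cfg.vascular_marker:
            continue
        summary = log2_change_over_window(s, cfg.target_day, cfg.tolerance_days)
        changes[s.patient_id] = summary.log2_change if summary.evaluable else float("nan")
    return changes


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and write the result bundle under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "tie2response",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    # ---- stage: read ----
    try:
        series_list = tio.read_measurements(config.measurements_path)
        patients = tio.read_patients(config.patients_path)
    except Exception as exc:
        raise PipelineError(f"[read] {exc}") from exc
    arm = dict(zip(patients["patient_id"], patients.get("arm", "vegfi")))
    logger.info("read: %d series, %d patients", len(series_list), len(patients))
    manifest["stages"]["read"] = {"n_series": len(series_list), "n_patients": len(patients)}

    # ---- stage: classify ----
    try:
        changes = _patient_changes(series_list, config)
        vegfi_changes = np.array([v for k, v in changes.items() if arm.get(k) == "vegfi"])
        placebo_changes = np.array([v for k, v in changes.items() if arm.get(k) == "placebo"])
        vegfi_changes = vegfi_changes[np.isfinite(vegfi_changes)]
        placebo_changes = placebo_changes[np.isfinite(placebo_changes)]

        clf = VascularResponseClassifier(
            alpha=config.alpha, threshold_source=config.threshold_source,
            random_state=config.seed,
        )
        fallback_used = False
        if config.threshold_source == "mixture":
            try:
                clf.fit(vegfi_changes,
                        placebo_changes=placebo_changes if placebo_changes.size >= 2 else None)
            except InsufficientDataError:
                if placebo_changes.size < 2:
                    raise
                logger.warning("classify: mixture source unavailable "
                               "(%d treated-arm changes); falling back to placebo-arm moments",
                               vegfi_changes.size)
                clf.set_params(threshold_source="placebo_arm")
                clf.fit(vegfi_changes, placebo_changes=placebo_changes)
                fallback_used = True
        else:
            clf.fit(vegfi_changes, placebo_changes=placebo_changes)
        thresholds = clf.thresholds_
        fallback_used = fallback_used or thresholds.source != config.threshold_source

        vegfi_series = [s for s in series_list
                        if s.marker == config.vascular_marker and arm.get(s.patient_id) == "vegfi"]
        calls, rate_table = classify_cohort(
            vegfi_series, thresholds, config.target_day, config.tolerance_days
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[classify] {exc}") from exc

    pd.DataFrame(
        [{"patient_id": c.patient_id, "fractional_change": c.fractional_change,
          "category": c.category} for c in calls]
    ).to_csv(out / "response_calls.csv", index=False)
    threshold_report = {
        "vcr_cut": thresholds.vcr_cut, "vnr_cut": thresholds.vnr_cut,
        "alpha": thresholds.alpha, "source": thresholds.source,
        "vcr_percent_reduction": thresholds.as_percent()[0],
        "vnr_percent_increase": thresholds.as_percent()[1],
    }
    if clf.mixture_ is not None:
        fit = clf.mixture_
        threshold_report.update({
            "mixture_weight_responder": fit.weight_responder,
            "mixture_mean_responder": fit.mean_responder,
            "mixture_sd_responder": fit.sd_responder,
            "mixture_weight_placebo_like": fit.weight_placebo_like,
            "mixture_mean_placebo_like": fit.mean_placebo_like,
            "mixture_sd_placebo_like": fit.sd_placebo_like,
            "mixture_loglik": fit.loglik,
            "mixture_converged": fit.converged,
            "mixture_degenerate": fit.degenerate,
        })
    tio.write_key_value(threshold_report, out / "thresholds.txt")
    rate_table.to_csv(out / "response_rates.csv", index=False)
    n_eval = sum(c.category != "unevaluable" for c in calls)
    logger.info("classify: %d/%d evaluable (source=%s)", n_eval, len(calls), thresholds.source)
    manifest["stages"]["classify"] = {
        "n_classified": len(calls), "n_evaluable": n_eval,
        "threshold_source": thresholds.source, "fallback_used": fallback_used,
        "vcr_cut": thresholds.vcr_cut, "vnr_cut": thresholds.vnr_cut,
    }

    # ---- stage: progression ----
    try:
        category_by_pid = {c.patient_id: c.category for c in calls}
        roles = {"vascular": (config.vascular_marker, config.rise_vascular)}
        if config.epithelial_marker:
            roles["epithelial"] = (config.epithelial_marker, config.rise_epithelial)
        calls_by_set: dict[str, dict] = {label: {} for label in roles}
        calls_by_set[COMBINED] = {}
        prog_rows = []
        by_patient: dict[str, list] = {}
        for s in series_list:
            for label, (marker, rise) in roles.items():
                if s.marker != marker:
                    continue
                rule = ProgressionRule(marker, rise, config.confirmations_required)
                try:
                    call = detect_marker_progression(s, rule, category_by_pid.get(s.patient_id))
                except UnevaluableSeriesError:
                    continue
                calls_by_set[label][s.patient_id] = call
                by_patient.setdefault(s.patient_id, []).append(call)
                prog_rows.append({
                    "patient_id": call.patient_id, "marker": call.marker,
                    "triggered": call.triggered, "trigger_day": call.trigger_day,
                    "nadir_value": call.nadir_value, "nadir_day": call.nadir_day,
                })
        for pid, pcalls in by_patient.items():
            combined = combine_progression_calls(pcalls)
            calls_by_set[COMBINED][pid] = combined
            prog_rows.append({
                "patient_id": pid, "marker": COMBINED, "triggered": combined.triggered,
                "trigger_day": combined.trigger_day, "nadir_value": combined.nadir_value,
                "nadir_day": combined.nadir_day,
            })
        pd.DataFrame(prog_rows).to_csv(out / "progression_calls.csv", index=False)
    except Exception as exc:
        raise PipelineError(f"[progression] {exc}") from exc
    n_trig = sum(1 for c in calls_by_set[COMBINED].values() if c.triggered)
    logger.info("progression: %d/%d combined calls triggered", n_trig, len(calls_by_set[COMBINED]))
    manifest["stages"]["progression"] = {
        "n_patients_scanned": len(calls_by_set[COMBINED]), "n_combined_triggered": n_trig,
    }

    # ---- stage: lead time ----
    try:
        rad = dict(zip(
            patients["patient_id"],
            [None if pd.isna(v) else float(v) for v in patients.get(
                "rad_pd_day", pd.Series([np.nan] * len(patients)))],
        ))
        det_rows = []
        for lead in config.lead_days:
            summary = lead_time_detection(calls_by_set, rad, lead)
            for label in summary.fraction:
                det_rows.append({
                    "lead_days": lead, "marker_set": label,
                    "n_progressors": summary.n_progressors,
                    "detected": summary.detected[label],
                    "fraction": summary.fraction[label],
                })
            if summary.n_progressors > 0:
                combined_ind = detection_indicators(calls_by_set[COMBINED], rad, lead)
                for label in roles:
                    single_ind = detection_indicators(calls_by_set[label], rad, lead)
                    pids = sorted(combined_ind)
                    stat, p, degen = compare_detection_fractions(
                        [combined_ind[i] for i in pids], [single_ind.get(i, False) for i in pids]
                    )
                    det_rows.append({
                        "lead_days": lead, "marker_set": f"combined_vs_{label}_p",
                        "n_progressors": summary.n_progressors,
                        "detected": stat, "fraction": p,
                    })
        detection = pd.DataFrame(det_rows)
        detection.to_csv(out / "detection_summary.csv", index=False)
    except Exception as exc:
        raise PipelineError(f"[leadtime] {exc}") from exc
    manifest["stages"]["leadtime"] = {"lead_days": list(config.lead_days)}

    # ---- stage: survival ----
    survival_report: dict = {}
    try:
        vegfi_pat = patients[patients.get("arm", "vegfi") == "vegfi"].copy()
        vegfi_pat["response_group"] = vegfi_pat["patient_id"].map(
            lambda p: "vCR" if category_by_pid.get(p) == "vCR"
            else ("other" if category_by_pid.get(p) in ("vPR", "vNR") else None)
        )
        vegfi_pat = vegfi_pat[vegfi_pat["response_group"].notna()]
        for endpoint, (tcol, ecol) in (("PFS", ("pfs_days", "pfs_event")),
                                       ("OS", ("os_days", "os_event"))):
            if tcol not in vegfi_pat.columns:
                continue
            df = vegfi_pat.rename(columns={tcol: "time_days", ecol: "event"})
            try:
                res = cox_hr(df, group_col="response_group", reference="vCR",
                             adjustment_covariates=config.adjustment_covariates)
                survival_report[f"{endpoint}_hr"] = res.hr
                survival_report[f"{endpoint}_hr_ci_low"] = res.ci_low
                survival_report[f"{endpoint}_hr_ci_high"] = res.ci_high
                survival_report[f"{endpoint}_p"] = res.p
                survival_report[f"{endpoint}_ph_ok"] = res.ph_ok
                if not res.ph_ok:
                    survival_report[f"{endpoint}_rmst_ratio"] = res.rmst_ratio
                    survival_report[f"{endpoint}_rmst_tau_days"] = res.tau_days
            except NonEstimableError as exc:
                survival_report[f"{endpoint}_error"] = str(exc)
        tio.write_key_value(survival_report, out / "survival_report.txt")
    except Exception as exc:
        raise PipelineError(f"[survival] {exc}") from exc
    manifest["stages"]["survival"] = {
        "n_grouped": int(len(vegfi_pat)),
        "endpoints": sorted({k.split("_")[0] for k in survival_report}),
    }

    tio.write_manifest(manifest, out / "manifest.json")
    return PipelineResult(out, thresholds, calls, rate_table, detection,
                          survival_report, manifest)
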