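import numpy as np
import pandas as pd
import pytest

from tie2response import (ConfigError, GeneratorConfig, ProgressionRule,
                          ResponseThresholds, UnevaluableSeriesError,
                          classify_response, combine_progression_calls,
                          detect_marker_progression, fit_two_component_mixture,
                          log2_change_over_window, simulate_cohort,
                          truth_recovery_report)
from tie2response.io import series_from_frame
from tie2response.response import classify_cohort

PRINTED_CUTS = ResponseThresholds(vcr_cut=-0.24, vnr_cut=0.07)


class TestDeterminismAndValidation:
    def test_same_seed_gives_identical_cohorts(self):
        cfg = GeneratorConfig(n_patients=40, seed=123)
        a, b = simulate_cohort(cfg), simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.measurements, b.measurements)
        pd.testing.assert_frame_equal(a.patients, b.patients)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        assert a.measurements.to_csv() == b.measurements.to_csv()

    def test_different_seeds_differ(self):
        a = simulate_cohort(GeneratorConfig(n_patients=40, seed=1))
        b = simulate_cohort(GeneratorConfig(n_patients=40, seed=2))
        assert not a.measurements.equals(b.measurements)

    def test_invalid_config_lists_offending_fields(self):
        with pytest.raises(ConfigError) as exc:
            simulate_cohort(GeneratorConfig(n_patients=0, noise_cv=-1.0,
                                            responder_fraction=2.0))
        msg = str(exc.value)
        assert "n_patients" in msg and "noise_cv" in msg and "responder_fraction" in msg

    def test_generator_config_yaml_roundtrip(self, tmp_path):
        cfg = GeneratorConfig(n_patients=55, seed=3, noise_cv=0.05,
                              lead_choices_days=(42,))
        cfg.to_yaml(tmp_path / "gen.yaml")
        back = GeneratorConfig.from_yaml(tmp_path / "gen.yaml")
        assert back == cfg
        (tmp_path / "bad.yaml").write_text("n_patients: 10\nbogus_field: 1\n")
        with pytest.raises(ConfigError, match="bogus_field"):
            GeneratorConfig.from_yaml(tmp_path / "bad.yaml")

    def test_all_concentrations_positive_and_schedule_increasing(self, default_cohort):
        m = default_cohort.measurements
        assert (m.concentration > 0).all()
        for _, g in m.groupby(["patient_id", "marker"]):
            assert g.day.is_monotonic_increasing and g.day.is_unique


class TestGeneratingMoments:
    def test_placebo_like_change_moments_at_n2000(self):
        cohort = simulate_cohort(GeneratorConfig(n_patients=2000, seed=42))
        ch = cohort.truth.loc[cohort.truth.true_class == "placebo_like", "true_change_log2"]
        assert ch.mean() == pytest.approx(0.16, abs=0.02)
        assert ch.std() == pytest.approx(0.28, abs=0.02)

    def test_law_of_large_numbers_at_n10000(self):
        cohort = simulate_cohort(GeneratorConfig(
            n_patients=10_000, seed=7, arm_fraction_vegfi=1.0, responder_fraction=1.0,
            fraction_progressing=0.0))
        ch = cohort.truth.true_change_log2
        assert ch.mean() == pytest.approx(-0.55, abs=0.01)
        assert ch.std() == pytest.approx(0.33, abs=0.01)


class TestNoiselessRecovery:
    def test_observed_change_equals_true_change_without_noise(self, noiseless_cohort):
        series = {(s.patient_id, s.marker): s
                  for s in series_from_frame(noiseless_cohort.measurements)}
        truth = noiseless_cohort.truth.set_index("patient_id")
        checked = 0
        for pid, row in truth.iterrows():
            s = series.get((pid, "TIE2"))
            if s is None:
                continue
            c = log2_change_over_window(s)
            if c.evaluable:
                assert c.log2_change == pytest.approx(row.true_change_log2, abs=1e-9)
                checked += 1
        assert checked > 30

    def test_noiseless_classification_matches_truth_exactly(self, noiseless_cohort):
        series = [s for s in series_from_frame(noiseless_cohort.measurements)
                  if s.marker == "TIE2"]
        calls, _ = classify_cohort(series, PRINTED_CUTS)
        truth = noiseless_cohort.truth.set_index("patient_id")
        for call in calls:
            if call.category == "unevaluable":
                continue
            true_frac = 2.0 ** truth.loc[call.patient_id, "true_change_log2"] - 1.0
            assert call.category == classify_response(true_frac, PRINTED_CUTS)

    def test_planted_trigger_precedes_radiological_pd(self, noiseless_cohort):
        t = noiseless_cohort.truth
        both = t.dropna(subset=["planted_trigger_day", "rad_pd_day"])
        assert len(both) > 0
        assert (both.planted_trigger_day < both.rad_pd_day).all()
        # lead is exactly as configured (42 days) for every detectable progressor
        assert ((both.rad_pd_day - both.planted_trigger_day) == 42).all()

    def test_noiseless_trigger_day_error_is_zero(self, noiseless_cohort):
        series = series_from_frame(noiseless_cohort.measurements)
        rises = {"TIE2": 0.40, "CK18": 0.50}
        by_pid = {}
        for s in series:
            try:
                c = detect_marker_progression(s, ProgressionRule(s.marker, rises[s.marker]))
            except UnevaluableSeriesError:
                continue
            by_pid.setdefault(s.patient_id, []).append(c)
        combined = [combine_progression_calls(v) for v in by_pid.values()]
        report = truth_recovery_report([], combined, noiseless_cohort.truth)
        assert len(report.trigger_day_errors) > 0
        assert all(e == 0 for e in report.trigger_day_errors)


class TestRecoveryUnderNoise:
    def test_classification_accuracy_regression_baseline(self):
        """Mean vCR-vs-rest accuracy against the generating class.

        The responder and placebo-like change components overlap, so even a
        perfect classifier mislabels mild responders; with the default
        measurement noise the attainable accuracy is about 0.84 (realized
        baseline recorded in the methods note).
        """
        accs = []
        for seed in range(8):
            cohort = simulate_cohort(GeneratorConfig(
                n_patients=500, seed=200 + seed, arm_fraction_vegfi=1.0))
            series = [s for s in series_from_frame(cohort.measurements) if s.marker == "TIE2"]
            calls, _ = classify_cohort(series, PRINTED_CUTS)
            report = truth_recovery_report(calls, [], cohort.truth)
            accs.append(report.classification_accuracy)
        assert np.mean(accs) > 0.80

    def test_mixture_refit_through_pipeline_recovers_components(self):
        """Changes recomputed from noise-free trajectories deconvolute back
        to the generating components (under the default noise the components
        overlap too strongly for the ML mixture to identify them; see the
        methods note)."""
        cfg = GeneratorConfig(n_patients=1200, seed=31, arm_fraction_vegfi=1.0,
                              fraction_progressing=0.0, noise_cv=0.0)
        cohort = simulate_cohort(cfg)
        series = [s for s in series_from_frame(cohort.measurements) if s.marker == "TIE2"]
        changes = [log2_change_over_window(s).log2_change for s in series]
        fit = fit_two_component_mixture([c for c in changes if np.isfinite(c)], seed=31)
        report = truth_recovery_report([], [], cohort.truth, mixture=fit, config=cfg)
        assert report.mean_component_error < 0.05
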