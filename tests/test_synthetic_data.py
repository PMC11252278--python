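"""Tests for the simulated-concert generator and its ground truth."""

import numpy as np
import pytest
from scipy import stats

from audiencesync import SimulationConfig, generate_audience, generate_dataset, \
    generate_driver, generate_raw_signals, generate_surveys
from audiencesync.synthetic_data import ConfigError
from audiencesync.signal_features import SignalError


def lag1_autocorr(x):
    return np.corrcoef(x[:-1], x[1:])[0, 1]


def small_config(**kw):
    base = dict(n_concerts=1, n_participants_per_concert=4, duration_s=120, seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(duration_s=-5)
        with pytest.raises(ConfigError):
            SimulationConfig(driver_ar_coefficient=1.5)
        with pytest.raises(ConfigError):
            SimulationConfig(covariate_effects={"NotACovariate": 1.0})

    def test_overlapping_pieces_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(piece_boundaries_s=[("A", 0, 100), ("B", 50, 150)],
                             duration_s=200)

    def test_piece_outside_recording_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(piece_boundaries_s=[("A", 0, 500)], duration_s=300)


class TestDriver:
    def test_zero_ar_unsmoothed_is_white(self):
        cfg = small_config(duration_s=1000, driver_ar_coefficient=0.0,
                           driver_smooth_s=0.0)
        d = generate_driver(cfg, "concert01")
        assert abs(lag1_autocorr(d.values)) < 0.1

    def test_ar_coefficient_recovered(self):
        cfg = small_config(duration_s=5000, driver_ar_coefficient=0.95,
                           driver_smooth_s=0.0)
        d = generate_driver(cfg, "concert01")
        assert lag1_autocorr(d.values) == pytest.approx(0.95, abs=0.03)

    def test_deterministic_and_concert_specific(self):
        cfg = small_config()
        a = generate_driver(cfg, "concert01")
        b = generate_driver(cfg, "concert01")
        c = generate_driver(cfg, "concert02")
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_standardized(self):
        d = generate_driver(small_config(duration_s=600), "concert01")
        assert d.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert d.values.std() == pytest.approx(1.0, abs=1e-12)


class TestAudience:
    def test_zero_coupling_by_construction(self):
        cfg = small_config(coupling_mean=0.0, coupling_sd=0.0, covariate_effects={})
        drv = generate_driver(cfg, "concert01")
        _, gt = generate_audience(cfg, drv, "concert01")
        for kappas in gt.coupling["concert01"].values():
            assert all(v == 0.0 for v in kappas.values())

    def test_resp_coupling_always_zero(self):
        cfg = small_config(coupling_mean=1.0)
        drv = generate_driver(cfg, "concert01")
        _, gt = generate_audience(cfg, drv, "concert01")
        assert all(k["RESP"] == 0.0 for k in gt.coupling["concert01"].values())

    def test_planted_openness_effect_correlates_with_coupling(self):
        cfg = small_config(n_participants_per_concert=500, duration_s=60,
                           covariate_effects={"Openness": 0.3}, coupling_sd=0.1)
        drv = generate_driver(cfg, "concert01")
        _, gt = generate_audience(cfg, drv, "concert01")
        cf = gt.covariate_frame().merge(gt.coupling_frame(),
                                        on=["concert_id", "participant_id"])
        r = np.corrcoef(cf["Openness"], cf["HR"])[0, 1]
        assert r > 0.3

    def test_lag_exceeding_duration_rejected(self):
        cfg = small_config()
        drv = generate_driver(cfg, "concert01")
        cfg.lag_range_s = 500.0  # bypass construction-time validation
        with pytest.raises(ConfigError):
            generate_audience(cfg, drv, "concert01")

    def test_lags_within_configured_range(self):
        cfg = small_config(lag_range_s=3.0)
        drv = generate_driver(cfg, "concert01")
        _, gt = generate_audience(cfg, drv, "concert01")
        assert all(abs(l) <= 3.0 for l in gt.lag_s["concert01"].values())


class TestSurveys:
    def test_planted_na_decrease_detected(self):
        cfg = small_config(n_participants_per_concert=300, duration_s=60)
        drv = generate_driver(cfg, "concert01")
        _, gt = generate_audience(cfg, drv, "concert01")
        s = generate_surveys(gt, cfg)
        t, p = stats.ttest_rel(s["NA_pre"], s["NA_post"])
        assert p < 0.01
        assert s["NA_post"].mean() < s["NA_pre"].mean()

    def test_null_pa_shift_gives_small_effect(self):
        cfg = small_config(n_participants_per_concert=300, duration_s=60)
        drv = generate_driver(cfg, "concert01")
        _, gt = generate_audience(cfg, drv, "concert01")
        s = generate_surveys(gt, cfg)
        es = (s["PA_pre"].mean() - s["PA_post"].mean()) / s["PA_pre"].std(ddof=1)
        assert abs(es) < 0.15

    def test_covariates_consistent_with_ground_truth(self):
        cfg = small_config(n_participants_per_concert=20, duration_s=60)
        drv = generate_driver(cfg, "concert01")
        _, gt = generate_audience(cfg, drv, "concert01")
        s = generate_surveys(gt, cfg).set_index("participant_id")
        for pid, covs in gt.covariates["concert01"].items():
            assert s.loc[pid, "Openness"] == pytest.approx(covs["Openness"])
            assert s.loc[pid, "F3"] == pytest.approx(covs["F3"])

    def test_factor_scores_orthogonal(self):
        cfg = small_config(n_participants_per_concert=100, duration_s=60)
        drv = generate_driver(cfg, "concert01")
        _, gt = generate_audience(cfg, drv, "concert01")
        s = generate_surveys(gt, cfg)
        F = s[[f"F{k}" for k in range(1, 8)]].to_numpy()
        C = np.corrcoef(F.T)
        assert np.allclose(C - np.eye(7), 0.0, atol=1e-8)

    def test_trait_and_item_ranges(self):
        cfg = small_config(n_participants_per_concert=50, duration_s=60)
        drv = generate_driver(cfg, "concert01")
        _, gt = generate_audience(cfg, drv, "concert01")
        s = generate_surveys(gt, cfg)
        for col in ("Openness", "Extraversion", "liked_Dean", "bored_Brahms"):
            assert s[col].between(1, 5).all()


class TestRawSignals:
    def _raw(self, **kw):
        cfg = small_config(n_participants_per_concert=1, duration_s=120)
        drv = generate_driver(cfg, "concert01")
        series, _ = generate_audience(cfg, drv, "concert01")
        return generate_raw_signals(series, drv, cfg, **kw), cfg

    def test_constant_hr_gives_unit_ibis(self):
        raw, _ = self._raw(hr_mean_bpm=60.0, hr_sd_bpm=0.0)
        ibis = np.diff(next(iter(raw.values()))["beat_times_s"])
        assert np.allclose(ibis, 1.0)

    def test_constant_rr_gives_five_second_breaths(self):
        raw, cfg = self._raw(rr_mean_bpm=12.0, rr_sd_bpm=0.0)
        w = next(iter(raw.values()))["resp_waveform"]
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(w, prominence=0.5)
        periods = np.diff(peaks) / cfg.raw_rate_hz
        assert np.median(periods) == pytest.approx(5.0, abs=0.3)

    def test_zero_impulse_rate_gives_flat_phasic(self):
        raw, _ = self._raw(scr_rate_per_s=0.0)
        eda = next(iter(raw.values()))["eda_trace"]
        # without sudomotor impulses only the slow tonic drift remains
        assert np.ptp(np.diff(eda)) < 0.05

    def test_negative_target_hr_rejected(self):
        with pytest.raises(SignalError):
            self._raw(hr_mean_bpm=-10.0, hr_sd_bpm=0.0)


class TestDataset:
    def test_byte_identical_under_same_seed(self):
        cfg = small_config(n_concerts=2, n_participants_per_concert=3)
        d1 = generate_dataset(cfg)
        d2 = generate_dataset(cfg)
        assert d1.timeseries.equals(d2.timeseries)
        assert d1.survey.equals(d2.survey)

    def test_row_counts(self):
        cfg = small_config(n_concerts=2, n_participants_per_concert=3)
        ds = generate_dataset(cfg)
        assert len(ds.timeseries) == 2 * 3 * 5 * cfg.n_samples
        assert len(ds.survey) == 6
        assert len(ds.concert_meta) == 2 * 3
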