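"""Synthetic concert audiences with known ground truth.

The generator emulates the statistical structure the synchrony analysis
assumes: during a concert every audience member's autonomic physiology is
partly driven by one shared, smoothly varying stimulus (the music), with
person-specific coupling strength, a person-specific response lag, and
autocorrelated idiosyncratic noise on top.

Per concert:

* a latent *driver* — a standardized, smoothed AR(1) series on the feature
  grid — stands in for the music's arousal contour;
* participant ``i``'s series on channel ``c`` is
  ``kappa[i, c] * driver(t - lag[i]) + AR(1) noise``, standardized;
* coupling strengths are ``coupling_mean`` plus planted linear effects of
  survey covariates (centered) plus Gaussian jitter, truncated at zero;
* the breathing waveform channel RESP is an independent per-participant
  oscillator with coupling exactly zero, so the analysis should find
  synchrony in HR/HRV/SCR/RR but *not* in RESP;
* surveys carry the very covariate values used to build the couplings, plus
  pre/post affect scales with a planted mean decrease of negative activation.

Everything is deterministic given the master seed; every stream is keyed by
(seed, purpose, concert) so concerts are independent and reproducible.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signal_features import ChannelSeries, SignalError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "Dataset",
    "generate_driver",
    "generate_audience",
    "generate_surveys",
    "generate_raw_signals",
    "generate_dataset",
    "write_dataset",
]

TRAITS = ("Extraversion", "Agreeableness", "Conscientiousness", "Neuroticism", "Openness")
FACTORS = tuple(f"F{k}" for k in range(1, 8))
AFFECT_CHANGES = ("PA_change", "NA_change", "VA_change")
PIECE_ITEMS = (
    "liked", "knew", "annoyed", "moved", "interesting",
    "inspired", "melancholic", "happy", "bored",
)
COUPLED_CHANNELS = ("HR", "HRV", "SCR", "RR")

# per-piece item means on the 1-5 scale: the contemporary piece is liked less
# but synchronizes most, mirroring the dissociation between evaluation and
# synchrony the analysis is designed to expose.
_PIECE_ITEM_MEANS = {
    "liked":       {"Beethoven": 4.0, "Dean": 3.1, "Brahms": 4.1},
    "knew":        {"Beethoven": 3.4, "Dean": 1.5, "Brahms": 3.3},
    "annoyed":     {"Beethoven": 1.5, "Dean": 2.4, "Brahms": 1.5},
    "moved":       {"Beethoven": 3.5, "Dean": 3.0, "Brahms": 3.6},
    "interesting": {"Beethoven": 3.7, "Dean": 3.9, "Brahms": 3.7},
    "inspired":    {"Beethoven": 3.4, "Dean": 3.4, "Brahms": 3.5},
    "melancholic": {"Beethoven": 2.9, "Dean": 2.5, "Brahms": 3.0},
    "happy":       {"Beethoven": 3.8, "Dean": 2.9, "Brahms": 3.9},
    "bored":       {"Beethoven": 1.8, "Dean": 2.2, "Brahms": 1.7},
}


class ConfigError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


PIECE_LABELS = ("Beethoven", "Dean", "Brahms")


def _default_covariate_effects():
    # sign pattern: openness raises coupling, extraversion and neuroticism
    # lower it (slopes per unit of the centered trait)
    return {"Openness": 0.30, "Extraversion": -0.25, "Neuroticism": -0.25}


def _default_panava_shifts():
    # post minus pre, in pre-SD units: negative activation drops during the
    # concert, valence rises slightly, positive activation is flat
    return {"PA": 0.0, "NA": -0.5, "VA": 0.1}


@dataclass
class SimulationConfig:
    """Conditions of a simulated concert series."""

    n_concerts: int = 11
    n_participants_per_concert: int = 60
    duration_s: float = 900.0
    feature_rate_hz: float = 1.0
    driver_ar_coefficient: float = 0.9
    driver_smooth_s: float = 5.0
    coupling_mean: float = 0.6
    coupling_sd: float = 0.15
    lag_range_s: float = 2.0
    noise_ar_coefficient: float = 0.7
    noise_sd: float = 1.0
    covariate_effects: Mapping[str, float] = field(default_factory=_default_covariate_effects)
    piece_boundaries_s: Sequence[tuple] | None = None
    piece_coupling: Mapping[str, float] = field(default_factory=dict)
    panava_shifts: Mapping[str, float] = field(default_factory=_default_panava_shifts)
    allow_negative_coupling: bool = False
    raw_rate_hz: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_concerts", "n_participants_per_concert"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        for name in ("duration_s", "feature_rate_hz", "noise_sd", "raw_rate_hz"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ConfigError(f"{name} must be a positive finite number")
        for name in ("driver_ar_coefficient", "noise_ar_coefficient"):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0 <= v < 1):
                raise ConfigError(f"{name} must lie in [0, 1)")
        if not np.isfinite(self.coupling_mean) or not np.isfinite(self.coupling_sd):
            raise ConfigError("coupling parameters must be finite")
        if self.lag_range_s < 0 or not np.isfinite(self.lag_range_s):
            raise ConfigError("lag_range_s must be non-negative")
        if self.duration_s < 60.0:
            raise ConfigError("duration must allow at least two 30-s segments")
        if self.piece_boundaries_s is None:
            # default: three equal back-to-back pieces spanning the recording
            third = self.duration_s / 3.0
            self.piece_boundaries_s = [
                (label, k * third, (k + 1) * third)
                for k, label in enumerate(PIECE_LABELS)
            ]
        prev_end = 0.0
        for label, start, end in self.piece_boundaries_s:
            if not (0 <= start < end <= self.duration_s):
                raise ConfigError(f"piece {label!r} interval [{start}, {end}] outside recording")
            if start < prev_end:
                raise ConfigError(f"piece {label!r} overlaps the previous piece")
            prev_end = end
        for k in self.covariate_effects:
            if k not in TRAITS + FACTORS + AFFECT_CHANGES:
                raise ConfigError(f"unknown covariate {k!r} in covariate_effects")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.feature_rate_hz))

    def concert_ids(self):
        return [f"concert{k + 1:02d}" for k in range(self.n_concerts)]


@dataclass
class GroundTruth:
    """Planted simulator state for recovery tests.

    ``coupling[concert][pid][channel]``, ``lag_s[concert][pid]`` and
    ``covariates[concert][pid][name]`` record exactly what each participant's
    series and survey were built from.  RESP coupling is always zero.
    """

    coupling: dict = field(default_factory=dict)
    lag_s: dict = field(default_factory=dict)
    covariates: dict = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=dict)

    def update(self, other: "GroundTruth") -> None:
        self.coupling.update(other.coupling)
        self.lag_s.update(other.lag_s)
        self.covariates.update(other.covariates)
        self.covariate_effects = dict(other.covariate_effects)

    def covariate_frame(self) -> pd.DataFrame:
        rows = []
        for concert, by_pid in self.covariates.items():
            for pid, covs in by_pid.items():
                rows.append({"concert_id": concert, "participant_id": pid, **covs})
        return pd.DataFrame(rows)

    def coupling_frame(self) -> pd.DataFrame:
        rows = []
        for concert, by_pid in self.coupling.items():
            for pid, kappas in by_pid.items():
                rows.append(
                    {"concert_id": concert, "participant_id": pid,
                     "lag_s": self.lag_s[concert][pid], **kappas}
                )
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _stream(config: SimulationConfig, *keys: str) -> np.random.Generator:
    entropy = [config.seed & 0x7FFFFFFF] + [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _ar1(rng: np.random.Generator, n: int, phi: float, innovation_sd: float = 1.0) -> np.ndarray:
    eps = rng.normal(0.0, innovation_sd, size=n)
    if phi == 0:
        return eps
    out = np.empty(n)
    out[0] = eps[0] / np.sqrt(1 - phi**2)  # stationary start
    for t in range(1, n):
        out[t] = phi * out[t - 1] + eps[t]
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    # reflect-pad so the smoothed series keeps its length and phase
    pad = window // 2
    xp = np.pad(x, (pad, pad), mode="reflect")
    return np.convolve(xp, kernel, mode="same")[pad: pad + len(x)]


# ---------------------------------------------------------------------------
# driver and audience physiology
# ---------------------------------------------------------------------------

def generate_driver(config: SimulationConfig, concert_id: str) -> ChannelSeries:
    """The shared stimulus proxy: standardized smoothed AR(1) on the grid.

    Deterministic given (config.seed, concert_id).  With
    ``driver_smooth_s = 0`` the raw AR(1) is returned, whose lag-1
    autocorrelation equals ``driver_ar_coefficient``.
    """
    rng = _stream(config, "driver", concert_id)
    x = _ar1(rng, config.n_samples, config.driver_ar_coefficient)
    x = _moving_average(x, int(round(config.driver_smooth_s * config.feature_rate_hz)))
    return ChannelSeries(
        concert_id=concert_id,
        participant_id="__driver__",
        channel="driver",
        rate_hz=config.feature_rate_hz,
        values=_standardize(x),
    )


def _piece_gain(config: SimulationConfig, t: np.ndarray) -> np.ndarray:
    """Time-varying coupling multiplier from per-piece settings (default 1)."""
    gain = np.ones_like(t)
    for label, start, end in config.piece_boundaries_s:
        mult = config.piece_coupling.get(label, 1.0)
        gain[(t >= start) & (t < end)] = mult
    return gain


def _draw_covariates(config: SimulationConfig, rng: np.random.Generator, n: int) -> pd.DataFrame:
    cov = {}
    for trait in TRAITS:
        cov[trait] = np.clip(rng.normal(3.0, 0.7, size=n), 1.0, 5.0)
    F = rng.normal(size=(n, len(FACTORS)))
    if n > len(FACTORS) + 1:
        # orthogonalize the factor scores, then rescale to unit variance
        Fc = F - F.mean(axis=0)
        Q, _ = np.linalg.qr(Fc)
        F = Q / Q.std(axis=0)
    for j, name in enumerate(FACTORS):
        cov[name] = F[:, j]
    shifts = dict(_default_panava_shifts())
    shifts.update(config.panava_shifts)
    for scale in ("PA", "NA", "VA"):
        # change in effect-size convention (pre - post)/SD_pre = -shift
        cov[f"{scale}_change"] = rng.normal(-shifts.get(scale, 0.0), 1.0, size=n)
    return pd.DataFrame(cov)


def generate_audience(config: SimulationConfig, driver: ChannelSeries, concert_id: str):
    """Simulate one audience's five feature channels plus its ground truth.

    Returns ``(series, ground_truth)`` where ``series`` is a flat list of
    :class:`ChannelSeries` (participants x channels HR, HRV, SCR, RR, RESP).
    """
    n = config.n_participants_per_concert
    max_lag = config.lag_range_s
    if max_lag >= config.duration_s:
        raise ConfigError("lag_range_s exceeds the series duration")
    rng_cov = _stream(config, "covariates", concert_id)
    cov = _draw_covariates(config, rng_cov, n)
    centered = cov - cov.mean(axis=0)

    pids = [f"{concert_id}_p{k + 1:03d}" for k in range(n)]
    t = driver.time()
    gain = _piece_gain(config, t)

    gt = GroundTruth(covariate_effects=dict(config.covariate_effects))
    gt.coupling[concert_id] = {}
    gt.lag_s[concert_id] = {}
    gt.covariates[concert_id] = {}

    series: list[ChannelSeries] = []
    for i, pid in enumerate(pids):
        rng = _stream(config, "participant", pid)
        lag = float(rng.uniform(-max_lag, max_lag))
        shifted = np.interp(t - lag, t, driver.values)
        base = config.coupling_mean + sum(
            beta * float(centered[name].iloc[i])
            for name, beta in config.covariate_effects.items()
        )
        kappas = {}
        for channel in COUPLED_CHANNELS:
            kappa = base + rng.normal(0.0, config.coupling_sd)
            if not config.allow_negative_coupling:
                kappa = max(0.0, kappa)
            kappas[channel] = float(kappa)
            noise = _ar1(rng, config.n_samples, config.noise_ar_coefficient,
                         innovation_sd=config.noise_sd * np.sqrt(1 - config.noise_ar_coefficient**2))
            values = _standardize(kappa * gain * shifted + noise)
            series.append(ChannelSeries(concert_id, pid, channel, config.feature_rate_hz, values))
        # RESP: uncoupled breathing oscillator, ~15 breaths/min with slow drift
        kappas["RESP"] = 0.0
        f_drift = _moving_average(_ar1(rng, config.n_samples, 0.98), 15)
        freq = 0.25 + 0.03 * _standardize(f_drift)
        phase = 2 * np.pi * np.cumsum(freq) / config.feature_rate_hz
        resp = np.sin(phase + rng.uniform(0, 2 * np.pi)) + rng.normal(0, 0.1, config.n_samples)
        series.append(ChannelSeries(concert_id, pid, "RESP", config.feature_rate_hz,
                                    _standardize(resp)))
        gt.coupling[concert_id][pid] = kappas
        gt.lag_s[concert_id][pid] = lag
        gt.covariates[concert_id][pid] = {k: float(cov[k].iloc[i]) for k in cov.columns}
    return series, gt


# ---------------------------------------------------------------------------
# surveys
# ---------------------------------------------------------------------------

def generate_surveys(ground_truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """Survey table consistent with the planted covariates.

    Big-Five traits and factor scores are copied verbatim from the ground
    truth (they are the covariates the couplings were built from).  PANAVA
    pre scores are drawn around concert-hall values; post = pre minus the
    planted change (effect-size convention, pre-SD of 1), so the mean
    negative-activation decrease survives into a paired test.  Nine
    experience items per piece are drawn on the 1-5 scale around
    piece-specific means.
    """
    rows = []
    piece_labels = [label for label, _, _ in config.piece_boundaries_s]
    pre_means = {"PA": 0.7, "NA": -1.0, "VA": 1.3}
    for concert_id, by_pid in ground_truth.covariates.items():
        rng = _stream(config, "survey", concert_id)
        for pid, covs in by_pid.items():
            row = {"concert_id": concert_id, "participant_id": pid}
            for name in TRAITS + FACTORS:
                row[name] = covs[name]
            for scale in ("PA", "NA", "VA"):
                pre = rng.normal(pre_means[scale], 1.0)
                row[f"{scale}_pre"] = pre
                row[f"{scale}_post"] = pre - covs[f"{scale}_change"]
            for piece in piece_labels:
                for item in PIECE_ITEMS:
                    mu = _PIECE_ITEM_MEANS.get(item, {}).get(piece, 3.0)
                    row[f"{item}_{piece}"] = float(np.clip(rng.normal(mu, 0.8), 1.0, 5.0))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# raw-level signals (exercises the feature-extraction stage end to end)
# ---------------------------------------------------------------------------

def generate_raw_signals(
    audience_series: Sequence[ChannelSeries],
    driver: ChannelSeries,
    config: SimulationConfig,
    *,
    hr_mean_bpm: float = 70.0,
    hr_sd_bpm: float = 5.0,
    rr_mean_bpm: float = 15.0,
    rr_sd_bpm: float = 2.0,
    scr_rate_per_s: float = 0.08,
) -> dict:
    """Raw signals whose derived features track the feature-level targets.

    Per participant: beat times whose 60/IBI follows the (rescaled) HR
    target; a respiration waveform with instantaneous frequency RR/60; an
    electrodermal trace of slow tonic drift plus Poisson impulses (rate
    modulated by the driver) convolved with a bi-exponential kernel.

    Returns ``{participant_id: {"beat_times_s", "resp_waveform",
    "eda_trace", "raw_rate_hz"}}``.
    """
    by_pid: dict[str, dict] = {}
    targets: dict[str, dict] = {}
    for s in audience_series:
        targets.setdefault(s.participant_id, {})[s.channel] = s
    raw_rate = config.raw_rate_hz
    n_raw = int(round(config.duration_s * raw_rate))
    t_raw = np.arange(n_raw) / raw_rate
    kernel_t = np.arange(0, 10.0, 1.0 / raw_rate)
    kernel = np.exp(-kernel_t / 3.0) - np.exp(-kernel_t / 0.75)
    kernel /= kernel.max()

    for pid, chans in targets.items():
        if "HR" not in chans or "RR" not in chans:
            continue
        rng = _stream(config, "raw", pid)
        hr = chans["HR"]
        hr_bpm = hr_mean_bpm + hr_sd_bpm * hr.values
        if np.any(hr_bpm <= 0):
            raise SignalError("target heart rate must be positive")
        t_grid = hr.time()
        beats = [0.0]
        while beats[-1] < config.duration_s:
            bpm = float(np.interp(beats[-1], t_grid, hr_bpm))
            beats.append(beats[-1] + 60.0 / bpm)
        rr_bpm = rr_mean_bpm + rr_sd_bpm * chans["RR"].values
        rr_raw = np.interp(t_raw, chans["RR"].time(), np.clip(rr_bpm, 2.0, None))
        phase = 2 * np.pi * np.cumsum(rr_raw / 60.0) / raw_rate
        resp_waveform = np.sin(phase) + rng.normal(0, 0.02, n_raw)
        # electrodermal: tonic drift + driver-modulated sudomotor bursts
        drv = np.interp(t_raw, driver.time(), driver.values)
        rate = np.clip(scr_rate_per_s * (1.0 + 0.8 * drv), 0.0, None)
        impulses = rng.poisson(rate / raw_rate).astype(float)
        phasic = np.convolve(impulses, kernel)[:n_raw]
        tonic = 2.0 + 0.3 * np.sin(2 * np.pi * t_raw / config.duration_s) \
            + np.cumsum(rng.normal(0, 0.002, n_raw)) / np.sqrt(raw_rate)
        by_pid[pid] = {
            "beat_times_s": np.array(beats),
            "resp_waveform": resp_waveform,
            "eda_trace": tonic + 0.3 * phasic,
            "raw_rate_hz": raw_rate,
        }
    return by_pid


# ---------------------------------------------------------------------------
# whole datasets
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """All artifacts of one simulated concert series."""

    timeseries: pd.DataFrame     # concert_id, participant_id, channel, time_s, value
    survey: pd.DataFrame
    concert_meta: pd.DataFrame   # concert_id, piece, start_s, end_s
    ground_truth: GroundTruth
    series: list = field(default_factory=list, repr=False)


def generate_dataset(config: SimulationConfig) -> Dataset:
    """Simulate the full concert series (physiology + surveys + metadata)."""
    gt = GroundTruth(covariate_effects=dict(config.covariate_effects))
    all_series: list[ChannelSeries] = []
    for concert_id in config.concert_ids():
        driver = generate_driver(config, concert_id)
        series, gt_c = generate_audience(config, driver, concert_id)
        gt.update(gt_c)
        all_series.extend(series)
    frames = []
    for s in all_series:
        frames.append(pd.DataFrame({
            "concert_id": s.concert_id,
            "participant_id": s.participant_id,
            "channel": s.channel,
            "time_s": s.time(),
            "value": s.values,
        }))
    ts = pd.concat(frames, ignore_index=True)
    survey = generate_surveys(gt, config)
    meta = pd.DataFrame(
        [
            {"concert_id": cid, "piece": label, "start_s": start, "end_s": end}
            for cid in config.concert_ids()
            for label, start, end in config.piece_boundaries_s
        ]
    )
    return Dataset(timeseries=ts, survey=survey, concert_meta=meta,
                   ground_truth=gt, series=all_series)


def write_dataset(dataset: Dataset, outdir, fmt: str = "csv") -> dict:
    """Write timeseries/survey/meta/ground-truth files; returns the paths."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt == "parquet":
        ts_path = out / "timeseries.parquet"
        dataset.timeseries.to_parquet(ts_path, index=False)
    elif fmt == "csv":
        ts_path = out / "timeseries.csv"
        dataset.timeseries.to_csv(ts_path, index=False, na_rep="NA")
    else:
        raise ConfigError(f"unknown format {fmt!r}")
    survey_path = out / "survey.csv"
    dataset.survey.to_csv(survey_path, index=False, na_rep="NA")
    meta_path = out / "concert_meta.csv"
    dataset.concert_meta.to_csv(meta_path, index=False, na_rep="NA")
    gt_path = out / "ground_truth.json"
    dataset.ground_truth.to_json(gt_path)
    return {"timeseries": ts_path, "survey": survey_path,
            "concert_meta": meta_path, "ground_truth": gt_path}
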