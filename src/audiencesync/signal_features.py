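"""Feature extraction from raw physiological signals.

Converts raw-level recordings — inter-beat intervals from blood-volume pulse,
a respiration-belt waveform, an electrodermal trace — into the five feature
series the synchrony analysis runs on:

====== =========================================== ======================
name   meaning                                     units
====== =========================================== ======================
HR     instantaneous heart rate, 60 / IBI          beats per minute
HRV    windowed RMSSD of inter-beat intervals      milliseconds
RR     respiration rate from breath peak spacing   breaths per minute
RESP   the respiration waveform itself (z-scored)  normalized displacement
SCR    phasic skin conductance after moving-median arbitrary conductance
       detrending of the tonic level               units
====== =========================================== ======================

These are deliberately simple, dependency-light operators: the synchrony
statistic only consumes the temporal shape of each feature series, so a
transparent tonic/phasic split (moving median) and plain peak detection are
used rather than model-based deconvolution or device-specific pipelines.
All outputs land on one uniform feature grid per participant; samples without
support are NaN and are excluded pairwise downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import find_peaks

__all__ = [
    "ChannelSeries",
    "CHANNELS",
    "heart_rate_from_ibi",
    "rmssd_hrv",
    "respiration_features",
    "phasic_scr",
]

#: feature channels, in canonical order; RESP is the raw breathing waveform.
CHANNELS = ("HR", "HRV", "SCR", "RR", "RESP")


class SignalError(ValueError):
    """Raised for physiologically invalid or degenerate raw input."""


@dataclass
class ChannelSeries:
    """One participant's single-channel feature series on a uniform grid."""

    concert_id: str
    participant_id: str
    channel: str
    rate_hz: float
    values: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise SignalError("values must be a non-empty 1-d vector")
        if not (self.rate_hz > 0):
            raise SignalError("rate_hz must be positive")

    @property
    def n(self) -> int:
        return len(self.values)

    def time(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n) / self.rate_hz

    def slice_time(self, start_s: float, end_s: float) -> "ChannelSeries":
        t = self.time()
        mask = (t >= start_s) & (t < end_s)
        if not mask.any():
            raise SignalError("empty time slice")
        return ChannelSeries(
            concert_id=self.concert_id,
            participant_id=self.participant_id,
            channel=self.channel,
            rate_hz=self.rate_hz,
            values=self.values[mask].copy(),
            t0_s=float(t[mask][0]),
        )


def _feature_grid(duration_s: float, rate_hz: float, t0_s: float = 0.0) -> np.ndarray:
    return t0_s + np.arange(int(round(duration_s * rate_hz))) / rate_hz


# ---------------------------------------------------------------------------
# cardiac features
# ---------------------------------------------------------------------------

def heart_rate_from_ibi(
    beat_times_s: np.ndarray,
    feature_rate_hz: float,
    *,
    duration_s: float | None = None,
    concert_id: str = "",
    participant_id: str = "",
) -> ChannelSeries:
    """Instantaneous heart rate (60/IBI, beats/min) on the feature grid.

    Each inter-beat interval contributes one value at its ending beat time;
    the grid is filled by linear interpolation over beat times, held constant
    beyond the first/last beat.
    """
    t = np.asarray(beat_times_s, dtype=float)
    if len(t) < 2:
        raise SignalError("need at least 2 beats")
    ibi = np.diff(t)
    if np.any(ibi <= 0):
        raise SignalError("inter-beat intervals must be positive")
    hr = 60.0 / ibi
    if duration_s is None:
        duration_s = t[-1]
    grid = _feature_grid(duration_s, feature_rate_hz)
    values = np.interp(grid, t[1:], hr)
    return ChannelSeries(concert_id, participant_id, "HR", feature_rate_hz, values)


def rmssd_hrv(
    beat_times_s: np.ndarray,
    feature_rate_hz: float,
    *,
    window_s: float = 30.0,
    duration_s: float | None = None,
    concert_id: str = "",
    participant_id: str = "",
) -> ChannelSeries:
    """Short-term heart-rate variability: windowed RMSSD in milliseconds.

    For each grid point, the RMSSD (root mean square of successive
    inter-beat-interval differences) is computed from the beats falling in a
    window of ``window_s`` centered on it.  One successive difference (three
    beats) suffices for a defined value; windows with fewer are NaN.  RMSSD is
    invariant to adding a constant to all IBIs.
    """
    t = np.asarray(beat_times_s, dtype=float)
    if len(t) < 2:
        raise SignalError("need at least 2 beats")
    ibi_ms = np.diff(t) * 1000.0
    # successive IBI difference k is anchored at beat time t[k+1]
    diff_times = t[2:]
    sq_diffs = np.diff(ibi_ms) ** 2
    if duration_s is None:
        duration_s = t[-1]
    grid = _feature_grid(duration_s, feature_rate_hz)
    values = np.full(len(grid), np.nan)
    half = window_s / 2.0
    if len(sq_diffs) == 0:
        warnings.warn("fewer than 3 beats overall: HRV is all-missing")
    else:
        lo = np.searchsorted(diff_times, grid - half, side="left")
        hi = np.searchsorted(diff_times, grid + half, side="right")
        csum = np.concatenate([[0.0], np.cumsum(sq_diffs)])
        cnt = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            means = (csum[hi] - csum[lo]) / cnt
        values[cnt > 0] = np.sqrt(means[cnt > 0])
        if not np.any(cnt > 0):
            warnings.warn("no window contains 2 inter-beat intervals; HRV all-missing")
    return ChannelSeries(concert_id, participant_id, "HRV", feature_rate_hz, values)


# ---------------------------------------------------------------------------
# respiration
# ---------------------------------------------------------------------------

def respiration_features(
    waveform: np.ndarray,
    waveform_rate_hz: float,
    feature_rate_hz: float,
    *,
    min_breath_spacing_s: float = 1.5,
    concert_id: str = "",
    participant_id: str = "",
):
    """Respiration rate and normalized breathing waveform from a belt signal.

    RR is 60 / (inter-peak interval) in breaths/min, from local maxima with
    prominence at least 0.25 x SD of the waveform and spacing at least
    ``min_breath_spacing_s``, linearly interpolated to the feature grid.
    RESP is the waveform itself, z-scored and resampled to the grid, so the
    phase of inhalation/exhalation is preserved.

    Returns ``(rr, resp)``; if fewer than 2 breath peaks are found, ``rr`` is
    None (undefined) and only RESP is usable.
    """
    w = np.asarray(waveform, dtype=float)
    if len(w) < 4:
        raise SignalError("waveform too short")
    duration_s = len(w) / waveform_rate_hz
    grid = _feature_grid(duration_s, feature_rate_hz)
    t_w = np.arange(len(w)) / waveform_rate_hz

    sd = np.nanstd(w)
    if sd > 0:
        resp_values = np.interp(grid, t_w, (w - np.nanmean(w)) / sd)
    else:
        resp_values = np.zeros(len(grid))
    resp = ChannelSeries(concert_id, participant_id, "RESP", feature_rate_hz, resp_values)

    rr = None
    if sd > 0:
        peaks, _ = find_peaks(
            w,
            prominence=0.25 * sd,
            distance=max(1, int(round(min_breath_spacing_s * waveform_rate_hz))),
        )
        if len(peaks) >= 2:
            peak_t = t_w[peaks]
            rr_inst = 60.0 / np.diff(peak_t)
            rr_values = np.interp(grid, peak_t[1:], rr_inst)
            rr = ChannelSeries(concert_id, participant_id, "RR", feature_rate_hz, rr_values)
    if rr is None:
        warnings.warn("fewer than 2 breath peaks: RR undefined")
    return rr, resp


# ---------------------------------------------------------------------------
# electrodermal activity
# ---------------------------------------------------------------------------

def phasic_scr(
    eda_trace: np.ndarray,
    trace_rate_hz: float,
    feature_rate_hz: float,
    *,
    tonic_window_s: float = 20.0,
    concert_id: str = "",
    participant_id: str = "",
) -> ChannelSeries:
    """Phasic skin-conductance response by moving-median detrending.

    The tonic level is a centered moving median over ``tonic_window_s``; the
    phasic SCR is the residual above it, clipped at zero (conductance bursts
    are strictly positive deflections), resampled to the feature grid.
    """
    x = np.asarray(eda_trace, dtype=float)
    if len(x) == 0 or np.all(np.isnan(x)):
        raise SignalError("electrodermal trace is empty or all-missing")
    win = max(3, int(round(tonic_window_s * trace_rate_hz)) | 1)  # odd length
    tonic = median_filter(x, size=win, mode="nearest")
    phasic = np.clip(x - tonic, 0.0, None)
    duration_s = len(x) / trace_rate_hz
    grid = _feature_grid(duration_s, feature_rate_hz)
    t_x = np.arange(len(x)) / trace_rate_hz
    values = np.interp(grid, t_x, phasic)
    return ChannelSeries(concert_id, participant_id, "SCR", feature_rate_hz, values)
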