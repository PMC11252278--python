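"""Dyadic surrogate synchrony (SUSY).

The statistic quantifies how strongly two feature time series co-vary on the
timescale of seconds, against a null in which their temporal alignment is
destroyed.  The recipe:

1. Cut both series into consecutive non-overlapping segments (default 30 s).
2. Within each aligned segment pair, compute Pearson cross-correlations at
   every integer lag in ``[-max_lag_s, +max_lag_s]`` samples (default +/-5 s,
   i.e. a 10-s cross-correlation range).
3. Fisher-Z transform each correlation (arctanh), average over lags within a
   segment, then over segments: the observed synchrony ``Z``.  The sign is
   kept, so in-phase coupling gives Z > 0 and anti-phase coupling Z < 0.
4. Build surrogate series by re-pairing segments of one series with a random
   derangement (permutation without fixed points) of the other's segments and
   re-aggregating; the surrogate distribution yields
   ``ES = (Z - mean(Zsurr)) / sd(Zsurr)``.

Implementation note: for one dyad all segment-by-segment mean-Z values are
precomputed into a matrix ``Zmat[i, j]`` (segment i of x against segment j of
y).  The observed Z is the mean of the diagonal and every surrogate is a mean
over a permutation's entries, so adding surrogates costs only indexing.
"""

from __future__ import annotations

import itertools
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SusyParams",
    "DyadResult",
    "segment",
    "fisher_z",
    "segment_cross_correlations",
    "observed_Z",
    "surrogate_Z",
    "dyad_synchrony",
]

#: correlations are clipped to +/- this value before arctanh so that degenerate
#: identical segments (r = 1 exactly) stay finite.
R_CLIP = 0.999


class SusyError(ValueError):
    """Raised when a series cannot support the synchrony computation."""


@dataclass(frozen=True)
class SusyParams:
    """Tuning parameters of the surrogate-synchrony statistic.

    Parameters
    ----------
    segment_length_s:
        Segment duration in seconds.  Cross-correlations are computed within
        aligned segments; surrogates shuffle whole segments.
    max_lag_s:
        Maximum lag in seconds on either side; the cross-correlation range is
        ``2 * max_lag_s``.
    n_surrogates:
        Number of surrogate re-pairings.  Capped at the number of distinct
        derangements when that number is smaller.
    min_overlap_fraction:
        A lag (or a partially missing segment) enters the aggregation only if
        the pairwise-complete overlap covers at least this fraction of the
        segment.
    rng_seed:
        Master seed; each dyad derives an independent stream from it, keyed by
        channel, scope and the unordered participant pair, so results do not
        depend on evaluation order.
    surrogate_mode:
        ``"derangement"`` (default): each surrogate pairs the segment sequence
        of one series with a derangement of the other's and aggregates like
        the observed statistic.  ``"segment_pairs"``: the null is the set of
        all n(n-1) single segment mispairings.
    """

    segment_length_s: float = 30.0
    max_lag_s: float = 5.0
    n_surrogates: int = 100
    min_overlap_fraction: float = 0.8
    rng_seed: int = 0
    surrogate_mode: str = "derangement"

    def __post_init__(self) -> None:
        if not (0 < self.min_overlap_fraction <= 1):
            raise SusyError("min_overlap_fraction must be in (0, 1]")
        if self.max_lag_s >= self.segment_length_s:
            raise SusyError("max_lag_s must be smaller than segment_length_s")
        if self.n_surrogates < 1:
            raise SusyError("n_surrogates must be positive")
        if self.surrogate_mode not in ("derangement", "segment_pairs"):
            raise SusyError(f"unknown surrogate_mode {self.surrogate_mode!r}")

    def segment_samples(self, rate_hz: float) -> int:
        n = int(round(self.segment_length_s * rate_hz))
        if n < 2:
            raise SusyError("segment_length_s x rate must give >= 2 samples")
        return n

    def lag_samples(self, rate_hz: float) -> int:
        return int(round(self.max_lag_s * rate_hz))


@dataclass
class DyadResult:
    """Observed synchrony, surrogate summary and effect size for one pair."""

    id_a: str
    id_b: str
    channel: str
    scope: str
    Z: float
    Zsurr_mean: float
    Zsurr_sd: float
    ES: float
    n_segments: int
    n_surrogates_used: int
    surrogate_Z: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment(values: np.ndarray, rate_hz: float, params: SusyParams):
    """Cut a series into consecutive segments; drop the trailing partial one.

    Returns ``(segments, usable)`` where ``segments`` is an
    ``(n_segments, segment_samples)`` array and ``usable`` marks segments whose
    missing fraction does not exceed ``1 - min_overlap_fraction``.
    """
    values = np.asarray(values, dtype=float)
    seg_len = params.segment_samples(rate_hz)
    n_seg = len(values) // seg_len
    if n_seg < 2:
        raise SusyError(
            f"series of {len(values)} samples yields {n_seg} segments of "
            f"{seg_len}; at least 2 are required for surrogates"
        )
    segs = values[: n_seg * seg_len].reshape(n_seg, seg_len)
    missing_frac = np.isnan(segs).mean(axis=1)
    usable = missing_frac <= (1.0 - params.min_overlap_fraction)
    return segs, usable


# ---------------------------------------------------------------------------
# correlation machinery
# ---------------------------------------------------------------------------

def fisher_z(r):
    """Fisher's Z transform, arctanh, with clipping at +/-0.999.

    Accepts scalars or arrays; NaN passes through.  Values outside [-1, 1]
    (beyond float tolerance) raise.
    """
    r = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(np.abs(r) > 1.0 + 1e-12):
            raise SusyError("correlation outside [-1, 1]")
    out = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    return float(out) if out.ndim == 0 else out


def _lag_slices(seg_len: int, lag: int):
    """Index ranges pairing x[t] with y[t + lag] inside one segment."""
    if lag >= 0:
        return slice(0, seg_len - lag), slice(lag, seg_len)
    return slice(-lag, seg_len), slice(0, seg_len + lag)


def _cross_corr_matrix(xsegs: np.ndarray, ysegs: np.ndarray, lag: int):
    """Pearson r of every x-segment against every y-segment at one lag.

    Vectorized for complete data; rows/columns are standardized within the
    overlap window.  Zero-variance windows give NaN.
    """
    seg_len = xsegs.shape[1]
    sx, sy = _lag_slices(seg_len, lag)
    A = xsegs[:, sx]
    B = ysegs[:, sy]
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    na = np.sqrt((A * A).sum(axis=1))
    nb = np.sqrt((B * B).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (A @ B.T) / (na[:, None] * nb[None, :])
    R[~np.isfinite(R)] = np.nan
    return R


def _cross_corr_matrix_masked(xsegs, ysegs, lag, min_overlap):
    """NaN-tolerant fallback: pairwise-complete Pearson r per segment pair."""
    seg_len = xsegs.shape[1]
    sx, sy = _lag_slices(seg_len, lag)
    A, B = xsegs[:, sx], ysegs[:, sy]
    n_x, n_y = A.shape[0], B.shape[0]
    R = np.full((n_x, n_y), np.nan)
    for i in range(n_x):
        for j in range(n_y):
            a, b = A[i], B[j]
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() < min_overlap:
                continue
            a, b = a[ok], b[ok]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                continue
            R[i, j] = np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)
    return R


def segment_cross_correlations(
    x_seg: np.ndarray, y_seg: np.ndarray, params: SusyParams, rate_hz: float = 1.0
) -> np.ndarray:
    """Lagged Pearson correlations between two aligned segments.

    Returns one r per integer lag in ``[-max_lag, +max_lag]`` samples
    (positive lag: y lags x, i.e. x[t] is paired with y[t + lag]).  Lags whose
    overlap falls below ``min_overlap_fraction`` of the segment, or with zero
    variance, are NaN.
    """
    x_seg = np.asarray(x_seg, dtype=float)[None, :]
    y_seg = np.asarray(y_seg, dtype=float)[None, :]
    seg_len = x_seg.shape[1]
    max_lag = params.lag_samples(rate_hz)
    min_overlap = params.min_overlap_fraction * seg_len
    out = np.full(2 * max_lag + 1, np.nan)
    has_nan = np.isnan(x_seg).any() or np.isnan(y_seg).any()
    for k, lag in enumerate(range(-max_lag, max_lag + 1)):
        if seg_len - abs(lag) < min_overlap:
            continue
        if has_nan:
            out[k] = _cross_corr_matrix_masked(x_seg, y_seg, lag, min_overlap)[0, 0]
        else:
            out[k] = _cross_corr_matrix(x_seg, y_seg, lag)[0, 0]
    return out


def _segment_z_matrix(xsegs, ysegs, params: SusyParams, rate_hz: float):
    """Mean Fisher-Z over lags for every (x segment, y segment) pair."""
    seg_len = xsegs.shape[1]
    max_lag = params.lag_samples(rate_hz)
    min_overlap = params.min_overlap_fraction * seg_len
    has_nan = np.isnan(xsegs).any() or np.isnan(ysegs).any()
    stack = []
    for lag in range(-max_lag, max_lag + 1):
        if seg_len - abs(lag) < min_overlap:
            continue
        if has_nan:
            R = _cross_corr_matrix_masked(xsegs, ysegs, lag, min_overlap)
        else:
            R = _cross_corr_matrix(xsegs, ysegs, lag)
        stack.append(fisher_z(R))
    if not stack:
        raise SusyError("no admissible lag under min_overlap_fraction")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(np.stack(stack), axis=0)


def _prepare_pair(x, y, params: SusyParams):
    """Segment both series, keep segments usable in both, return matrices."""
    if x.rate_hz != y.rate_hz:
        raise SusyError("series must share the feature rate")
    xsegs, xok = segment(x.values, x.rate_hz, params)
    ysegs, yok = segment(y.values, y.rate_hz, params)
    n = min(len(xsegs), len(ysegs))
    ok = xok[:n] & yok[:n]
    if ok.sum() < 2:
        raise SusyError("fewer than 2 usable segments shared by the dyad")
    return xsegs[:n][ok], ysegs[:n][ok]


def observed_Z(x, y, params: SusyParams):
    """Observed synchrony: mean over segments of mean-over-lags Fisher Z.

    Parameters are :class:`~audiencesync.signal_features.ChannelSeries`.
    Returns ``(Z, n_segments)``.
    """
    xsegs, ysegs = _prepare_pair(x, y, params)
    zmat = _segment_z_matrix(xsegs, ysegs, params, x.rate_hz)
    diag = np.diag(zmat)
    if np.all(np.isnan(diag)):
        raise SusyError("no usable segment")
    return float(np.nanmean(diag)), int(len(xsegs))


# ---------------------------------------------------------------------------
# surrogates
# ---------------------------------------------------------------------------

def _count_derangements(n: int) -> int:
    if n < 2:
        return 0
    a, b = 0, 1  # D(1), D(2)
    for k in range(3, n + 1):
        a, b = b, (k - 1) * (a + b)
    return b


def _all_derangements(n: int):
    idx = np.arange(n)
    return [np.array(p) for p in itertools.permutations(idx) if not np.any(np.array(p) == idx)]


def _random_derangement(rng: np.random.Generator, n: int) -> np.ndarray:
    idx = np.arange(n)
    while True:
        p = rng.permutation(n)
        if not np.any(p == idx):
            return p


def _derangements(rng: np.random.Generator, n: int, n_surrogates: int):
    """Seeded derangements; exhaustive when few exist, else sampled."""
    total = _count_derangements(n)
    if total == 0:
        raise SusyError("surrogates need >= 2 segments")
    if n <= 7 and total <= n_surrogates:
        if total == 1:
            warnings.warn("only one derangement exists for 2 segments")
        return _all_derangements(n)
    return [_random_derangement(rng, n) for _ in range(n_surrogates)]


def _dyad_rng(params: SusyParams, channel: str, scope: str, id_a: str, id_b: str):
    """Per-dyad RNG keyed by the unordered pair, channel and scope."""
    lo, hi = sorted([str(id_a), str(id_b)])
    key = [
        params.rng_seed & 0x7FFFFFFF,
        zlib.crc32(channel.encode()),
        zlib.crc32(scope.encode()),
        zlib.crc32(lo.encode()),
        zlib.crc32(hi.encode()),
    ]
    return np.random.default_rng(np.random.SeedSequence(key))


def _surrogate_values(zmat: np.ndarray, params: SusyParams, rng) -> np.ndarray:
    n = zmat.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        if params.surrogate_mode == "segment_pairs":
            off = zmat[~np.eye(n, dtype=bool)]
            return off[~np.isnan(off)]
        perms = _derangements(rng, n, params.n_surrogates)
        rows = np.arange(n)
        return np.array([np.nanmean(zmat[rows, p]) for p in perms])


def surrogate_Z(x, y, params: SusyParams) -> np.ndarray:
    """Surrogate synchrony values from segment-shuffled re-pairings."""
    a, b = (x, y) if str(x.participant_id) <= str(y.participant_id) else (y, x)
    xsegs, ysegs = _prepare_pair(a, b, params)
    zmat = _segment_z_matrix(xsegs, ysegs, params, a.rate_hz)
    rng = _dyad_rng(params, a.channel, "", a.participant_id, b.participant_id)
    return _surrogate_values(zmat, params, rng)


def dyad_synchrony(x, y, params: SusyParams, scope: str = "concert") -> DyadResult:
    """Full dyadic SUSY result: Z, surrogate summary, effect size.

    Symmetric in its arguments: the lag window is symmetric and the surrogate
    stream is keyed by the unordered pair, so swapping x and y changes
    nothing.
    """
    a, b = (x, y) if str(x.participant_id) <= str(y.participant_id) else (y, x)
    xsegs, ysegs = _prepare_pair(a, b, params)
    zmat = _segment_z_matrix(xsegs, ysegs, params, a.rate_hz)
    diag = np.diag(zmat)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        Z = float(np.nanmean(diag))
    rng = _dyad_rng(params, a.channel, scope, a.participant_id, b.participant_id)
    zsurr = _surrogate_values(zmat, params, rng)
    zsurr_mean = float(np.mean(zsurr))
    zsurr_sd = float(np.std(zsurr, ddof=1)) if len(zsurr) > 1 else 0.0
    if zsurr_sd > 0:
        es = (Z - zsurr_mean) / zsurr_sd
    else:
        warnings.warn("surrogate SD is zero; ES undefined")
        es = np.nan
    return DyadResult(
        id_a=str(a.participant_id),
        id_b=str(b.participant_id),
        channel=a.channel,
        scope=scope,
        Z=Z,
        Zsurr_mean=zsurr_mean,
        Zsurr_sd=zsurr_sd,
        ES=float(es),
        n_segments=int(len(xsegs)),
        n_surrogates_used=int(len(zsurr)),
        surrogate_Z=zsurr,
    )
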