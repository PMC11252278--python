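"""Audience-level synchrony: all pairs, contributions, presence tests.

A concert audience is treated as the ensemble of all unordered participant
pairs.  Audience synchrony is the mean of all dyadic synchronies; a
participant's *synchrony contribution* is the mean of the dyadic synchronies
that participant is part of (N-1 dyads in an audience of N), which turns the
inherently interpersonal statistic into an individual-level outcome for
regression.  The presence of synchrony in a channel is tested by a paired
t-test of observed contributions against their surrogate counterparts across
participants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signal_features import ChannelSeries
from .susy_core import DyadResult, SusyError, SusyParams, dyad_synchrony

__all__ = [
    "ContributionResult",
    "PresenceTestResult",
    "all_dyads",
    "contributions",
    "audience_synchrony",
    "slice_by_piece",
    "presence_test",
    "composite_contributions",
    "dyads_to_frame",
    "contributions_to_frame",
]


@dataclass
class ContributionResult:
    """One participant's synchrony contribution on one channel and scope."""

    concert_id: str
    participant_id: str
    channel: str
    scope: str
    Z_contribution: float
    Zsurr_contribution_mean: float
    Zsurr_contribution_sd: float
    ES_contribution: float
    n_partners: int


@dataclass
class PresenceTestResult:
    """Group-level test of observed vs surrogate synchrony contributions."""

    channel: str
    scope: str
    mean_Z: float
    mean_Zsurr: float
    t_statistic: float
    p_value: float
    mean_ES: float
    n: int


def all_dyads(
    audience_series: Sequence[ChannelSeries],
    channel: str,
    params: SusyParams,
    scope: str = "concert",
) -> list[DyadResult]:
    """Dyadic synchrony for every unordered pair on one channel.

    ``audience_series`` may mix channels; only ``channel`` is used.  An
    audience of N usable participants yields N(N-1)/2 results.  Dyads that
    fail (e.g. all-missing overlap) are skipped with a warning.
    """
    chan = [s for s in audience_series if s.channel == channel]
    if len(chan) < 2:
        raise SusyError(f"need >= 2 participants with channel {channel!r}")
    out = []
    for x, y in combinations(chan, 2):
        try:
            out.append(dyad_synchrony(x, y, params, scope=scope))
        except SusyError as exc:  # pragma: no cover - degenerate dyads
            warnings.warn(
                f"dyad ({x.participant_id}, {y.participant_id}) skipped: {exc}"
            )
    if not out:
        raise SusyError("no dyad could be computed")
    return out


def audience_synchrony(dyads: Sequence[DyadResult]) -> float:
    """Mean dyadic synchrony Z over all pairs of the audience."""
    if not dyads:
        raise SusyError("empty dyad list")
    return float(np.mean([d.Z for d in dyads]))


def contributions(
    dyads: Sequence[DyadResult], concert_id: str = ""
) -> list[ContributionResult]:
    """Per-participant synchrony contributions from a full dyad table.

    A participant's contribution is the mean of their N-1 dyadic Z values.
    The participant-level surrogate distribution is built draw-wise: the s-th
    surrogate contribution is the mean over partners of the s-th surrogate Z
    of each dyad, which preserves between-surrogate variance for the
    participant-level effect size.
    """
    if not dyads:
        raise SusyError("empty dyad list")
    by_pid: dict[str, list[DyadResult]] = {}
    for d in dyads:
        by_pid.setdefault(d.id_a, []).append(d)
        by_pid.setdefault(d.id_b, []).append(d)
    out = []
    for pid in sorted(by_pid):
        ds = by_pid[pid]
        zs = np.array([d.Z for d in ds])
        if np.all(np.isnan(zs)):
            warnings.warn(f"participant {pid} has no defined dyads; skipped")
            continue
        n_surr = min(len(d.surrogate_Z) for d in ds)
        surr = np.mean([d.surrogate_Z[:n_surr] for d in ds], axis=0)
        z_c = float(np.nanmean(zs))
        surr_mean = float(np.mean(surr))
        surr_sd = float(np.std(surr, ddof=1)) if n_surr > 1 else 0.0
        es = (z_c - surr_mean) / surr_sd if surr_sd > 0 else np.nan
        out.append(
            ContributionResult(
                concert_id=concert_id,
                participant_id=pid,
                channel=ds[0].channel,
                scope=ds[0].scope,
                Z_contribution=z_c,
                Zsurr_contribution_mean=surr_mean,
                Zsurr_contribution_sd=surr_sd,
                ES_contribution=float(es),
                n_partners=len(ds),
            )
        )
    return out


def slice_by_piece(
    series: Sequence[ChannelSeries],
    concert_meta: pd.DataFrame,
    params: SusyParams | None = None,
) -> dict[str, list[ChannelSeries]]:
    """Cut every series into per-piece sub-series.

    ``concert_meta`` has columns concert_id, piece, start_s, end_s.  Pieces
    too short for at least two segments (when ``params`` is given) are
    skipped with a warning.  Boundaries outside a recording raise.
    """
    out: dict[str, list[ChannelSeries]] = {}
    meta_by_concert = dict(tuple(concert_meta.groupby("concert_id")))
    for s in series:
        meta = meta_by_concert.get(s.concert_id)
        if meta is None:
            continue
        t_end = s.t0_s + s.n / s.rate_hz
        for _, row in meta.iterrows():
            if row.start_s < s.t0_s - 1e-9 or row.end_s > t_end + 1e-9:
                raise SusyError(
                    f"piece {row.piece!r} [{row.start_s}, {row.end_s}] outside "
                    f"recording [{s.t0_s}, {t_end}]"
                )
            if params is not None and (row.end_s - row.start_s) < 2 * params.segment_length_s:
                warnings.warn(f"piece {row.piece!r} shorter than 2 segments; skipped")
                continue
            out.setdefault(row.piece, []).append(s.slice_time(row.start_s, row.end_s))
    return out


def presence_test(contribs: Sequence[ContributionResult]) -> PresenceTestResult:
    """Paired t-test of observed vs surrogate synchrony contributions.

    Tests the null that the distributions of Z and Zsurr across participants
    share a mean; a significantly positive difference indicates synchrony.
    """
    pairs = [
        (c.Z_contribution, c.Zsurr_contribution_mean, c.ES_contribution)
        for c in contribs
        if np.isfinite(c.Z_contribution) and np.isfinite(c.Zsurr_contribution_mean)
    ]
    if len(pairs) < 3:
        raise SusyError("presence test needs >= 3 participants")
    z, zs, es = map(np.array, zip(*pairs))
    diffs = z - zs
    if np.allclose(diffs, 0.0):
        warnings.warn("all Z equal Zsurr; t reported as 0")
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_rel(z, zs)
    return PresenceTestResult(
        channel=contribs[0].channel,
        scope=contribs[0].scope,
        mean_Z=float(np.mean(z)),
        mean_Zsurr=float(np.mean(zs)),
        t_statistic=float(t_stat),
        p_value=float(p),
        mean_ES=float(np.nanmean(es)),
        n=len(pairs),
    )


def composite_contributions(
    contribs: Sequence[ContributionResult],
    channels: Sequence[str] = ("HR", "HRV", "SCR", "RR"),
) -> list[ContributionResult]:
    """Overall synchrony across channels (breathing waveform excluded).

    Each participant's composite is the mean of their channel-wise effect
    sizes after z-standardizing ES within concert and channel, so channels
    with different ES scales weigh equally.  Participants missing a channel
    contribute the mean of their remaining channels (pairwise deletion).
    """
    df = contributions_to_frame([c for c in contribs if c.channel in channels])
    if df.empty:
        raise SusyError("no contributions on the requested channels")
    df = df[np.isfinite(df["ES_contribution"])]

    def _zscore(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        return (x - x.mean()) / sd if sd > 0 else x - x.mean()

    df = df.copy()
    df["es_std"] = df.groupby(["concert_id", "channel"])["ES_contribution"].transform(_zscore)
    out = []
    grouped = df.groupby(["concert_id", "participant_id", "scope"])
    for (concert_id, pid, scope), g in grouped:
        out.append(
            ContributionResult(
                concert_id=concert_id,
                participant_id=pid,
                channel="ALL",
                scope=scope,
                Z_contribution=np.nan,
                Zsurr_contribution_mean=np.nan,
                Zsurr_contribution_sd=np.nan,
                ES_contribution=float(g["es_std"].mean()),
                n_partners=int(g["n_partners"].max()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# tabular views
# ---------------------------------------------------------------------------

def dyads_to_frame(dyads: Sequence[DyadResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id_a": d.id_a, "id_b": d.id_b, "channel": d.channel,
                "scope": d.scope, "Z": d.Z, "Zsurr_mean": d.Zsurr_mean,
                "Zsurr_sd": d.Zsurr_sd, "ES": d.ES,
                "n_segments": d.n_segments,
                "n_surrogates_used": d.n_surrogates_used,
            }
            for d in dyads
        ]
    )


def contributions_to_frame(contribs: Sequence[ContributionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "concert_id": c.concert_id, "participant_id": c.participant_id,
                "channel": c.channel, "scope": c.scope,
                "Z_contribution": c.Z_contribution,
                "Zsurr_contribution_mean": c.Zsurr_contribution_mean,
                "Zsurr_contribution_sd": c.Zsurr_contribution_sd,
                "ES_contribution": c.ES_contribution,
                "n_partners": c.n_partners,
            }
            for c in contribs
        ]
    )
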