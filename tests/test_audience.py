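"""Tests for audience-level aggregation of dyadic synchronies."""

import numpy as np
import pandas as pd
import pytest

from audiencesync import (
    SusyParams,
    all_dyads,
    audience_synchrony,
    composite_contributions,
    contributions,
    presence_test,
    slice_by_piece,
)
from audiencesync.audience import ContributionResult
from audiencesync.susy_core import DyadResult, SusyError


def fake_dyads(n_participants, rng, n_surr=10, channel="HR"):
    """Synthetic all-pairs dyad table with random Z and surrogate draws."""
    pids = [f"p{k:02d}" for k in range(n_participants)]
    out = []
    for i in range(n_participants):
        for j in range(i + 1, n_participants):
            surr = rng.normal(0, 0.05, size=n_surr)
            z = rng.normal(0.1, 0.2)
            out.append(DyadResult(
                id_a=pids[i], id_b=pids[j], channel=channel, scope="concert",
                Z=z, Zsurr_mean=surr.mean(), Zsurr_sd=surr.std(ddof=1),
                ES=(z - surr.mean()) / surr.std(ddof=1),
                n_segments=10, n_surrogates_used=n_surr, surrogate_Z=surr,
            ))
    return out


class TestAllDyads:
    @pytest.mark.parametrize("n, expected", [(2, 1), (5, 10)])
    def test_pair_counts(self, n, expected, white_noise, params):
        series = [white_noise(120, pid=f"p{k}", seed=k) for k in range(n)]
        assert len(all_dyads(series, "HR", params)) == expected

    def test_single_participant_rejected(self, white_noise, params):
        with pytest.raises(SusyError):
            all_dyads([white_noise(120, "p0", 0)], "HR", params)


class TestContributions:
    def test_partner_counts(self):
        rng = np.random.default_rng(0)
        contribs = contributions(fake_dyads(6, rng), "c1")
        assert all(c.n_partners == 5 for c in contribs)

    def test_equal_dyads_give_equal_contributions(self):
        rng = np.random.default_rng(1)
        dyads = fake_dyads(4, rng)
        for d in dyads:
            d.Z = 0.42
        contribs = contributions(dyads)
        assert all(c.Z_contribution == pytest.approx(0.42) for c in contribs)

    @pytest.mark.parametrize("seed", range(5))
    def test_mean_contribution_equals_audience_synchrony(self, seed):
        # each dyad enters two participants' means, normalized by N-1, so the
        # grand mean over participants equals the mean over dyads exactly
        rng = np.random.default_rng(seed)
        dyads = fake_dyads(6, rng)
        contribs = contributions(dyads)
        assert np.mean([c.Z_contribution for c in contribs]) == pytest.approx(
            audience_synchrony(dyads), abs=1e-12
        )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        dyads = fake_dyads(5, rng)
        by_pid = {c.participant_id: c.Z_contribution for c in contributions(dyads)}
        relabel = {f"p{k:02d}": f"q{(k + 2) % 5:02d}" for k in range(5)}
        for d in dyads:
            d.id_a, d.id_b = relabel[d.id_a], relabel[d.id_b]
        by_new = {c.participant_id: c.Z_contribution for c in contributions(dyads)}
        for old, new in relabel.items():
            assert by_new[new] == pytest.approx(by_pid[old], abs=1e-15)


class TestSliceByPiece:
    def meta(self, pieces):
        return pd.DataFrame(
            [{"concert_id": "c1", "piece": p, "start_s": a, "end_s": b}
             for p, a, b in pieces]
        )

    def test_piece_lengths(self, white_noise):
        s = white_noise(300, "p0", 0)
        sliced = slice_by_piece([s], self.meta([("A", 0, 120), ("B", 120, 300)]))
        assert len(sliced["A"][0].values) == 120  # 4 segments of 30 s
        assert len(sliced["B"][0].values) == 180

    def test_boundaries_outside_recording_raise(self, white_noise):
        s = white_noise(100, "p0", 0)
        with pytest.raises(SusyError):
            slice_by_piece([s], self.meta([("A", 0, 500)]))

    def test_short_piece_skipped_with_warning(self, white_noise, params):
        s = white_noise(300, "p0", 0)
        with pytest.warns(UserWarning):
            sliced = slice_by_piece([s], self.meta([("A", 0, 45), ("B", 45, 300)]), params)
        assert "A" not in sliced and "B" in sliced

    def test_piece_samples_bounded_by_total(self, white_noise):
        s = white_noise(300, "p0", 0)
        sliced = slice_by_piece([s], self.meta([("A", 0, 100), ("B", 150, 290)]))
        assert sum(len(v[0].values) for v in sliced.values()) <= 300


class TestPresenceTest:
    def test_z_equal_zsurr_gives_t_zero(self):
        rng = np.random.default_rng(0)
        contribs = contributions(fake_dyads(5, rng))
        for c in contribs:
            c.Zsurr_contribution_mean = c.Z_contribution
        with pytest.warns(UserWarning):
            res = presence_test(contribs)
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0

    def test_needs_three_participants(self):
        rng = np.random.default_rng(1)
        contribs = contributions(fake_dyads(2, rng))
        with pytest.raises(SusyError):
            presence_test(contribs)


class TestComposite:
    def _contrib(self, pid, channel, es, concert="c1"):
        return ContributionResult(
            concert_id=concert, participant_id=pid, channel=channel,
            scope="concert", Z_contribution=0.1, Zsurr_contribution_mean=0.0,
            Zsurr_contribution_sd=0.05, ES_contribution=es, n_partners=3,
        )

    def test_identical_patterns_across_channels(self):
        es_by_pid = {"p1": -1.0, "p2": 0.0, "p3": 1.0}
        contribs = [
            self._contrib(pid, ch, 2.0 * es + shift)
            for pid, es in es_by_pid.items()
            for ch, shift in [("HR", 0.0), ("HRV", 5.0), ("SCR", -1.0), ("RR", 2.0)]
        ]
        comps = {c.participant_id: c.ES_contribution
                 for c in composite_contributions(contribs)}
        # after within-channel standardization every channel carries the same
        # participant pattern, so the composite is that standardized pattern
        expected = {"p1": -1.0, "p2": 0.0, "p3": 1.0}
        for pid, v in expected.items():
            assert comps[pid] == pytest.approx(v, abs=1e-12)

    def test_composite_centered_within_concert(self):
        rng = np.random.default_rng(2)
        contribs = [
            self._contrib(f"p{k}", ch, rng.normal())
            for k in range(6) for ch in ("HR", "HRV", "SCR", "RR")
        ]
        vals = [c.ES_contribution for c in composite_contributions(contribs)]
        assert np.mean(vals) == pytest.approx(0.0, abs=1e-12)

    def test_missing_channel_uses_remaining(self):
        contribs = [
            self._contrib(pid, ch, es)
            for pid, es in [("p1", -1.0), ("p2", 0.0), ("p3", 1.0)]
            for ch in ("HR", "HRV")
        ]
        contribs.append(self._contrib("p1", "SCR", np.nan))  # dropped pairwise
        comps = composite_contributions(contribs)
        assert len(comps) == 3
        assert all(np.isfinite(c.ES_contribution) for c in comps)
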