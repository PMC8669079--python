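"""Protocol arithmetic and search logic (simulation-free parts)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isthmus import analysis as A
from isthmus import geometry as G
from isthmus import protocols as P


def _proto(**kw):
    site = G.ElectrodeSet([(np.array([0, 1, 2]), G.APPLIED)], "atp_block")
    return P.PacingProtocol(site=site, **kw)


class TestAtpSchedule:
    def test_burst_rule_at_vtcl_400(self):
        proto = _proto()
        seq1 = P.atp_schedule(400.0, 0.0, proto, sequence=1)
        assert seq1[0] == pytest.approx(352.0)  # 0.88 x 400
        assert np.diff(seq1) == pytest.approx(352.0)
        assert len(seq1) == 8
        seq2 = P.atp_schedule(400.0, 0.0, proto, sequence=2)
        assert np.diff(seq2) == pytest.approx(342.0)  # 10 ms faster

    def test_start_offset_from_last_sensed_activation(self):
        seq1 = P.atp_schedule(500.0, 1000.0, _proto(), sequence=1)
        assert seq1[0] == pytest.approx(1440.0)

    def test_zero_sequences_empty_schedule(self):
        proto = _proto(n_sequences=0)
        assert P.atp_schedule(400.0, 0.0, proto, sequence=1) == []

    def test_interval_below_refractory_floor_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            P.atp_schedule(65.0, 0.0, _proto(), sequence=2)

    def test_nonpositive_vtcl_rejected(self):
        with pytest.raises(ValueError):
            P.atp_schedule(0.0, 0.0, _proto())

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        vtcl=st.floats(150.0, 600.0),
        t_last=st.floats(0.0, 5000.0),
    )
    def test_intervals_uniform_and_fraction_exact(self, vtcl, t_last):
        seq1 = P.atp_schedule(vtcl, t_last, _proto(), sequence=1)
        gaps = np.diff(seq1)
        np.testing.assert_allclose(gaps, 0.88 * vtcl, rtol=1e-12)
        assert seq1[0] == pytest.approx(t_last + 0.88 * vtcl)


class TestStrengthSelection:
    def test_quota_rule_on_worked_example(self):
        mins = [10.0, 10.0, 20.0, 20.0, 30.0, 100.0]
        s_p, s_f = P.select_protocol_strengths(mins)
        assert s_p == 30.0 and s_f == 100.0

    def test_all_equal_collapses_both(self):
        s_p, s_f = P.select_protocol_strengths([40.0] * 6)
        assert s_p == s_f == 40.0

    def test_one_refractory_episode_blocks_full_quota_only(self):
        mins = [10.0, 20.0, 20.0, 30.0, 30.0, P.NotFound]
        s_p, s_f = P.select_protocol_strengths(mins)
        assert s_p == 30.0
        assert s_f is P.NotFound

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(10.0, 500.0), min_size=6, max_size=6))
    def test_agrees_with_bruteforce_count(self, mins):
        s_p, s_f = P.select_protocol_strengths(mins)
        # oracle: smallest strength among the candidates terminating >= quota
        for quota, got in ((5, s_p), (6, s_f)):
            ok = sorted(v for v in mins if sum(m <= v for m in mins) >= quota)
            assert got == ok[0]


class _FakeEpisode:
    vtcl = 300.0
    vt_class = A.SLOW


class TestStrengthSearch:
    def _patch(self, monkeypatch, threshold):
        calls = []

        def fake_run_shock(episode, shock, window_factor=3.0):
            calls.append(shock.voltage)
            return P.TherapyOutcome(
                therapy="fake",
                strength=shock.voltage,
                terminated=shock.voltage >= threshold,
                vt_class=A.SLOW,
                vtcl=300.0,
                time_of_last_activation=0.0,
                post_window_used=900.0,
            )

        monkeypatch.setattr(P, "run_shock", fake_run_shock)
        return calls

    def test_returns_smallest_terminating_grid_point(self, monkeypatch):
        self._patch(monkeypatch, threshold=47.0)
        v = P.find_min_strength(_FakeEpisode(), None, step=10.0, vmax=100.0)
        assert v == 50.0

    def test_result_minus_step_simulated_and_fails(self, monkeypatch):
        calls = self._patch(monkeypatch, threshold=47.0)
        cache = {}
        v = P.find_min_strength(
            _FakeEpisode(), None, step=10.0, vmax=100.0, _cache=cache
        )
        assert cache[v].terminated
        assert not cache[v - 10.0].terminated

    def test_not_found_when_cap_reached(self, monkeypatch):
        self._patch(monkeypatch, threshold=1e9)
        v = P.find_min_strength(_FakeEpisode(), None, step=20.0, vmax=100.0)
        assert v is P.NotFound
        assert not v  # falsy sentinel

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(threshold=st.floats(5.0, 290.0))
    def test_matches_exhaustive_sweep_oracle(self, threshold):
        with pytest.MonkeyPatch.context() as mp:
            self._patch(mp, threshold)
            step, vmax = 15.0, 300.0
            v = P.find_min_strength(_FakeEpisode(), None, step=step, vmax=vmax)
        grid = np.arange(step, vmax + step / 2, step)
        oracle = [g for g in grid if g >= threshold]
        assert v == (oracle[0] if oracle else P.NotFound)

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            P.find_min_strength(_FakeEpisode(), None, step=0.0, vmax=100.0)


class TestTimingSweepTable:
    def test_failures_excluded_from_mean(self, monkeypatch):
        # voltage threshold depends on fraction: at 0.5 nothing terminates
        def fake_run_shock(episode, shock, window_factor=3.0):
            term = shock.onset_fraction > 0.6 and shock.voltage >= 40.0
            return P.TherapyOutcome(
                "fake", shock.voltage, term, A.SLOW, 300.0, 0.0, 900.0
            )

        monkeypatch.setattr(P, "run_shock", fake_run_shock)
        tab = P.timing_sweep(
            [_FakeEpisode(), _FakeEpisode()],
            None,
            fractions=(0.5, 0.88),
            step=20.0,
            vmax=100.0,
        )
        r05 = tab[tab.fraction == 0.5].iloc[0]
        r88 = tab[tab.fraction == 0.88].iloc[0]
        assert r05.n_failures == 2 and np.isnan(r05.mean_min_strength)
        assert r88.n_failures == 0 and r88.mean_min_strength == 40.0

    def test_single_episode_mean_is_its_min(self, monkeypatch):
        def fake_run_shock(episode, shock, window_factor=3.0):
            return P.TherapyOutcome(
                "fake", shock.voltage, shock.voltage >= 55.0, A.SLOW,
                300.0, 0.0, 900.0,
            )

        monkeypatch.setattr(P, "run_shock", fake_run_shock)
        tab = P.timing_sweep(
            [_FakeEpisode()], None, fractions=(0.88,), step=30.0, vmax=120.0
        )
        assert tab.iloc[0].mean_min_strength == 60.0

    def test_empty_episode_list_rejected(self):
        with pytest.raises(ValueError):
            P.timing_sweep([], None)


class TestShockSpecValidation:
    def _es(self):
        return G.ElectrodeSet(
            [(np.array([0]), G.APPLIED), (np.array([1]), G.GROUND)],
            "transmural_pair",
            meta={"n_cubes": 2},
        )

    @pytest.mark.parametrize(
        "kw",
        [
            dict(duration=0.0),
            dict(onset_fraction=0.0),
            dict(onset_fraction=1.2),
            dict(waveform="biphasic"),
        ],
    )
    def test_invalid_specs_rejected(self, kw):
        from isthmus.solver import ShockSpec

        with pytest.raises(ValueError):
            ShockSpec(self._es(), voltage=10.0, **kw)
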