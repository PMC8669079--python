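"""Activation sensing, cycle-length metrics, efficacy and energy accounting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isthmus import analysis as A
from isthmus import synthetic as SY


class TestDetectActivations:
    def test_constant_resting_trace_is_empty(self):
        t = np.arange(0, 1000, 0.5)
        series = A.detect_activations(t, np.full_like(t, -80.0))
        assert len(series) == 0

    def test_square_train_recovers_upstrokes(self):
        t = np.arange(0, 1500, 0.5)
        vm = np.where((t % 300) < 150, 10.0, -80.0)
        series = A.detect_activations(t, vm)
        assert len(series) == 4
        np.testing.assert_allclose(np.diff(series.times), 300.0)

    def test_refractory_gate_merges_close_crossings(self):
        t = np.arange(0, 200, 0.5)
        vm = np.full_like(t, -80.0)
        for onset in (50.0, 60.0):  # two crossings 10 ms apart
            vm[(t >= onset) & (t < onset + 4)] = 10.0
        series = A.detect_activations(t, vm)
        assert len(series) == 1

    def test_empty_trace_errors(self):
        with pytest.raises(ValueError, match="empty"):
            A.detect_activations(np.array([]), np.array([]))

    def test_roundtrip_on_synthetic_ap_train(self):
        spec = SY.FixtureSpec(seed=3, params={"n_pulses": 6, "period": 280.0})
        t, vm, truth = SY.make_ap_train(spec)
        series = A.detect_activations(t, vm)
        assert len(series) == len(truth)
        np.testing.assert_allclose(series.times, truth, atol=1.5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_noisy_train_recovered_within_one_sample(self, seed):
        spec = SY.FixtureSpec(
            seed=seed, params={"n_pulses": 4, "period": 300.0, "noise_sd": 2.0}
        )
        t, vm, truth = SY.make_ap_train(spec)
        series = A.detect_activations(t, vm)
        assert len(series) == len(truth)
        assert np.abs(series.times - truth).max() <= 2.0  # +-1 sample + rise


class TestVtclAndClass:
    def test_regular_times_give_exact_cycle_length(self):
        s = A.ActivationSeries("x", np.array([0.0, 300.0, 600.0, 900.0]))
        vtcl, cv = A.measure_vtcl(s)
        assert vtcl == 300.0 and cv == 0.0

    def test_mean_over_last_cycles(self):
        s = A.ActivationSeries("x", np.array([0.0, 300.0, 610.0, 900.0]))
        vtcl, cv = A.measure_vtcl(s)
        assert vtcl == pytest.approx(300.0)
        assert cv > 0

    def test_two_activations_error(self):
        with pytest.raises(ValueError):
            A.measure_vtcl(A.ActivationSeries("x", np.array([0.0, 300.0])))

    @pytest.mark.parametrize(
        "vtcl, expected",
        [(270.0, A.FAST), (320.0, A.FAST), (321.0, A.SLOW), (530.0, A.SLOW)],
    )
    def test_fast_slow_boundary_at_320(self, vtcl, expected):
        assert A.classify_vt(vtcl) == expected


class TestTermination:
    def _series(self, times):
        return A.ActivationSeries("ref", np.asarray(times, dtype=float))

    def test_resting_tissue_is_terminated(self):
        assert A.is_terminated(
            self._series([]), 300.0, therapy_end=1000.0, sim_end=2000.0,
            final_vm_max=-79.0,
        )

    def test_continuing_reentry_is_not_terminated(self):
        times = np.arange(1000.0, 2000.0, 300.0)
        assert not A.is_terminated(
            self._series(times), 300.0, 1000.0, 2000.0, final_vm_max=10.0
        )

    def test_single_early_ectopic_then_quiescence_is_terminated(self):
        # one post-therapy beat outside the final window
        assert A.is_terminated(
            self._series([1050.0]), 300.0, 1000.0, 2000.0, final_vm_max=-75.0
        )

    def test_short_follow_up_refuses_verdict(self):
        with pytest.raises(ValueError, match="shorter"):
            A.is_terminated(self._series([]), 300.0, 1000.0, 1500.0, -80.0)


class _Out:
    def __init__(self, therapy, strength, terminated, vt_class):
        self.therapy = therapy
        self.strength = strength
        self.terminated = terminated
        self.vt_class = vt_class


class TestEfficacy:
    def test_rounding_matches_printed_fractions(self):
        # 4/7 -> 57%, 2/7 -> 29%
        outs = [_Out("a", 1, i < 4, A.FAST) for i in range(7)]
        outs += [_Out("b", 1, i < 2, A.FAST) for i in range(7)]
        tab = A.efficacy(outs).frame
        a = tab[(tab.therapy == "a") & (tab["class"] == "ALL")].iloc[0]
        b = tab[(tab.therapy == "b") & (tab["class"] == "ALL")].iloc[0]
        assert a.efficacy == 57 and b.efficacy == 29

    def test_zero_successes(self):
        tab = A.efficacy([_Out("a", 1, False, A.SLOW)] * 5).frame
        assert (tab[tab["class"] == "ALL"].efficacy == 0).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.booleans(), st.sampled_from([A.SLOW, A.FAST])),
            min_size=1,
            max_size=40,
        )
    )
    def test_all_counts_equal_slow_plus_fast(self, rows):
        outs = [_Out("t", 10, ok, cls) for ok, cls in rows]
        tab = A.efficacy(outs).frame
        by = {r["class"]: r for _, r in tab.iterrows()}
        assert by["ALL"].n_total == by[A.SLOW].n_total + by[A.FAST].n_total
        assert by["ALL"].n_success == by[A.SLOW].n_success + by[A.FAST].n_success

    def test_empty_stratum_reported_not_dropped(self):
        tab = A.efficacy([_Out("t", 1, True, A.SLOW)] * 3).frame
        fast = tab[tab["class"] == A.FAST].iloc[0]
        assert fast.n_total == 0 and np.isnan(fast.efficacy)


class TestShockEnergy:
    def test_negative_voltage_rejected(self):
        with pytest.raises(ValueError):
            A.shock_energy(-1.0)

    def test_zero_voltage_zero_energy(self):
        assert A.shock_energy(0.0) == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        v1=st.floats(1.0, 2000.0),
        v2=st.floats(1.0, 2000.0),
    )
    def test_energy_ratio_is_square_of_voltage_ratio(self, v1, v2):
        r = A.shock_energy(v1) / A.shock_energy(v2)
        assert r == pytest.approx((v1 / v2) ** 2, rel=1e-12)

    def test_fitted_capacitance_reproduces_operating_points(self):
        pairs = [(860.0, 37.0), (1700.0, 145.0), (80.0, 0.32), (120.0, 0.72)]
        c = A.fit_capacitance(pairs)
        assert c == pytest.approx(A.DEFAULT_CAPACITANCE, rel=0.015)
        for v, e in pairs:
            assert A.shock_energy(v, c) == pytest.approx(e, rel=0.015)
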