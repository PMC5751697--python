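import math

import numpy as np
import pytest

from trajgrn.dynamic_model import (
    ModelSpecError,
    OdeModelSpec,
    RateSchedule,
    SegmentError,
    rate_at,
    regulatory_function,
    simulate_piecewise,
    simulate_segment,
)
from trajgrn.gp_smooth import SmoothedCurves


def _simple_spec(n=1, **overrides):
    base = dict(
        c=np.zeros(n), k0=np.zeros(n), d0=np.full(n, 0.3),
        A=np.ones(n), a=np.zeros((n, n)), b=np.zeros((n, n)),
    )
    base.update(overrides)
    return OdeModelSpec(**base)


class TestRegulatoryFunction:
    def test_zero_state_gives_zero(self):
        assert regulatory_function([0, 0], [1, 2], [1, 1]) == 0.0

    def test_pure_repression_gives_zero_numerator(self):
        assert regulatory_function([3, 5], [0, 0], [1, 2]) == 0.0

    def test_single_regulator_half_saturation(self):
        assert regulatory_function([1.0], [1.0], [1.0]) == pytest.approx(0.5)

    def test_activation_without_denominator_term_rejected(self):
        with pytest.raises(ModelSpecError):
            regulatory_function([1.0], [1.0], [0.0])
        with pytest.raises(ModelSpecError):
            OdeModelSpec(c=[0], k0=[1], d0=[1], A=[1],
                         a=[[1.0]], b=[[0.0]])

    def test_repression_decreases_with_repressor_level(self):
        f_low = regulatory_function([1.0, 0.5], [1.0, 0.0], [1.0, 1.0])
        f_high = regulatory_function([1.0, 5.0], [1.0, 0.0], [1.0, 1.0])
        assert f_high < f_low


class TestRateSchedules:
    def test_group1_preset_switches_k_at_t_up(self):
        spec = OdeModelSpec.with_group_presets(
            c=[0.1], k0=[2.0], d0=[0.5], A=[3.0],
            a=np.zeros((1, 1)), b=np.zeros((1, 1)), groups=[1],
        )
        ks = [s for s in spec.schedules[0] if s.rate == "k"]
        assert rate_at(2400.0, 2.0, ks) == 2.0
        assert rate_at(2600.0, 2.0, ks) == 6.0
        assert rate_at(2500.0, 2.0, ks) == 6.0  # switch is inclusive

    def test_group2_preset_windows(self):
        spec = OdeModelSpec.with_group_presets(
            c=[0.1], k0=[2.0], d0=[0.5], A=[4.0],
            a=np.zeros((1, 1)), b=np.zeros((1, 1)), groups=[2],
        )
        ks = [s for s in spec.schedules[0] if s.rate == "k"]
        ds = [s for s in spec.schedules[0] if s.rate == "d"]
        assert rate_at(750.0, 2.0, ks) == 8.0
        assert rate_at(1500.0, 2.0, ks) == 2.0
        assert rate_at(2750.0, 0.5, ds) == 2.0
        assert rate_at(3500.0, 0.5, ds) == 0.5

    def test_no_schedule_means_constant_rate(self):
        assert rate_at(123.0, 1.7, []) == 1.7

    def test_unit_multiplier_presets_reduce_to_constant_model(self):
        spec = OdeModelSpec.with_group_presets(
            c=[0.1, 0.1], k0=[2.0, 2.0], d0=[0.5, 0.5], A=[1.0, 1.0],
            a=np.zeros((2, 2)), b=np.zeros((2, 2)), groups=[1, 2],
        )
        for i in range(2):
            for t in (100.0, 750.0, 2500.0, 2750.0, 3500.0):
                k = [s for s in spec.schedules[i] if s.rate == "k"]
                d = [s for s in spec.schedules[i] if s.rate == "d"]
                assert rate_at(t, 2.0, k) == 2.0
                assert rate_at(t, 0.5, d) == 0.5

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ModelSpecError, match="overlap"):
            _simple_spec(schedules=[[
                RateSchedule("k", 0.0, 100.0, 2.0),
                RateSchedule("k", 50.0, 150.0, 3.0),
            ]])


class TestFreeParameters:
    def test_auto_regulation_adds_exactly_two(self):
        a = np.zeros((3, 3))
        b = np.zeros((3, 3))
        a[1, 0] = b[1, 0] = 1.0
        spec = _simple_spec(n=3, a=a, b=b, k0=np.ones(3))
        n_before = len(spec.free_parameter_names())
        a2, b2 = a.copy(), b.copy()
        a2[2, 2] = b2[2, 2] = 1.0
        spec2 = _simple_spec(n=3, a=a2, b=b2, k0=np.ones(3))
        assert len(spec2.free_parameter_names()) == n_before + 2

    def test_with_parameters_roundtrip(self):
        spec = _simple_spec(n=2, k0=np.ones(2))
        new = spec.with_parameters({"k0[1]": 3.5, "d0[0]": 0.7})
        assert new.get_parameter("k0[1]") == 3.5
        assert new.get_parameter("d0[0]") == 0.7
        assert spec.get_parameter("k0[1]") == 1.0  # original untouched

    def test_changed_A_propagates_into_schedules(self):
        spec = OdeModelSpec.with_group_presets(
            c=[0.1], k0=[2.0], d0=[0.5], A=[3.0],
            a=np.zeros((1, 1)), b=np.zeros((1, 1)), groups=[1], t_up=100.0,
        )
        new = spec.with_parameters({"A[0]": 5.0})
        ks = [s for s in new.schedules[0] if s.rate == "k"]
        assert rate_at(200.0, 2.0, ks) == 10.0

    def test_json_roundtrip(self):
        spec = OdeModelSpec.with_group_presets(
            c=[0.1, 0.2], k0=[2.0, 1.0], d0=[0.5, 0.4], A=[3.0, 2.0],
            a=np.array([[0, 0.5], [0, 0]]), b=np.array([[0, 1.0], [0.2, 0]]),
            groups=[1, 2],
        )
        back = OdeModelSpec.from_json(spec.to_json())
        assert np.array_equal(back.a, spec.a)
        assert back.schedules == spec.schedules
        assert back.groups == spec.groups


class TestSimulateSegment:
    def test_pure_decay_matches_closed_form(self):
        spec = _simple_spec(d0=np.array([0.3]))
        sim = simulate_segment(spec, 0.0, 50.0, [2.0])
        expected = 2.0 * np.exp(-0.3 * sim.times)
        assert np.max(np.abs(sim.states[0] - expected)) < 1e-5

    def test_constant_input_reaches_fixed_point(self):
        # single gene, self-saturating: steady state solves
        # 0 = c + k * x/(1+x) - d x
        spec = OdeModelSpec(c=[0.2], k0=[2.0], d0=[0.5], A=[1.0],
                            a=[[1.0]], b=[[1.0]])
        sim = simulate_segment(spec, 0.0, 400.0, [0.1])
        x = sim.states[0, -1]
        residual = 0.2 + 2.0 * x / (1 + x) - 0.5 * x
        assert abs(residual) < 1e-5

    def test_nonnegativity_from_zero_start(self):
        a = np.array([[0, 0.5], [0.5, 0]])
        b = np.array([[0, 1.0], [1.0, 0]])
        spec = OdeModelSpec(c=[0.1, 0.0], k0=[1.0, 1.0], d0=[0.2, 0.3],
                            A=[1, 1], a=a, b=b)
        sim = simulate_segment(spec, 0.0, 100.0, [0.0, 0.0])
        assert np.all(sim.states >= 0)

    def test_negative_initial_condition_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            simulate_segment(_simple_spec(), 0.0, 10.0, [-1.0])

    def test_schedule_discontinuity_is_resolved(self):
        # decay flips on only inside a window; compare against the exact
        # piecewise-exponential solution
        spec = _simple_spec(
            d0=np.array([0.2]),
            schedules=[[RateSchedule("d", 10.0, 20.0, 5.0)]],
        )
        sim = simulate_segment(spec, 0.0, 30.0, [1.0])
        t = sim.times
        expected = np.where(
            t < 10, np.exp(-0.2 * t),
            np.where(
                t < 20,
                math.exp(-0.2 * 10) * np.exp(-1.0 * (t - 10)),
                math.exp(-0.2 * 10 - 1.0 * 10) * np.exp(-0.2 * (t - 20)),
            ),
        )
        assert np.max(np.abs(sim.states[0] - expected)) < 1e-5


class TestSimulatePiecewise:
    def _obs(self, n_genes, T, value=1.0):
        return SmoothedCurves(
            grid=np.arange(T, dtype=float),
            mean=np.full((n_genes, T), value),
            variance=np.zeros((n_genes, T)),
            gene_ids=[f"g{i}" for i in range(n_genes)],
        )

    def test_horizon_grid_final_point(self):
        spec = _simple_spec()
        obs = self._obs(1, 394)
        sim = simulate_piecewise(spec, obs, segment_len=100)
        assert sim.times[-1] == 393.0
        assert sim.states.shape == (1, 394)
        assert not np.isnan(sim.states).any()

    def test_single_segment_equals_simulate_segment(self):
        spec = _simple_spec()
        obs = self._obs(1, 51, value=2.0)
        piece = simulate_piecewise(spec, obs, segment_len=50)
        direct = simulate_segment(spec, 0.0, 50.0, [2.0])
        assert np.allclose(piece.states, direct.states, atol=1e-9)

    def test_each_segment_restarts_from_observation(self):
        spec = _simple_spec(d0=np.array([0.5]))
        obs = self._obs(1, 101, value=3.0)
        sim = simulate_piecewise(spec, obs, segment_len=50)
        assert sim.states[0, 0] == pytest.approx(3.0)
        assert sim.states[0, 50] == pytest.approx(3.0)  # restart value

    def test_segment_lengths_give_consistent_errors(self, cascade):
        # halving the restart interval must not change the error wildly
        from trajgrn.abc_fit import simulation_error
        spec, obs = cascade
        wrong = spec.with_parameters({"k0[0]": 1.8, "d0[1]": 0.06})
        e50 = simulation_error(simulate_piecewise(wrong, obs, segment_len=50), obs)
        e100 = simulation_error(simulate_piecewise(wrong, obs, segment_len=100), obs)
        assert e50 > 0 and e100 > 0
        assert 0.5 <= e100 / (2 * e50) <= 2.0 or e50 <= e100 <= 2 * e50

    def test_failed_segment_recorded_not_raised(self, monkeypatch):
        import trajgrn.dynamic_model as dm
        spec = _simple_spec()
        obs = self._obs(1, 101)
        real = dm.simulate_segment

        def flaky(spec_, t0, t1, x0, **kw):
            if t0 == 0.0:
                raise SegmentError(t0, t1, "forced failure")
            return real(spec_, t0, t1, x0, **kw)

        monkeypatch.setattr(dm, "simulate_segment", flaky)
        sim = dm.simulate_piecewise(spec, obs, segment_len=50)
        assert len(sim.failures) == 1
        assert np.isnan(sim.states[0, :50]).all()
        assert not np.isnan(sim.states[0, 50:]).any()
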