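"""Tip dynamics laws, calibration, and the 1D network oracle."""

import math

import numpy as np
import pytest

from astersim.fibers import Fiber, FiberState
from astersim.instability import (DynamicsParams, Model,
                                  calibrate_free_rate,
                                  calibrate_linear_relation,
                                  barrier_survival_probability,
                                  catastrophe_rate, growth_speed,
                                  sample_initial_length,
                                  simulate_network_1d,
                                  simulate_tip_survival, step_tip)


@pytest.fixture
def params():
    return DynamicsParams(v_g=0.1, f_g=1.67, k_free=0.0639)


class TestGrowthSpeed:
    def test_zero_force_gives_free_speed(self, params):
        assert growth_speed(0.0, params) == pytest.approx(0.1)

    @pytest.mark.parametrize("mult,expected", [(1, 0.1 / math.e),
                                               (2, 0.1 / math.e ** 2)])
    def test_exponential_force_law(self, params, mult, expected):
        assert growth_speed(mult * params.f_g, params) == \
            pytest.approx(expected, rel=1e-4)

    def test_strictly_decreasing(self, params):
        f = np.linspace(0, 10, 50)
        v = growth_speed(f, params)
        assert (np.diff(v) < 0).all()


class TestCatastropheRate:
    def test_stalled_rate_is_exact(self, params):
        assert catastrophe_rate(0.0, params) == pytest.approx(0.3, abs=0)

    def test_free_rate_is_exact(self, params):
        assert catastrophe_rate(params.v_g, params) == \
            pytest.approx(params.k_free, abs=1e-15)

    def test_half_speed_harmonic_interpolation(self):
        p = DynamicsParams(v_g=0.1, k_free=0.0639, k_stall=0.3)
        # mean catastrophe time is linear in speed
        expect = 1.0 / (0.5 / 0.3 + 0.5 / 0.0639)
        assert catastrophe_rate(0.05, p) == pytest.approx(expect, rel=1e-6)
        assert catastrophe_rate(0.05, p) == pytest.approx(0.1054, abs=2e-4)

    def test_non_pausing_ignores_speed(self):
        p = DynamicsParams(model=Model.NON_PAUSING, k_cat_const=0.045)
        assert catastrophe_rate(0.0, p) == 0.045
        assert catastrophe_rate(p.v_g, p) == 0.045

    def test_out_of_range_speed_clips_with_warning(self, params, caplog):
        with caplog.at_level("WARNING"):
            k = catastrophe_rate(2 * params.v_g, params)
        assert k == pytest.approx(params.k_free)
        assert "clipping" in caplog.text


class TestCalibration:
    def test_survival_inversion(self):
        assert calibrate_free_rate(0.81, 3.3) == \
            pytest.approx(-math.log(0.81) / 3.3)
        assert calibrate_free_rate(0.81, 3.3) == pytest.approx(0.063855,
                                                               abs=1e-5)
        assert calibrate_free_rate(1.0, 5.0) == 0.0
        assert calibrate_free_rate(math.exp(-1), 1.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_invalid_survival_rejected(self, bad):
        with pytest.raises(ValueError):
            calibrate_free_rate(bad, 3.3)

    def test_unreachable_barrier_recovers_analytic_rate(self):
        """With the barrier beyond reach, the fit equals the inversion."""
        rows, _ = calibrate_linear_relation(
            [1.0], barrier_distance=10.0, v_g=0.3)
        assert rows[0]["k_free_per_s"] == pytest.approx(
            calibrate_free_rate(0.81, 3.3), rel=1e-3)

    def test_calibrated_rate_reproduces_survival(self):
        rows, _ = calibrate_linear_relation([1.0, 2.0, 4.0], v_g=0.3)
        for r in rows:
            assert r["survival_check"] == pytest.approx(0.81, abs=1e-4)

    def test_k_free_increases_with_characteristic_force(self):
        """A larger f_g means less slowdown at the barrier, a lower hazard
        under load, and hence a larger admissible zero-force rate."""
        rows, (slope, _) = calibrate_linear_relation(
            np.linspace(0.5, 4.0, 6), v_g=0.3)
        ks = [r["k_free_per_s"] for r in rows]
        assert not any(math.isnan(k) for k in ks)
        assert (np.diff(ks) >= -1e-12).all()
        assert slope > 0

    def test_survival_monotone_in_rate(self):
        s1 = barrier_survival_probability(0.02, 1.67)
        s2 = barrier_survival_probability(0.1, 1.67)
        assert s1 > s2


class TestSampling:
    def test_initial_length_mean_variance_and_floor(self):
        p = DynamicsParams()
        rng = np.random.default_rng(11)
        draws = np.array([sample_initial_length(rng, p)
                          for _ in range(100_000)])
        assert draws.mean() == pytest.approx(1.0, abs=0.02)
        assert draws.var() == pytest.approx(1.0, rel=0.05)
        assert (draws >= p.min_length).all()

    def test_tip_survival_monte_carlo(self):
        rng = np.random.default_rng(5)
        s = simulate_tip_survival(0.0639, 3.3, 10_000, rng)
        assert s == pytest.approx(math.exp(-0.0639 * 3.3), abs=0.02)


class TestStepTip:
    def test_growth_without_catastrophe(self, params):
        f = Fiber.straight((0, 0), (1, 0), 1.0)

        class NoCat:
            def random(self):
                return 1.0
        g = step_tip(f, 0.0, 0.01, NoCat(), params)
        assert g.length == pytest.approx(1.0 + params.v_g * 0.01)
        assert g.state is FiberState.GROWING

    def test_catastrophe_probability_closed_form(self):
        p = DynamicsParams(model=Model.NON_PAUSING, k_cat_const=0.05)
        assert -math.expm1(-0.05 * 0.01) == pytest.approx(4.9988e-4,
                                                          rel=1e-4)
        f = Fiber.straight((0, 0), (1, 0), 1.0)

        class Under:
            def random(self):
                return 4.0e-4
        g = step_tip(f, 0.0, 0.01, Under(), p)
        assert g.state is FiberState.SHRINKING

    def test_renucleation_at_min_length(self, params):
        f = Fiber.straight((0, 0), (1, 0), 0.11)
        f = Fiber(f.vertices, length=f.length, state=FiberState.SHRINKING)
        g = step_tip(f, 0.0, 0.5, np.random.default_rng(0), params)
        assert g.length == pytest.approx(params.min_length)
        assert g.state is FiberState.GROWING

    def test_paused_fiber_is_inert(self, params):
        f = Fiber.straight((0, 0), (1, 0), 1.0)
        f = Fiber(f.vertices, length=1.0, state=FiberState.PAUSED)

        class Boom:
            def random(self):  # pragma: no cover
                raise AssertionError("paused tips draw no catastrophe")
        g = step_tip(f, 0.0, 0.01, Boom(), params)
        assert g.length == pytest.approx(1.0)
        assert g.state is FiberState.PAUSED


class TestNetworkOracle:
    def test_steady_state_matches_sawtooth_closed_form(self):
        """Time-averaged length of the unconfined two-state process.

        With exponential growth excursions (mean v_g/k) above the
        re-nucleation floor, followed by full collapse, the renewal-reward
        mean length is v_g/k + min_length; the Monte-Carlo oracle should
        agree within 5%.
        """
        p = DynamicsParams(v_g=0.1, v_s=0.1, k_free=0.0639)
        t, m = simulate_network_1d(p, 400, 800, np.random.default_rng(21))
        assert m[t > 300].mean() == pytest.approx(
            p.v_g / p.k_free + p.min_length, rel=0.05)

    def test_mean_length_decreasing_in_catastrophe_rate(self):
        means = []
        for k in (0.02, 0.045, 0.07):
            p = DynamicsParams(model=Model.NON_PAUSING, k_cat_const=k,
                               v_g=0.1, v_s=0.1)
            t, m = simulate_network_1d(p, 200, 600,
                                       np.random.default_rng(30))
            means.append(m[t > 400].mean())
        assert means[0] > means[1] > means[2]
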