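import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neuroculture.meanfield import (
    MeanFieldParams,
    classify_fixed_point,
    classify_orbit_tail,
    critical_z1,
    critical_z2,
    critical_z3,
    equilibrium_energy_curve,
    find_fixed_points,
    sigma,
    simulate,
    simulate_batch,
    step_1d,
    step_2d,
)


class TestSigma:
    def test_midpoint_at_E_low_over_w(self):
        assert sigma(2.0 / 1.5, 2.0, 1.5) == pytest.approx(0.5, abs=1e-15)

    def test_saturation_limits(self):
        assert sigma(1e6, 2.0, 1.5) == pytest.approx(1.0, abs=1e-12)
        assert sigma(-1e6, 2.0, 1.5) == pytest.approx(0.0, abs=1e-12)

    def test_value_at_zero_energy(self):
        # 0.5 * (tanh(-2) + 1)
        assert sigma(0.0, 2.0, 1.5) == pytest.approx(0.017986209962092, rel=1e-12)

    def test_strictly_increasing(self):
        E = np.linspace(-5, 8, 200)
        s = sigma(E, 2.0, 1.5)
        assert np.all(np.diff(s) > 0)


class TestStep1d:
    def test_silent_state_is_absorbing(self):
        assert step_1d(0.0, 0.1, 10.0) == 0.0

    def test_full_activity_value(self):
        assert step_1d(1.0, 0.1, 10.0) == pytest.approx(1 - 0.9**10, rel=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            step_1d(1.5, 0.1, 10.0)

    @settings(derandomize=True, max_examples=100)
    @given(p=st.floats(0.01, 0.5), z=st.floats(0.5, 50.0),
           q0=st.floats(1e-6, 1.0))
    def test_orbits_monotone(self, p, z, q0):
        q = q0
        traj = [q]
        for _ in range(200):
            q = step_1d(q, p, z)
            traj.append(q)
        d = np.diff(traj)
        assert np.all(d >= -1e-12) or np.all(d <= 1e-12)

    def test_subcritical_orbit_dies_supercritical_survives(self):
        for p in (0.05, 0.2):
            z_c = critical_z1(p)
            for factor, dies in ((0.8, True), (1.3, False)):
                q = 0.5
                for _ in range(4000):
                    q = step_1d(q, p, factor * z_c)
                assert (q < 1e-6) == dies


class TestStep2d:
    def test_silent_point_is_fixed(self, energy_map_params):
        params = energy_map_params(z=25)
        assert step_2d(0.0, 4.0, params) == (0.0, 4.0)

    def test_cost_not_paid_when_unaffordable(self, energy_map_params):
        params = energy_map_params(z=25)  # r = 10
        q, E = 0.5, 1.0  # E < r*q
        _, E_next = step_2d(q, E, params)
        assert E_next == pytest.approx((1 - 0.05) * E + 0.05 * 4.0, rel=1e-14)

    def test_cost_paid_at_gate_equality(self, energy_map_params):
        params = energy_map_params(z=25)
        q = 0.1
        E = params.r * q  # H(0) = 1: cost is paid exactly at the boundary
        _, E_next = step_2d(q, E, params)
        expected = (1 - 0.05) * E + 0.05 * 4.0 - params.r * q
        assert E_next == pytest.approx(expected, rel=1e-14)

    def test_high_connectivity_example(self):
        params = MeanFieldParams(p=0.1, z=210, w=1.5, E_low=2.0, E_bar=4.0,
                                 eps=0.05, r=1.0)
        s4 = 0.5 * (math.tanh(1.5 * 4.0 - 2.0) + 1.0)
        q_next, E_next = step_2d(1.0, 4.0, params)
        assert E_next == pytest.approx(0.95 * 4 + 0.05 * 4 - 1.0, rel=1e-14)  # = 3
        assert q_next == pytest.approx(1 - (1 - 0.1 * s4) ** 210, rel=1e-12)

    def test_domain_errors(self, energy_map_params):
        params = energy_map_params(z=25)
        with pytest.raises(ValueError):
            step_2d(-0.1, 1.0, params)
        with pytest.raises(ValueError):
            step_2d(0.5, 4.5, params)

    @settings(derandomize=True, max_examples=200)
    @given(q=st.floats(0, 1), E=st.floats(0, 4),
           z=st.floats(0.1, 300), r=st.floats(0.1, 20),
           eps=st.floats(0.001, 0.5))
    def test_forward_invariance(self, q, E, z, r, eps):
        params = MeanFieldParams(p=0.1, z=z, w=1.5, E_low=2.0, E_bar=4.0,
                                 eps=eps, r=r)
        q2, E2 = step_2d(q, E, params)
        assert 0.0 <= q2 <= 1.0
        assert 0.0 <= E2 <= 4.0

    def test_reduces_to_1d_map_when_energy_gate_saturated(self):
        # E_low -> -inf makes sigma -> 1 and the q-equation collapse to
        # the bare excitation map
        params = MeanFieldParams(p=0.1, z=20.0, w=1.5, E_low=-1e3,
                                 E_bar=4.0, eps=0.05, r=1.0)
        for q in (0.1, 0.5, 0.9):
            q2, _ = step_2d(q, 2.0, params)
            assert q2 == pytest.approx(step_1d(q, 0.1, 20.0), abs=1e-12)


class TestSimulate:
    def test_silent_start_relaxes_to_recovery_level(self, energy_map_params):
        params = energy_map_params(z=25)
        orbit = simulate(params, 0.0, 1.0, 100)
        assert np.all(orbit.q == 0.0)
        expected = 4.0 + (1.0 - 4.0) * (1 - 0.05) ** np.arange(101)
        np.testing.assert_allclose(orbit.E, expected, rtol=1e-12)

    def test_deterministic(self, energy_map_params):
        params = energy_map_params(z=25)
        a = simulate(params, 0.5, 4.0, 500)
        b = simulate(params, 0.5, 4.0, 500)
        np.testing.assert_array_equal(a.q, b.q)
        np.testing.assert_array_equal(a.E, b.E)

    def test_batch_matches_scalar_path(self, energy_map_params):
        params = energy_map_params(z=25)
        orbit = simulate(params, 0.5, 4.0, 300)
        q_tail, E_tail = simulate_batch(
            p=0.1, z=np.array([25.0]), w=1.5, E_low=2.0, E_bar=4.0,
            eps=0.05, r=10.0, q0=0.5, E0=4.0, T=300, keep_last=301,
        )
        np.testing.assert_allclose(q_tail[:, 0], orbit.q, rtol=1e-12, atol=1e-15)
        np.testing.assert_allclose(E_tail[:, 0], orbit.E, rtol=1e-12, atol=1e-15)


class TestCriticalConnectivities:
    def test_z1_closed_form_points(self):
        assert critical_z1(1 - math.exp(-1)) == pytest.approx(1.0, rel=1e-12)
        assert critical_z1(0.1) == pytest.approx(9.491221581, rel=1e-9)
        assert critical_z1(1e-4) == pytest.approx(1e4, rel=1e-3)  # ~ 1/p

    def test_z1_domain(self):
        for p in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                critical_z1(p)

    def test_z2_defining_identity(self, energy_map_params):
        params = energy_map_params(z=10)
        z2 = critical_z2(params)
        s = sigma(4.0, 2.0, 1.5)
        assert -z2 * math.log1p(-0.1 * s) == pytest.approx(1.0, abs=1e-12)
        assert z2 == pytest.approx(9.4946, abs=2e-4)

    def test_z3_value_and_validity(self, energy_map_params):
        params = energy_map_params(z=10)  # r = 10, E_bar/r = 0.4
        s = sigma(4.0, 2.0, 1.5)
        expected = math.log(0.6) / (0.4 * math.log(1 - 0.1 * s))
        assert critical_z3(params) == pytest.approx(expected, rel=1e-12)
        assert critical_z3(params) == pytest.approx(12.13, abs=0.01)
        cheap = MeanFieldParams(p=0.1, z=10, w=1.5, E_low=2.0, E_bar=4.0,
                                eps=0.05, r=4.0)  # E_bar/r = 1
        with pytest.raises(ValueError, match="not applicable"):
            critical_z3(cheap)


class TestEquilibriumCurve:
    def test_inverse_identity(self, energy_map_params):
        params = energy_map_params(z=50)
        for q_star in (0.01, 0.05, 0.2):
            E = equilibrium_energy_curve(q_star, params)
            # q* must be a fixed point of the activity equation at that E
            lhs = 1 - (1 - 0.1 * sigma(E, 2.0, 1.5)) ** (q_star * 50)
            assert lhs == pytest.approx(q_star, rel=1e-10)

    def test_strictly_increasing_on_domain(self, energy_map_params):
        params = energy_map_params(z=50)
        qs = np.linspace(0.005, 0.5, 100)
        Es = [equilibrium_energy_curve(q, params) for q in qs]
        assert np.all(np.diff(Es) > 0)

    def test_out_of_range_raises(self, energy_map_params):
        # at tiny z the required efficacy exceeds the maximal probability
        params = energy_map_params(z=2)
        with pytest.raises(ValueError, match="no equilibrium"):
            equilibrium_energy_curve(0.9, params)

    def test_single_crossing_with_relaxation_line(self, energy_map_params):
        params = energy_map_params(z=50)
        qs = np.linspace(1e-4, 0.019, 400)  # affordable range for r=10
        gaps = []
        for q in qs:
            try:
                gaps.append(equilibrium_energy_curve(q, params)
                            - (4.0 - 10.0 * q / 0.05))
            except ValueError:
                gaps.append(np.inf)
        signs = np.sign(gaps)
        crossings = np.sum(np.diff(signs) != 0)
        assert crossings == 1


class TestFixedPoints:
    def test_below_z2_only_silent_attractor(self, energy_map_params):
        points = find_fixed_points(energy_map_params(z=5))
        assert [fp.branch for fp in points] == ["silent"]
        assert points[0].stability == "attractor"
        assert (points[0].q_star, points[0].E_star) == (0.0, 4.0)

    def test_between_z2_and_z3_silent_repeller_plus_interior(self, energy_map_params):
        params = energy_map_params(z=10)
        points = {fp.branch: fp for fp in find_fixed_points(params)}
        assert set(points) == {"silent", "interior"}
        assert points["silent"].stability == "repeller"
        fp = points["interior"]
        assert fp.E_star == pytest.approx(4.0 - 10.0 * fp.q_star / 0.05, rel=1e-10)
        assert fp.E_star >= 10.0 * fp.q_star
        q2, E2 = step_2d(fp.q_star, fp.E_star, params)
        assert abs(q2 - fp.q_star) <= 1e-10
        assert abs(E2 - fp.E_star) <= 1e-10

    def test_above_z3_saturated_attractor_exists(self, energy_map_params):
        params = energy_map_params(z=25)
        points = {fp.branch: fp for fp in find_fixed_points(params)}
        assert set(points) == {"silent", "interior", "saturated"}
        sat = points["saturated"]
        assert sat.q_star > 4.0 / 10.0  # q* > E_bar / r
        assert sat.E_star == 4.0
        assert sat.stability == "attractor"

    def test_silent_eigenvalues_closed_form(self, energy_map_params):
        for z in (5.0, 10.0, 25.0):
            params = energy_map_params(z=z)
            fp = find_fixed_points(params)[0]
            s = sigma(4.0, 2.0, 1.5)
            lam1 = -z * math.log1p(-0.1 * s)
            assert fp.eigenvalues[0].real == pytest.approx(lam1, abs=1e-12)
            assert fp.eigenvalues[1].real == pytest.approx(0.95, abs=1e-12)

    def test_silent_point_nonhyperbolic_exactly_at_z2(self, energy_map_params):
        params = energy_map_params(z=critical_z2(energy_map_params(z=10)))
        fp = find_fixed_points(params)[0]
        assert fp.stability == "nonhyperbolic"

    def test_numerical_jacobian_agrees_with_closed_form_at_silent(self, energy_map_params):
        from neuroculture.meanfield import FixedPoint, _branch_map
        params = energy_map_params(z=25)
        f = _branch_map("interior", params)  # silent point pays (zero) cost
        h = 1e-7
        J = np.array(
            [
                [(f(h, 4.0)[0] - f(-h, 4.0)[0]) / (2 * h),
                 (f(0.0, 4.0 + h)[0] - f(0.0, 4.0 - h)[0]) / (2 * h)],
                [(f(h, 4.0)[1] - f(-h, 4.0)[1]) / (2 * h),
                 (f(0.0, 4.0 + h)[1] - f(0.0, 4.0 - h)[1]) / (2 * h)],
            ]
        )
        s = sigma(4.0, 2.0, 1.5)
        assert J[0, 0] == pytest.approx(-25 * math.log1p(-0.1 * s), abs=1e-6)
        assert J[1, 1] == pytest.approx(0.95, abs=1e-8)
        assert J[0, 1] == pytest.approx(0.0, abs=1e-8)
        assert J[1, 0] == pytest.approx(-10.0, abs=1e-6)

    def test_nonzero_fixed_point_lower_bound_1d(self):
        # q2* > 1 - e*(1-p)^z for the supercritical 1-D map
        for p, factor in ((0.1, 1.5), (0.3, 2.0), (0.05, 1.2)):
            z = factor * critical_z1(p)
            q = 1.0
            for _ in range(10_000):
                q = step_1d(q, p, z)
            assert q > 1 - math.e * (1 - p) ** z


class TestOrbitClassification:
    def test_fixed_point_tail(self, energy_map_params):
        orbit = simulate(energy_map_params(z=10), 0.5, 4.0, 30_000)
        label, _ = classify_orbit_tail(*orbit.tail(10_000))
        assert label == "fixed-point"

    def test_exact_period_two_signal(self):
        q = np.tile([0.2, 0.8], 5000)
        E = np.tile([1.0, 3.0], 5000)
        label, period = classify_orbit_tail(q, E)
        assert label == "periodic"
        assert period == 2

    def test_invariant_curve_recognised_as_periodic(self, energy_map_params):
        orbit = simulate(energy_map_params(z=11.5, E_low=1.0), 0.5, 4.0, 60_000)
        label, _ = classify_orbit_tail(*orbit.tail(20_000))
        assert label == "periodic"

    def test_chaotic_orbit_is_complex(self):
        params = MeanFieldParams(p=0.1, z=210, w=1.5, E_low=2.0, E_bar=4.0,
                                 eps=0.05, r=1.0)
        orbit = simulate(params, 0.5, 4.0, 100_000)
        label, _ = classify_orbit_tail(*orbit.tail(20_000))
        assert label == "complex"

    def test_short_tail_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            classify_orbit_tail(np.zeros(100), np.zeros(100))
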