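"""The fractal-fractional Adams-Bashforth scheme: closed-form weights,
fractal factors, the explicit update, and its structural invariants."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fracad.ff_solver import (FFOrder, TimeGrid, ab_weight_pair,
                              classical_ab2, fractal_factor,
                              read_trajectory, solve_ff, write_trajectory)
from fracad.model import conserved_sums, vector_field
from fracad.oracles import PowerForcingSpec, power_forcing_exact


class TestOrderAndGrid:
    @pytest.mark.parametrize("p,q", [(0.0, 0.5), (1.2, 1.0), (0.5, 0.0),
                                     (0.5, 1.0001), (-0.1, 0.5)])
    def test_orders_outside_unit_interval_rejected(self, p, q):
        with pytest.raises(ValueError):
            FFOrder(p, q)

    def test_grid_nodes_and_horizon(self):
        g = TimeGrid(step=0.05, n_steps=400)
        assert g.horizon == pytest.approx(20.0)
        assert len(g.nodes) == 401
        assert g.nodes[0] == 0.0

    def test_from_horizon_requires_integer_multiple(self):
        with pytest.raises(ValueError):
            TimeGrid.from_horizon(0.3, 1.0)


class TestWeights:
    @pytest.mark.parametrize("m,n", [(0, 0), (5, 5), (7, 3), (200, 0)])
    def test_integer_order_collapses_to_ab2(self, m, n):
        w = ab_weight_pair(m, n, p=1.0)
        assert w.wA == pytest.approx(3.0, abs=1e-12)
        assert w.wB == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("p", [0.3, 0.5, 0.9, 1.0])
    @pytest.mark.parametrize("m", [0, 4, 31])
    def test_diagonal_weights(self, m, p):
        # at n = m the (m-n)^p terms vanish (0^p = 0) leaving (p+2, 1)
        w = ab_weight_pair(m, m, p)
        assert w.wA == pytest.approx(p + 2.0, abs=1e-13)
        assert w.wB == pytest.approx(1.0, abs=1e-13)

    def test_frozen_half_order_values(self):
        # direct evaluation of the two bracketed coefficients at m=1, n=0
        w = ab_weight_pair(1, 0, 0.5)
        assert w.wA == pytest.approx(3.5 * math.sqrt(2.0) - 4.0, rel=1e-12)
        assert w.wB == pytest.approx(2.0**1.5 - 2.5, rel=1e-12)

    def test_invalid_indices_and_order(self):
        with pytest.raises(ValueError):
            ab_weight_pair(2, 3, 0.5)
        with pytest.raises(ValueError):
            ab_weight_pair(3, 1, 1.5)

    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5, 0.7, 0.9, 1.0])
    def test_weight_positivity_over_grid(self, p):
        # empirical: both weights stay positive for all m <= 512
        m = 512
        k = np.arange(m, -1, -1, dtype=float)
        wA = (k + p + 2) * (k + 1) ** p - (k + 2 * p + 2) * k**p
        wB = (k + 1) ** (p + 1) - (k + 1 + p) * k**p
        assert np.all(wA > 0)
        assert np.all(wB > 0)


class TestFractalFactor:
    def test_unit_dimension_is_identically_one(self):
        g = TimeGrid(0.1, 10)
        assert all(fractal_factor(n, g, 1.0) == 1.0 for n in range(-1, 6))

    def test_interior_node(self):
        g = TimeGrid(0.5, 10)
        assert fractal_factor(4, g, 0.5) == pytest.approx(2.0**-0.5, rel=1e-12)

    def test_origin_is_regularized_to_first_node(self):
        g = TimeGrid(0.1, 10)
        expected = 0.1**-0.5
        assert fractal_factor(0, g, 0.5) == pytest.approx(expected, rel=1e-12)
        assert fractal_factor(-1, g, 0.5) == pytest.approx(expected, rel=1e-12)

    def test_below_history_node_rejected(self):
        with pytest.raises(ValueError):
            fractal_factor(-2, TimeGrid(0.1, 10), 0.5)


class TestSolver:
    def test_zero_rhs_constant_trajectory(self):
        traj = solve_ff(lambda t, y: 0.0 * y, 7.0, TimeGrid(0.1, 20),
                        FFOrder(0.7, 0.9))
        np.testing.assert_array_equal(traj.states, 7.0)

    def test_zero_steps_returns_initial_state_only(self, defaults):
        params, _, y0 = defaults
        traj = solve_ff(vector_field(params), y0, TimeGrid(0.05, 0),
                        FFOrder(0.9, 0.9))
        assert traj.states.shape == (1, 7)
        np.testing.assert_array_equal(traj.states[0], y0.as_array())

    def test_initial_state_stored_exactly(self, defaults):
        params, _, y0 = defaults
        traj = solve_ff(vector_field(params), y0, TimeGrid(0.05, 10),
                        FFOrder(0.8, 0.8))
        np.testing.assert_array_equal(traj.states[0], y0.as_array())

    def test_integer_order_reduces_to_classical_ab2(self, defaults):
        params, _, y0 = defaults
        grid = TimeGrid(0.1, 200)
        a = solve_ff(vector_field(params), y0, grid, FFOrder(1.0, 1.0))
        b = classical_ab2(vector_field(params), y0, grid)
        rel = np.max(np.abs(a.states - b.states)
                     / np.maximum(np.abs(b.states), 1.0))
        assert rel <= 1e-10

    @pytest.mark.parametrize("p", [0.6, 0.85, 1.0])
    def test_constant_forcing_exact_at_unit_dimension(self, p):
        # q = 1, h == c: the scheme telescopes to y0 + c t^p / Gamma(p+1)
        spec = PowerForcingSpec(c=3.0, a=0.0, y0=2.0)
        grid = TimeGrid(0.02, 50)
        traj = solve_ff(spec.rhs(), spec.y0, grid, FFOrder(p, 1.0))
        exact = spec.y0 + spec.c * grid.nodes**p / math.gamma(p + 1.0)
        rel = np.max(np.abs(traj.states[:, 0] - exact)
                     / np.maximum(np.abs(exact), 1e-30))
        assert rel <= 1e-10

    @pytest.mark.parametrize("p,q", [(0.75, 0.75), (0.85, 0.95), (1.0, 0.8)])
    def test_pair_sums_conserved(self, defaults, p, q):
        params, _, y0 = defaults
        traj = solve_ff(vector_field(params), y0, TimeGrid(0.05, 200),
                        FFOrder(p, q))
        totals = conserved_sums(traj.states)
        for tot, ref in zip(totals, (101000.0, 101000.0, 10100.0)):
            assert np.max(np.abs(tot - ref) / ref) <= 1e-12

    def test_solver_is_linear_in_initial_condition(self, defaults):
        params, _, y0 = defaults
        grid = TimeGrid(0.05, 50)
        order = FFOrder(0.85, 0.9)
        f = vector_field(params)
        a = solve_ff(f, 3.0 * y0.as_array(), grid, order)
        b = solve_ff(f, y0, grid, order)
        np.testing.assert_allclose(a.states, 3.0 * b.states, rtol=1e-12)

    def test_determinism_bit_identical(self, defaults):
        params, _, y0 = defaults
        f = vector_field(params)
        args = (f, y0, TimeGrid(0.05, 100), FFOrder(0.9, 0.85))
        np.testing.assert_array_equal(solve_ff(*args).states,
                                      solve_ff(*args).states)

    def test_p_and_q_are_not_interchangeable(self, defaults):
        params, _, y0 = defaults
        f = vector_field(params)
        grid = TimeGrid(0.05, 100)
        a = solve_ff(f, y0, grid, FFOrder(0.9, 0.8)).endpoint()
        b = solve_ff(f, y0, grid, FFOrder(0.8, 0.9)).endpoint()
        assert np.max(np.abs(a - b)) > 1.0

    def test_overflow_reports_step_index(self):
        with pytest.raises(FloatingPointError, match="step"):
            solve_ff(lambda t, y: 1e300 * y, 1.0, TimeGrid(1.0, 10),
                     FFOrder(1.0, 1.0))

    def test_negative_population_warned_once(self, defaults, caplog):
        params, _, y0 = defaults
        with caplog.at_level("WARNING", logger="fracad.ff_solver"):
            solve_ff(vector_field(params), y0, TimeGrid(0.05, 400),
                     FFOrder(1.0, 1.0))
        hits = [r for r in caplog.records if "negative" in r.message]
        assert len(hits) == 1

    def test_self_convergence_under_step_halving(self, defaults):
        # empirical order >= ~0.85 despite the weakly singular kernel
        from fracad.oracles import fine_grid_reference
        params, _, y0 = defaults
        f = vector_field(params)
        order = FFOrder(0.9, 0.9)
        errs = {}
        for l in (0.02, 0.01):
            grid = TimeGrid.from_horizon(l, 2.0)
            got = solve_ff(f, y0, grid, order).endpoint()
            ref = fine_grid_reference(f, y0, order, grid, 0.0025).endpoint()
            errs[l] = np.max(np.abs(got - ref) / np.maximum(np.abs(ref), 1.0))
        assert errs[0.02] / errs[0.01] >= 1.8


class TestClassicalAB2:
    def test_zero_rhs(self):
        traj = classical_ab2(lambda t, y: 0.0 * y, 7.0, TimeGrid(0.1, 10))
        np.testing.assert_array_equal(traj.states, 7.0)

    def test_scalar_decay_endpoint(self):
        traj = classical_ab2(lambda t, y: -y, 1.0, TimeGrid(0.01, 100))
        assert traj.endpoint()[0] == pytest.approx(math.exp(-1.0), abs=1e-4)

    def test_first_step_is_euler(self):
        traj = classical_ab2(lambda t, y: -y, 1.0, TimeGrid(0.1, 1))
        assert traj.states[1, 0] == pytest.approx(1.0 - 0.1, abs=1e-15)


class TestTrajectoryIO:
    def test_round_trip_is_exact(self, defaults, tmp_path):
        params, _, y0 = defaults
        traj = solve_ff(vector_field(params), y0, TimeGrid(0.05, 40),
                        FFOrder(0.9, 0.95))
        path = tmp_path / "traj.csv"
        write_trajectory(traj, path)
        back = read_trajectory(path)
        np.testing.assert_array_equal(back.states, traj.states)
        np.testing.assert_array_equal(back.times, traj.times)

    def test_header(self, defaults, tmp_path):
        params, _, y0 = defaults
        traj = solve_ff(vector_field(params), y0, TimeGrid(0.05, 2),
                        FFOrder(1, 1))
        path = tmp_path / "t.csv"
        write_trajectory(traj, path)
        assert path.read_text().splitlines()[0] == "time,R,Q,Abeta,Ip,Ia,S,D"


@given(p=st.floats(0.05, 1.0), k=st.integers(0, 300))
def test_weight_pair_consistency_with_power_forcing_identity(p, k):
    """wA - wB telescopes to (p+1)[(k+1)^p - k^p], the identity behind the
    constant-forcing exactness."""
    w = ab_weight_pair(k + 3, 3, p)  # arbitrary m with m - n = k
    expected = (p + 1.0) * ((k + 1.0)**p - float(k)**p)
    assert w.wA - w.wB == pytest.approx(expected, rel=1e-9, abs=1e-9)
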