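"""Replicator drift, deterministic integration and vertex analysis."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import bisect

from cmcgame import (
    GameState,
    SimulationSettings,
    UsageError,
    drift,
    drift_discrepancy,
    integrate_deterministic,
    vertex_stability,
)

from conftest import random_parameters

DET = SimulationSettings(sigma=0.0, h=0.01, steps=10_000)


class TestDrift:
    def test_printed_two_subject_baseline(self, params_two, interior_two):
        d = drift(interior_two, params_two, mode="printed", form="replicator")
        assert d.factors == pytest.approx((-1.0, 7.625), abs=1e-12)
        assert d.drifts == pytest.approx((-0.25, 1.90625), abs=1e-12)

    def test_printed_tripartite_baseline(self, params_three, interior_three):
        d = drift(interior_three, params_three, mode="printed", form="replicator")
        assert d.factors == pytest.approx((4.25, 7.625, 2.125), abs=1e-12)
        assert d.drifts == pytest.approx((1.0625, 1.90625, 0.53125), abs=1e-12)

    @pytest.mark.parametrize("x", [0.0, 1.0])
    def test_replicator_drift_vanishes_at_own_vertex(self, params_two, x):
        d = drift(GameState(x, 0.37), params_two, form="replicator")
        assert d.drifts[0] == 0.0

    def test_linear_form_keeps_own_probability_factor(self, params_two):
        state = GameState(0.5, 0.5)
        lin = drift(state, params_two, form="linear")
        rep = drift(state, params_two, form="replicator")
        assert lin.factors == rep.factors
        assert lin.drifts[0] == pytest.approx(0.5 * lin.factors[0], abs=1e-15)

    def test_derived_mode_uses_expected_payoff_gap(self, params_two):
        # at y=1 the derived lead-hospital factor is the payoff gap of the
        # (·, active) column: 8 − (−ξ(I+U)+Sl+Tp) = 8 − 10.5
        d = drift(GameState(0.5, 1.0), params_two, mode="derived")
        assert d.factors[0] == pytest.approx(-2.5, abs=1e-12)


class TestDriftDiscrepancy:
    def test_two_subject_x_component_is_constant(self, params_two):
        expected = params_two.xi * params_two.Tp * (1 - params_two.pi)
        for x in np.linspace(0, 1, 7):
            for y in np.linspace(0, 1, 7):
                disc = drift_discrepancy(GameState(x, y), params_two)
                assert disc[0] == pytest.approx(expected, abs=1e-10)
                assert disc[1] == pytest.approx(0.0, abs=1e-10)

    def test_tripartite_z_component_closed_form(self, params_three):
        p = params_three
        for x in np.linspace(0, 1, 5):
            for y in np.linspace(0, 1, 5):
                disc = drift_discrepancy(GameState(x, y, 0.4), p)
                expected = (p.xi - 1) * p.Tg * (1 - x) * (1 - y)
                assert disc[2] == pytest.approx(expected, abs=1e-10)
                assert disc[1] == pytest.approx(0.0, abs=1e-10)

    def test_tripartite_z_component_vanishes_on_aggressive_edges(self, params_three):
        for state in (GameState(1.0, 0.3, 0.6), GameState(0.2, 1.0, 0.6)):
            assert drift_discrepancy(state, params_three)[2] == pytest.approx(
                0.0, abs=1e-10
            )


class TestIntegration:
    def test_vertices_are_exact_fixed_points(self):
        """Every corner of the state cube is a fixed point of the
        replicator dynamics, exactly, for random parameter draws."""
        rng = np.random.default_rng(7)
        short = SimulationSettings(sigma=0.0, h=0.01, steps=100)
        for _ in range(25):
            for model in ("two", "three"):
                params = random_parameters(rng, model)
                dims = 2 if model == "two" else 3
                for idx in range(2**dims):
                    vertex = tuple(float((idx >> i) & 1) for i in range(dims))
                    traj = integrate_deterministic(
                        GameState(*vertex), params, short
                    )
                    assert np.array_equal(traj.states[-1], np.array(vertex))

    def test_baseline_two_subject_converges_to_cooperation(self, params_two):
        traj = integrate_deterministic(GameState(0.5, 0.5), params_two, DET)
        x, y = traj.states[-1]
        assert x > 0.9 and y > 0.9

    def test_low_authority_cession_discourages_lead_hospital(self, params_two):
        # Tp = 5: the lead hospital builds inefficiently while the primary
        # institutions still participate actively
        traj = integrate_deterministic(
            GameState(0.5, 0.5), params_two.replace(Tp=5.0), DET
        )
        x, y = traj.states[-1]
        assert x < 0.05 and y > 0.95

    def test_euler_matches_adaptive_reference_solver(self, params_two):
        """Independent cross-check: an adaptive RK45 solve of the same
        two-subject replicator vector field lands on the same terminal."""
        def rhs(_t, s):
            d = drift(GameState(*np.clip(s, 0, 1)), params_two, mode="printed")
            return list(d.drifts)

        euler = integrate_deterministic(GameState(0.5, 0.5), params_two, DET)
        ref = solve_ivp(rhs, (0.0, 100.0), [0.5, 0.5], rtol=1e-8, atol=1e-10)
        assert np.abs(euler.states[-1] - ref.y[:, -1]).max() < 1e-3

    def test_halving_step_barely_moves_terminal(self, params_two):
        coarse = integrate_deterministic(GameState(0.5, 0.5), params_two, DET)
        fine = integrate_deterministic(
            GameState(0.5, 0.5), params_two, DET.with_(h=0.005, steps=20_000)
        )
        assert np.abs(coarse.states[-1] - fine.states[-1]).max() < 1e-3

    def test_nonzero_sigma_rejected(self, params_two):
        with pytest.raises(UsageError):
            integrate_deterministic(
                GameState(0.5, 0.5), params_two, DET.with_(sigma=0.1)
            )

    def test_monotone_policy_effect_on_participation_factor(self):
        """The participation drift factor f_y never decreases in the policy
        effect coefficient v (its v-derivative is R + (1−q)D ≥ 0)."""
        rng = np.random.default_rng(11)
        for _ in range(40):
            params = random_parameters(rng, "two")
            if params.v > 0.99:
                params = params.replace(v=0.5)
            state = GameState(float(rng.uniform(0, 1)), float(rng.uniform(0, 1)))
            lo = drift(state, params).factors[1]
            hi = drift(state, params.replace(v=min(1.0, params.v + 0.01))).factors[1]
            assert hi >= lo - 1e-12


class TestVertexStability:
    def test_baseline_two_subject_classification(self, params_two):
        reports = {r.vertex: r for r in vertex_stability(params_two)}
        assert reports[(1, 1)].classification == "stable"
        for vertex in ((0, 0), (0, 1), (1, 0)):
            assert reports[vertex].classification != "stable"
        assert not any(r.degenerate for r in reports.values())

    def test_baseline_tripartite_all_aggressive_is_stable(self, params_three):
        reports = {r.vertex: r for r in vertex_stability(params_three)}
        assert reports[(1, 1, 1)].classification == "stable"
        assert sum(r.classification == "stable" for r in reports.values()) == 1

    def test_weak_integration_flips_the_stable_vertex(self, params_two):
        reports = {r.vertex: r for r in vertex_stability(params_two.replace(xi=0.1))}
        assert reports[(0, 1)].classification == "stable"
        assert reports[(1, 1)].classification != "stable"

    def test_degenerate_factor_flagged_not_classified(self, params_two):
        # with Sl + Tp = I + U (and pi = xi = 0.5, all halves binary-exact)
        # the lead-hospital factor vanishes identically at y = 0
        params = params_two.replace(Tp=17.0)
        reports = {r.vertex: r for r in vertex_stability(params)}
        assert reports[(0, 0)].degenerate
        assert reports[(0, 0)].classification is None

    def test_integration_intensity_threshold_recovered_by_bisection(self, params_two):
        """The sign change of the printed lead-hospital factor at y=1 sits
        at xi* = 18/37."""
        def factor(xi):
            return drift(GameState(0.5, 1.0), params_two.replace(xi=xi)).factors[0]

        root = bisect(factor, 0.1, 0.9, xtol=1e-12)
        assert abs(root - 18.0 / 37.0) < 1e-9
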