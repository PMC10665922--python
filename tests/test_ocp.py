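import numpy as np
import pytest

from smootheffort import (GravityCondition, OcpSpec, OcpSolverError,
                          PlantParams, Trajectory, effort_cost,
                          smoothness_cost, solve, sweep_conditions,
                          trajectory_rtpv)
from conftest import frictionless_params


def make_traj(t, theta=None, theta_dot=None, theta_ddot=None, tau_h=None,
              u_h=None):
    n = len(t)
    z = np.zeros(n)
    return Trajectory(
        t=np.asarray(t, float),
        theta=z if theta is None else np.asarray(theta, float),
        theta_dot=z if theta_dot is None else np.asarray(theta_dot, float),
        theta_ddot=z if theta_ddot is None else np.asarray(theta_ddot, float),
        tau_h=z if tau_h is None else np.asarray(tau_h, float),
        u_h=z if u_h is None else np.asarray(u_h, float),
        cost_effort=np.nan, cost_smooth=np.nan, cost_total=np.nan,
        beta=np.nan, solver_status={}, spec=None)


class TestEffortCost:
    def test_zero_velocity_means_zero_effort(self):
        t = np.linspace(0, 0.6, 101)
        traj = make_traj(t, tau_h=np.ones_like(t))
        assert effort_cost(traj) == 0.0

    def test_constant_integrand(self):
        t = np.linspace(0, 0.6, 101)
        traj = make_traj(t, tau_h=np.ones_like(t),
                         theta_dot=np.ones_like(t))
        assert effort_cost(traj) == pytest.approx(0.6, rel=1e-12)

    def test_sine_squared_closed_form(self):
        # int_0^pi sin^2 = pi/2
        t = np.linspace(0, np.pi, 2001)
        traj = make_traj(t, tau_h=np.sin(t), theta_dot=np.sin(t))
        assert effort_cost(traj) == pytest.approx(np.pi / 2, rel=1e-8)

    def test_dominates_net_work(self, traj_1g_up):
        net = abs(float(np.trapezoid(traj_1g_up.tau_h
                                     * traj_1g_up.theta_dot,
                                     traj_1g_up.t)))
        assert effort_cost(traj_1g_up) >= net - 1e-9


class TestSmoothnessCost:
    def test_zero_control_no_damping_no_gravity(self):
        t = np.linspace(0, 0.6, 101)
        traj = make_traj(t, theta_dot=np.sin(t), theta_ddot=np.cos(t),
                         tau_h=np.ones_like(t))
        cond = GravityCondition(alpha=1.0)  # zero effective gravity
        params = frictionless_params()
        assert smoothness_cost(traj, cond, params) == 0.0

    def test_equals_inertia_squared_jerk_on_consistent_trajectory(
            self, traj_1g_up):
        """Along a dynamics-consistent solution the smoothness integrand is
        (I * jerk)^2, so Cs must match I^2 * int jerk^2 evaluated through an
        entirely separate route (dense differentiation of acceleration)."""
        td, _, _, acc, _ = traj_1g_up.resample(num=20001)
        jerk = np.gradient(acc, td)
        I = traj_1g_up.spec.params.inertia
        cs_jerk = I ** 2 * np.trapezoid(jerk ** 2, td)
        assert traj_1g_up.cost_smooth == pytest.approx(cs_jerk, rel=2e-2)


class TestSolve:
    def test_boundary_conditions_and_cost_identity(self, traj_1g_up):
        spec = traj_1g_up.spec
        lo, hi = spec.boundary_angles()
        assert traj_1g_up.theta[0] == pytest.approx(lo, abs=1e-10)
        assert traj_1g_up.theta[-1] == pytest.approx(hi, abs=1e-10)
        assert traj_1g_up.theta_dot[0] == pytest.approx(0.0, abs=1e-10)
        assert traj_1g_up.theta_dot[-1] == pytest.approx(0.0, abs=1e-10)
        c = spec.params.weight_moment * spec.params.g0
        assert traj_1g_up.tau_h[0] == pytest.approx(c * np.cos(lo), rel=1e-9)
        assert traj_1g_up.cost_total == pytest.approx(
            traj_1g_up.cost_effort + spec.beta * traj_1g_up.cost_smooth)
        assert traj_1g_up.solver_status["max_defect"] < spec.tol

    def test_reported_costs_match_standalone_quadrature(self, traj_1g_up):
        assert effort_cost(traj_1g_up) == pytest.approx(
            traj_1g_up.cost_effort, rel=1e-3)
        assert smoothness_cost(traj_1g_up) == pytest.approx(
            traj_1g_up.cost_smooth, rel=1e-3)

    def test_deterministic_bit_for_bit(self):
        spec = OcpSpec(cond=GravityCondition(alpha=0.6), nodes=41)
        t1 = solve(spec)
        t2 = solve(spec)
        assert np.array_equal(t1.theta, t2.theta)
        assert np.array_equal(t1.u_h, t2.u_h)
        assert t1.cost_total == t2.cost_total

    def test_gravity_free_symmetric_plant_gives_symmetric_profile(self):
        """No gravity, no damping: the problem is invariant under time
        reversal, so rtPV must be 50% across smoothness weights."""
        for beta in (1e-4, 1e-3, 1e-2):
            spec = OcpSpec(cond=GravityCondition(alpha=1.0),
                           params=frictionless_params(), beta=beta, nodes=41)
            assert trajectory_rtpv(solve(spec)) == pytest.approx(50.0,
                                                                 abs=0.5)

    def test_mirror_up_down_under_opposite_gravity(self):
        """Reflection theta -> -theta maps an upward movement at g_eff onto
        a downward movement at -g_eff; rtPV must agree."""
        params = frictionless_params()
        up = OcpSpec(cond=GravityCondition(alpha=0.0, direction="upward"),
                     params=params, nodes=41)
        down = OcpSpec(cond=GravityCondition(alpha=2.0,
                                             direction="downward"),
                       params=params, nodes=41)
        assert trajectory_rtpv(solve(up)) == pytest.approx(
            trajectory_rtpv(solve(down)), abs=0.5)

    def test_skew_direction_under_gravity(self):
        spec = OcpSpec(cond=GravityCondition(alpha=0.0), nodes=61)
        assert trajectory_rtpv(solve(spec)) < 50.0  # 1g up: right-skewed
        spec = OcpSpec(cond=GravityCondition(alpha=2.0), nodes=61)
        assert trajectory_rtpv(solve(spec)) > 50.0  # -1g up: left-skewed

    def test_node_doubling_changes_rtpv_little(self):
        vals = {}
        for N in (41, 81):
            spec = OcpSpec(cond=GravityCondition(alpha=0.0), nodes=N)
            vals[N] = trajectory_rtpv(solve(spec))
        assert abs(vals[41] - vals[81]) < 0.2

    def test_nonconvergence_raises_with_diagnostic(self):
        spec = OcpSpec(cond=GravityCondition(alpha=0.0), nodes=41)
        with pytest.raises(OcpSolverError, match="SLSQP"):
            solve(spec, maxiter=2)

    def test_invalid_specs_rejected(self):
        cond = GravityCondition(alpha=0.0)
        with pytest.raises(ValueError):
            OcpSpec(cond=cond, duration=-1.0)
        with pytest.raises(ValueError):
            OcpSpec(cond=cond, beta=0.0)
        with pytest.raises(ValueError):
            OcpSpec(cond=cond, nodes=10)
        with pytest.raises(ValueError):
            OcpSpec(cond=cond, theta_start=0.3, theta_end=0.3)


class TestSigmaShift:
    def test_engaged_shift_changes_solution_and_settles(self):
        rule = {("upward", "acceleration"): 1, ("upward", "deceleration"): 0,
                ("downward", "acceleration"): 0,
                ("downward", "deceleration"): 0}
        p = PlantParams(inertial_shift=0.08, sigma_rule=rule)
        spec = OcpSpec(cond=GravityCondition(alpha=0.0), params=p, nodes=41)
        shifted = solve(spec)
        baseline = solve(OcpSpec(cond=GravityCondition(alpha=0.0), nodes=41))
        # heavier accelerating inertia lengthens the acceleration phase
        assert trajectory_rtpv(shifted) != pytest.approx(
            trajectory_rtpv(baseline), abs=0.05)
        assert shifted.solver_status["max_defect"] < spec.tol


class TestSweep:
    def test_single_condition_reduces_to_plain_solve(self):
        spec = OcpSpec(cond=GravityCondition(alpha=0.0), nodes=41)
        res = sweep_conditions(spec, [1.0])
        assert res.ok and len(res.trajectories) == 1
        direct = solve(OcpSpec(cond=GravityCondition(alpha=1.0), nodes=41))
        assert trajectory_rtpv(res.trajectories[0]) == pytest.approx(
            trajectory_rtpv(direct), abs=0.1)

    def test_eleven_condition_grid(self):
        spec = OcpSpec(cond=GravityCondition(alpha=0.0), nodes=41)
        alphas = np.round(np.linspace(0, 2, 11), 10)
        res = sweep_conditions(spec, alphas)
        assert res.ok, res.failures
        assert [c.alpha for c in res.conditions] == list(alphas)
        ce = [t.cost_effort for t in res.trajectories]
        assert len(set(np.round(ce, 6))) == len(ce)  # strictly varying

    def test_warm_start_agrees_with_cold_start(self):
        """Sweep warm starts are an efficiency device only: a cold solve of
        a mid-sweep condition must land on the same optimum."""
        spec = OcpSpec(cond=GravityCondition(alpha=0.0), nodes=41)
        res = sweep_conditions(spec, [0.0, 0.2, 0.4])
        warm = res.trajectories[2]
        cold = solve(OcpSpec(cond=GravityCondition(alpha=0.4), nodes=41))
        assert warm.cost_total == pytest.approx(cold.cost_total, rel=1e-5)
        assert trajectory_rtpv(warm) == pytest.approx(
            trajectory_rtpv(cold), abs=0.1)
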