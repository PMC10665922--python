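"""Smooth-Effort optimal control of a single elbow movement.

The model plans a rest-to-rest movement of fixed duration T by minimizing

    J(u_h) = Ce + beta * Cs

where ``Ce = int |tau_h * theta_dot| dt`` is the absolute work of the net
joint torque (the effort term, responsible for the model's inactivation
periods) and ``Cs = int (u_h - B*theta_ddot + mhl*g_eff*theta_dot*sin th)^2 dt``
is a smoothness term that, along dynamics-consistent trajectories, equals
``I^2 * int jerk(theta)^2 dt``.  The control is the commanded torque change
``u_h = d(tau_h)/dt``.

The problem is transcribed by fixed-step Hermite-Simpson collocation
(:mod:`smootheffort._collocation`) and solved deterministically with SLSQP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import simpson
from scipy.interpolate import CubicHermiteSpline

from ._collocation import CollocationProblem, NlpSolution
from .plant import GravityCondition, PlantParams, effective_gravity

__all__ = [
    "OcpSpec",
    "Trajectory",
    "OcpSolverError",
    "SweepResult",
    "effort_cost",
    "smoothness_cost",
    "solve",
    "sweep_conditions",
]

#: Default experimental geometry: 45 degree movement centred on the
#: horizontal forearm.
THETA_LOW = -np.pi / 8
THETA_HIGH = np.pi / 8


class OcpSolverError(RuntimeError):
    """Raised when the transcribed problem fails to converge.

    Carries the raw NLP diagnostic in ``solution``.
    """

    def __init__(self, message: str, solution: NlpSolution | None = None):
        super().__init__(message)
        self.solution = solution


@dataclass(frozen=True)
class OcpSpec:
    """Specification of one movement-planning problem.

    ``theta_start``/``theta_end`` in rad, ``duration`` (the movement duration
    MD) in s, ``beta`` the dimensionless smoothness weight, ``nodes`` the
    collocation grid size, ``tol`` the admissible dynamics defect at the
    solution, ``abs_mode`` how the absolute-work integrand is handled
    ("slack" exact reformulation or "smooth" surrogate with width ``eps``).
    """

    cond: GravityCondition
    params: PlantParams = field(default_factory=PlantParams)
    theta_start: float | None = None
    theta_end: float | None = None
    duration: float = 0.6
    beta: float = 1.9e-3
    nodes: int = 101
    tol: float = 1e-6
    abs_mode: str = "smooth"
    eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.nodes < 20:
            raise ValueError(f"nodes must be >= 20, got {self.nodes}")
        lo, hi = self.boundary_angles()
        if lo == hi:
            raise ValueError("theta_start and theta_end must differ")

    def boundary_angles(self) -> tuple[float, float]:
        """Resolve boundary angles; defaults follow the movement direction."""
        if self.theta_start is not None and self.theta_end is not None:
            return self.theta_start, self.theta_end
        if self.cond.direction == "upward":
            return THETA_LOW, THETA_HIGH
        return THETA_HIGH, THETA_LOW


@dataclass
class Trajectory:
    """Time-gridded optimal solution of one movement-planning problem."""

    t: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray
    theta_ddot: np.ndarray
    tau_h: np.ndarray
    u_h: np.ndarray
    cost_effort: float
    cost_smooth: float
    cost_total: float
    beta: float
    solver_status: dict
    spec: OcpSpec | None = None

    def splines(self):
        """Cubic Hermite interpolants (theta, omega, tau) over the grid."""
        th = CubicHermiteSpline(self.t, self.theta, self.theta_dot)
        om = CubicHermiteSpline(self.t, self.theta_dot, self.theta_ddot)
        ta = CubicHermiteSpline(self.t, self.tau_h, self.u_h)
        return th, om, ta

    def resample(self, fs: float | None = None, num: int | None = None):
        """Resample on a dense uniform grid (``fs`` Hz or ``num`` samples).

        Returns (t, theta, theta_dot, theta_ddot, tau_h) as arrays.
        """
        if fs is not None:
            num = int(round((self.t[-1] - self.t[0]) * fs)) + 1
        elif num is None:
            num = 6001
        td = np.linspace(self.t[0], self.t[-1], num)
        th, om, ta = self.splines()
        return td, th(td), om(td), om.derivative()(td), ta(td)


@dataclass
class SweepResult:
    """Per-condition outcome of a gravity sweep (order preserved)."""

    conditions: list[GravityCondition]
    trajectories: list[Trajectory | None]
    failures: dict[float, str]

    @property
    def ok(self) -> bool:
        return not self.failures


# --------------------------------------------------------------------- costs

def effort_cost(traj: Trajectory) -> float:
    """Absolute work of the net joint torque: int |tau_h * theta_dot| dt."""
    return float(simpson(np.abs(traj.tau_h * traj.theta_dot), x=traj.t))


def smoothness_cost(traj: Trajectory, cond: GravityCondition | None = None,
                    params: PlantParams | None = None) -> float:
    """Squared-smoothness cost int (u_h - B*acc + c*vel*sin(theta))^2 dt.

    Along trajectories consistent with the reduced dynamics (sigma = 0) the
    integrand equals (I * jerk)^2, so this is I^2 times the integrated
    squared jerk of theta.
    """
    if traj.spec is not None:
        cond = cond or traj.spec.cond
        params = params or traj.spec.params
    if cond is None or params is None:
        raise ValueError("cond and params are required when the trajectory "
                         "carries no spec")
    c = params.weight_moment * effective_gravity(cond, params)
    r = (traj.u_h - params.damping * traj.theta_ddot
         + c * traj.theta_dot * np.sin(traj.theta))
    return float(simpson(r ** 2, x=traj.t))


# --------------------------------------------------------------------- solve

def _phase_sigma(spec: OcpSpec, accel: np.ndarray,
                 vel: np.ndarray) -> np.ndarray:
    """Resolve sigma per point from the acceleration-phase pattern.

    A point is in the acceleration phase when the velocity magnitude is
    increasing (accel * vel >= 0); vel ~ 0 points inherit the acceleration
    sign of the movement direction.
    """
    p = spec.params
    d = spec.cond.direction
    sig_acc = p.sigma(d, "acceleration")
    sig_dec = p.sigma(d, "deceleration")
    lo, hi = spec.boundary_angles()
    v = np.where(np.abs(vel) > 1e-12, vel, np.sign(hi - lo))
    accel_phase = accel * v >= 0
    return np.where(accel_phase, sig_acc, sig_dec)


def _build_problem(spec: OcpSpec, sigma_nodes: np.ndarray,
                   sigma_mid: np.ndarray, beta: float) -> CollocationProblem:
    p = spec.params
    g_eff = effective_gravity(spec.cond, p)
    c = p.weight_moment * g_eff
    th0, thT = spec.boundary_angles()
    Ie_n = p.inertia + sigma_nodes * p.inertial_shift
    Ie_m = p.inertia + sigma_mid * p.inertial_shift
    return CollocationProblem(
        n_nodes=spec.nodes, duration=spec.duration,
        inertia_nodes=Ie_n, inertia_mid=Ie_m,
        damping=p.damping, c_grav=c,
        theta_start=th0, theta_end=thT,
        beta=beta, mode=spec.abs_mode, eps=spec.eps,
    )


def _beta_stages(beta: float) -> list[float]:
    """Homotopy path in beta: small weights are reached by warm-started steps
    (half-decade ladder down from 1e-3)."""
    if beta >= 1e-3:
        return [beta]
    stages = [1e-3]
    step = 10.0 ** 0.5
    while stages[-1] / step > beta * 1.0000001:
        stages.append(stages[-1] / step)
    stages.append(beta)
    return stages


def _states_from_trajectory(traj: Trajectory, N: int, T: float) -> np.ndarray:
    """Interpolate a previous solution onto an N-node grid as a warm start."""
    t_new = np.linspace(0.0, T, N)
    scale = (traj.t[-1] - traj.t[0]) / T if T > 0 else 1.0
    t_src = traj.t[0] + (t_new - t_new[0]) * scale
    th, om, ta = traj.splines()
    u = np.interp(t_src, traj.t, traj.u_h)
    um = np.interp(0.5 * (t_src[:-1] + t_src[1:]), traj.t, traj.u_h)
    return np.concatenate([th(t_src), om(t_src), ta(t_src), u, um])


def solve(spec: OcpSpec, initial: Trajectory | None = None,
          maxiter: int = 1500) -> Trajectory:
    """Solve the Smooth-Effort problem for one movement.

    Deterministic: identical specs (and warm starts) give identical
    trajectories.  A warm start from a neighbouring solve is tried first;
    cold starts follow a minimum-jerk initial guess with a homotopy path in
    beta for small smoothness weights.  Raises :class:`OcpSolverError` on
    non-convergence or if the dynamics defect at the reported solution
    exceeds ``spec.tol``.
    """
    p = spec.params
    use_shift = (p.inertial_shift != 0.0
                 and any(p.sigma_rule[k] for k in p.sigma_rule))
    N = spec.nodes
    sigma_n = np.zeros(N)
    sigma_m = np.zeros(N - 1)
    if not use_shift:
        return _solve_fixed_sigma(spec, sigma_n, sigma_m, initial, maxiter)

    # Fixed-point iteration on the acceleration-phase pattern: solve with a
    # frozen sigma pattern, re-derive the pattern from the solution, repeat.
    traj = _solve_fixed_sigma(spec, sigma_n, sigma_m, initial, maxiter)
    for _ in range(8):
        acc = traj.theta_ddot
        vel = traj.theta_dot
        new_n = _phase_sigma(spec, acc, vel).astype(float)
        acc_m = 0.5 * (acc[:-1] + acc[1:])
        vel_m = 0.5 * (vel[:-1] + vel[1:])
        new_m = _phase_sigma(spec, acc_m, vel_m).astype(float)
        if np.array_equal(new_n, sigma_n) and np.array_equal(new_m, sigma_m):
            break
        sigma_n, sigma_m = new_n, new_m
        traj = _solve_fixed_sigma(spec, sigma_n, sigma_m, traj, maxiter)
    else:
        warnings.warn("sigma phase pattern did not settle in 8 iterations; "
                      "returning the last converged solution")
    return traj


def _solve_fixed_sigma(spec: OcpSpec, sigma_n, sigma_m,
                       initial: Trajectory | None, maxiter: int) -> Trajectory:
    stages = _beta_stages(spec.beta)
    z_states = None
    if initial is not None:
        z_states = _states_from_trajectory(initial, spec.nodes, spec.duration)
        stages = [spec.beta]  # warm start: go straight at the target weight

    sol = None
    for b in stages:
        final = b == stages[-1]
        prob = _build_problem(spec, sigma_n, sigma_m, b)
        z0 = prob.initial_guess(z_states)
        sol = prob.solve_nlp(z0,
                             maxiter=maxiter if final else 200,
                             acc=1e-9 if final else 1e-8)
        z_states = sol.z[: prob.n_states]

    if (not sol.success or sol.max_defect > spec.tol) and initial is not None:
        # warm start led astray: retry the cold homotopy path
        return _solve_fixed_sigma(spec, sigma_n, sigma_m, None, maxiter)
    if not sol.success:
        raise OcpSolverError(
            f"SLSQP failed (status {sol.status}: {sol.message}, "
            f"nit={sol.nit}, max defect {sol.max_defect:.2e})", sol)
    if sol.max_defect > spec.tol:
        raise OcpSolverError(
            f"dynamics defect {sol.max_defect:.2e} exceeds tol {spec.tol:.2e}",
            sol)
    return _trajectory_from_solution(spec, prob, sol)


def _trajectory_from_solution(spec: OcpSpec, prob: CollocationProblem,
                              sol: NlpSolution) -> Trajectory:
    z = sol.z
    N = prob.N
    th, om, ta = z[prob.iTH], z[prob.iOM], z[prob.iTA]
    u = z[prob.iU]
    um = z[prob.iUM]
    acc = prob._accel(th, om, ta, prob.Ie_n)
    t = np.linspace(0.0, prob.T, N)

    # costs from the collocation quadrature (nodes + midpoints), with the
    # exact absolute value regardless of the solver's abs_mode
    thm = 0.5 * (th[:-1] + th[1:]) + prob.h / 8 * (om[:-1] - om[1:])
    omm = 0.5 * (om[:-1] + om[1:]) + prob.h / 8 * (acc[:-1] - acc[1:])
    tam = 0.5 * (ta[:-1] + ta[1:]) + prob.h / 8 * (u[:-1] - u[1:])
    am = prob._accel(thm, omm, tam, prob.Ie_m)
    ce = float(prob.w_node @ np.abs(ta * om) + prob.w_mid @ np.abs(tam * omm))
    r_n = u - prob.B * acc + prob.c * om * np.sin(th)
    r_m = um - prob.B * am + prob.c * omm * np.sin(thm)
    cs = float(prob.w_node @ r_n ** 2 + prob.w_mid @ r_m ** 2)

    status = {
        "success": sol.success,
        "status": sol.status,
        "message": sol.message,
        "nit": sol.nit,
        "max_defect": sol.max_defect,
        "nlp_objective": sol.objective,
    }
    return Trajectory(
        t=t, theta=th, theta_dot=om, theta_ddot=acc, tau_h=ta, u_h=u,
        cost_effort=ce, cost_smooth=cs, cost_total=ce + spec.beta * cs,
        beta=spec.beta, solver_status=status, spec=spec,
    )


def sweep_conditions(spec_template: OcpSpec,
                     alphas: Sequence[float]) -> SweepResult:
    """Solve one movement per compensation fraction, warm-starting along the
    sweep.  Per-condition failures are recorded and the sweep continues."""
    conditions: list[GravityCondition] = []
    trajectories: list[Trajectory | None] = []
    failures: dict[float, str] = {}
    prev: Trajectory | None = None
    for alpha in alphas:
        cond = GravityCondition(alpha=float(alpha),
                                direction=spec_template.cond.direction)
        spec = replace(spec_template, cond=cond)
        conditions.append(cond)
        try:
            traj = solve(spec, initial=prev)
        except OcpSolverError as exc:
            failures[float(alpha)] = str(exc)
            trajectories.append(None)
            continue
        trajectories.append(traj)
        prev = traj
    return SweepResult(conditions=conditions, trajectories=trajectories,
                       failures=failures)
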