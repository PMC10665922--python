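"""Independent single-shooting re-optimization of a planned movement.

Serves as a cross-check on the collocation solver: the control u(t) is a
piecewise-linear profile on a coarse grid, the state (theta, omega, tau_h)
is integrated with fixed-step RK4 on a dense grid, and the cost plus
terminal rest conditions are optimized with SLSQP.  Everything here —
transcription, integration, quadrature — is deliberately different from
the collocation path, so agreement of the two objective values is evidence
about the solution, not about shared code.

Gradients are forward finite differences computed on a vectorized ensemble
of perturbed control profiles (one RK4 sweep integrates all perturbations
simultaneously).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .ocp import OcpSpec, Trajectory
from .plant import effective_gravity

__all__ = ["reoptimize_shooting"]


def _integrate_cost(U, spec: OcpSpec, n_steps: int):
    """RK4 ensemble integration; U has shape (k, M) of control profiles.

    Returns (J, terminal_state) with shapes (k,) and (k, 3).
    """
    p = spec.params
    I = p.inertia
    B = p.damping
    c = p.weight_moment * effective_gravity(spec.cond, p)
    th0, thT = spec.boundary_angles()
    T = spec.duration
    dt = T / n_steps
    M = U.shape[1]
    t_ctrl = np.linspace(0.0, T, M)

    def u_of(t):
        # piecewise-linear interpolation, vectorized over the ensemble
        x = np.clip(t / T * (M - 1), 0, M - 1 - 1e-12)
        i = int(x)
        w = x - i
        return (1 - w) * U[:, i] + w * U[:, i + 1]

    k = U.shape[0]
    th = np.full(k, th0)
    om = np.zeros(k)
    ta = np.full(k, c * np.cos(th0))
    J = np.zeros(k)
    eps = spec.eps

    def rhs(th, om, ta, u):
        a = (ta - B * om - c * np.cos(th)) / I
        return om, a, u

    def run_cost(th, om, ta, u):
        a = (ta - B * om - c * np.cos(th)) / I
        r = u - B * a + c * om * np.sin(th)
        return np.sqrt((ta * om) ** 2 + eps ** 2) + spec.beta * r ** 2

    g_prev = run_cost(th, om, ta, u_of(0.0))
    for s in range(n_steps):
        t = s * dt
        u1 = u_of(t)
        u2 = u_of(t + dt / 2)
        u4 = u_of(t + dt)
        k1 = rhs(th, om, ta, u1)
        k2 = rhs(th + dt / 2 * k1[0], om + dt / 2 * k1[1],
                 ta + dt / 2 * k1[2], u2)
        k3 = rhs(th + dt / 2 * k2[0], om + dt / 2 * k2[1],
                 ta + dt / 2 * k2[2], u2)
        k4 = rhs(th + dt * k3[0], om + dt * k3[1], ta + dt * k3[2], u4)
        th = th + dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        om = om + dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        ta = ta + dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        g_new = run_cost(th, om, ta, u4)
        J += dt / 2 * (g_prev + g_new)
        g_prev = g_new
    return J, np.stack([th, om, ta], axis=1)


def reoptimize_shooting(traj: Trajectory, n_ctrl: int = 41,
                        n_steps: int = 600,
                        maxiter: int = 200) -> tuple[float, dict]:
    """Re-optimize a collocation solution by dense single shooting.

    Returns the re-optimized objective value and a diagnostics dict
    (initial shooting objective, terminal violation, solver status).
    """
    spec = traj.spec
    if spec is None:
        raise ValueError("trajectory carries no spec")
    p = spec.params
    c = p.weight_moment * effective_gravity(spec.cond, p)
    th0, thT = spec.boundary_angles()
    target = np.array([thT, 0.0, c * np.cos(thT)])
    scale = np.array([0.5, 2.0, 3.0])  # constraint balance

    t_ctrl = np.linspace(0.0, spec.duration, n_ctrl)
    u0 = np.interp(t_ctrl, traj.t, traj.u_h)
    fd_step = 1e-6 * max(1.0, float(np.max(np.abs(u0))))

    cache: dict[bytes, tuple] = {}

    def ensemble(u):
        key = u.tobytes()
        if key not in cache:
            cache.clear()
            U = np.tile(u, (n_ctrl + 1, 1))
            U[1:] += np.eye(n_ctrl) * fd_step
            J, X = _integrate_cost(U, spec, n_steps)
            cache[key] = (J, X)
        return cache[key]

    def fun(u):
        J, _ = ensemble(u)
        return J[0], (J[1:] - J[0]) / fd_step

    def con(u):
        _, X = ensemble(u)
        return (X[0] - target) / scale

    def con_jac(u):
        _, X = ensemble(u)
        return ((X[1:] - X[0]) / fd_step / scale).T

    J_init = fun(u0)[0]
    res = minimize(fun, u0, jac=True, method="SLSQP",
                   constraints=[{"type": "eq", "fun": con, "jac": con_jac}],
                   options={"maxiter": maxiter, "ftol": 1e-10})
    _, X = ensemble(res.x)
    diag = {
        "J_init": float(J_init),
        "terminal_violation": float(np.max(np.abs(X[0] - target))),
        "status": int(res.status),
        "nit": int(res.nit),
        "message": str(res.message),
    }
    return float(res.fun), diag
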