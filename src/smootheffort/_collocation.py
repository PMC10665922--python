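"""Hermite-Simpson transcription of the smooth-effort optimal control problem.

The continuous problem is transcribed on a fixed grid of N nodes with the
state x = (theta, omega, tau_h) and the control u = d(tau_h)/dt.  Between
consecutive nodes a collocation midpoint is formed by Hermite interpolation
and a Simpson defect constrains the interval.  The resulting nonlinear
program is solved with SLSQP using analytic objective gradients and
constraint Jacobians (verified against finite differences in the test
suite).

Two treatments of the non-smooth absolute-work integrand |tau_h * omega| are
provided:

``slack``
    Exact reformulation: at every node and midpoint two non-negative slack
    variables s+ and s- satisfy s+ - s- = tau_h*omega, and the quadrature of
    s+ + s- enters the objective.  At the optimum min(s+, s-) = 0, so the
    quadrature equals that of |tau_h*omega| exactly.
``smooth``
    Smooth surrogate sqrt(x^2 + eps^2) with configurable eps.

The dynamics use a per-point effective inertia array so that the
direction/phase-gated inertial shift can be resolved by an outer fixed-point
iteration over the acceleration-phase pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = ["CollocationProblem", "NlpSolution"]


@dataclass
class NlpSolution:
    z: np.ndarray
    success: bool
    status: int
    message: str
    nit: int
    objective: float
    max_defect: float


class CollocationProblem:
    """One transcription instance: fixed grid, plant constants, boundary data.

    Parameters
    ----------
    n_nodes : int
        Number of collocation nodes (N >= 20).
    duration : float
        Movement duration T, s.
    inertia_nodes, inertia_mid : ndarray
        Effective inertia I + sigma*Is at each node (N,) and midpoint (N-1,).
    damping, c_grav : float
        Damping B and gravity moment c = mhl * g_eff.
    theta_start, theta_end : float
        Boundary angles, rad.  Boundary angular velocity is zero and the
        boundary torque equals the static holding torque c*cos(theta), as
        forced by rest-to-rest boundary conditions under the dynamics.
    beta : float
        Smoothness weight.
    mode : {"slack", "smooth"}
        Treatment of the absolute-work integrand.
    eps : float
        Smoothing width for ``mode="smooth"``.
    """

    def __init__(self, n_nodes: int, duration: float,
                 inertia_nodes: np.ndarray, inertia_mid: np.ndarray,
                 damping: float, c_grav: float,
                 theta_start: float, theta_end: float,
                 beta: float, mode: str = "slack", eps: float = 1e-6):
        if n_nodes < 20:
            raise ValueError(f"n_nodes must be >= 20, got {n_nodes}")
        if mode not in ("slack", "smooth"):
            raise ValueError(f"mode must be 'slack' or 'smooth', got {mode!r}")
        self.N = int(n_nodes)
        self.T = float(duration)
        self.h = self.T / (self.N - 1)
        self.Ie_n = np.asarray(inertia_nodes, dtype=float)
        self.Ie_m = np.asarray(inertia_mid, dtype=float)
        if self.Ie_n.shape != (self.N,) or self.Ie_m.shape != (self.N - 1,):
            raise ValueError("inertia arrays must have shapes (N,) and (N-1,)")
        if np.any(self.Ie_n <= 0) or np.any(self.Ie_m <= 0):
            raise ValueError("effective inertia must be positive everywhere")
        self.B = float(damping)
        self.c = float(c_grav)
        self.theta0 = float(theta_start)
        self.thetaT = float(theta_end)
        self.beta = float(beta)
        self.mode = mode
        self.eps = float(eps)

        N = self.N
        self.n_states = 4 * N + (N - 1)  # theta, omega, tau, u, u_mid
        self.n_slack = 2 * (2 * N - 1) if mode == "slack" else 0
        self.n_var = self.n_states + self.n_slack
        # variable slices
        self.iTH = slice(0, N)
        self.iOM = slice(N, 2 * N)
        self.iTA = slice(2 * N, 3 * N)
        self.iU = slice(3 * N, 4 * N)
        self.iUM = slice(4 * N, 5 * N - 1)
        if mode == "slack":
            base = self.n_states
            self.iSP = slice(base, base + 2 * N - 1)
            self.iSM = slice(base + 2 * N - 1, base + 2 * (2 * N - 1))

        # Simpson quadrature weights over nodes and midpoints
        h = self.h
        wn = np.full(N, h / 3.0)
        wn[0] = wn[-1] = h / 6.0
        self.w_node = wn
        self.w_mid = np.full(N - 1, 2.0 * h / 3.0)

        self.tau0 = self.c * np.cos(self.theta0)
        self.tauT = self.c * np.cos(self.thetaT)

    # ---------------------------------------------------------------- pieces

    def _accel(self, th, om, ta, Ie):
        return (ta - self.B * om - self.c * np.cos(th)) / Ie

    def _midstates(self, z):
        """Hermite midpoint states and the node dynamics used to build them."""
        h = self.h
        th, om, ta = z[self.iTH], z[self.iOM], z[self.iTA]
        u = z[self.iU]
        a = self._accel(th, om, ta, self.Ie_n)
        thm = 0.5 * (th[:-1] + th[1:]) + h / 8 * (om[:-1] - om[1:])
        omm = 0.5 * (om[:-1] + om[1:]) + h / 8 * (a[:-1] - a[1:])
        tam = 0.5 * (ta[:-1] + ta[1:]) + h / 8 * (u[:-1] - u[1:])
        return th, om, ta, u, a, thm, omm, tam

    def _smooth_residual(self, th, om, ta, u, Ie):
        """Integrand root of the smoothness cost: u - B*acc + c*omega*sin(theta).

        For dynamics-consistent trajectories this equals I * d3(theta)/dt3.
        """
        a = self._accel(th, om, ta, Ie)
        return u - self.B * a + self.c * om * np.sin(th)

    # ------------------------------------------------------------- objective

    def objective(self, z):
        val, _ = self._objective_impl(z, need_grad=False)
        return val

    def objective_with_grad(self, z):
        return self._objective_impl(z, need_grad=True)

    def _objective_impl(self, z, need_grad):
        N, h, B, c, beta = self.N, self.h, self.B, self.c, self.beta
        th, om, ta, u, a, thm, omm, tam = self._midstates(z)
        um = z[self.iUM]
        am = self._accel(thm, omm, tam, self.Ie_m)

        r_n = u - B * a + c * om * np.sin(th)
        r_m = um - B * am + c * omm * np.sin(thm)

        if self.mode == "smooth":
            p_n = ta * om
            p_m = tam * omm
            e_n = np.sqrt(p_n ** 2 + self.eps ** 2)
            e_m = np.sqrt(p_m ** 2 + self.eps ** 2)
        else:
            sp, sm = z[self.iSP], z[self.iSM]
            e_n = sp[:N] + sm[:N]
            e_m = sp[N:] + sm[N:]

        J = (self.w_node @ (e_n + beta * r_n ** 2)
             + self.w_mid @ (e_m + beta * r_m ** 2))
        if not need_grad:
            return J, None

        grad = np.zeros(self.n_var)
        ath_n = c * np.sin(th) / self.Ie_n
        aom_n = -B / self.Ie_n
        ata_n = 1.0 / self.Ie_n
        ath_m = c * np.sin(thm) / self.Ie_m
        aom_m = -B / self.Ie_m
        ata_m = 1.0 / self.Ie_m

        # node terms
        two_br = 2.0 * beta * r_n * self.w_node
        rth_n = -B * ath_n + c * om * np.cos(th)
        rom_n = -B * aom_n + c * np.sin(th)
        rta_n = -B * ata_n
        if self.mode == "smooth":
            dphi_n = (ta * om) / e_n * self.w_node
            grad[self.iOM] += dphi_n * ta
            grad[self.iTA] += dphi_n * om
        grad[self.iTH] += two_br * rth_n
        grad[self.iOM] += two_br * rom_n
        grad[self.iTA] += two_br * rta_n
        grad[self.iU] += two_br

        # midpoint terms, chained through the Hermite midstates
        gth_m = np.zeros(N - 1)
        gom_m = np.zeros(N - 1)
        gta_m = np.zeros(N - 1)
        two_brm = 2.0 * beta * r_m * self.w_mid
        gth_m += two_brm * (-B * ath_m + c * omm * np.cos(thm))
        gom_m += two_brm * (-B * aom_m + c * np.sin(thm))
        gta_m += two_brm * (-B * ata_m)
        gum = two_brm
        if self.mode == "smooth":
            dphi_m = (tam * omm) / e_m * self.w_mid
            gom_m += dphi_m * tam
            gta_m += dphi_m * omm

        self._chain_mid_to_primitives(grad, gth_m, gom_m, gta_m,
                                      ath_n, aom_n, ata_n)
        grad[self.iUM] += gum

        if self.mode == "slack":
            grad[self.iSP] = np.concatenate([self.w_node, self.w_mid])
            grad[self.iSM] = np.concatenate([self.w_node, self.w_mid])
        return J, grad

    def _chain_mid_to_primitives(self, grad, gth_m, gom_m, gta_m,
                                 ath_n, aom_n, ata_n):
        """Accumulate d(mid term)/d(node vars) into a flat gradient."""
        h8 = self.h / 8.0
        L, R = slice(0, self.N - 1), slice(1, self.N)
        g = np.zeros(self.N)
        # theta_L / theta_R
        np.add.at(grad[self.iTH], np.arange(self.N - 1),
                  0.5 * gth_m + gom_m * h8 * ath_n[L])
        np.add.at(grad[self.iTH], np.arange(1, self.N),
                  0.5 * gth_m - gom_m * h8 * ath_n[R])
        # omega_L / omega_R
        np.add.at(grad[self.iOM], np.arange(self.N - 1),
                  gth_m * h8 + gom_m * (0.5 + h8 * aom_n[L]))
        np.add.at(grad[self.iOM], np.arange(1, self.N),
                  -gth_m * h8 + gom_m * (0.5 - h8 * aom_n[R]))
        # tau_L / tau_R
        np.add.at(grad[self.iTA], np.arange(self.N - 1),
                  gom_m * h8 * ata_n[L] + 0.5 * gta_m)
        np.add.at(grad[self.iTA], np.arange(1, self.N),
                  -gom_m * h8 * ata_n[R] + 0.5 * gta_m)
        # u_L / u_R (enter only through tau_mid)
        np.add.at(grad[self.iU], np.arange(self.N - 1), gta_m * h8)
        np.add.at(grad[self.iU], np.arange(1, self.N), -gta_m * h8)
        del g

    # ------------------------------------------------------------ constraints

    def constraints(self, z):
        N, h = self.N, self.h
        th, om, ta, u, a, thm, omm, tam = self._midstates(z)
        um = z[self.iUM]
        am = self._accel(thm, omm, tam, self.Ie_m)
        d1 = th[1:] - th[:-1] - h / 6 * (om[:-1] + 4 * omm + om[1:])
        d2 = om[1:] - om[:-1] - h / 6 * (a[:-1] + 4 * am + a[1:])
        d3 = ta[1:] - ta[:-1] - h / 6 * (u[:-1] + 4 * um + u[1:])
        out = [d1, d2, d3]
        if self.mode == "slack":
            sp, sm = z[self.iSP], z[self.iSM]
            out.append(sp[:N] - sm[:N] - ta * om)
            out.append(sp[N:] - sm[N:] - tam * omm)
        return np.concatenate(out)

    def constraints_jac(self, z):
        N, h, B, c = self.N, self.h, self.B, self.c
        th, om, ta, u, a, thm, omm, tam = self._midstates(z)
        h6, h8, h2_12 = h / 6.0, h / 8.0, h * h / 12.0
        ath_n = c * np.sin(th) / self.Ie_n
        aom_n = -B / self.Ie_n
        ata_n = 1.0 / self.Ie_n
        ath_m = c * np.sin(thm) / self.Ie_m
        aom_m = -B / self.Ie_m
        ata_m = 1.0 / self.Ie_m

        n_def = 3 * (N - 1)
        n_con = n_def + (2 * N - 1 if self.mode == "slack" else 0)
        Jc = np.zeros((n_con, self.n_var))
        k = np.arange(N - 1)
        rows1, rows2, rows3 = k, N - 1 + k, 2 * (N - 1) + k
        oTH, oOM, oTA, oU, oUM = (self.iTH.start, self.iOM.start,
                                  self.iTA.start, self.iU.start,
                                  self.iUM.start)
        L, R = k, k + 1

        # d1 rows
        Jc[rows1, oTH + L] += -1.0 - h2_12 * ath_n[L]
        Jc[rows1, oTH + R] += 1.0 + h2_12 * ath_n[R]
        Jc[rows1, oOM + L] += -h / 2.0 - h2_12 * aom_n[L]
        Jc[rows1, oOM + R] += -h / 2.0 + h2_12 * aom_n[R]
        Jc[rows1, oTA + L] += -h2_12 * ata_n[L]
        Jc[rows1, oTA + R] += h2_12 * ata_n[R]

        # midpoint-acceleration partials w.r.t. primitives
        dam_thL = ath_m * 0.5 + aom_m * h8 * ath_n[L]
        dam_thR = ath_m * 0.5 - aom_m * h8 * ath_n[R]
        dam_omL = ath_m * h8 + aom_m * (0.5 + h8 * aom_n[L])
        dam_omR = -ath_m * h8 + aom_m * (0.5 - h8 * aom_n[R])
        dam_taL = aom_m * h8 * ata_n[L] + ata_m * 0.5
        dam_taR = -aom_m * h8 * ata_n[R] + ata_m * 0.5
        dam_uL = ata_m * h8
        dam_uR = -ata_m * h8

        # d2 rows
        Jc[rows2, oTH + L] += -h6 * ath_n[L] - 4 * h6 * dam_thL
        Jc[rows2, oTH + R] += -h6 * ath_n[R] - 4 * h6 * dam_thR
        Jc[rows2, oOM + L] += -1.0 - h6 * aom_n[L] - 4 * h6 * dam_omL
        Jc[rows2, oOM + R] += 1.0 - h6 * aom_n[R] - 4 * h6 * dam_omR
        Jc[rows2, oTA + L] += -h6 * ata_n[L] - 4 * h6 * dam_taL
        Jc[rows2, oTA + R] += -h6 * ata_n[R] - 4 * h6 * dam_taR
        Jc[rows2, oU + L] += -4 * h6 * dam_uL
        Jc[rows2, oU + R] += -4 * h6 * dam_uR

        # d3 rows
        Jc[rows3, oTA + L] += -1.0
        Jc[rows3, oTA + R] += 1.0
        Jc[rows3, oU + L] += -h6
        Jc[rows3, oU + R] += -h6
        Jc[rows3, oUM + k] += -4 * h6

        if self.mode == "slack":
            oSP, oSM = self.iSP.start, self.iSM.start
            rn = n_def + np.arange(N)
            Jc[rn, oTA + np.arange(N)] = -om
            Jc[rn, oOM + np.arange(N)] = -ta
            Jc[rn, oSP + np.arange(N)] = 1.0
            Jc[rn, oSM + np.arange(N)] = -1.0
            rm = n_def + N + k
            # -(omm * d tam + tam * d omm) w.r.t. primitives
            Jc[rm, oTA + L] += -(omm * 0.5 + tam * h8 * ata_n[L])
            Jc[rm, oTA + R] += -(omm * 0.5 - tam * h8 * ata_n[R])
            Jc[rm, oU + L] += -omm * h8
            Jc[rm, oU + R] += omm * h8
            Jc[rm, oTH + L] += -tam * h8 * ath_n[L]
            Jc[rm, oTH + R] += tam * h8 * ath_n[R]
            Jc[rm, oOM + L] += -tam * (0.5 + h8 * aom_n[L])
            Jc[rm, oOM + R] += -tam * (0.5 - h8 * aom_n[R])
            Jc[rm, oSP + N + k] = 1.0
            Jc[rm, oSM + N + k] = -1.0
        return Jc

    # ---------------------------------------------------------------- bounds

    def bounds(self):
        lb = np.full(self.n_var, -np.inf)
        ub = np.full(self.n_var, np.inf)
        N = self.N
        for i, v in ((0, self.theta0), (N - 1, self.thetaT)):
            lb[i] = ub[i] = v
        lb[self.iOM.start] = ub[self.iOM.start] = 0.0
        lb[self.iOM.stop - 1] = ub[self.iOM.stop - 1] = 0.0
        lb[self.iTA.start] = ub[self.iTA.start] = self.tau0
        lb[self.iTA.stop - 1] = ub[self.iTA.stop - 1] = self.tauT
        if self.mode == "slack":
            lb[self.iSP] = 0.0
            lb[self.iSM] = 0.0
        return lb, ub

    # ----------------------------------------------------------- initial guess

    def initial_guess(self, z_states: np.ndarray | None = None):
        """Minimum-jerk warm start (or attach slacks to a given state vector)."""
        N, h = self.N, self.h
        if z_states is None:
            t = np.linspace(0.0, self.T, N)
            s = t / self.T
            mj = 10 * s ** 3 - 15 * s ** 4 + 6 * s ** 5
            dmj = (30 * s ** 2 - 60 * s ** 3 + 30 * s ** 4) / self.T
            ddmj = (60 * s - 180 * s ** 2 + 120 * s ** 3) / self.T ** 2
            dddmj = (60 - 360 * s + 360 * s ** 2) / self.T ** 3
            amp = self.thetaT - self.theta0
            th = self.theta0 + amp * mj
            om = amp * dmj
            al = amp * ddmj
            # inverse dynamics on the node inertia
            ta = self.Ie_n * al + self.B * om + self.c * np.cos(th)
            u = (self.Ie_n * amp * dddmj + self.B * al
                 - self.c * om * np.sin(th))
            um = 0.5 * (u[:-1] + u[1:])
            z_states = np.concatenate([th, om, ta, u, um])
        z = np.empty(self.n_var)
        z[: self.n_states] = z_states
        if self.mode == "slack":
            th, om, ta = (z_states[self.iTH], z_states[self.iOM],
                          z_states[self.iTA])
            u = z_states[self.iU]
            a = self._accel(th, om, ta, self.Ie_n)
            thm = 0.5 * (th[:-1] + th[1:]) + h / 8 * (om[:-1] - om[1:])
            omm = 0.5 * (om[:-1] + om[1:]) + h / 8 * (a[:-1] - a[1:])
            tam = 0.5 * (ta[:-1] + ta[1:]) + h / 8 * (u[:-1] - u[1:])
            p = np.concatenate([ta * om, tam * omm])
            z[self.iSP] = np.maximum(p, 0.0)
            z[self.iSM] = np.maximum(-p, 0.0)
        lb, ub = self.bounds()
        return np.clip(z, lb, ub)

    # ------------------------------------------------------------------ solve

    def _var_scale(self) -> np.ndarray:
        """Typical magnitudes per variable group (SLSQP's quasi-Newton model
        degrades badly on the raw, poorly scaled variables)."""
        s = np.ones(self.n_var)
        s[self.iTH] = 0.5
        s[self.iOM] = 2.0
        s[self.iTA] = 3.0
        s[self.iU] = 50.0
        s[self.iUM] = 50.0
        return s

    def solve_nlp(self, z0: np.ndarray, maxiter: int = 600,
                  acc: float = 1e-9) -> NlpSolution:
        lb, ub = self.bounds()
        s = self._var_scale()

        def fg(y):
            val, grad = self.objective_with_grad(y * s)
            return val, grad * s

        res = minimize(
            fg, z0 / s, jac=True, method="SLSQP",
            bounds=np.column_stack([lb / s, ub / s]),
            constraints=[{"type": "eq",
                          "fun": lambda y: self.constraints(y * s),
                          "jac": lambda y: self.constraints_jac(y * s) * s}],
            options={"maxiter": maxiter, "ftol": acc},
        )
        z = res.x * s
        n_def = 3 * (self.N - 1)
        max_defect = float(np.max(np.abs(self.constraints(z)[:n_def])))
        return NlpSolution(z=z, success=bool(res.success),
                           status=int(res.status), message=str(res.message),
                           nit=int(res.nit), objective=float(res.fun),
                           max_defect=max_defect)
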