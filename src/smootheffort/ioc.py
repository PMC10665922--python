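"""Inverse optimal control: identifying the smoothness weight beta.

Given per-condition mean rtPV observations over the eleven-condition
gravity gradient, the forward model is run over a grid of smoothness
weights beta in [1e-5, 1] and two agreement criteria are evaluated per
weight:

* AAE — the average absolute error between predicted and observed
  condition-mean rtPV, in % of MD;
* the Pearson correlation coefficient across conditions, computed only
  when the predicted curve shows enough variability (range above a small
  threshold) and retained only when significant (p < 0.05).

The optimal weights are the AAE minimizer and the (defined, significant)
correlation maximizer over the grid.

The module follows the estimator idiom of statistical modelling packages:
:class:`RtpvInverseOC` is built from the observed curve, ``fit()`` sweeps
the grid and returns a :class:`BetaFitResult` carrying the per-beta tables
and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .ocp import OcpSpec, Trajectory, solve
from .plant import GravityCondition
from .metrics import trajectory_rtpv

__all__ = [
    "RtpvInverseOC",
    "BetaFitResult",
    "default_beta_grid",
    "predict_rtpv_curve",
    "aae",
    "pearson_guarded",
    "fit_beta",
]

#: Default log-spaced search grid over the admissible weight interval.
BETA_MIN, BETA_MAX = 1e-5, 1.0


def default_beta_grid(num: int = 25) -> np.ndarray:
    return np.geomspace(BETA_MIN, BETA_MAX, num)


# ------------------------------------------------------------- criteria

def aae(pred: np.ndarray, exp: np.ndarray) -> float:
    """Average absolute error between predicted and observed curves (% MD)."""
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if pred.shape != exp.shape:
        raise ValueError(
            f"curve length mismatch: {pred.shape} vs {exp.shape}")
    return float(np.mean(np.abs(pred - exp)))


def pearson_guarded(pred: np.ndarray, exp: np.ndarray,
                    variability_eps: float = 0.5,
                    alpha_sig: float = 0.05) -> tuple[float, float]:
    """Pearson r across conditions, guarded against flat predictions.

    Returns ``(nan, nan)`` when the predicted curve's range is below
    ``variability_eps`` (% MD) — a flat prediction carries no gradient
    information — and ``(nan, p)`` when the correlation is not significant
    at ``alpha_sig``.  Undefined is a value, not an error.
    """
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if pred.shape != exp.shape:
        raise ValueError(
            f"curve length mismatch: {pred.shape} vs {exp.shape}")
    if pred.size < 3:
        raise ValueError("need at least 3 conditions for a correlation")
    if float(np.ptp(pred)) < variability_eps:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(pred, exp)
    if p >= alpha_sig:
        return float("nan"), float(p)
    return float(r), float(p)


# ------------------------------------------------------------- forward runs

def predict_rtpv_curve(beta: float, alphas: np.ndarray,
                       spec_template: OcpSpec,
                       starts: list[Trajectory] | None = None
                       ) -> tuple[np.ndarray, list[Trajectory]]:
    """One predicted rtPV per condition at a fixed weight (same MD and
    direction throughout).  ``starts`` warm-start each condition's solve
    (typically the neighbouring weight's solutions).  Solver failures
    propagate."""
    curve = np.empty(len(alphas))
    trajs: list[Trajectory] = []
    prev_in_sweep: Trajectory | None = None
    for i, alpha in enumerate(alphas):
        cond = GravityCondition(alpha=float(alpha),
                                direction=spec_template.cond.direction)
        spec = replace(spec_template, cond=cond, beta=float(beta))
        start = starts[i] if starts is not None else prev_in_sweep
        traj = solve(spec, initial=start)
        curve[i] = trajectory_rtpv(traj)
        trajs.append(traj)
        prev_in_sweep = traj
    return curve, trajs


# ---------------------------------------------------------------- results

@dataclass
class BetaFitResult:
    """Grid tables and selected optima of one inverse-OC fit.

    ``rtpv_pred`` has one row per beta and one column per condition (% MD).
    ``pearson_r`` is NaN where undefined (flat prediction) or not
    significant.  ``beta_opt_r`` is None when no grid point yields a
    defined, significant correlation.
    """

    beta_grid: np.ndarray
    alphas: np.ndarray
    direction: str
    observed: np.ndarray
    rtpv_pred: np.ndarray
    aae: np.ndarray
    pearson_r: np.ndarray
    pearson_p: np.ndarray
    beta_opt_aae: float
    beta_opt_r: float | None
    variability_eps: float
    alpha_sig: float

    @property
    def aae_opt(self) -> float:
        return float(self.aae[np.argmin(self.aae)])

    @property
    def r_opt(self) -> float | None:
        if self.beta_opt_r is None:
            return None
        return float(self.pearson_r[np.nanargmax(self.pearson_r)])

    @property
    def predicted_opt(self) -> np.ndarray:
        """Predicted curve at the AAE-optimal weight."""
        return self.rtpv_pred[int(np.argmin(self.aae))]

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-beta table (beta, aae, pearson_r, pearson_p)."""
        return pd.DataFrame({
            "beta": self.beta_grid,
            "aae_pct_md": self.aae,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
        })

    def summary(self) -> str:
        lines = [
            "Smooth-Effort inverse optimal control fit",
            "=" * 57,
            f"direction:        {self.direction}",
            f"conditions:       {len(self.alphas)} "
            f"(label_g {1 - self.alphas[0]:+.1f} .. "
            f"{1 - self.alphas[-1]:+.1f})",
            f"beta grid:        {len(self.beta_grid)} points in "
            f"[{self.beta_grid[0]:.2e}, {self.beta_grid[-1]:.2e}]",
            "-" * 57,
            f"beta* (AAE)       {self.beta_opt_aae:.3e}   "
            f"AAE = {self.aae_opt:.3f} % of MD",
        ]
        if self.beta_opt_r is not None:
            lines.append(f"beta* (Pearson)   {self.beta_opt_r:.3e}   "
                         f"r = {self.r_opt:.4f}")
        else:
            lines.append("beta* (Pearson)   undefined (no grid point with a "
                         "defined, significant r)")
        lines.append("=" * 57)
        return "\n".join(lines)


# ------------------------------------------------------------------ model

class RtpvInverseOC:
    """Inverse-OC estimator of the smoothness weight from a mean-rtPV curve.

    Parameters
    ----------
    observed : array-like
        Condition-mean rtPV values, % of MD, one per compensation fraction.
    alphas : array-like
        Compensation fractions, same order as ``observed``.
    spec_template : OcpSpec, optional
        Forward-model settings (plant, duration, grid size); the template's
        beta and alpha are overridden during the sweep.
    variability_eps, alpha_sig : float
        Guards of the Pearson criterion: minimum predicted range (% MD) for
        r to be defined, and the significance level.
    """

    def __init__(self, observed, alphas, spec_template: OcpSpec | None = None,
                 variability_eps: float = 0.5, alpha_sig: float = 0.05):
        self.observed = np.asarray(observed, dtype=float)
        self.alphas = np.asarray(alphas, dtype=float)
        if self.observed.shape != self.alphas.shape:
            raise ValueError("observed and alphas must have equal length")
        if spec_template is None:
            spec_template = OcpSpec(cond=GravityCondition(alpha=0.0))
        self.spec_template = spec_template
        self.variability_eps = float(variability_eps)
        self.alpha_sig = float(alpha_sig)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, direction: str = "upward",
                       **kwargs) -> "RtpvInverseOC":
        """Build from a tidy table with columns label_g, direction,
        mean_rtpv."""
        sub = df[df["direction"] == direction]
        if sub.empty:
            raise ValueError(f"no rows for direction {direction!r}")
        sub = sub.sort_values("label_g", ascending=False)
        alphas = 1.0 - sub["label_g"].to_numpy(dtype=float)
        template = kwargs.pop("spec_template", None)
        if template is None:
            template = OcpSpec(cond=GravityCondition(alpha=0.0,
                                                     direction=direction))
        return cls(sub["mean_rtpv"].to_numpy(dtype=float), alphas,
                   spec_template=template, **kwargs)

    def predict(self, beta: float,
                starts: list[Trajectory] | None = None) -> np.ndarray:
        curve, _ = predict_rtpv_curve(beta, self.alphas, self.spec_template,
                                      starts)
        return curve

    def fit(self, beta_grid=None) -> BetaFitResult:
        """Sweep the weight grid and select the optima.

        The grid is traversed from the largest weight down; each weight's
        eleven condition solves are warm-started from the previous weight's
        solutions, which keeps the sweep cheap without changing the optima
        (warm and cold starts agree within solver tolerance).
        """
        grid = (default_beta_grid() if beta_grid is None
                else np.sort(np.asarray(beta_grid, dtype=float)))
        if grid[0] < BETA_MIN * 0.999 or grid[-1] > BETA_MAX * 1.001:
            raise ValueError(
                f"beta grid must lie within [{BETA_MIN}, {BETA_MAX}]")
        n_b, n_c = len(grid), len(self.alphas)
        rtpv_pred = np.empty((n_b, n_c))
        aae_vals = np.empty(n_b)
        r_vals = np.full(n_b, np.nan)
        p_vals = np.full(n_b, np.nan)
        starts: list[Trajectory] | None = None
        for i in range(n_b - 1, -1, -1):  # large beta first: easy -> hard
            curve, trajs = predict_rtpv_curve(grid[i], self.alphas,
                                              self.spec_template, starts)
            starts = trajs
            rtpv_pred[i] = curve
            aae_vals[i] = aae(curve, self.observed)
            r_vals[i], p_vals[i] = pearson_guarded(
                curve, self.observed, self.variability_eps, self.alpha_sig)

        i_aae = int(np.argmin(aae_vals))
        beta_opt_r = None
        if np.any(np.isfinite(r_vals)):
            beta_opt_r = float(grid[int(np.nanargmax(r_vals))])
        return BetaFitResult(
            beta_grid=grid, alphas=self.alphas,
            direction=self.spec_template.cond.direction,
            observed=self.observed, rtpv_pred=rtpv_pred, aae=aae_vals,
            pearson_r=r_vals, pearson_p=p_vals,
            beta_opt_aae=float(grid[i_aae]), beta_opt_r=beta_opt_r,
            variability_eps=self.variability_eps, alpha_sig=self.alpha_sig,
        )


def fit_beta(exp_curve, beta_grid, spec_template: OcpSpec,
             alphas=None, **kwargs) -> BetaFitResult:
    """Functional wrapper around :class:`RtpvInverseOC`."""
    if alphas is None:
        alphas = np.round(np.linspace(0.0, 2.0, len(np.asarray(exp_curve))),
                          10)
    model = RtpvInverseOC(exp_curve, alphas, spec_template=spec_template,
                          **kwargs)
    return model.fit(beta_grid)
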