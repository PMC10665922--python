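"""Physical model of the coupled human-exoskeleton forearm.

The plant is a single rotational degree of freedom (elbow flexion/extension)
moving in a parasagittal plane while an exoskeleton applies a gravity-like
torque at the joint.  The coupled dynamics are

    (I + sigma*Is) * theta_ddot = tau_h + tau_r - B*theta_dot - mhl*g*cos(theta)

where ``tau_h`` is the net human joint torque, ``tau_r`` the robot torque,
``B`` a viscous damping, ``mhl`` the mass times weight-moment-arm product of
the forearm and ``I`` the apparent inertia of the coupled system.  ``Is`` is
a direction- and phase-dependent inertial increment (gated by ``sigma`` in
{0, 1}) modelling the non-ideal dynamic contribution of the exoskeleton.

Because the robot compensates a fraction ``alpha`` of the human gravity
torque, the dynamics reduce to the same equation with an *effective* gravity

    g_eff = g0 * (1 - alpha),     alpha in [0, 2]

so that alpha = 0 is normal gravity (the "1g" condition, transparent mode),
alpha = 1 is microgravity (0g) and alpha = 2 is reversed gravity (-1g).

Angle convention: theta = 0 is the horizontal forearm; positive theta is
flexion (hand up).  The experimental targets sit at +/-22.5 deg around the
horizontal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import yaml

__all__ = [
    "PlantParams",
    "GravityCondition",
    "Direction",
    "Phase",
    "effective_gravity",
    "gravity_torque",
    "robot_torque",
    "forward_dynamics",
    "load_default_params",
    "ALPHA_GRID",
]

Direction = Literal["upward", "downward"]
Phase = Literal["acceleration", "deceleration"]

#: The eleven compensation fractions of the gradual-gravity experiment,
#: spanning 1g (alpha=0) to -1g (alpha=2) in 0.2g steps.
ALPHA_GRID: tuple[float, ...] = tuple(round(0.2 * k, 1) for k in range(11))

_SIGMA_KEYS = (
    ("upward", "acceleration"),
    ("upward", "deceleration"),
    ("downward", "acceleration"),
    ("downward", "deceleration"),
)


def _default_sigma_rule() -> dict[tuple[str, str], int]:
    # "Ideal exoskeleton" default: the inertial shift is never engaged.
    return {k: 0 for k in _SIGMA_KEYS}


@dataclass(frozen=True)
class PlantParams:
    """Physical constants of the coupled human-exoskeleton forearm.

    Parameters
    ----------
    inertia : float
        Apparent rotational inertia ``I`` of the coupled system, kg m^2.
    inertial_shift : float
        Inertial increment ``Is`` engaged when sigma = 1, kg m^2.  May be
        negative as long as ``I + Is > 0``.
    damping : float
        Viscous damping ``B`` of the human elbow, N m s / rad.
    weight_moment : float
        Product ``mhl`` of the forearm mass and its weight moment arm, kg m.
    g0 : float
        Gravitational acceleration, m/s^2.
    sigma_rule : dict
        Map from (direction, phase) to {0, 1} gating the inertial shift.
        Defaults to all-zero (shift never active).
    """

    inertia: float = 0.35
    inertial_shift: float = 0.0
    damping: float = 0.05
    weight_moment: float = 0.2934
    g0: float = 9.81
    sigma_rule: dict[tuple[str, str], int] = field(
        default_factory=_default_sigma_rule
    )

    def __post_init__(self) -> None:
        if self.inertia <= 0:
            raise ValueError(f"inertia must be positive, got {self.inertia}")
        if self.inertia + self.inertial_shift <= 0:
            raise ValueError(
                "inertia + inertial_shift must be positive, got "
                f"{self.inertia + self.inertial_shift}"
            )
        if self.damping < 0:
            raise ValueError(f"damping must be non-negative, got {self.damping}")
        if self.weight_moment <= 0:
            raise ValueError(
                f"weight_moment must be positive, got {self.weight_moment}"
            )
        if self.g0 <= 0:
            raise ValueError(f"g0 must be positive, got {self.g0}")
        missing = [k for k in _SIGMA_KEYS if k not in self.sigma_rule]
        if missing:
            raise ValueError(f"sigma_rule missing entries for {missing}")
        bad = {k: v for k, v in self.sigma_rule.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"sigma_rule values must be 0 or 1, got {bad}")

    def sigma(self, direction: Direction, phase: Phase) -> int:
        """Resolve the inertial-shift gate for a movement direction/phase."""
        return self.sigma_rule[(direction, phase)]

    def effective_inertia(self, direction: Direction, phase: Phase) -> float:
        """``I + sigma*Is`` for the given direction and phase."""
        return self.inertia + self.sigma(direction, phase) * self.inertial_shift


@dataclass(frozen=True)
class GravityCondition:
    """One gravity-like-torque condition of the exoskeleton.

    ``alpha`` is the compensated fraction of the gravity torque; the condition
    label in g-units is ``1 - alpha`` (alpha=0 -> 1g, alpha=1 -> 0g,
    alpha=2 -> -1g).
    """

    alpha: float
    direction: Direction = "upward"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 2.0:
            raise ValueError(
                f"alpha must lie in [0, 2] (got {self.alpha}); the admissible "
                "compensation range spans 1g (alpha=0) to -1g (alpha=2)"
            )
        if self.direction not in ("upward", "downward"):
            raise ValueError(f"direction must be 'upward' or 'downward', got "
                             f"{self.direction!r}")

    @property
    def label_g(self) -> float:
        """Condition label in g-units: 1 - alpha."""
        return 1.0 - self.alpha

    @classmethod
    def from_label_g(cls, label_g: float,
                     direction: Direction = "upward") -> "GravityCondition":
        """Build a condition from its g-unit label (1g -> 1.0, -1g -> -1.0)."""
        return cls(alpha=1.0 - label_g, direction=direction)


def effective_gravity(cond: GravityCondition, params: PlantParams) -> float:
    """Net gravity-like acceleration after robotic compensation, m/s^2.

    g_eff = g0 - alpha*g0.  Linear in alpha; exactly zero at alpha = 1.
    """
    return params.g0 * (1.0 - cond.alpha)


def gravity_torque(theta: float, g_eff: float, params: PlantParams) -> float:
    """Gravity torque term as it appears in the dynamics: -mhl*g_eff*cos(theta).

    Zero at theta = +/-pi/2 (vertical forearm) and even in theta.
    """
    return -params.weight_moment * g_eff * math.cos(theta)


def robot_torque(theta: float, cond: GravityCondition,
                 params: PlantParams) -> float:
    """Torque applied by the exoskeleton: alpha * mhl * g0 * cos(theta).

    Substituting this into the coupled dynamics collapses the true-gravity and
    robot terms into the single effective-gravity term exactly.
    """
    return cond.alpha * params.weight_moment * params.g0 * math.cos(theta)


def forward_dynamics(theta: float, theta_dot: float, tau_h: float,
                     cond: GravityCondition, params: PlantParams,
                     phase: Phase = "acceleration") -> float:
    """Angular acceleration of the forearm under the reduced dynamics.

    theta_ddot = (tau_h - B*theta_dot - mhl*g_eff*cos(theta)) / (I + sigma*Is)
    """
    inertia = params.effective_inertia(cond.direction, phase)
    if inertia <= 0:
        raise ValueError(
            f"effective inertia I + sigma*Is = {inertia} must be positive"
        )
    g_eff = effective_gravity(cond, params)
    net = (tau_h - params.damping * theta_dot
           + gravity_torque(theta, g_eff, params))
    return net / inertia


def load_default_params() -> PlantParams:
    """Load the plant parameters shipped with the package.

    The packaged ``plant_defaults.yaml`` holds the identified constants of the
    coupled human-exoskeleton system (I = 0.35 kg m^2, B = 0.05 N m s/rad,
    mhl = 0.2934 kg m) and the all-zero sigma rule.
    """
    text = resources.files("smootheffort").joinpath(
        "plant_defaults.yaml").read_text()
    return params_from_mapping(yaml.safe_load(text))


def params_from_mapping(cfg: dict) -> PlantParams:
    """Build :class:`PlantParams` from a configuration mapping.

    ``sigma_rule`` entries are keyed ``"direction,phase"`` in the file format.
    """
    sigma_cfg = cfg.get("sigma_rule")
    if sigma_cfg is None:
        rule = _default_sigma_rule()
    else:
        rule = {}
        for key, val in sigma_cfg.items():
            direction, phase = (part.strip() for part in key.split(","))
            rule[(direction, phase)] = int(val)
    return PlantParams(
        inertia=float(cfg.get("inertia", 0.35)),
        inertial_shift=float(cfg.get("inertial_shift", 0.0)),
        damping=float(cfg.get("damping", 0.05)),
        weight_moment=float(cfg.get("weight_moment", 0.2934)),
        g0=float(cfg.get("g0", 9.81)),
        sigma_rule=rule,
    )
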