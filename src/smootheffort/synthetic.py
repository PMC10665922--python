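"""Synthetic experiments emulating the exoskeleton study's recordings.

The study's raw recordings are not publicly deposited, so this module
generates complete trial-by-trial datasets with the statistical structure
the analysis pipeline assumes: per-condition movements whose means follow
the Smooth-Effort model, plus trial-to-trial kinematic variability, and
surface-EMG-like signals whose envelope carries the gravity-holding tonic
level and a movement-torque-derived phasic component.

Every generated trial is reproducible in isolation: all randomness flows
from one experiment seed through named streams (participant, condition,
block, trial), so regenerating any single trial does not require replaying
the whole experiment.

What the generator emulates — and what it does not: means follow the model
by construction, noise magnitudes are plausible defaults (the study prints
only SEM bars, not variance components), and EMG is an amplitude-modulated
broadband carrier, not a motor-unit process.  Passing pipeline tests on
this data shows the pipeline recovers what the generator encodes; it is not
evidence about the real recordings.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .plant import ALPHA_GRID, GravityCondition, PlantParams, \
    effective_gravity
from .ocp import OcpSpec, Trajectory, solve
from .kinematics import KINEMATIC_FS, TrialRecording
from .emg import EMG_FS, CHANNEL_NAMES, EmgRecording
from .io import write_trial_file, write_emg_file

__all__ = [
    "ExperimentDesign",
    "GroundTruth",
    "design_template",
    "generate_trial_kinematics",
    "generate_trial_emg",
    "generate_experiment",
    "stream",
]


# --------------------------------------------------------------- randomness

def stream(seed: int, *keys) -> np.random.Generator:
    """Named random stream: one generator per (seed, keys) identity.

    String keys are hashed with CRC32; integer keys pass through.  The same
    (seed, keys) always yields the same generator state.
    """
    spawn = tuple(
        k if isinstance(k, (int, np.integer))
        else zlib.crc32(str(k).encode()) for k in keys
    )
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=spawn)
    return np.random.default_rng(ss)


# ------------------------------------------------------------------ designs

@dataclass(frozen=True)
class ExperimentDesign:
    """Block structure of one synthetic experiment.

    Noise levels: ``md_jitter`` and ``amp_jitter`` are multiplicative
    standard deviations on movement duration and amplitude; ``motor_noise``
    scales smooth low-frequency kinematic noise relative to peak velocity;
    ``emg_noise`` is the multiplicative envelope noise of the EMG carrier.
    """

    name: str
    participants: int
    alphas: tuple[float, ...]
    blocks_per_condition: int
    trials_per_block: int
    condition_order: str  # "randomized" or "gradient"
    md_target: float = 0.6
    md_jitter: float = 0.05
    amp_jitter: float = 0.02
    motor_noise: float = 0.02
    emg_noise: float = 0.10
    participant_param_sd: float = 0.02


def design_template(name: str, participants: int | None = None,
                    **overrides) -> ExperimentDesign:
    """The study's three experiment templates.

    ``exp1``: 1g/0g/-1g, six 15-trial blocks per condition, randomized
    condition order after the initial 1g blocks.  ``exp2``: same with two
    25-trial blocks.  ``exp3``: the eleven-condition 0.2g-step gradient,
    one block of 15 flexions + 15 extensions per condition, traversed
    monotonically (half the participants start at 1g, half at -1g).
    """
    base = {
        "exp1": ExperimentDesign(
            name="exp1", participants=22, alphas=(0.0, 1.0, 2.0),
            blocks_per_condition=6, trials_per_block=15,
            condition_order="randomized"),
        "exp2": ExperimentDesign(
            name="exp2", participants=29, alphas=(0.0, 1.0, 2.0),
            blocks_per_condition=2, trials_per_block=25,
            condition_order="randomized"),
        "exp3": ExperimentDesign(
            name="exp3", participants=10, alphas=ALPHA_GRID,
            blocks_per_condition=1, trials_per_block=30,
            condition_order="gradient"),
    }
    try:
        design = base[name]
    except KeyError:
        raise ValueError(f"unknown design template {name!r}; choose from "
                         f"{sorted(base)}") from None
    if participants is not None:
        overrides["participants"] = participants
    return replace(design, **overrides) if overrides else design


@dataclass
class GroundTruth:
    """What the generator put in: stored alongside every dataset."""

    true_beta: float
    base_params: dict
    participant_params: list[dict]
    model_rtpv: dict  # {"upward": {alpha: rtpv}, "downward": {...}}
    noise: dict
    nodes: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


# --------------------------------------------------------------- kinematics

def _bandlimited_noise(rng, n, fs, cutoff=4.0):
    white = rng.standard_normal(n)
    sos = butter(2, cutoff, btype="low", fs=fs, output="sos")
    return sosfiltfilt(sos, white)


def generate_trial_kinematics(traj: Trajectory, rng: np.random.Generator,
                              fs: float = KINEMATIC_FS,
                              md_jitter: float = 0.05,
                              amp_jitter: float = 0.02,
                              motor_noise: float = 0.02,
                              pad: float = 1.2,
                              k_md: float | None = None,
                              k_amp: float | None = None,
                              meta: dict | None = None) -> TrialRecording:
    """One noisy trial sampled from a model trajectory at the camera rate.

    Applies multiplicative duration and amplitude jitter (drawn from the
    ``*_jitter`` levels unless explicit ``k_md``/``k_amp`` factors are
    given), adds smooth band-limited positional noise whose induced
    velocity has standard deviation ``motor_noise * PV``, and pads > 1 s of
    rest on both sides (needed by the EMG baseline windows downstream).
    """
    if k_md is None:
        k_md = float(np.exp(md_jitter * rng.standard_normal()))
    if k_amp is None:
        k_amp = float(np.exp(amp_jitter * rng.standard_normal()))
    T = (traj.t[-1] - traj.t[0]) * k_md

    n_pad = int(round(pad * fs))
    n_mov = int(np.ceil(T * fs))
    n_tot = 2 * n_pad + n_mov + 1
    t = np.arange(n_tot) / fs
    t_on = n_pad / fs

    th_sp, om_sp, _ = traj.splines()
    tau_local = np.clip((t - t_on) / k_md, traj.t[0], traj.t[-1])
    theta0 = traj.theta[0]
    pos = theta0 + k_amp * (th_sp(tau_local) - theta0)

    pv = float(np.max(np.abs(traj.theta_dot)))
    if motor_noise > 0:
        noise = _bandlimited_noise(rng, n_tot, fs)
        dnoise = np.gradient(noise, 1.0 / fs)
        sd = dnoise.std()
        if sd > 0:
            noise *= motor_noise * pv / sd
        pos = pos + noise
    return TrialRecording(t=t, position=pos, fs=fs, meta=meta or {})


# --------------------------------------------------------------------- EMG

def _group_drive(tau: np.ndarray, sign: int, gain: float,
                 floor: float) -> np.ndarray:
    """Envelope-level drive of one muscle group from the net torque trace.

    The flexor group (sign=+1) realizes the positive part of the net
    torque, the extensor group (sign=-1) the magnitude of the negative
    part, on top of a small co-activation floor.  With the torque trace
    extended by the static holding torque outside the movement, the tonic
    (gravity-holding) level and phasic epochs — including drops below tonic
    during inactivation — emerge from this single mapping.
    """
    return floor + gain * np.maximum(sign * tau, 0.0)


def generate_trial_emg(traj: Trajectory, kin: TrialRecording,
                       rng: np.random.Generator,
                       fs: float = EMG_FS,
                       emg_noise: float = 0.10,
                       gain: float = 0.25,
                       floor: float = 0.03,
                       meta: dict | None = None) -> EmgRecording:
    """Surface-EMG-like traces for the four muscles of one trial.

    Each channel is an amplitude-modulated broadband carrier: the
    modulation is the group drive from the model torque (static holding
    torque during rest padding), with multiplicative low-frequency noise;
    the carrier is white noise, so the laboratory band-pass/rectify/
    envelope pipeline recovers the modulation up to a constant factor.
    """
    if traj.spec is None:
        raise ValueError("trajectory carries no spec")
    dur = kin.t[-1] - kin.t[0]
    n = int(round(dur * fs)) + 1
    t = np.arange(n) / fs

    # movement bounds inside the padded trial (duration jitter from kin meta)
    t_on = kin.meta.get("t_on", 1.2)
    k_md = kin.meta.get("k_md", 1.0)
    T = (traj.t[-1] - traj.t[0]) * k_md

    _, _, ta_sp = traj.splines()
    tau_local = np.clip((t - t_on) / k_md, traj.t[0], traj.t[-1])
    tau = np.asarray(ta_sp(tau_local), dtype=float)

    channels = {}
    for name in CHANNEL_NAMES:
        sign = +1 if name in ("biceps_long", "brachioradialis") else -1
        drive = _group_drive(tau, sign, gain, floor)
        if emg_noise > 0:
            mult = 1.0 + emg_noise * _bandlimited_noise(rng, n, fs, cutoff=8.0)
            drive = np.maximum(drive * mult, 0.0)
        carrier = rng.standard_normal(n)
        channels[name] = drive * carrier
    return EmgRecording(t=t, channels=channels, fs=fs,
                        onset=float(t_on), offset=float(t_on + T),
                        meta=meta or {})


# -------------------------------------------------------------- experiment

def _participant_params(base: PlantParams, sd: float,
                        rng: np.random.Generator) -> PlantParams:
    """Perturb the identified inertia and weight moment per participant."""
    return PlantParams(
        inertia=base.inertia * float(np.exp(sd * rng.standard_normal())),
        inertial_shift=base.inertial_shift,
        damping=base.damping,
        weight_moment=base.weight_moment
        * float(np.exp(sd * rng.standard_normal())),
        g0=base.g0,
        sigma_rule=dict(base.sigma_rule),
    )


def _condition_schedule(design: ExperimentDesign, p_idx: int,
                        rng: np.random.Generator) -> list[float]:
    """Block-level condition order for one participant."""
    if design.condition_order == "gradient":
        alphas = sorted(design.alphas)
        if p_idx % 2 == 1:
            alphas = alphas[::-1]
        order = alphas
    else:
        # initial condition first (alpha=0, transparent mode), the rest
        # randomized, as in the three-condition designs
        rest = [a for a in design.alphas if a != 0.0]
        rng.shuffle(rest)
        order = [0.0] + rest if 0.0 in design.alphas else rest
    return [a for a in order for _ in range(design.blocks_per_condition)]


def generate_experiment(design: ExperimentDesign, out_dir,
                        seed: int, true_beta: float = 1.9e-3,
                        params: PlantParams | None = None,
                        nodes: int = 41, emg: bool = True) -> GroundTruth:
    """Generate a full synthetic experiment on disk.

    Writes one kinematic (and optionally EMG) trial file per trial under
    ``participant_PP/block_BB/`` plus ``manifest.json`` and
    ``ground_truth.json``.  Fully reproducible from (design, seed).
    Returns the :class:`GroundTruth` record.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = params or PlantParams()

    # nominal per-condition model rtPV (the generating curve)
    from .metrics import trajectory_rtpv  # deferred: avoids import cycle
    model_rtpv: dict[str, dict[str, float]] = {}
    nominal_cache: dict[tuple[float, str], Trajectory] = {}
    for direction in ("upward", "downward"):
        model_rtpv[direction] = {}
        prev = None
        for alpha in sorted(design.alphas):
            spec = OcpSpec(cond=GravityCondition(alpha=alpha,
                                                 direction=direction),
                           params=base, beta=true_beta, nodes=nodes,
                           duration=design.md_target)
            traj = solve(spec, initial=prev)
            prev = traj
            nominal_cache[(alpha, direction)] = traj
            model_rtpv[direction][f"{alpha:.1f}"] = trajectory_rtpv(traj)

    participant_params: list[PlantParams] = []
    manifest: list[dict] = []
    for p in range(design.participants):
        p_rng = stream(seed, "participant", p)
        pp = _participant_params(base, design.participant_param_sd, p_rng)
        participant_params.append(pp)
        schedule = _condition_schedule(design, p, p_rng)

        cache: dict[tuple[float, str], Trajectory] = {}
        for b, alpha in enumerate(schedule):
            block_dir = out / f"participant_{p:02d}" / f"block_{b:02d}"
            for tr_i in range(design.trials_per_block):
                direction = "upward" if tr_i % 2 == 0 else "downward"
                key = (alpha, direction)
                if key not in cache:
                    spec = OcpSpec(
                        cond=GravityCondition(alpha=alpha,
                                              direction=direction),
                        params=pp, beta=true_beta, nodes=nodes,
                        duration=design.md_target)
                    cache[key] = solve(
                        spec, initial=nominal_cache.get(key))
                traj = cache[key]

                rng_kin = stream(seed, "kin", p, b, tr_i)
                k_md = float(np.exp(design.md_jitter
                                    * rng_kin.standard_normal()))
                k_amp = float(np.exp(design.amp_jitter
                                     * rng_kin.standard_normal()))
                # k_md is recorded in the metadata for the EMG alignment
                meta = {
                    "participant": p, "block": b, "trial": tr_i,
                    "alpha": alpha, "label_g": round(1.0 - alpha, 10),
                    "direction": direction, "t_on": 1.2, "k_md": k_md,
                }
                kin = generate_trial_kinematics(
                    traj, rng_kin, motor_noise=design.motor_noise,
                    k_md=k_md, k_amp=k_amp, meta=meta)
                kin_path = block_dir / f"trial_{tr_i:03d}_kin.csv"
                write_trial_file(kin_path, kin)
                entry = {"participant": p, "block": b, "trial": tr_i,
                         "alpha": alpha, "direction": direction,
                         "kin": str(kin_path.relative_to(out))}
                if emg:
                    rng_emg = stream(seed, "emg", p, b, tr_i)
                    rec = generate_trial_emg(traj, kin, rng_emg,
                                             emg_noise=design.emg_noise,
                                             meta=meta)
                    emg_path = block_dir / f"trial_{tr_i:03d}_emg.csv"
                    write_emg_file(emg_path, rec)
                    entry["emg"] = str(emg_path.relative_to(out))
                manifest.append(entry)

    truth = GroundTruth(
        true_beta=true_beta,
        base_params=_params_dict(base),
        participant_params=[_params_dict(p) for p in participant_params],
        model_rtpv=model_rtpv,
        noise={"md_jitter": design.md_jitter, "amp_jitter": design.amp_jitter,
               "motor_noise": design.motor_noise,
               "emg_noise": design.emg_noise,
               "participant_param_sd": design.participant_param_sd},
        nodes=nodes,
    )
    (out / "ground_truth.json").write_text(truth.to_json())
    (out / "manifest.json").write_text(json.dumps(
        {"design": asdict(design), "seed": seed, "trials": manifest},
        indent=1))
    return truth


def _params_dict(p: PlantParams) -> dict:
    return {
        "inertia": p.inertia, "inertial_shift": p.inertial_shift,
        "damping": p.damping, "weight_moment": p.weight_moment, "g0": p.g0,
    }
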