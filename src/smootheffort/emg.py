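"""EMG processing: band-pass, rectification, normalization, envelope and
tonic-phasic decomposition.

The four recorded muscles are grouped into flexors (biceps long head,
brachioradialis) and extensors (triceps long and lateral heads).  The tonic
component — the activity level holding the limb against the effective
gravity — is the straight line between the average envelope in a baseline
window 1 s to 0.5 s before movement onset and one 0.5 s to 1 s after the
offset.  The phasic component is the envelope minus that line: positive
epochs are activation (net accelerating drive), negative epochs are
inactivation (drive below the gravity-holding level, letting gravity act).

Operation order follows the laboratory pipeline: normalization is applied
to the rectified signal *before* enveloping (normalizing the envelope
instead changes the areas).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "EmgRecording",
    "PhasicEmg",
    "FLEXOR_CHANNELS",
    "EXTENSOR_CHANNELS",
    "preprocess",
    "normalize",
    "envelope",
    "tonic_phasic",
    "activation_inactivation_areas",
    "group_envelope",
]

EMG_FS = 2000.0  # Hz, design value of the surface-EMG system

CHANNEL_NAMES = ("biceps_long", "brachioradialis",
                 "triceps_long", "triceps_lateral")
FLEXOR_CHANNELS = ("biceps_long", "brachioradialis")
EXTENSOR_CHANNELS = ("triceps_long", "triceps_lateral")


@dataclass
class EmgRecording:
    """Multi-channel surface EMG aligned to a parent kinematic trial.

    ``channels`` maps muscle name to its raw trace; ``onset``/``offset`` are
    the movement bounds (s) taken from the kinematic segmentation.
    """

    t: np.ndarray
    channels: dict[str, np.ndarray]
    fs: float = EMG_FS
    onset: float | None = None
    offset: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float)
                         for k, v in self.channels.items()}
        for name, tr in self.channels.items():
            if tr.shape != self.t.shape:
                raise ValueError(f"channel {name!r} length mismatch")


@dataclass
class PhasicEmg:
    """Envelope with its tonic/phasic decomposition over one trial."""

    t: np.ndarray
    envelope: np.ndarray
    tonic: np.ndarray
    phasic: np.ndarray
    activation_area: float | None = None
    inactivation_area: float | None = None


def preprocess(raw: np.ndarray, fs: float = EMG_FS,
               band: tuple[float, float] = (20.0, 450.0),
               order: int = 4) -> np.ndarray:
    """Band-pass (zero-phase Butterworth), mean-centre and rectify."""
    low, high = band
    if fs <= 2 * high:
        raise ValueError(
            f"sampling rate {fs} Hz too low for a {high} Hz band edge")
    sos = butter(order, band, btype="bandpass", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, np.asarray(raw, dtype=float))
    return np.abs(filtered - filtered.mean())


def normalize(rectified: np.ndarray, participant_max: float) -> np.ndarray:
    """Scale by the participant-and-muscle maximum over all their trials."""
    if participant_max <= 0:
        raise ValueError(
            f"participant maximum must be positive, got {participant_max}")
    return np.asarray(rectified, dtype=float) / participant_max


def envelope(normalized: np.ndarray, fs: float = EMG_FS,
             cutoff: float = 3.0, order: int = 5) -> np.ndarray:
    """Low-pass envelope (zero-phase Butterworth, 3 Hz design cutoff).

    Slight negative undershoots (filter ringing) are possible and left in
    place; they are far smaller than the inactivation troughs of interest.
    """
    x = np.asarray(normalized, dtype=float)
    sos = butter(order, cutoff, btype="low", fs=fs, output="sos")
    padlen = min(x.size - 1, int(3 * fs / cutoff))
    return sosfiltfilt(sos, x, padlen=padlen)


def tonic_phasic(env: np.ndarray, onset: float, offset: float,
                 fs: float = EMG_FS, t0: float = 0.0) -> PhasicEmg:
    """Tonic/phasic decomposition of an envelope around one movement.

    The pre-movement baseline is the envelope average over
    [onset-1 s, onset-0.5 s], the post-movement baseline the average over
    [offset+0.5 s, offset+1 s]; the tonic trace is the straight line
    anchored at (onset, pre) and (offset, post), extended flat outside the
    movement.  ``phasic = envelope - tonic`` everywhere (exact
    reconstruction); negative phasic is meaningful (inactivation).
    """
    env = np.asarray(env, dtype=float)
    t = t0 + np.arange(env.size) / fs
    if onset - 1.0 < t[0] - 1e-9 or offset + 1.0 > t[-1] + 1e-9:
        raise ValueError(
            "recording must span [onset-1s, offset+1s] for the baseline "
            f"windows; have [{t[0]:.3f}, {t[-1]:.3f}] s, need "
            f"[{onset - 1.0:.3f}, {offset + 1.0:.3f}] s")
    pre = env[(t >= onset - 1.0) & (t <= onset - 0.5)].mean()
    post = env[(t >= offset + 0.5) & (t <= offset + 1.0)].mean()
    frac = np.clip((t - onset) / (offset - onset), 0.0, 1.0)
    tonic = pre + (post - pre) * frac
    return PhasicEmg(t=t, envelope=env, tonic=tonic, phasic=env - tonic)


def activation_inactivation_areas(
        phasic: np.ndarray, t: np.ndarray,
        onset: float, offset: float,
        threshold: float = 0.05) -> tuple[float, float]:
    """Activation and inactivation areas of a phasic trace over the movement.

    Activation integrates phasic samples exceeding 5% of the phasic maximum;
    inactivation integrates |phasic| over samples below -5% of the
    (absolute) phasic minimum.  Both span the whole movement interval with
    no assumption on where bursts start or end.  An identically zero phasic
    trace yields (0, 0).
    """
    phasic = np.asarray(phasic, dtype=float)
    t = np.asarray(t, dtype=float)
    inside = (t >= onset) & (t <= offset)
    p = phasic[inside]
    ti = t[inside]
    if p.size == 0:
        return 0.0, 0.0
    pmax = p.max()
    pmin = p.min()
    act = 0.0
    if pmax > 0:
        sel = p > threshold * pmax
        act = float(np.trapezoid(np.where(sel, p, 0.0), ti))
    inact = 0.0
    if pmin < 0:
        sel = p < -threshold * abs(pmin)
        inact = float(np.trapezoid(np.where(sel, -p, 0.0), ti))
    return act, inact


def group_envelope(rec: EmgRecording, group: tuple[str, ...],
                   participant_max: dict[str, float]) -> np.ndarray:
    """Mean normalized envelope of a muscle group (flexors or extensors)."""
    envs = []
    for name in group:
        rect = preprocess(rec.channels[name], rec.fs)
        envs.append(envelope(normalize(rect, participant_max[name]), rec.fs))
    return np.mean(envs, axis=0)
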