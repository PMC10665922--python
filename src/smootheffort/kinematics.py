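"""Experimental-style kinematic trial processing.

Mirrors the laboratory pipeline applied to the optoelectronic recordings:
position traces sampled at 179 Hz are low-pass filtered (zero-phase
Butterworth, 5 Hz cutoff, 5th design order), differentiated, segmented at
5% of peak velocity and summarized as per-trial movement metrics with the
double-acceleration-reversal exclusion rule.

Note on the filter order: "fifth order" is the design order of the one-pass
filter; the forward-backward (zero-phase) application doubles the effective
order and moves the -3 dB point slightly below the design cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .metrics import MovementMetrics, SegmentationError, compute_metrics

__all__ = [
    "TrialRecording",
    "filter_position",
    "differentiate",
    "process_trial",
]

KINEMATIC_FS = 179.0  # Hz, design value of the motion-capture system


@dataclass
class TrialRecording:
    """One recorded movement trial: a uniformly sampled position trace.

    ``position`` is the elbow angle in rad (or an endpoint-equivalent scalar
    coordinate in m; the pipeline is agnostic).  The recording must extend
    at least ~1 s beyond the movement on both sides so that downstream EMG
    baselines can be anchored.
    """

    t: np.ndarray
    position: np.ndarray
    fs: float = KINEMATIC_FS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.t.shape != self.position.shape:
            raise ValueError("t and position must have equal length")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            # tolerate the rounding of text storage (microsecond scale)
            if not np.allclose(dt, dt[0], rtol=0, atol=max(2e-6, 1e-3 * dt[0])):
                raise ValueError("sampling must be uniform")


def filter_position(trial: TrialRecording, cutoff: float = 5.0,
                    order: int = 5) -> np.ndarray:
    """Zero-phase low-pass Butterworth filtering of the position trace.

    The filter runs as second-order sections (well conditioned at low
    cutoff/fs ratios) with odd-reflect padding of about three filter time
    constants, which keeps warm-up transients — they would bias rtPV near
    the onset — out of the trace.  DC is preserved.
    """
    if trial.fs <= 2 * cutoff:
        raise ValueError(
            f"sampling rate {trial.fs} Hz too low for a {cutoff} Hz cutoff")
    padlen = int(3 * trial.fs / cutoff)
    if trial.position.size <= padlen:
        raise ValueError(
            f"trace of {trial.position.size} samples is shorter than the "
            f"filter warm-up ({padlen} samples)")
    sos = butter(order, cutoff, btype="low", fs=trial.fs, output="sos")
    return sosfiltfilt(sos, trial.position, padlen=padlen)


def differentiate(filtered: np.ndarray,
                  fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Velocity and acceleration by central differences (one-sided at the
    edges); output lengths equal the input length."""
    dt = 1.0 / fs
    velocity = np.gradient(filtered, dt)
    acceleration = np.gradient(velocity, dt)
    return velocity, acceleration


def process_trial(trial: TrialRecording, cutoff: float = 5.0,
                  order: int = 5) -> MovementMetrics:
    """Filter, differentiate and summarize one trial.

    Trials whose velocity cannot be segmented are returned flagged invalid
    (with the reason), never dropped silently.
    """
    pos = filter_position(trial, cutoff=cutoff, order=order)
    vel, acc = differentiate(pos, trial.fs)
    try:
        return compute_metrics(vel, acc, trial.fs)
    except SegmentationError as exc:
        return MovementMetrics(onset=np.nan, offset=np.nan, md=np.nan,
                               pv=np.nan, pa=np.nan, rtpv=np.nan,
                               valid=False, invalid_reason=str(exc))
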