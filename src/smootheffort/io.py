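"""Plain-text trial-file schema and round-trip readers/writers.

Trial files are delimited text with a commented header block declaring the
schema version, kind, sampling rate, units and a JSON metadata record.
Chosen over binary formats for inspectability; no motion-capture container
dependency.

Example::

    # smootheffort-trial v1
    # kind: kinematics
    # fs: 179.0
    # units: t=s position=rad
    # meta: {"participant": 1, "alpha": 0.0, ...}
    t,position
    0.000000,-0.392699
    ...
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .kinematics import TrialRecording
from .emg import EmgRecording

__all__ = [
    "SchemaError",
    "write_trial_file",
    "read_trial_file",
    "write_emg_file",
    "read_emg_file",
]

_MAGIC = "# smootheffort-trial v1"


class SchemaError(ValueError):
    """A trial file violates the declared schema."""


def _write(path, kind, fs, units, meta, frame: pd.DataFrame,
           float_format="%.6f"):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"{_MAGIC}\n# kind: {kind}\n# fs: {fs!r}\n")
        fh.write(f"# units: {units}\n")
        fh.write(f"# meta: {json.dumps(meta, sort_keys=True)}\n")
        frame.to_csv(fh, index=False, float_format=float_format)


def _read(path):
    path = Path(path)
    header: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _MAGIC:
            raise SchemaError(f"{path}: missing schema magic line "
                              f"({_MAGIC!r}); got {first!r}")
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("# "):
                fh.seek(pos)
                break
            pos = fh.tell()
            key, _, val = line[2:].partition(":")
            header[key.strip()] = val.strip()
        frame = pd.read_csv(fh)
    for req in ("kind", "fs", "meta"):
        if req not in header:
            raise SchemaError(f"{path}: header field {req!r} missing")
    try:
        fs = float(header["fs"])
    except ValueError as exc:
        raise SchemaError(f"{path}: fs is not numeric: {header['fs']!r}") \
            from exc
    meta = json.loads(header["meta"])
    return header["kind"], fs, meta, frame


def write_trial_file(path, trial: TrialRecording) -> None:
    frame = pd.DataFrame({"t": trial.t, "position": trial.position})
    _write(path, "kinematics", trial.fs, "t=s position=rad", trial.meta,
           frame)


def read_trial_file(path) -> TrialRecording:
    kind, fs, meta, frame = _read(path)
    if kind != "kinematics":
        raise SchemaError(f"{path}: expected kind 'kinematics', got {kind!r}")
    missing = {"t", "position"} - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return TrialRecording(t=frame["t"].to_numpy(),
                          position=frame["position"].to_numpy(),
                          fs=fs, meta=meta)


def write_emg_file(path, rec: EmgRecording) -> None:
    frame = pd.DataFrame({"t": rec.t})
    for name in rec.channels:
        frame[name] = rec.channels[name]
    meta = dict(rec.meta)
    meta["onset"] = rec.onset
    meta["offset"] = rec.offset
    _write(path, "emg", rec.fs, "t=s channels=normalized", meta, frame,
           float_format="%.5f")


def read_emg_file(path) -> EmgRecording:
    kind, fs, meta, frame = _read(path)
    if kind != "emg":
        raise SchemaError(f"{path}: expected kind 'emg', got {kind!r}")
    if "t" not in frame.columns:
        raise SchemaError(f"{path}: missing column 't'")
    chan_cols = [c for c in frame.columns if c != "t"]
    if not chan_cols:
        raise SchemaError(f"{path}: no channel columns")
    onset = meta.pop("onset", None)
    offset = meta.pop("offset", None)
    return EmgRecording(
        t=frame["t"].to_numpy(),
        channels={c: frame[c].to_numpy() for c in chan_cols},
        fs=fs, onset=onset, offset=offset, meta=meta)
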