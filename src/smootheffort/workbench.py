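"""End-to-end analysis driver: synthesize -> process -> fit -> report.

Ties the pipeline stages together under a single serializable
:class:`RunConfig`.  Every artifact written by :func:`run_full_analysis`
carries the configuration hash, and a config snapshot is stored next to the
outputs, so a report is reproducible from its directory alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .plant import PlantParams, params_from_mapping
from .ocp import OcpSpec
from .plant import GravityCondition
from .kinematics import process_trial
from .emg import (EXTENSOR_CHANNELS, FLEXOR_CHANNELS, group_envelope,
                  preprocess, tonic_phasic, activation_inactivation_areas)
from .io import read_trial_file, read_emg_file
from .ioc import RtpvInverseOC
from .synthetic import design_template, generate_experiment

__all__ = [
    "RunConfig",
    "run_full_analysis",
    "process_kinematics_dir",
    "process_emg_dir",
    "condition_means",
]

log = logging.getLogger("smootheffort")


@dataclass
class RunConfig:
    """Serializable settings of one full analysis run."""

    seed: int = 1
    out_root: str = "smootheffort_run"
    design: str = "exp3"
    participants: int | None = None
    blocks_per_condition: int | None = None
    trials_per_block: int | None = None
    true_beta: float = 1.9e-3
    plant: dict = field(default_factory=dict)
    nodes: int = 41
    duration: float = 0.6
    beta_grid_num: int = 13
    beta_grid_min: float = 1e-5
    beta_grid_max: float = 1.0
    emg: bool = False

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**(yaml.safe_load(text) or {}))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def plant_params(self) -> PlantParams:
        return params_from_mapping(self.plant) if self.plant else PlantParams()


# ------------------------------------------------------------- processing

def process_kinematics_dir(data_dir) -> pd.DataFrame:
    """Process every kinematic trial listed in a dataset manifest.

    Returns one row per trial: metadata plus MD (s), PV (rad/s),
    PA (rad/s^2), rtPV (% of MD) and the validity flag.  Invalid trials are
    flagged, never dropped.
    """
    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    rows = []
    for entry in manifest["trials"]:
        trial = read_trial_file(data_dir / entry["kin"])
        m = process_trial(trial)
        rows.append({
            "participant": entry["participant"], "block": entry["block"],
            "trial": entry["trial"], "alpha": entry["alpha"],
            "label_g": round(1.0 - entry["alpha"], 10),
            "direction": entry["direction"],
            "md_s": m.md, "pv_rad_s": m.pv, "pa_rad_s2": m.pa,
            "rtpv_pct_md": m.rtpv, "valid": m.valid,
            "invalid_reason": m.invalid_reason,
        })
    return pd.DataFrame(rows)


def _participant_maxima(data_dir, manifest) -> dict[int, dict[str, float]]:
    """Per-participant, per-muscle maximum of the rectified signal over all
    their trials (the normalization reference)."""
    maxima: dict[int, dict[str, float]] = {}
    for entry in manifest["trials"]:
        if "emg" not in entry:
            continue
        rec = read_emg_file(Path(data_dir) / entry["emg"])
        per = maxima.setdefault(entry["participant"], {})
        for name, raw in rec.channels.items():
            rect = preprocess(raw, rec.fs)
            per[name] = max(per.get(name, 0.0), float(rect.max()))
    return maxima


def process_emg_dir(data_dir) -> pd.DataFrame:
    """Flexor/extensor activation and inactivation areas per trial.

    Two passes: the first finds each participant-muscle normalization
    maximum across all trials, the second computes group envelopes, the
    tonic/phasic decomposition around each movement, and the areas.
    """
    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    maxima = _participant_maxima(data_dir, manifest)
    rows = []
    for entry in manifest["trials"]:
        if "emg" not in entry:
            continue
        rec = read_emg_file(data_dir / entry["emg"])
        per_max = maxima[entry["participant"]]
        for label, group in (("flexors", FLEXOR_CHANNELS),
                             ("extensors", EXTENSOR_CHANNELS)):
            env = group_envelope(rec, group, per_max)
            ph = tonic_phasic(env, rec.onset, rec.offset, rec.fs,
                              t0=rec.t[0])
            act, inact = activation_inactivation_areas(
                ph.phasic, ph.t, rec.onset, rec.offset)
            rows.append({
                "participant": entry["participant"],
                "block": entry["block"], "trial": entry["trial"],
                "alpha": entry["alpha"],
                "label_g": round(1.0 - entry["alpha"], 10),
                "direction": entry["direction"], "muscle_group": label,
                "activation_area": act, "inactivation_area": inact,
            })
    return pd.DataFrame(rows)


def condition_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Valid-trial mean rtPV per (direction, label_g), in % of MD."""
    ok = trials[trials["valid"]]
    g = (ok.groupby(["direction", "label_g"])["rtpv_pct_md"]
         .agg(["mean", "std", "count"]).reset_index())
    return g.rename(columns={"mean": "mean_rtpv", "std": "sd_rtpv",
                             "count": "n_trials"})


# ------------------------------------------------------------------ driver

def run_full_analysis(config: RunConfig) -> Path:
    """Synthesize a dataset, run the full pipeline and write the report.

    Stages: synthetic experiment -> kinematic processing -> condition
    means -> inverse-OC weight fit per direction -> tables and figures.
    Any stage failure raises with a stage-named diagnostic.  Returns the
    report directory.
    """
    out = Path(config.out_root)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    chash = config.config_hash
    t_start = time.time()

    def stage(name):
        log.info("[%s] stage %-12s t=%.1fs", chash, name,
                 time.time() - t_start)

    try:
        stage("synthesize")
        overrides = {k: v for k, v in (
            ("participants", config.participants),
            ("blocks_per_condition", config.blocks_per_condition),
            ("trials_per_block", config.trials_per_block)) if v is not None}
        design = design_template(config.design, **overrides)
        data_dir = out / "data"
        generate_experiment(design, data_dir, seed=config.seed,
                            true_beta=config.true_beta,
                            params=config.plant_params(),
                            nodes=config.nodes, emg=config.emg)
    except Exception as exc:
        raise RuntimeError(f"stage 'synthesize' failed: {exc}") from exc

    try:
        stage("process-kin")
        trials = process_kinematics_dir(data_dir)
        _write_table(trials, out / "trials.csv", chash,
                     "one row per trial; md_s s, pv_rad_s rad/s, "
                     "pa_rad_s2 rad/s^2, rtpv_pct_md % of MD")
        means = condition_means(trials)
        _write_table(means, out / "condition_means.csv", chash,
                     "mean rtPV per condition, % of MD")
    except Exception as exc:
        raise RuntimeError(f"stage 'process-kin' failed: {exc}") from exc

    if config.emg:
        try:
            stage("process-emg")
            areas = process_emg_dir(data_dir)
            _write_table(areas, out / "emg_areas.csv", chash,
                         "activation/inactivation areas, normalized "
                         "units x s")
        except Exception as exc:
            raise RuntimeError(f"stage 'process-emg' failed: {exc}") from exc

    grid = np.geomspace(config.beta_grid_min, config.beta_grid_max,
                        config.beta_grid_num)
    fits = {}
    for direction in ("upward", "downward"):
        try:
            stage(f"fit-{direction}")
            model = RtpvInverseOC.from_dataframe(
                means, direction=direction,
                spec_template=OcpSpec(
                    cond=GravityCondition(alpha=0.0, direction=direction),
                    params=config.plant_params(), nodes=config.nodes,
                    duration=config.duration))
            res = model.fit(grid)
            fits[direction] = res
            _write_table(res.to_frame(), out / f"beta_fit_{direction}.csv",
                         chash, "per-beta AAE (% of MD) and Pearson r")
            (out / f"beta_fit_{direction}.txt").write_text(
                res.summary() + f"\n# config {chash}\n")
        except Exception as exc:
            raise RuntimeError(
                f"stage 'fit-{direction}' failed: {exc}") from exc

    try:
        stage("figures")
        _figures(out, means, fits, chash)
    except Exception as exc:
        raise RuntimeError(f"stage 'figures' failed: {exc}") from exc
    stage("done")
    return out


def _write_table(df: pd.DataFrame, path: Path, chash: str,
                 units: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config: {chash}\n# units: {units}\n")
        df.to_csv(fh, index=False)


def _figures(out: Path, means: pd.DataFrame, fits: dict, chash: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, direction in zip(axes, ("upward", "downward")):
        sub = means[means["direction"] == direction]
        ax.errorbar(sub["label_g"], sub["mean_rtpv"], yerr=sub["sd_rtpv"],
                    fmt="o-", label="synthetic data")
        if direction in fits:
            res = fits[direction]
            ax.plot(1.0 - res.alphas, res.predicted_opt, "s--",
                    label=f"model (beta*={res.beta_opt_aae:.1e})")
        ax.axhline(50, color="0.7", lw=0.8)
        ax.set_xlabel("gravity condition (g units)")
        ax.set_title(direction)
        ax.invert_xaxis()
    axes[0].set_ylabel("rtPV (% of MD)")
    axes[0].legend(fontsize=8)
    fig.suptitle(f"rtPV across gravity conditions [config {chash}]",
                 fontsize=9)
    fig.tight_layout()
    fig.savefig(out / "rtpv_vs_condition.png", dpi=120)
    plt.close(fig)

    if fits:
        fig, axes = plt.subplots(1, len(fits), figsize=(9, 3.5))
        axes = np.atleast_1d(axes)
        for ax, (direction, res) in zip(axes, fits.items()):
            ax.semilogx(res.beta_grid, res.aae, "o-", label="AAE (% MD)")
            ax2 = ax.twinx()
            ax2.semilogx(res.beta_grid, res.pearson_r, "s--", color="C1",
                         label="Pearson r")
            ax.axvline(res.beta_opt_aae, color="C0", lw=0.8, ls=":")
            ax.set_xlabel("beta")
            ax.set_title(direction)
        fig.suptitle(f"fit criteria vs smoothness weight [config {chash}]",
                     fontsize=9)
        fig.tight_layout()
        fig.savefig(out / "aae_r_vs_beta.png", dpi=120)
        plt.close(fig)
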