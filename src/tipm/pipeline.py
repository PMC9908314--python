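"""End-to-end orchestration: simulate -> extract -> tune -> longitudinal -> qc.

Stages communicate only through documented plain-file formats (tidy CSV trace
tables, peak CSVs, JSON summaries), so each stage is independently testable
from fixtures.  A run manifest records the configuration hash, the seed,
every file written with its row count, and every excluded cell with a reason.
Outputs are deterministic given the seed: rerunning with the same
configuration produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import longitudinal as lng
from . import qc as qcmod
from . import traces as trc
from . import tuning as tun
from .simulate import (
    SimulationConfig,
    config_from_yaml,
    generate_frame_pair,
    simulate_experiment,
    write_frame_pair,
)

__all__ = ["run_all", "load_run_config"]


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def load_run_config(path_or_dict: str | Path | dict) -> dict:
    if isinstance(path_or_dict, dict):
        return dict(path_or_dict)
    return yaml.safe_load(Path(path_or_dict).read_text())


def _age2_population(neurons, change_cfg: dict, rng: np.random.Generator):
    """Apply configured developmental gain changes to build the age-2 cohort."""
    frac = float(change_cfg.get("ipsi_increase_fraction", 0.0))
    delta = float(change_cfg.get("ipsi_increase", 0.0))
    contra_sd = float(change_cfg.get("contra_change_sd", 0.0))
    out = []
    for n in neurons:
        gi = n.tonic_gain_ipsi + (delta if rng.random() < frac else 0.0)
        gc = max(n.tonic_gain_contra + (rng.normal(0.0, contra_sd) if contra_sd else 0.0), 0.0)
        out.append(dataclasses.replace(n, tonic_gain_ipsi=gi, tonic_gain_contra=gc))
    return out


def run_all(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run the full pipeline from a YAML config; return the run manifest.

    The config is the simulation schema of `tipm.simulate.config_from_yaml`
    plus optional keys ``ages`` (list of one or two ages, default [4, 7]),
    ``gain_change`` (developmental changes applied to the second age:
    ``ipsi_increase_fraction``, ``ipsi_increase``, ``contra_change_sd``),
    ``n_shuffles`` (default 1000) and ``qc``
    (``frame_shift_px: [dx, dy]``, ``pixel_size_um``, ``frame_noise_sd``).
    """
    cfg = load_run_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    ages = list(cfg.get("ages", [4, 7]))
    gain_change = dict(cfg.get("gain_change", {}))
    n_shuffles = int(cfg.get("n_shuffles", 1000))
    qc_cfg = dict(cfg.get("qc", {}))

    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "stages": [],
        "exclusions": [],
    }

    def record(stage: str, files: dict[str, int]) -> None:
        manifest["stages"].append({"stage": stage, "outputs": files})

    def write_csv(df: pd.DataFrame, name: str) -> int:
        df.to_csv(out / name, index=False)
        return len(df)

    # ---- stage 1: simulate -------------------------------------------------
    sim_keys = {
        "seed", "n_cells", "sample_rate_hz", "trials_per_magnitude",
        "repeats_per_trial", "anesthetized", "mount_roll_jitter_deg",
        "fish_id", "session_id", "age_dpf", "stimuli", "population",
    }
    sim_cfg_dict = {k: v for k, v in cfg.items() if k in sim_keys}
    base = config_from_yaml(sim_cfg_dict)
    rng_dev = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    files: dict[str, int] = {}
    gt_all: dict = {}
    session_traces: dict[int, pd.DataFrame] = {}
    for i, age in enumerate(ages):
        neurons = base.neurons if i == 0 else _age2_population(
            base.neurons, gain_change, rng_dev
        )
        sim = dataclasses.replace(
            base, neurons=neurons, age_dpf=int(age),
            session_id=f"s{age}dpf", seed=seed + i,
        )
        traces, gt = simulate_experiment(sim)
        session_traces[age] = traces
        gt_all[str(age)] = gt
        files[f"traces_age{age}.csv"] = write_csv(traces, f"traces_age{age}.csv")
    (out / "ground_truth.json").write_text(json.dumps(gt_all, indent=2, sort_keys=True))
    files["ground_truth.json"] = len(gt_all)
    dx, dy = qc_cfg.get("frame_shift_px", [3, -2])
    pre, post, info = generate_frame_pair(
        (int(dx), int(dy)), seed=seed,
        noise_sd=float(qc_cfg.get("frame_noise_sd", 0.05)),
    )
    write_frame_pair(out / "frame_pair.tif", pre, post, info)
    files["frame_pair.tif"] = 2
    record("simulate", files)

    # ---- stage 2: extract --------------------------------------------------
    files = {}
    peaks_by_age: dict[int, pd.DataFrame] = {}
    for age, traces in session_traces.items():
        ntr = trc.normalize(traces, "trial_baseline")
        peaks = trc.extract_peaks(ntr, "post_return_first_1s")
        peaks_by_age[age] = peaks
        files[f"peaks_age{age}.csv"] = write_csv(peaks, f"peaks_age{age}.csv")
    record("extract", files)

    # ---- stage 3: tune -----------------------------------------------------
    first_age = ages[0]
    tuning = tun.tune_cells(peaks_by_age[first_age])
    record("tune", {"tuning.csv": write_csv(tuning, "tuning.csv")})

    # ---- stage 4: longitudinal --------------------------------------------
    if len(ages) >= 2:
        changes = lng.classify_cells(
            peaks_by_age[ages[0]], peaks_by_age[ages[1]],
            n_shuffles=n_shuffles, seed=seed,
        )
        excluded = changes[changes["category"] == "excluded"]
        for _, row in excluded.iterrows():
            manifest["exclusions"].append(
                {"stage": "longitudinal", "cell_id": row["cell_id"],
                 "direction": row["direction"], "reason": row["reason"]}
            )
        split = lng.early_tuned_split(changes)
        ok = changes[changes["category"] != "excluded"]
        wide = ok.pivot_table(index="cell_id", columns="direction",
                              values="delta_slope", aggfunc="first")
        if {"ipsi", "contra"}.issubset(wide.columns):
            rho, p, n = lng.change_correlation(
                wide["ipsi"].to_numpy(), wide["contra"].to_numpy()
            )
        else:
            rho, p, n = float("nan"), float("nan"), 0
        summary = {
            "group_counts": {
                d: ok[ok["direction"] == d]["category"].value_counts().to_dict()
                for d in ok["direction"].unique()
            },
            "early_tuned_split": split.to_dict(orient="records"),
            "change_correlation": {"rho": rho, "p": p, "n": n},
            "n_excluded": int(len(excluded)),
        }
        (out / "longitudinal_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        record("longitudinal", {
            "changes.csv": write_csv(changes, "changes.csv"),
            "longitudinal_summary.json": 1,
        })

    # ---- stage 5: qc -------------------------------------------------------
    shift = qcmod.frame_shift(
        pre, post, pixel_size_um=float(qc_cfg.get("pixel_size_um", 1.0))
    )
    positions = pd.DataFrame(
        [
            {"cell_id": n.cell_id, "hemisphere": n.hemisphere,
             "x_um": n.position_um[0], "y_um": n.position_um[1],
             "z_um": n.position_um[2]}
            for n in base.neurons
        ]
    )
    responsive = tuning.set_index("cell_id")["responsive_ipsi"]
    labels = positions["cell_id"].map(responsive).fillna(False).to_numpy(bool)
    pos_cmp = qcmod.position_group_compare(positions, labels)
    qc_report = {
        "frame_shift": shift.to_dict(),
        "true_frame_shift_px": [int(dx), int(dy)],
        "position_comparison": pos_cmp.to_dict(orient="records"),
    }
    (out / "qc.json").write_text(json.dumps(qc_report, indent=2, sort_keys=True))
    record("qc", {"qc.json": 1})

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
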