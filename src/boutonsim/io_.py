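"""Configuration and result I/O.

Configurations are YAML with explicit units in the key names (volume_um3,
ca_out_M, rrp_refill_rate_per_s, ...); no unit conversion happens at the
I/O boundary.  Ensembles persist to HDF5 (event table plus traces) with the
configuration hash, seeds and package version embedded so every artifact
can be regenerated; summary tables are CSV with a fixed column order.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .assembly import (ModelConfig, build_canonical_model,
                       build_reconstructed_like_model)
from .stimulus import ProtocolSpec, make_protocol


def config_hash(config: ModelConfig) -> str:
    """Stable short hash of the canonical YAML serialization."""
    text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def save_config(config: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path) -> ModelConfig:
    """Load and validate a configuration; unknown keys are rejected with a
    message naming the offending key."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    try:
        return ModelConfig.from_dict(data)
    except (TypeError, ValueError, KeyError) as err:
        raise ValueError(f"{path}: invalid configuration: {err}") from None


FIXTURES = {
    "control_canonical": lambda: build_canonical_model(80, stores_blocked=False),
    "stores_blocked_canonical": lambda: build_canonical_model(80, stores_blocked=True),
    "reconstructed_like": lambda: build_reconstructed_like_model(80),
    "high_ca_4mM": lambda: build_canonical_model(80, ca_out=4e-3),
}


def fixture_config(name: str) -> ModelConfig:
    try:
        return FIXTURES[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")


def write_fixture_files(out_dir) -> List[str]:
    """Emit the canonical fixture YAML files."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for name in FIXTURES:
        path = os.path.join(out_dir, f"{name}.yaml")
        save_config(fixture_config(name), path)
        paths.append(path)
    return paths


# --------------------------------------------------------------------------
# Results

SUMMARY_COLUMNS = ["config_hash", "config_name", "n_vdcc", "isi_s",
                   "frequency_Hz", "n_trials", "base_seed",
                   "pr1", "pr1_se", "pr2", "pr2_se", "ppr", "ppr_se",
                   "p11", "p11_se", "cv_pr2"]


def summary_row(config: ModelConfig, protocol: ProtocolSpec, summary,
                base_seed: int) -> dict:
    n_vdcc = next((p.count for p in config.populations if p.label == "vdcc"), 0)
    pr = summary.pr_per_stimulus
    se = summary.pr_se
    return {
        "config_hash": config_hash(config),
        "config_name": config.name,
        "n_vdcc": n_vdcc,
        "isi_s": protocol.isi or np.nan,
        "frequency_Hz": protocol.frequency or np.nan,
        "n_trials": summary.n_trials,
        "base_seed": base_seed,
        "pr1": pr[0] if len(pr) else np.nan,
        "pr1_se": se[0] if len(se) else np.nan,
        "pr2": pr[1] if len(pr) > 1 else np.nan,
        "pr2_se": se[1] if len(se) > 1 else np.nan,
        "ppr": np.nan if summary.ppr is None else summary.ppr,
        "ppr_se": np.nan if summary.ppr_se is None else summary.ppr_se,
        "p11": np.nan if summary.p11 is None else summary.p11,
        "p11_se": np.nan if summary.p11_se is None else summary.p11_se,
        "cv_pr2": np.nan if summary.cv_pr2 is None else summary.cv_pr2,
    }


def write_summary_csv(rows: Sequence[dict], path) -> pd.DataFrame:
    """Summary CSV with fixed column order; re-parsing reproduces full
    float precision (values are written with repr precision)."""
    if not rows:
        raise ValueError("no summary rows to write")
    df = pd.DataFrame(list(rows), columns=SUMMARY_COLUMNS)
    # no float_format: pandas writes shortest round-trip representations
    df.to_csv(path, index=False)
    return df


def read_summary_csv(path) -> pd.DataFrame:
    """Re-read a summary CSV with round-trip float parsing."""
    return pd.read_csv(path, float_precision="round_trip")


def write_ensemble_h5(trials, path, config: ModelConfig,
                      base_seed: int) -> None:
    """Persist an ensemble: per-trial event tables and trace arrays, with a
    sidecar JSON of configuration hash, seeds and versions."""
    import h5py
    from . import __version__

    with h5py.File(path, "w") as h5:
        h5.attrs["schema_version"] = 1
        h5.attrs["config_hash"] = config_hash(config)
        h5.attrs["config_name"] = config.name
        h5.attrs["base_seed"] = base_seed
        h5.attrs["package_version"] = __version__
        h5.attrs["onsets"] = np.asarray(trials[0].protocol.onsets)
        h5.attrs["rng_algorithm"] = trials[0].rng_algorithm
        ev_t = np.concatenate([tr.event_times for tr in trials]) \
            if trials else np.zeros(0)
        ev_p = np.concatenate([tr.event_pathways for tr in trials]).astype("S13") \
            if trials else np.zeros(0, dtype="S13")
        offsets = np.cumsum([0] + [len(tr.event_times) for tr in trials])
        h5.create_dataset("events/time_s", data=ev_t)
        h5.create_dataset("events/pathway", data=ev_p)
        h5.create_dataset("events/trial_offsets", data=offsets)
        h5.create_dataset("traces/time_s", data=trials[0].trace_times)
        h5.create_dataset("traces/columns",
                          data=np.array(trials[0].trace_columns, dtype="S40"))
        stack = np.stack([tr.trace for tr in trials])
        h5.create_dataset("traces/counts", data=stack, compression="gzip")
        h5.create_dataset("seeds", data=np.array([tr.seed for tr in trials]))
    sidecar = {
        "config_hash": config_hash(config),
        "config_name": config.name,
        "base_seed": base_seed,
        "n_trials": len(trials),
        "package_version": __version__,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_event_log(path):
    """Reload an HDF5 ensemble as a ReleaseEventLog-compatible structure."""
    import h5py
    from .analysis import ReleaseEventLog

    with h5py.File(path, "r") as h5:
        ev_t = h5["events/time_s"][...]
        ev_p = h5["events/pathway"][...].astype(str)
        off = h5["events/trial_offsets"][...]
        n_trials = len(off) - 1
        onsets = tuple(h5.attrs.get("onsets", ()))
        times = [np.sort(ev_t[off[i]:off[i + 1]]) for i in range(n_trials)]
        paths = [ev_p[off[i]:off[i + 1]] for i in range(n_trials)]
    return ReleaseEventLog(times, paths, onsets, n_trials)


# --------------------------------------------------------------------------
# Experiment presets


@dataclass
class ExperimentPreset:
    """A named sweep: fixture, protocol factory, parameter grid, trials."""

    name: str
    config_name: str
    protocol_kind: str
    n_vdcc_grid: tuple = (80,)
    isi_grid_s: tuple = ()
    frequency: float = 0.0
    n_pulses: int = 0
    n_trials: Optional[int] = None  # None -> per-VDCC schedule

    def points(self):
        if self.protocol_kind == "paired_pulse" and self.isi_grid_s:
            for n in self.n_vdcc_grid:
                for isi in self.isi_grid_s:
                    yield n, make_protocol("paired_pulse", isi=isi)
        elif self.protocol_kind == "train":
            for n in self.n_vdcc_grid:
                yield n, make_protocol("train", frequency=self.frequency,
                                       n_pulses=self.n_pulses)
        else:
            for n in self.n_vdcc_grid:
                yield n, make_protocol("single")


def standard_presets() -> dict:
    from .stimulus import isi_grid

    vdcc_sweep = tuple(range(40, 161, 20))
    return {
        "pr_vdcc_sweep": ExperimentPreset(
            "pr_vdcc_sweep", "control_canonical", "paired_pulse",
            n_vdcc_grid=vdcc_sweep, isi_grid_s=(0.040,)),
        "ppr_isi_sweep": ExperimentPreset(
            "ppr_isi_sweep", "control_canonical", "paired_pulse",
            n_vdcc_grid=(80,), isi_grid_s=isi_grid()),
        "train_20hz": ExperimentPreset(
            "train_20hz", "control_canonical", "train",
            n_vdcc_grid=(80,), frequency=20.0, n_pulses=20),
        "train_10hz": ExperimentPreset(
            "train_10hz", "control_canonical", "train",
            n_vdcc_grid=(80,), frequency=10.0, n_pulses=20),
        "train_50hz": ExperimentPreset(
            "train_50hz", "control_canonical", "train",
            n_vdcc_grid=(80,), frequency=50.0, n_pulses=20),
    }
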