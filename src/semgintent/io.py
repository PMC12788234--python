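"""On-disk formats: delimited trial tables + JSON event sidecars, HDF5
containers for trials and featurized windows, and run manifests."""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .config import WindowingConfig, config_to_dict
from .experiment import FeatureSet
from .synthetic import N_CHANNELS, SignalTrial


# -- delimited text + sidecar ------------------------------------------------

def write_trial_csv(trial: SignalTrial, path: str | Path) -> None:
    """One CSV per trial (time_ms, ch1..ch8) plus a .events.json sidecar."""
    path = Path(path)
    n = trial.samples.shape[0]
    df = pd.DataFrame(
        trial.samples, columns=[f"ch{i + 1}" for i in range(N_CHANNELS)]
    )
    df.insert(0, "time_ms", np.arange(n) * 1000 // trial.fs)
    df.to_csv(path, index=False)
    sidecar = {
        "trial_id": trial.trial_id,
        "subject_id": trial.subject_id,
        "fs": trial.fs,
        "events": [list(e) for e in trial.events],
    }
    path.with_suffix(".events.json").write_text(json.dumps(sidecar, indent=1))


def read_trial_csv(path: str | Path) -> SignalTrial:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".events.json").read_text())
    return SignalTrial(
        samples=df[[f"ch{i + 1}" for i in range(N_CHANNELS)]].to_numpy(),
        fs=int(meta["fs"]),
        events=tuple(tuple(e) for e in meta["events"]),
        trial_id=meta["trial_id"],
        subject_id=meta["subject_id"],
    )


# -- HDF5 containers ---------------------------------------------------------

def write_trials_h5(trials: Sequence[SignalTrial], path: str | Path) -> None:
    """All trials in one hierarchical container, one group per trial."""
    with h5py.File(path, "w") as fh:
        for t in trials:
            g = fh.create_group(t.trial_id)
            g.create_dataset("samples", data=t.samples)
            g.create_dataset("events", data=np.array(t.events, dtype=np.int64))
            g.attrs["fs"] = t.fs
            g.attrs["subject_id"] = t.subject_id


def read_trials_h5(path: str | Path) -> list[SignalTrial]:
    trials = []
    with h5py.File(path, "r") as fh:
        for tid in fh:
            g = fh[tid]
            trials.append(
                SignalTrial(
                    samples=g["samples"][...],
                    fs=int(g.attrs["fs"]),
                    events=tuple(tuple(int(x) for x in row) for row in g["events"][...]),
                    trial_id=tid,
                    subject_id=str(g.attrs["subject_id"]),
                )
            )
    return sorted(trials, key=lambda t: t.trial_id)


def write_windows_h5(fs_set: FeatureSet, wcfg: WindowingConfig,
                     path: str | Path, raw: np.ndarray | None = None) -> None:
    """Featurized-window container; group attributes record the windowing
    config so a round trip is bit-exact and self-describing."""
    with h5py.File(path, "w") as fh:
        if raw is not None:
            fh.create_dataset("raw", data=raw)
        fh.create_dataset("tfmap", data=fs_set.tfmap)
        fh.create_dataset("spectrum", data=fs_set.spectrum)
        fh.create_dataset("labels", data=fs_set.labels)
        fh.create_dataset("starts", data=fs_set.starts)
        str_dt = h5py.string_dtype()
        fh.create_dataset("trial_ids", data=fs_set.trial_ids.astype(object), dtype=str_dt)
        fh.create_dataset("subject_ids", data=fs_set.subject_ids.astype(object), dtype=str_dt)
        for key, value in config_to_dict(wcfg).items():
            fh.attrs[key] = value


def read_windows_h5(path: str | Path) -> tuple[FeatureSet, WindowingConfig]:
    with h5py.File(path, "r") as fh:
        fs_set = FeatureSet(
            tfmap=fh["tfmap"][...],
            spectrum=fh["spectrum"][...],
            labels=fh["labels"][...],
            trial_ids=fh["trial_ids"].asstr()[...],
            starts=fh["starts"][...],
            subject_ids=fh["subject_ids"].asstr()[...],
        )
        wcfg = WindowingConfig(**{k: int(fh.attrs[k]) for k in
                                  ("window_ms", "step_ms", "plabel_ms", "fs")})
    return fs_set, wcfg


# -- run manifests -----------------------------------------------------------

def write_manifest(path: str | Path, seed: int, config: dict,
                   artifacts: Sequence[str]) -> None:
    manifest = {
        "version": _package_version(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "config": config,
        "artifacts": list(artifacts),
    }
    Path(path).write_text(json.dumps(manifest, indent=1))


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("semgintent")
    except PackageNotFoundError:
        return "unknown"
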