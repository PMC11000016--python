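"""Readers and writers for the pipeline's on-disk formats.

Tabular artifacts are TSV with ``#``-prefixed header comments carrying
provenance (config hash, seed); arrays travel in HDF5 containers; ground
truth and reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from gatingnet.containers import EpochArray, Leadfield

__all__ = [
    "write_trials",
    "read_trials",
    "write_epochs",
    "read_epochs",
    "write_leadfield",
    "read_leadfield",
    "write_report",
    "read_report",
]

TRIAL_COLUMNS = [
    "subject",
    "trial",
    "trial_type",
    "switching",
    "matching",
    "response",
    "correct",
    "rt_s",
]


def write_trials(trials: pd.DataFrame, path: str | Path, header: dict | None = None) -> None:
    """Write a behavioral trial table as TSV with optional comment header."""
    path = Path(path)
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}={v}\n")
        trials[TRIAL_COLUMNS].to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_trials(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    return df


def write_epochs(epochs: EpochArray, path: str | Path, header: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times_s", data=epochs.times_s)
        f.create_dataset(
            "channel_names", data=np.array(epochs.channel_names, dtype="S")
        )
        if epochs.condition_labels is not None:
            f.create_dataset(
                "condition_labels",
                data=np.asarray(epochs.condition_labels, dtype="S"),
            )
        if epochs.channel_positions is not None:
            f.create_dataset("channel_positions", data=epochs.channel_positions)
        f.attrs["sfreq_hz"] = epochs.sfreq_hz
        f.attrs["onset_sample"] = epochs.onset_sample
        for k, v in (header or {}).items():
            f.attrs[str(k)] = str(v)


def read_epochs(path: str | Path) -> EpochArray:
    with h5py.File(path, "r") as f:
        for ds in ("data", "times_s", "channel_names"):
            if ds not in f:
                raise ValueError(f"{Path(path).name}: missing dataset {ds!r}")
        labels = None
        if "condition_labels" in f:
            labels = np.array([s.decode() for s in f["condition_labels"][()]])
        ch_pos = f["channel_positions"][()] if "channel_positions" in f else None
        return EpochArray(
            data=f["data"][()],
            times_s=f["times_s"][()],
            sfreq_hz=float(f.attrs["sfreq_hz"]),
            channel_names=[s.decode() for s in f["channel_names"][()]],
            condition_labels=labels,
            channel_positions=ch_pos,
        )


def write_leadfield(lf: Leadfield, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("gain", data=lf.gain)
        f.create_dataset("voxel_positions", data=lf.voxel_positions)
        f.create_dataset("channel_names", data=np.array(lf.channel_names, dtype="S"))
        if lf.channel_positions is not None:
            f.create_dataset("channel_positions", data=lf.channel_positions)


def read_leadfield(path: str | Path) -> Leadfield:
    with h5py.File(path, "r") as f:
        ch_pos = f["channel_positions"][()] if "channel_positions" in f else None
        return Leadfield(
            gain=f["gain"][()],
            voxel_positions=f["voxel_positions"][()],
            channel_names=[s.decode() for s in f["channel_names"][()]],
            channel_positions=ch_pos,
        )


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_to_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
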