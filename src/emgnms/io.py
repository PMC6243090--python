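"""CSV/JSON persistence of datasets and fits.

Time-series CSV layout: first column ``time_s``, one column per channel,
mandatory header row, UTF-8, '.' decimal.  A dataset directory contains
one CSV per trial (EMG, angles, measured torques), the MVC recordings,
and a ``dataset.json`` manifest; subject ground truth, when present, is
written to a separate file so calibration code cannot read it by accident.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import Dataset, Trial
from .emg import RawEmg

__all__ = ["save_timeseries", "load_timeseries", "save_dataset", "load_dataset"]


def save_timeseries(path, time_s: np.ndarray, columns: dict) -> None:
    frame = pd.DataFrame({"time_s": time_s, **columns})
    frame.to_csv(path, index=False)


def load_timeseries(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if frame.columns[0] != "time_s":
        raise ValueError(f"{path}: first column must be 'time_s'")
    return frame


def save_dataset(dataset: Dataset, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "fs": dataset.fs,
        "channel_names": list(dataset.channel_names),
        "body_mass": dataset.body_mass,
        "meta": dataset.meta,
        "trials": [],
        "mvc_files": [],
    }
    for trial in dataset.trials:
        fname = f"trial_{trial.trial_id}.csv"
        t = np.arange(trial.n_samples) / trial.fs
        cols = {f"emg_{c}": trial.emg[:, i] for i, c in enumerate(dataset.channel_names)}
        cols["theta1"] = np.full(trial.n_samples, trial.theta1)
        cols["theta2"] = np.full(trial.n_samples, trial.theta2)
        cols["tau_m_sh"] = trial.tau_m_sh
        cols["tau_m_el"] = trial.tau_m_el
        save_timeseries(outdir / fname, t, cols)
        manifest["trials"].append(
            {
                "file": fname,
                "pose_id": trial.pose_id,
                "direction": trial.direction,
                "repetition": trial.repetition,
                "theta1": trial.theta1,
                "theta2": trial.theta2,
                "force": list(map(float, trial.force)),
            }
        )
    for k, rec in enumerate(dataset.mvc_recordings):
        fname = f"mvc_{k}.csv"
        t = np.arange(rec.n_samples) / rec.fs
        save_timeseries(
            outdir / fname,
            t,
            {f"emg_{c}": rec.samples[:, i] for i, c in enumerate(rec.channel_names)},
        )
        manifest["mvc_files"].append(fname)
    (outdir / "dataset.json").write_text(json.dumps(manifest, indent=2))


def load_dataset(indir) -> Dataset:
    indir = Path(indir)
    manifest = json.loads((indir / "dataset.json").read_text())
    channels = tuple(manifest["channel_names"])
    fs = manifest["fs"]
    trials = []
    for info in manifest["trials"]:
        frame = load_timeseries(indir / info["file"])
        emg = frame[[f"emg_{c}" for c in channels]].to_numpy()
        trials.append(
            Trial(
                pose_id=info["pose_id"],
                direction=info["direction"],
                repetition=info["repetition"],
                theta1=info["theta1"],
                theta2=info["theta2"],
                fs=fs,
                emg=emg,
                tau_m_sh=frame["tau_m_sh"].to_numpy(),
                tau_m_el=frame["tau_m_el"].to_numpy(),
                force=np.array(info["force"]),
            )
        )
    mvc = []
    for fname in manifest["mvc_files"]:
        frame = load_timeseries(indir / fname)
        mvc.append(
            RawEmg(frame[[f"emg_{c}" for c in channels]].to_numpy(), fs=fs,
                   channel_names=channels)
        )
    return Dataset(
        trials=tuple(trials),
        channel_names=channels,
        fs=fs,
        mvc_recordings=tuple(mvc),
        body_mass=manifest["body_mass"],
        meta=manifest.get("meta", {}),
    )
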