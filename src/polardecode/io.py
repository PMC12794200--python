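"""On-disk formats: HDF5 subject containers, CSV kinematics, JSON logs.

A simulated subject is stored as a single HDF5 container::

    /session_<s>/trial_<k>/eeg            channels x samples, uV
    /session_<s>/trial_<k>/kin_t|kin_x|kin_y
    ...trigger sample indices as attributes...

with a JSON sidecar (`<stem>.json`) recording every configuration value
and seed needed to regenerate it.  Kinematics can additionally be
exported as `timestamp,x,y` CSV, one file per trial.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from .synthetic import (EncodingConfig, KinematicsTrace, ProtocolConfig,
                        TrialRecording)


def _config_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    return {k: (v.tolist() if isinstance(v, np.ndarray) else
                list(v) if isinstance(v, tuple) else v)
            for k, v in d.items()}


def write_subject(path, trials: list[TrialRecording],
                  protocol: ProtocolConfig, encoding: EncodingConfig) -> Path:
    """Write a subject's trials plus a JSON config sidecar; returns the path."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for tr in trials:
            grp = f.create_group(f"session_{tr.session_id:03d}/trial_{tr.trial_id:04d}")
            grp.create_dataset("eeg", data=tr.eeg, compression="gzip", compression_opts=1)
            grp.create_dataset("kin_t", data=tr.kinematics.timestamps)
            grp.create_dataset("kin_x", data=tr.kinematics.x)
            grp.create_dataset("kin_y", data=tr.kinematics.y)
            for key, val in tr.trigger_onsets.items():
                grp.attrs[key] = val
            grp.attrs["trial_id"] = tr.trial_id
            grp.attrs["session_id"] = tr.session_id
    sidecar = {
        "protocol": _config_dict(protocol),
        "encoding": _config_dict(encoding),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_subject(path) -> tuple[list[TrialRecording], dict]:
    """Read a subject container; returns (trials, sidecar_config_dict)."""
    path = Path(path)
    trials = []
    with h5py.File(path, "r") as f:
        for skey in sorted(f.keys()):
            for tkey in sorted(f[skey].keys()):
                grp = f[skey][tkey]
                kin = KinematicsTrace(
                    timestamps=grp["kin_t"][()],
                    x=grp["kin_x"][()],
                    y=grp["kin_y"][()],
                )
                trials.append(TrialRecording(
                    eeg=grp["eeg"][()],
                    trigger_onsets={k: int(grp.attrs[k])
                                    for k in ("prep", "move_on", "move_off")},
                    kinematics=kin,
                    trial_id=int(grp.attrs["trial_id"]),
                    session_id=int(grp.attrs["session_id"]),
                ))
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    trials.sort(key=lambda t: t.trial_id)
    return trials, sidecar


def write_kinematics_csv(path, trace: KinematicsTrace) -> Path:
    """Write one trial's camera trace as `timestamp,x,y` rows."""
    path = Path(path)
    data = np.column_stack([trace.timestamps, trace.x, trace.y])
    np.savetxt(path, data, delimiter=",", header="timestamp,x,y", comments="")
    return path


def read_kinematics_csv(path) -> KinematicsTrace:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    return KinematicsTrace(timestamps=data[:, 0], x=data[:, 1], y=data[:, 2])


def write_angles(path, angles) -> Path:
    """Store per-trial angle label epochs (rad at 100 Hz) in HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for ep in angles:
            d = f.create_dataset(f"trial_{ep.trial_id:04d}", data=ep.theta)
            d.attrs["rate_hz"] = ep.rate_hz
    return path


def read_angles(path):
    from .kinematics import AngleEpoch

    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            out.append(AngleEpoch(trial_id=int(key.split("_")[1]),
                                  theta=f[key][()],
                                  rate_hz=float(f[key].attrs["rate_hz"])))
    return out


def write_window_dataset(path, dataset) -> Path:
    """Store a windowed dataset (windows/labels/ids/split) in HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("windows", data=dataset.windows, compression="gzip",
                         compression_opts=1)
        f.create_dataset("labels", data=dataset.labels)
        f.create_dataset("trial_ids", data=dataset.trial_ids)
        keys = np.array(sorted(dataset.split_assignment))
        f.create_dataset("split_trials", data=keys)
        f.create_dataset("split_folds",
                         data=np.array([dataset.split_assignment[k] for k in keys]))
    return path


def read_window_dataset(path):
    from .dataset import WindowDataset

    with h5py.File(path, "r") as f:
        assignment = {int(t): int(v) for t, v in
                      zip(f["split_trials"][()], f["split_folds"][()])}
        return WindowDataset(windows=f["windows"][()], labels=f["labels"][()],
                             trial_ids=f["trial_ids"][()],
                             split_assignment=assignment)


def save_weights(path, model) -> Path:
    """Checkpoint a model's parameters to an .npz archive."""
    path = Path(path)
    np.savez(path, *model.get_weights())
    return path


def load_weights(path, model) -> None:
    with np.load(path) as archive:
        model.set_weights([archive[k] for k in archive.files])


def write_signature_arrays(path, mrcp_results, ersp_results) -> Path:
    """Store MRCP traces and ERSP maps per channel in HDF5."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for res in mrcp_results:
            grp = f.create_group(f"mrcp/{res.channel}")
            grp.create_dataset("time", data=res.time)
            grp.create_dataset("mean", data=res.mean)
            grp.create_dataset("ci95", data=res.ci95)
        for res in ersp_results:
            grp = f.create_group(f"ersp/{res.channel}")
            grp.create_dataset("freqs", data=res.freqs)
            grp.create_dataset("times", data=res.times)
            grp.create_dataset("power_db", data=res.power)
    return path


def write_json(path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
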