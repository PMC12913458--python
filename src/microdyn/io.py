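"""Readers and writers.

Two on-disk forms for recordings:

* EEGLAB ``.set``/``.fdt`` pairs — the distribution format of typical
  public resting-state datasets.  Writing uses a minimal MAT-file struct
  (float32 ``.fdt`` payload); reading goes through :mod:`mne`.
* a plain fixture format: little-endian float32 ``.bin`` plus a JSON
  sidecar with channel names, sampling rate and metadata.  This is the
  default interchange format for synthetic cohorts.

Templates are serialized as CSV (K rows x channel columns) with a JSON
metadata sidecar; labels as per-epoch integer CSV; ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._types import ConfigError, LabelSequence, Recording, TemplateSet
from .synthetic import GroundTruth

__all__ = [
    "save_fixture", "load_fixture", "save_eeglab_set", "load_eeglab_set",
    "save_cohort", "load_cohort", "save_ground_truth",
    "save_templates", "load_templates", "save_labels", "load_labels",
]


# -- fixture format ---------------------------------------------------------

def save_fixture(rec: Recording, directory, stem: str | None = None) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = rec.subject or "recording" if stem is None else stem
    bin_path = directory / f"{stem}.bin"
    rec.data.astype("<f4").tofile(bin_path)
    sidecar = {
        "format": "microdyn-fixture-v1",
        "data_file": bin_path.name,
        "dtype": "<f4",
        "order": "channels_x_samples_C",
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "fs": rec.fs,
        "ch_names": rec.ch_names,
        "subject": rec.subject,
        "group": rec.group,
        "units": "uV",
    }
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return directory / f"{stem}.json"


def load_fixture(sidecar_path) -> Recording:
    sidecar_path = Path(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    if meta.get("format") != "microdyn-fixture-v1":
        raise ConfigError(f"{sidecar_path} is not a microdyn fixture sidecar")
    raw = np.fromfile(sidecar_path.parent / meta["data_file"],
                      dtype=meta["dtype"])
    data = raw.reshape(meta["n_channels"], meta["n_samples"]).astype(float)
    return Recording(data=data, fs=meta["fs"], ch_names=meta["ch_names"],
                     subject=meta.get("subject", ""), group=meta.get("group"))


# -- EEGLAB .set/.fdt -------------------------------------------------------

def save_eeglab_set(rec: Recording, set_path) -> Path:
    """Write a minimal EEGLAB-compatible .set (MAT struct) + .fdt pair."""
    from scipy.io import savemat

    set_path = Path(set_path)
    set_path.parent.mkdir(parents=True, exist_ok=True)
    fdt_path = set_path.with_suffix(".fdt")
    # .fdt stores (nbchan, pnts) in column-major order
    np.asarray(rec.data, dtype="<f4").T.tofile(fdt_path)
    chanlocs = np.empty((rec.n_channels,), dtype=[("labels", object)])
    chanlocs["labels"] = rec.ch_names
    eeg = {
        "data": fdt_path.name,
        "setname": rec.subject or set_path.stem,
        "nbchan": float(rec.n_channels),
        "pnts": float(rec.n_samples),
        "trials": 1.0,
        "srate": float(rec.fs),
        "xmin": 0.0,
        "xmax": (rec.n_samples - 1) / rec.fs,
        "chanlocs": chanlocs,
        "ref": "average",
        "icawinv": np.empty((0, 0)),
        "icasphere": np.empty((0, 0)),
        "icaweights": np.empty((0, 0)),
        "icaact": np.empty((0, 0)),
        "event": np.empty((0, 0)),
    }
    savemat(set_path, {"EEG": eeg}, appendmat=False)
    return set_path


def load_eeglab_set(set_path, subject: str = "",
                    group: str | None = None) -> Recording:
    """Read an EEGLAB .set/.fdt recording (µV) via mne."""
    import mne

    raw = mne.io.read_raw_eeglab(str(set_path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne works in volts; recordings are µV
    return Recording(data=data, fs=float(raw.info["sfreq"]),
                     ch_names=list(raw.ch_names),
                     subject=subject or Path(set_path).stem, group=group)


# -- cohorts ----------------------------------------------------------------

def save_cohort(recordings: list[Recording], groups: list[str], directory,
                fmt: str = "fixture") -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for rec, group in zip(recordings, groups):
        stem = rec.subject or f"subject{len(manifest):03d}"
        if fmt == "fixture":
            save_fixture(rec, directory, stem=stem)
            entry_file = f"{stem}.json"
        elif fmt == "set":
            save_eeglab_set(rec, directory / f"{stem}.set")
            entry_file = f"{stem}.set"
        else:
            raise ConfigError(f"unknown cohort format {fmt!r}")
        manifest.append({"subject": stem, "group": group, "file": entry_file})
    man_path = directory / "cohort.json"
    man_path.write_text(json.dumps({"format": fmt, "subjects": manifest},
                                   indent=1))
    return man_path


def load_cohort(directory) -> tuple[list[Recording], list[str]]:
    directory = Path(directory)
    meta = json.loads((directory / "cohort.json").read_text())
    recordings, groups = [], []
    for entry in meta["subjects"]:
        path = directory / entry["file"]
        if meta["format"] == "fixture":
            rec = load_fixture(path)
        else:
            rec = load_eeglab_set(path, subject=entry["subject"],
                                  group=entry["group"])
        rec.subject, rec.group = entry["subject"], entry["group"]
        recordings.append(rec)
        groups.append(entry["group"])
    return recordings, groups


def save_ground_truth(gt: GroundTruth, path) -> Path:
    path = Path(path)
    payload = {
        "templates": gt.templates.maps.tolist(),
        "labels": [ls.flat.tolist() for ls in gt.labels],
        "params": gt.params,
    }
    path.write_text(json.dumps(payload))
    return path


# -- templates and labels ---------------------------------------------------

def save_templates(templates: TemplateSet, csv_path) -> Path:
    csv_path = Path(csv_path)
    names = (templates.ch_names if templates.ch_names
             else [f"ch{i}" for i in range(templates.n_channels)])
    pd.DataFrame(templates.maps, columns=names).to_csv(csv_path, index=False)
    meta = {"K": templates.K, "n_channels": templates.n_channels,
            "unit_norm": True}
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return csv_path


def load_templates(csv_path) -> TemplateSet:
    df = pd.read_csv(csv_path)
    return TemplateSet(maps=df.to_numpy(dtype=float),
                       ch_names=list(df.columns))


def save_labels(labels: LabelSequence, csv_path) -> Path:
    csv_path = Path(csv_path)
    pd.DataFrame(labels.labels).to_csv(csv_path, index=False)
    return csv_path


def load_labels(csv_path, fs: float, K: int | None = None) -> LabelSequence:
    df = pd.read_csv(csv_path)
    return LabelSequence(labels=df.to_numpy(dtype=np.int64), fs=fs, K=K)
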