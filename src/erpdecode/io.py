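"""On-disk containers.

EpochSet HDF5 layout::

    /data        float32, trials x channels x samples (uV)
    /time        float64, ms relative to the locking event
    /channels    variable-length UTF-8 labels
    /condition   variable-length UTF-8 per-trial labels
    /trial_info/<column>   optional per-trial metadata
    attrs: sfreq, subject_id, locking_event
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochSet


def save_epochs(path, epochs: EpochSet) -> None:
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("time", data=epochs.times)
        f.create_dataset("channels", data=np.array(epochs.channels, dtype=object),
                         dtype=str_dt)
        f.create_dataset("condition", data=epochs.condition.astype(object),
                         dtype=str_dt)
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["subject_id"] = epochs.subject_id
        f.attrs["locking_event"] = epochs.locking_event
        if epochs.trial_info is not None:
            grp = f.create_group("trial_info")
            for col in epochs.trial_info.columns:
                vals = epochs.trial_info[col].to_numpy()
                if vals.dtype == object or vals.dtype.kind in "US":
                    grp.create_dataset(col, data=vals.astype(object), dtype=str_dt)
                else:
                    grp.create_dataset(col, data=vals)


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        info = None
        if "trial_info" in f:
            cols = {}
            for col in f["trial_info"]:
                vals = f["trial_info"][col][()]
                if vals.dtype.kind in "OS":
                    vals = np.array([v.decode() if isinstance(v, bytes) else v
                                     for v in vals], dtype=object)
                cols[col] = vals
            info = pd.DataFrame(cols)
        return EpochSet(
            data=f["data"][()].astype(float),
            times=f["time"][()],
            sfreq=float(f.attrs["sfreq"]),
            channels=[c.decode() if isinstance(c, bytes) else c
                      for c in f["channels"][()]],
            condition=np.array([c.decode() if isinstance(c, bytes) else c
                                for c in f["condition"][()]], dtype=object),
            subject_id=str(f.attrs["subject_id"]),
            locking_event=str(f.attrs["locking_event"]),
            trial_info=info,
        )


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n")
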