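"""HDF5 serialization of epoch sets plus CSV/JSON report writers."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import SensorArray
from .simulate import EpochSet


def save_epochs(path: str | Path, epochs: EpochSet) -> None:
    """Write an EpochSet to HDF5 with a JSON metadata sidecar.

    Layout: /data (trials x channels x samples), /times (ms),
    /labels/image_id, /labels/category, /sensors/{positions, orientations,
    region, channel_ids}; attributes sfreq and subject_id.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        lab = f.create_group("labels")
        lab.create_dataset("image_id", data=epochs.image_id)
        lab.create_dataset(
            "category", data=np.asarray(epochs.category, dtype="S")
        )
        sens = f.create_group("sensors")
        sens.create_dataset("positions", data=epochs.sensors.positions)
        sens.create_dataset("orientations", data=epochs.sensors.orientations)
        sens.create_dataset("region", data=np.asarray(epochs.sensors.region, dtype="S"))
        sens.create_dataset(
            "channel_ids", data=np.asarray(epochs.sensors.channel_ids, dtype="S")
        )
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["subject_id"] = epochs.subject_id
    sidecar = {
        "subject_id": epochs.subject_id,
        "sfreq": epochs.sfreq,
        "n_trials": epochs.n_trials,
        "n_channels": epochs.n_channels,
        "n_samples": epochs.n_samples,
        "categories": sorted(set(epochs.category.tolist())),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_epochs(path: str | Path) -> EpochSet:
    """Read an EpochSet written by :func:`save_epochs`."""
    with h5py.File(path, "r") as f:
        sensors = SensorArray(
            channel_ids=f["sensors/channel_ids"][()].astype(str).astype(object),
            positions=f["sensors/positions"][()],
            orientations=f["sensors/orientations"][()],
            region=f["sensors/region"][()].astype(str).astype(object),
        )
        return EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            image_id=f["labels/image_id"][()],
            category=f["labels/category"][()].astype(str).astype(object),
            sensors=sensors,
            sfreq=float(f.attrs["sfreq"]),
            subject_id=str(f.attrs["subject_id"]),
        )


def write_rejection_report(path: str | Path, epochs: EpochSet,
                           rejected: np.ndarray, threshold: float) -> None:
    """CSV of rejected trials with their worst-channel peak-to-peak value."""
    rows = []
    for t in rejected:
        ptp = epochs.data[t].max(axis=-1) - epochs.data[t].min(axis=-1)
        c = int(np.argmax(ptp))
        rows.append(
            {
                "trial_id": int(t),
                "channel": str(epochs.sensors.channel_ids[c]),
                "peak_to_peak": float(ptp[c]),
                "threshold": threshold,
            }
        )
    pd.DataFrame(rows, columns=["trial_id", "channel", "peak_to_peak", "threshold"]).to_csv(
        path, index=False
    )


def write_f_map_csv(path: str | Path, positions: np.ndarray, maps: dict) -> None:
    """F-map table: vertex id, position, one F column per contrast."""
    table = {
        "vertex_id": np.arange(len(positions)),
        "x": positions[:, 0],
        "y": positions[:, 1],
        "z": positions[:, 2],
    }
    for name, fmap in maps.items():
        table[f"F_{name.replace('/', '_')}"] = fmap.f_values
    pd.DataFrame(table).to_csv(path, index=False)


def write_decoding_csv(path: str | Path, result) -> None:
    """Per-window accuracy table (both schemes) with CIs and p-values."""
    rows = []
    for scheme, mean, ci, binom in (
        ("categorical", result.categorical_mean, result.categorical_ci,
         result.binom_p_categorical),
        ("random", result.random_mean, result.random_ci, result.binom_p_random),
    ):
        for i, t in enumerate(result.window_centers):
            rows.append(
                {
                    "window_center_ms": float(t),
                    "scheme": scheme,
                    "accuracy_mean": float(mean[i]),
                    "ci_low": float(ci[0, i]) if ci is not None else np.nan,
                    "ci_high": float(ci[1, i]) if ci is not None else np.nan,
                    "binom_p": float(binom[i]) if binom is not None else np.nan,
                    "paired_p": float(result.paired_p[i])
                    if result.paired_p is not None
                    else np.nan,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
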