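"""Plain-text and HDF5 persistence for sessions, units and photometry.

Trial tables, lick trains and pulse trains travel as CSV with times in
seconds at 6 decimal places; spike trains and photometry traces live in HDF5
(``/units/<id>/spike_times``, ``/photometry/f465`` / ``f405`` with an ``fs``
attribute), mirroring common acquisition layouts.
"""
from __future__ import annotations

from pathlib import Path
from typing import List, Sequence

import h5py
import numpy as np
import pandas as pd

from .core import SpikeTrain
from .synthetic import PhotometryRecording, TRIAL_COLUMNS

__all__ = [
    "save_trials",
    "load_trials",
    "save_times",
    "load_times",
    "save_units",
    "load_units",
    "save_photometry",
    "load_photometry",
]

_FLOAT_FMT = "%.6f"


def save_trials(path: str | Path, trials: pd.DataFrame) -> None:
    trials.to_csv(path, index=False, float_format=_FLOAT_FMT)


def load_trials(path: str | Path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return trials


def save_times(path: str | Path, times: np.ndarray, column: str = "time_s") -> None:
    """One-column CSV of event times (licks, pulses) in seconds."""
    pd.DataFrame({column: np.asarray(times, float)}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def load_times(path: str | Path) -> np.ndarray:
    frame = pd.read_csv(path)
    return frame.iloc[:, 0].to_numpy(float)


def save_units(path: str | Path, units: Sequence[SpikeTrain]) -> None:
    with h5py.File(path, "w") as f:
        root = f.create_group("units")
        for u in units:
            g = root.create_group(str(u.unit_id))
            g.create_dataset("spike_times", data=u.times)
            if u.waveform is not None:
                g.create_dataset("waveform", data=u.waveform)
            if u.tetrode is not None:
                g.attrs["tetrode"] = int(u.tetrode)
            if u.depth_um is not None:
                g.attrs["depth_um"] = float(u.depth_um)


def load_units(path: str | Path) -> List[SpikeTrain]:
    units: List[SpikeTrain] = []
    with h5py.File(path, "r") as f:
        for uid, g in f["units"].items():
            units.append(
                SpikeTrain(
                    times=g["spike_times"][()],
                    unit_id=uid,
                    waveform=g["waveform"][()] if "waveform" in g else None,
                    tetrode=int(g.attrs["tetrode"]) if "tetrode" in g.attrs else None,
                    depth_um=float(g.attrs["depth_um"]) if "depth_um" in g.attrs else None,
                )
            )
    return units


def save_photometry(path: str | Path, rec: PhotometryRecording) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("photometry")
        g.create_dataset("f465", data=rec.f465)
        g.create_dataset("f405", data=rec.f405)
        g.attrs["fs"] = float(rec.fs)


def load_photometry(path: str | Path) -> PhotometryRecording:
    with h5py.File(path, "r") as f:
        g = f["photometry"]
        f465 = g["f465"][()]
        f405 = g["f405"][()]
        fs = float(g.attrs["fs"])
    t = np.arange(f465.size) / fs
    return PhotometryRecording(t=t, f465=f465, f405=f405, fs=fs)
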