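"""Epoched multi-sensor data container with trial metadata and HDF5 I/O."""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd

from .config import PERCEPT_CODES, PERCEPT_NAMES
from .layout import SensorLayout

__all__ = ["Epochs"]

_TRIALINFO_COLS = ["condition", "percept", "run", "artifact"]


@dataclass
class Epochs:
    """Trials x sensors x samples data, per-sample times (ms, t=0 = motion
    onset) and per-trial metadata.

    ``trialinfo`` is a DataFrame with columns ``condition`` (1..4),
    ``percept`` ("bound"/"unbound"/"unclassified"), ``run`` (0-based) and
    ``artifact`` (bool, the generator's planted contamination flag).
    """

    data: np.ndarray
    times: np.ndarray
    trialinfo: pd.DataFrame
    layout: SensorLayout | None = None
    fs: float = 250.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x sensors x samples")
        if self.times.shape[0] != self.data.shape[2]:
            raise ValueError("times length must equal the sample count")
        dt = np.diff(self.times)
        if dt.size and (dt.min() <= 0 or not np.allclose(dt, 1000.0 / self.fs)):
            raise ValueError("times must increase uniformly at 1000/fs ms")
        if len(self.trialinfo) != self.data.shape[0]:
            raise ValueError("trialinfo length must equal the trial count")
        missing = set(_TRIALINFO_COLS) - set(self.trialinfo.columns)
        if missing:
            raise ValueError(f"trialinfo is missing columns {sorted(missing)}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select(self, mask) -> "Epochs":
        """Subset trials by a boolean mask or index array."""
        mask = np.asarray(mask)
        return Epochs(self.data[mask],
                      self.times,
                      self.trialinfo.iloc[np.nonzero(mask)[0] if mask.dtype == bool else mask]
                      .reset_index(drop=True),
                      self.layout, self.fs)

    def crop(self, t_lo: float, t_hi: float) -> "Epochs":
        """Restrict the epoch to ``t_lo <= t <= t_hi`` (ms)."""
        keep = (self.times >= t_lo) & (self.times <= t_hi)
        if not keep.any():
            raise ValueError("crop window contains no samples")
        return Epochs(self.data[:, :, keep], self.times[keep],
                      self.trialinfo.copy(), self.layout, self.fs)

    def percept_mask(self, name: str) -> np.ndarray:
        if name not in PERCEPT_CODES:
            raise ValueError(f"unknown percept {name!r}")
        return (self.trialinfo["percept"] == name).to_numpy()

    # ---- HDF5 I/O ---------------------------------------------------------
    def save(self, path, seed: int | None = None) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data.astype(np.float32))
            f.create_dataset("times", data=self.times)
            ti = np.stack([
                self.trialinfo["condition"].to_numpy(dtype=np.int64),
                self.trialinfo["percept"].map(PERCEPT_CODES).to_numpy(dtype=np.int64),
                self.trialinfo["run"].to_numpy(dtype=np.int64),
                self.trialinfo["artifact"].to_numpy(dtype=np.int64),
            ], axis=1)
            f.create_dataset("trialinfo", data=ti)
            f.attrs["fs"] = float(self.fs)
            if seed is not None:
                f.attrs["seed"] = int(seed)

    @classmethod
    def load(cls, path, layout: SensorLayout | None = None) -> "Epochs":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            times = f["times"][()]
            ti = f["trialinfo"][()]
            fs = float(f.attrs["fs"])
        trialinfo = pd.DataFrame({
            "condition": ti[:, 0],
            "percept": [PERCEPT_NAMES[int(c)] for c in ti[:, 1]],
            "run": ti[:, 2],
            "artifact": ti[:, 3].astype(bool),
        })
        return cls(data, times, trialinfo, layout, fs)
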