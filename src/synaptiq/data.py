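"""Core data containers and plain-text / HDF5 I/O.

The containers are thin dataclasses around numpy arrays and pandas frames
that enforce the physical invariants (uniform sampling, non-negative
intensities, non-negative distances).  On-disk formats are plain text:
CSV with ``# key=value`` header lines for sweep metadata, sidecar JSON for
generator ground truth, plus an optional HDF5 layout for sweeps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SweepTrace",
    "LineProfilePair",
    "EMDataset",
    "write_ground_truth",
    "read_ground_truth",
    "read_profiles_csv",
    "write_profiles_csv",
]


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class SweepTrace:
    """A uniformly sampled current recording.

    Parameters
    ----------
    time_ms : array
        Sample times in ms, uniform grid.
    current_pA : array
        Membrane current in pA; inward currents are negative.
    fs_khz : float
        Sampling rate in kHz (samples per ms).
    markers : dict
        Named timestamps in ms (``t0_ms``, ``app_start_ms``, ``app_stop_ms``,
        ``light_on_ms``, ``light_off_ms``, ...). Must lie within the record.
    """

    time_ms: np.ndarray
    current_pA: np.ndarray
    fs_khz: float
    markers: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_ms = _as_float_array(self.time_ms, "time_ms")
        self.current_pA = _as_float_array(self.current_pA, "current_pA")
        if self.time_ms.size != self.current_pA.size:
            raise ValueError("time_ms and current_pA must have equal length")
        if self.time_ms.size < 2:
            raise ValueError("trace needs at least 2 samples")
        dt = np.diff(self.time_ms)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9) or dt[0] <= 0:
            raise ValueError("time grid must be uniform and increasing")
        if self.fs_khz <= 0:
            raise ValueError("fs_khz must be positive")
        if not np.isclose(1.0 / dt[0], self.fs_khz, rtol=1e-4):
            raise ValueError(
                f"fs_khz={self.fs_khz} inconsistent with grid spacing {dt[0]} ms"
            )
        lo, hi = self.time_ms[0], self.time_ms[-1]
        for key, val in self.markers.items():
            if val is None:
                continue
            if not (lo <= val <= hi):
                raise ValueError(f"marker {key}={val} ms outside record [{lo}, {hi}]")

    # -- convenience ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.time_ms.size

    @property
    def duration_ms(self) -> float:
        return float(self.time_ms[-1] - self.time_ms[0])

    def index_at(self, t_ms: float) -> int:
        """Index of the sample nearest to ``t_ms``."""
        return int(round((t_ms - self.time_ms[0]) * self.fs_khz))

    def copy(self) -> "SweepTrace":
        return SweepTrace(
            self.time_ms.copy(), self.current_pA.copy(), self.fs_khz, dict(self.markers)
        )

    # -- I/O -----------------------------------------------------------
    def to_csv(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# synaptiq SweepTrace v1\n")
            fh.write(f"# fs_khz={self.fs_khz!r}\n")
            for key, val in self.markers.items():
                if val is not None:
                    fh.write(f"# {key}={float(val)!r}\n")
            fh.write("time_ms,current_pA\n")
            np.savetxt(fh, np.column_stack([self.time_ms, self.current_pA]),
                       fmt="%.9g", delimiter=",")

    @classmethod
    def from_csv(cls, path) -> "SweepTrace":
        path = Path(path)
        fs = None
        markers: dict = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                body = line[1:].strip()
                if "=" not in body:
                    continue
                key, val = body.split("=", 1)
                key = key.strip()
                if key == "fs_khz":
                    fs = float(val)
                else:
                    markers[key] = float(val)
        df = pd.read_csv(path, comment="#")
        if fs is None:
            fs = 1.0 / float(np.diff(df["time_ms"].to_numpy()[:2])[0])
        return cls(df["time_ms"].to_numpy(), df["current_pA"].to_numpy(), fs, markers)

    def to_hdf5(self, path, group: str = "sweep") -> None:
        import h5py

        with h5py.File(path, "a") as fh:
            if group in fh:
                del fh[group]
            grp = fh.create_group(group)
            grp.create_dataset("current_pA", data=self.current_pA)
            grp.attrs["fs_khz"] = self.fs_khz
            grp.attrs["t_start_ms"] = self.time_ms[0]
            for key, val in self.markers.items():
                if val is not None:
                    grp.attrs[key] = float(val)

    @classmethod
    def from_hdf5(cls, path, group: str = "sweep") -> "SweepTrace":
        import h5py

        with h5py.File(path, "r") as fh:
            grp = fh[group]
            current = grp["current_pA"][()]
            fs = float(grp.attrs["fs_khz"])
            t0 = float(grp.attrs.get("t_start_ms", 0.0))
            markers = {
                k: float(v)
                for k, v in grp.attrs.items()
                if k not in ("fs_khz", "t_start_ms")
            }
        time = t0 + np.arange(current.size) / fs
        return cls(time, current, fs, markers)


@dataclass
class LineProfilePair:
    """Dual-channel fluorescence intensities along a scan line.

    Positions are nm along the line (0 at the first sample, uniform grid);
    intensities are arbitrary fluorescence units (AFU) and non-negative.
    """

    animal_id: str
    position_nm: np.ndarray
    ch1: np.ndarray
    ch2: np.ndarray

    def __post_init__(self):
        self.position_nm = _as_float_array(self.position_nm, "position_nm")
        self.ch1 = _as_float_array(self.ch1, "ch1")
        self.ch2 = _as_float_array(self.ch2, "ch2")
        n = self.position_nm.size
        if self.ch1.size != n or self.ch2.size != n:
            raise ValueError("position and channel arrays must have equal length")
        if n < 3:
            raise ValueError("profile needs at least 3 samples")
        d = np.diff(self.position_nm)
        if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6):
            raise ValueError("positions must be strictly increasing and uniform")
        if np.any(self.ch1 < 0) or np.any(self.ch2 < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def pixel_nm(self) -> float:
        return float(self.position_nm[1] - self.position_nm[0])

    @property
    def n_pixels(self) -> int:
        return self.position_nm.size

    def channel(self, which: int) -> np.ndarray:
        if which not in (1, 2):
            raise ValueError("channel must be 1 or 2")
        return self.ch1 if which == 1 else self.ch2


def write_profiles_csv(pairs: list, path) -> None:
    """Write one or more LineProfilePairs to a single CSV."""
    frames = [
        pd.DataFrame(
            {
                "position_nm": p.position_nm,
                "ch1_afu": p.ch1,
                "ch2_afu": p.ch2,
                "animal_id": p.animal_id,
            }
        )
        for p in pairs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_profiles_csv(path) -> list:
    df = pd.read_csv(path)
    out = []
    for animal, sub in df.groupby("animal_id", sort=False):
        out.append(
            LineProfilePair(
                str(animal),
                sub["position_nm"].to_numpy(),
                sub["ch1_afu"].to_numpy(),
                sub["ch2_afu"].to_numpy(),
            )
        )
    return out


class EMDataset:
    """Docked-vesicle distance measurements grouped by profile and synapse.

    Wraps a DataFrame with one row per docked vesicle, columns
    ``animal, synapse_id, profile_id, distance_nm`` plus optional
    ``genotype`` (default ``"all"``), ``has_dense_projection`` (default True)
    and ``n_total_vesicles`` (per-profile total vesicle count, optional).
    Profiles with a dense projection but no docked vesicles are represented
    by a row with a missing ``distance_nm`` so they still count in the
    per-profile denominators.
    """

    REQUIRED = ("animal", "synapse_id", "profile_id", "distance_nm")

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValueError(f"EMDataset missing column {col!r}")
        if "genotype" not in df.columns:
            df["genotype"] = "all"
        if "has_dense_projection" not in df.columns:
            df["has_dense_projection"] = True
        d = df["distance_nm"]
        if (d.dropna() < 0).any():
            raise ValueError("distances must be non-negative")
        self.df = df

    @property
    def included(self) -> pd.DataFrame:
        """Rows from profiles containing a dense projection."""
        return self.df[self.df["has_dense_projection"].astype(bool)]

    @property
    def vesicles(self) -> pd.DataFrame:
        inc = self.included
        return inc[inc["distance_nm"].notna()]

    @property
    def profiles(self) -> pd.DataFrame:
        """Unique (genotype, animal, synapse_id, profile_id) with dense projection."""
        cols = ["genotype", "animal", "synapse_id", "profile_id"]
        return self.included[cols].drop_duplicates().reset_index(drop=True)

    @property
    def n_profiles(self) -> int:
        return len(self.profiles)

    def for_genotype(self, genotype: str) -> "EMDataset":
        return EMDataset(self.df[self.df["genotype"] == genotype])

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EMDataset":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.df)


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.bool_):
            return bool(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_ground_truth(truth: dict, path) -> None:
    """Write a generator ground-truth record to sidecar JSON."""
    with open(path, "w") as fh:
        json.dump(truth, fh, cls=_NumpyJSONEncoder, indent=1, sort_keys=True)


def read_ground_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
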