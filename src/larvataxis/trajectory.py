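"""Trajectory container and I/O.

A trajectory is the 3-point skeleton (head, centroid, tail) of one larva
tracked at a fixed frame rate.  Positions are in cm, times in seconds.
Tables are read and written as delimited text with a JSON sidecar for
metadata; cohorts can be stored in a single HDF5 file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "read_trajectory", "write_trajectory", "read_cohort_h5", "write_cohort_h5"]

_COLUMNS = ["t", "head_x", "head_y", "centroid_x", "centroid_y", "tail_x", "tail_y"]


@dataclass
class Trajectory:
    t: np.ndarray                # (N,) s, uniform
    head: np.ndarray             # (N, 2) cm
    centroid: np.ndarray         # (N, 2) cm
    tail: np.ndarray             # (N, 2) cm
    frame_rate: float            # Hz
    id: str = "larva-0"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.t)
        for name in ("head", "centroid", "tail"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, 2):
                raise ValueError(f"{name} must have shape ({n}, 2)")
            setattr(self, name, arr)
        self.t = np.asarray(self.t, dtype=float)
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(np.abs(dt - 1.0 / self.frame_rate) > 1e-6):
                raise ValueError("frames are not uniformly sampled at the stated frame rate")

    def __len__(self):
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "head_x": self.head[:, 0],
                "head_y": self.head[:, 1],
                "centroid_x": self.centroid[:, 0],
                "centroid_y": self.centroid[:, 1],
                "tail_x": self.tail[:, 0],
                "tail_y": self.tail[:, 1],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_rate: float, id: str = "larva-0", meta=None):
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trajectory table is missing columns {missing}")
        return cls(
            t=df["t"].to_numpy(float),
            head=df[["head_x", "head_y"]].to_numpy(float),
            centroid=df[["centroid_x", "centroid_y"]].to_numpy(float),
            tail=df[["tail_x", "tail_y"]].to_numpy(float),
            frame_rate=frame_rate,
            id=id,
            meta=dict(meta or {}),
        )


def write_trajectory(traj: Trajectory, path, sep: str = "\t") -> None:
    """Write a trajectory table plus a ``.json`` metadata sidecar."""
    path = Path(path)
    traj.to_frame().to_csv(path, sep=sep, index=False)
    sidecar = {"frame_rate": traj.frame_rate, "id": traj.id, **traj.meta}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1, default=str))


def read_trajectory(path, sep: str = "\t", frame_rate: float | None = None) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    fr = frame_rate or meta.get("frame_rate")
    if fr is None:
        dt = np.median(np.diff(df["t"].to_numpy(float)))
        fr = 1.0 / dt
    return Trajectory.from_frame(df, frame_rate=float(fr), id=str(meta.pop("id", path.stem)), meta=meta)


def write_cohort_h5(trajectories, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for traj in trajectories:
            g = f.create_group(traj.id)
            g.create_dataset("t", data=traj.t)
            g.create_dataset("head", data=traj.head)
            g.create_dataset("centroid", data=traj.centroid)
            g.create_dataset("tail", data=traj.tail)
            g.attrs["frame_rate"] = traj.frame_rate
            g.attrs["meta"] = json.dumps(traj.meta, default=str)


def read_cohort_h5(path) -> list:
    import h5py

    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            out.append(
                Trajectory(
                    t=g["t"][:],
                    head=g["head"][:],
                    centroid=g["centroid"][:],
                    tail=g["tail"][:],
                    frame_rate=float(g.attrs["frame_rate"]),
                    id=name,
                    meta=json.loads(g.attrs.get("meta", "{}")),
                )
            )
    return out


def read_spine_table(path, sep: str = "\t", frame_rate: float | None = None) -> Trajectory:
    """Minimal reader for tracker-style spine tables.

    Expects columns ``t`` and spine points ``x0,y0 .. xN,yN`` ordered head to
    tail; head/centroid/tail are taken as the first, middle and last points.
    """
    df = pd.read_csv(path, sep=sep)
    xcols = sorted((c for c in df.columns if c.startswith("x")), key=lambda c: int(c[1:]))
    ycols = sorted((c for c in df.columns if c.startswith("y")), key=lambda c: int(c[1:]))
    if not xcols or len(xcols) != len(ycols):
        raise ValueError("spine table needs matching x*/y* columns")
    mid = len(xcols) // 2
    t = df["t"].to_numpy(float)
    fr = frame_rate or 1.0 / np.median(np.diff(t))
    pick = lambda xc, yc: np.column_stack([df[xc].to_numpy(float), df[yc].to_numpy(float)])
    return Trajectory(
        t=t,
        head=pick(xcols[0], ycols[0]),
        centroid=pick(xcols[mid], ycols[mid]),
        tail=pick(xcols[-1], ycols[-1]),
        frame_rate=float(fr),
        id=Path(path).stem,
    )
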