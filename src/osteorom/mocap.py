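"""Comparison of empirical joint-angle traces against viable-pose envelopes.

A motion-capture trace (time series of hip FE / ABAD / LAR angles, in the
same sign convention as the pose grid: flexion +, abduction +, external
rotation +) is tested frame by frame against a ROM map: each frame is
snapped to the nearest grid pose and is viable iff that grid pose is. This
answers whether an observed gait stays inside the osteologically possible
envelope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sampling import ROMMap

__all__ = ["JointAngleTrace", "TraceViabilityReport", "load_trace",
           "save_trace", "trace_viability"]


@dataclass
class JointAngleTrace:
    """Ordered hip-angle frames: time (s) plus fe/abad/lar (degrees)."""

    times: np.ndarray       # (N,) strictly increasing, seconds
    fe: np.ndarray          # (N,) degrees
    abad: np.ndarray
    lar: np.ndarray
    condition: str = ""     # substrate / speed label

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64).reshape(-1)
        self.fe = np.asarray(self.fe, dtype=np.float64).reshape(-1)
        self.abad = np.asarray(self.abad, dtype=np.float64).reshape(-1)
        self.lar = np.asarray(self.lar, dtype=np.float64).reshape(-1)
        n = len(self.times)
        if not (len(self.fe) == len(self.abad) == len(self.lar) == n):
            raise ValueError("angle columns must match the time column length")
        if n == 0:
            raise ValueError("trace is empty")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time must be strictly increasing")
        for name, a in (("time", self.times), ("fe", self.fe),
                        ("abad", self.abad), ("lar", self.lar)):
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite values in {name} column")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def angles(self) -> np.ndarray:
        """(N, 3) array ordered (abad, fe, lar) to match the pose grid."""
        return np.column_stack([self.abad, self.fe, self.lar])


def load_trace(path: str | Path) -> JointAngleTrace:
    """Read a trace CSV with header ``time,fe,abad,lar[,condition]``."""
    df = pd.read_csv(path, comment="#")
    required = {"time", "fe", "abad", "lar"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV is missing columns: {sorted(missing)}")
    condition = ""
    if "condition" in df.columns and len(df):
        condition = str(df["condition"].iloc[0])
    return JointAngleTrace(
        times=df["time"].to_numpy(float), fe=df["fe"].to_numpy(float),
        abad=df["abad"].to_numpy(float), lar=df["lar"].to_numpy(float),
        condition=condition,
    )


def save_trace(trace: JointAngleTrace, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time": trace.times, "fe": trace.fe,
                       "abad": trace.abad, "lar": trace.lar})
    if trace.condition:
        df["condition"] = trace.condition
    df.to_csv(path, index=False)
    return path


@dataclass
class TraceViabilityReport:
    frame_viable: np.ndarray            # (N,) bool
    snapped: np.ndarray                 # (N, 3) grid poses (abad, fe, lar)
    out_of_range: np.ndarray            # (N,) bool, frames beyond the grid
    fraction_viable: float
    excursions: list[tuple[int, int]]   # inclusive frame runs of unviability
    condition: str = ""

    def to_frame(self, trace: JointAngleTrace) -> pd.DataFrame:
        return pd.DataFrame({
            "time": trace.times,
            "fe": trace.fe, "abad": trace.abad, "lar": trace.lar,
            "snapped_abad": self.snapped[:, 0],
            "snapped_fe": self.snapped[:, 1],
            "snapped_lar": self.snapped[:, 2],
            "viable": self.frame_viable.astype(int),
            "out_of_range": self.out_of_range.astype(int),
        })

    def summary(self) -> dict:
        return {
            "condition": self.condition,
            "n_frames": int(len(self.frame_viable)),
            "fraction_viable": self.fraction_viable,
            "n_excursions": len(self.excursions),
            "excursions": [[int(a), int(b)] for a, b in self.excursions],
        }

    def save_summary(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")
        return Path(path)


def _snap_axis(values: np.ndarray, axis_values: np.ndarray,
               step: float) -> tuple[np.ndarray, np.ndarray]:
    """Snap to nearest grid value; exact half-step ties break toward zero."""
    lo, hi = axis_values[0], axis_values[-1]
    out_of_range = (values < lo - step / 2) | (values > hi + step / 2)
    frac = (values - lo) / step
    idx = np.round(frac).astype(int)
    # np.round ties to even; enforce tie-toward-zero on exact .5 fractions
    tie = np.isclose(np.abs(frac - np.floor(frac)), 0.5, atol=1e-9)
    if np.any(tie):
        low = np.floor(frac[tie]).astype(int)
        high = low + 1
        cand_low = lo + step * low
        cand_high = lo + step * high
        idx[tie] = np.where(np.abs(cand_low) <= np.abs(cand_high), low, high)
    idx = np.clip(idx, 0, len(axis_values) - 1)
    return axis_values[idx], out_of_range


def trace_viability(trace: JointAngleTrace, rom_map: ROMMap) -> TraceViabilityReport:
    """Classify each frame of *trace* against the ROM map's viable set.

    Frames are snapped to the nearest grid pose (ties toward zero on each
    axis); frames outside the grid ranges are flagged and count as
    unviable. Runs of consecutive unviable frames are reported as
    excursions.
    """
    if trace.n_frames == 0:
        raise ValueError("empty trace")
    grid = rom_map.grid
    snapped_cols = []
    oor = np.zeros(trace.n_frames, dtype=bool)
    for axis, values in (("abad", trace.abad), ("fe", trace.fe),
                         ("lar", trace.lar)):
        snapped, out = _snap_axis(values, grid.axis_values(axis), grid.step)
        snapped_cols.append(snapped)
        oor |= out
    snapped = np.column_stack(snapped_cols)
    viable_set = rom_map.viable_set()
    frame_viable = np.array([
        (not o) and (tuple(np.round(p, 9)) in viable_set)
        for p, o in zip(snapped, oor)
    ])
    excursions: list[tuple[int, int]] = []
    start = None
    for i, v in enumerate(frame_viable):
        if not v and start is None:
            start = i
        elif v and start is not None:
            excursions.append((start, i - 1))
            start = None
    if start is not None:
        excursions.append((start, trace.n_frames - 1))
    return TraceViabilityReport(
        frame_viable=frame_viable,
        snapped=snapped,
        out_of_range=oor,
        fraction_viable=float(frame_viable.mean()),
        excursions=excursions,
        condition=trace.condition,
    )
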