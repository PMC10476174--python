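"""Trajectory and cohort statistics for trophoblast cell tracking.

Sliding-window speed, per-axis directionality, nearest-4 neighborhood
persistence, axial displacement regression, the log-linear developmental
staging regression, and pooled developmental efficiency.  Axis convention:
Y is the crypt axis and downward motion is reported as negative Y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "TrackSet",
    "CohortCounts",
    "sliding_speed",
    "directionality",
    "neighborhood_persistence",
    "displacement_regression",
    "staging_regression",
    "stage_from_count",
    "developmental_efficiency",
]


@dataclass
class TrackSet:
    """3D cell trajectories: one row per (cell, time point).

    Columns: cell_id, t_h, x_um, y_um, z_um.  Frame interval typically 10 or
    15 min of live imaging.
    """

    records: pd.DataFrame
    frame_interval_h: float = 0.25

    REQUIRED = ("cell_id", "t_h", "x_um", "y_um", "z_um")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.records]
        if missing:
            raise ValueError(f"track table missing columns {missing}")
        rec = self.records.sort_values(["cell_id", "t_h"]).reset_index(drop=True)
        if rec.duplicated(["cell_id", "t_h"]).any():
            raise ValueError("duplicate (cell_id, t_h) records")
        self.records = rec

    def positions(self, cell_id) -> pd.DataFrame:
        return self.records[self.records["cell_id"] == cell_id]

    @property
    def cell_ids(self):
        return self.records["cell_id"].unique()

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_interval_h: float = 0.25) -> "TrackSet":
        return cls(pd.read_csv(path), frame_interval_h=frame_interval_h)


@dataclass
class CohortCounts:
    """Per-replicate (successes, totals) with condition labels."""

    counts: pd.DataFrame  # columns: condition, successes, totals

    def __post_init__(self):
        c = self.counts
        for col in ("successes", "totals"):
            if col not in c:
                raise ValueError(f"cohort table missing column {col!r}")
        if ((c["successes"] < 0) | (c["successes"] > c["totals"])).any():
            raise ValueError("require 0 <= successes <= totals")

    @classmethod
    def from_replicates(cls, replicates: Sequence[Tuple[int, int]], condition: str = "") -> "CohortCounts":
        return cls(
            pd.DataFrame(
                [{"condition": condition, "successes": s, "totals": t} for s, t in replicates]
            )
        )


# ---------------------------------------------------------------------------
# Per-cell kinematics
# ---------------------------------------------------------------------------


def _window_steps(tracks: TrackSet, window: float):
    """Displacement vectors over a sliding window per cell.

    Yields (cell_id, t_start, step_vector) at every frame whose partner
    frame ``t + window`` exists in the track (tolerance of 1% of the window
    on the time match).
    """
    tol = 0.01 * window
    for cid, sub in tracks.records.groupby("cell_id", sort=True):
        t = sub["t_h"].to_numpy()
        xyz = sub[["x_um", "y_um", "z_um"]].to_numpy()
        j = np.searchsorted(t, t + window - tol)
        for i in range(len(t)):
            if j[i] < len(t) and abs(t[j[i]] - (t[i] + window)) <= tol:
                yield cid, t[i], xyz[j[i]] - xyz[i]


def sliding_speed(tracks: TrackSet, window: float = 1.0, step: Optional[float] = None) -> pd.DataFrame:
    """Sliding-window cell speed (μm/h).

    ``speed(t) = ||p(t + window) - p(t)|| / window`` evaluated at every
    frame (step defaults to the imaging interval).  Tracks shorter than the
    window contribute no rows.
    """
    rows = [
        {"cell_id": cid, "t_h": t, "speed_um_per_h": float(np.linalg.norm(v)) / window}
        for cid, t, v in _window_steps(tracks, window)
    ]
    df = pd.DataFrame(rows, columns=["cell_id", "t_h", "speed_um_per_h"])
    if step is not None and len(df):
        # subsample to the requested step per cell
        keep = []
        for cid, sub in df.groupby("cell_id"):
            t0 = sub["t_h"].iloc[0]
            keep.append(sub[np.isclose((sub["t_h"] - t0) % step, 0, atol=1e-9) | np.isclose((sub["t_h"] - t0) % step, step, atol=1e-9)])
        df = pd.concat(keep, ignore_index=True)
    return df


def directionality(tracks: TrackSet, axis, window: float = 1.0) -> pd.DataFrame:
    """Directionality of the windowed steps along a reference axis.

    With ``alpha`` the angle in degrees between the step vector and the axis
    unit vector, directionality is ``(180 - alpha) / 90 - 1``: +1 parallel,
    0 orthogonal, -1 anti-parallel.  Zero-length steps are skipped.
    """
    d = np.asarray(axis, dtype=float)
    d /= np.linalg.norm(d)
    rows = []
    for cid, t, v in _window_steps(tracks, window):
        n = np.linalg.norm(v)
        if n == 0:
            continue
        alpha = math.degrees(math.acos(float(np.clip(v @ d / n, -1.0, 1.0))))
        rows.append({"cell_id": cid, "t_h": t, "directionality": (180.0 - alpha) / 90.0 - 1.0})
    return pd.DataFrame(rows, columns=["cell_id", "t_h", "directionality"])


def _nearest4(xyz: np.ndarray, ids: np.ndarray) -> Dict[object, frozenset]:
    """Nearest-4 neighbor sets; distance ties broken by cell-id order."""
    out = {}
    order_key = np.argsort(ids, kind="stable")
    for i in range(len(ids)):
        d = np.linalg.norm(xyz - xyz[i], axis=1)
        d[i] = np.inf
        # sort by (distance, id) for deterministic tie handling
        sel = sorted(range(len(ids)), key=lambda j: (d[j], ids[j]))[:4]
        out[ids[i]] = frozenset(ids[j] for j in sel)
    return out


def neighborhood_persistence(tracks: TrackSet, interval: float = 1.0) -> pd.DataFrame:
    """Fraction of the nearest-4 neighborhood kept between adjacent hours.

    The neighborhood of each cell is its four nearest cells in 3D; the
    persistence between frames one ``interval`` apart is the shared fraction
    of that set, in [0, 1].  Requires at least 5 cells per frame.
    """
    rec = tracks.records
    times = np.sort(rec["t_h"].unique())
    pairs = []
    tol = 0.01 * interval
    for t in times:
        match = times[np.isclose(times, t + interval, atol=tol)]
        if match.size:
            pairs.append((t, match[0]))
    rows = []
    for t0, t1 in pairs:
        f0 = rec[np.isclose(rec["t_h"], t0)]
        f1 = rec[np.isclose(rec["t_h"], t1)]
        common = np.intersect1d(f0["cell_id"].to_numpy(), f1["cell_id"].to_numpy())
        if len(f0) < 5 or len(f1) < 5:
            raise ValueError("neighborhood persistence requires >= 5 cells per frame")
        n0 = _nearest4(f0[["x_um", "y_um", "z_um"]].to_numpy(), f0["cell_id"].to_numpy())
        n1 = _nearest4(f1[["x_um", "y_um", "z_um"]].to_numpy(), f1["cell_id"].to_numpy())
        for cid in common:
            rows.append(
                {
                    "cell_id": cid,
                    "t_h": t0,
                    "persistence": len(n0[cid] & n1[cid]) / 4.0,
                }
            )
    return pd.DataFrame(rows, columns=["cell_id", "t_h", "persistence"])


# ---------------------------------------------------------------------------
# Regressions and cohort summaries
# ---------------------------------------------------------------------------


def displacement_regression(
    tracks: TrackSet, axis, time_origin: str = "track_start", reference: str = "track_start"
) -> Dict[str, float]:
    """OLS of axial displacement against time, pooled over cells.

    Displacement is projected on the axis unit vector, relative to each
    track's first position (``reference="track_start"``) or kept absolute
    (``"none"``); time runs from each track's start
    (``time_origin="track_start"``) or is kept absolute (``"absolute"``).
    Returns slope (μm/h), intercept (μm) and R².
    """
    d = np.asarray(axis, dtype=float)
    d /= np.linalg.norm(d)
    ts, ys = [], []
    for cid, sub in tracks.records.groupby("cell_id"):
        xyz = sub[["x_um", "y_um", "z_um"]].to_numpy()
        proj = (xyz - (xyz[0] if reference == "track_start" else 0.0)) @ d
        t = sub["t_h"].to_numpy()
        ts.append(t - (t[0] if time_origin == "track_start" else 0.0))
        ys.append(proj)
    x = np.concatenate(ts)
    y = np.concatenate(ys)
    if len(x) < 3:
        raise ValueError("need at least 3 points for the regression")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: constant time values")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return {"slope": float(slope), "intercept": float(intercept), "r_squared": r2, "n": len(x)}


def staging_regression(counts: pd.DataFrame, x: str = "stage", y: str = "cell_number") -> Dict[str, float]:
    """Log-linear staging fit ``y = A * exp(k * x)`` by OLS on ``ln y``.

    Matches culture days to in-utero stages through total (or lineage) cell
    numbers; the published total-cell fit has A = 0.133, k = 1.489.
    """
    d = counts[[x, y]].dropna()
    if len(d) < 2:
        raise ValueError("staging regression needs at least 2 points")
    if (d[y] <= 0).any():
        raise ValueError("cell numbers must be positive for the log-linear fit")
    k, lnA = np.polyfit(d[x].to_numpy(dtype=float), np.log(d[y].to_numpy(dtype=float)), 1)
    return {"A": float(np.exp(lnA)), "k": float(k)}


def stage_from_count(count: float, A: float, k: float) -> float:
    """Invert the staging regression: ``x = ln(count / A) / k``."""
    if count <= 0:
        raise ValueError("count must be positive")
    return float(math.log(count / A) / k)


def developmental_efficiency(counts: CohortCounts, condition: Optional[str] = None) -> Dict[str, object]:
    """Pooled percentage of successfully developed embryos.

    ``100 * sum(successes) / sum(totals)`` rounded to the nearest integer
    for reporting (per-replicate fractions are retained); invariant to
    replicate ordering.
    """
    c = counts.counts
    if condition is not None:
        c = c[c["condition"] == condition]
    total = int(c["totals"].sum())
    if total == 0:
        raise ValueError("zero total embryos")
    succ = int(c["successes"].sum())
    return {
        "efficiency_pct": int(round(100.0 * succ / total)),
        "successes": succ,
        "totals": total,
        "per_replicate": (c["successes"] / c["totals"]).tolist(),
    }
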