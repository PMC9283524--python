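"""Trajectory observables for receptor-activation analysis.

RMSD to a reference (optionally after Kabsch superposition), per-particle
RMSF averaged over replicas, TM3-TM6-style activation-distance series with
running averages, active/inactive state classification, dwell segments and
first-passage (deactivation) times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ACTIVE_BAND, INACTIVE_DISTANCE
from .gamd import Trajectory
from .structure_metrics import kabsch

__all__ = [
    "DistanceSeries",
    "StateDwell",
    "rmsd_series",
    "rmsf_profile",
    "activation_distance_series",
    "running_average",
    "classify_states",
    "count_transitions",
]


@dataclass
class DistanceSeries:
    """An activation-distance time series with figure reference lines
    (cryo-EM active band, inactive-receptor distance) attached as metadata."""

    time: np.ndarray
    distance: np.ndarray
    replica: int = 0
    window: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.distance = np.asarray(self.distance, float)
        if np.any(self.distance < 0):
            raise ValueError("distances must be non-negative")

    def smoothed(self, window: Optional[float] = None) -> np.ndarray:
        w = self.window if window is None else window
        return running_average(self.distance, w, time=self.time)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "distance": self.distance,
                             "smoothed": self.smoothed()
                             if self.window > 0 else self.distance})


@dataclass
class StateDwell:
    """Per-frame state labels with dwell segments and deactivation summary.

    Labels are 'active', 'inactive' or 'intermediate'; segment durations sum
    to the trajectory length (frame count x frame interval)."""

    labels: np.ndarray
    segments: list[tuple[str, float, float]]  # (state, start time, duration)
    fraction_active: float
    first_passage_inactive: Optional[float]
    frame_interval: float

    def to_dict(self) -> dict:
        return {"fraction_active": self.fraction_active,
                "first_passage_inactive": self.first_passage_inactive,
                "n_segments": len(self.segments),
                "segments": [{"state": s, "start": t, "duration": d}
                             for s, t, d in self.segments]}


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------

def _particle_view(traj: Trajectory) -> np.ndarray:
    if traj.configurations is None:
        raise ValueError("trajectory carries no configurations")
    n_dof = traj.configurations.shape[1]
    if n_dof % 3 != 0:
        raise ValueError("configurations are not 3D particle coordinates")
    return traj.configurations.reshape(traj.n_frames, n_dof // 3, 3)


def rmsd_series(traj: Trajectory, reference: np.ndarray,
                selection: Optional[Sequence[int]] = None,
                superpose: bool = False) -> np.ndarray:
    """Per-frame RMSD (Å) of selected particles to a reference configuration,
    optionally after least-squares superposition on the selection."""
    frames = _particle_view(traj)
    ref = np.asarray(reference, float).reshape(-1, 3)
    sel = np.arange(frames.shape[1]) if selection is None else np.asarray(selection)
    if sel.size == 0:
        raise ValueError("empty selection")
    if ref.shape[0] == frames.shape[1]:
        ref = ref[sel]
    elif ref.shape[0] != sel.size:
        raise ValueError("reference size does not match the selection")
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        mob = frames[i, sel]
        if superpose:
            out[i], _, _ = kabsch(mob, ref)
        else:
            out[i] = math.sqrt(float(np.mean(np.sum((mob - ref) ** 2, axis=1))))
    return out


def rmsf_profile(trajectories: Sequence[Trajectory],
                 selection: Optional[Sequence[int]] = None,
                 superpose: bool = False) -> np.ndarray:
    """Per-particle RMSF (Å): within each replica, fluctuation about that
    replica's mean structure; then the arithmetic mean across replicas."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    per_replica = []
    for traj in trajectories:
        frames = _particle_view(traj)
        if frames.shape[0] == 0:
            raise ValueError("empty trajectory")
        sel = (np.arange(frames.shape[1]) if selection is None
               else np.asarray(selection))
        coords = frames[:, sel]
        if superpose:
            ref = coords[0]
            aligned = np.empty_like(coords)
            for i in range(coords.shape[0]):
                _, R, t = kabsch(coords[i], ref)
                aligned[i] = coords[i] @ R.T + t
            coords = aligned
        mean = coords.mean(axis=0)
        rmsf = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
        per_replica.append(rmsf)
    return np.mean(per_replica, axis=0)


# ---------------------------------------------------------------------------
# Activation distance
# ---------------------------------------------------------------------------

def activation_distance_series(traj: Trajectory, cv_index: int = 0,
                               atom_indices: Optional[tuple[int, int]] = None,
                               inactive_ref: float = INACTIVE_DISTANCE,
                               active_band: tuple[float, float] = ACTIVE_BAND,
                               window: float = 0.0) -> DistanceSeries:
    """TM3-TM6-style distance per frame.

    Toy mode (default) passes through the recorded collective variable;
    structure-backed mode computes the distance between two labeled particles
    when ``atom_indices`` is given. Reference lines (inactive distance,
    cryo-EM active band) travel in the metadata.
    """
    if atom_indices is not None:
        frames = _particle_view(traj)
        i, j = atom_indices
        dist = np.linalg.norm(frames[:, i] - frames[:, j], axis=1)
    else:
        if traj.cv.shape[1] <= cv_index:
            raise ValueError("trajectory carries no such collective variable")
        dist = traj.cv[:, cv_index].copy()
    return DistanceSeries(
        time=traj.time.copy(), distance=dist, replica=traj.replica,
        window=window,
        metadata={"inactive_ref": inactive_ref,
                  "active_band": list(active_band)})


def running_average(series, window: float, time=None) -> np.ndarray:
    """Centered moving average over all samples within +-window/2; edges use
    the truncated window. ``window`` is in time units (the sampling interval
    when ``time`` is omitted counts as 1 per sample)."""
    y = np.asarray(series, float)
    t = np.arange(y.size, dtype=float) if time is None else np.asarray(time, float)
    if y.size == 0:
        return y.copy()
    dt = np.min(np.diff(t)) if y.size > 1 else 1.0
    if window < dt - 1e-12:
        raise ValueError("window must be at least the sampling interval")
    half = window / 2.0
    csum = np.concatenate([[0.0], np.cumsum(y)])
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    return (csum[hi] - csum[lo]) / (hi - lo)


# ---------------------------------------------------------------------------
# State classification
# ---------------------------------------------------------------------------

def classify_states(series: DistanceSeries,
                    inactive_ref: Optional[float] = None,
                    active_band: Optional[tuple[float, float]] = None,
                    margin: float = 1.0,
                    window: Optional[float] = None) -> StateDwell:
    """Label frames active / inactive / intermediate on the running-averaged
    series and compute dwell segments and the first-passage (deactivation)
    time.

    Frames within ``margin`` of the inactive reference are inactive; frames
    inside the active band are active; everything else is intermediate. The
    smoothing suppresses single-frame recrossings.
    """
    meta = series.metadata
    if inactive_ref is None:
        inactive_ref = meta.get("inactive_ref", INACTIVE_DISTANCE)
    if active_band is None:
        active_band = tuple(meta.get("active_band", ACTIVE_BAND))
    if inactive_ref >= active_band[0]:
        raise ValueError("inactive reference must lie below the active band")
    if inactive_ref + margin >= active_band[0]:
        raise ValueError("overlapping state definitions: inactive margin "
                         "reaches into the active band")
    w = series.window if window is None else window
    d = series.smoothed(w) if w and w > 0 else series.distance
    labels = np.full(d.size, "intermediate", dtype=object)
    labels[np.abs(d - inactive_ref) <= margin] = "inactive"
    labels[(d >= active_band[0]) & (d <= active_band[1])] = "active"

    n = d.size
    if n > 1:
        frame_interval = float(np.median(np.diff(series.time)))
    else:
        frame_interval = float(series.time[0]) if n else 0.0
    segments: list[tuple[str, float, float]] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            segments.append((str(labels[start]), float(series.time[start]),
                             (i - start) * frame_interval))
            start = i
    fraction_active = float(np.mean(labels == "active")) if n else 0.0
    inactive_hits = np.nonzero(labels == "inactive")[0]
    first_passage = float(series.time[inactive_hits[0]]) if inactive_hits.size else None
    return StateDwell(labels=np.asarray(labels), segments=segments,
                      fraction_active=fraction_active,
                      first_passage_inactive=first_passage,
                      frame_interval=frame_interval)


def count_transitions(dwell: StateDwell) -> int:
    """Number of inactive<->active transitions (intermediate frames are
    ignored; a transition is a change between consecutive non-intermediate
    states)."""
    core = [s for s in dwell.labels if s != "intermediate"]
    return sum(1 for a, b in zip(core, core[1:]) if a != b)
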