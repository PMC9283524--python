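"""Cumulant-expansion reweighting of boosted trajectories.

Recovers unbiased free-energy profiles from Gaussian-accelerated runs: the
biased histogram along the collective variable(s) is corrected per bin by the
second-order cumulant expansion of <exp(beta dV)>,

    F_j = -kBT ln p*_j - C1_j - (beta/2) C2_j,

with C1 the bin mean and C2 the bin variance of the total applied boost.
Bins with fewer pooled frames than the cutoff are excluded; the profile is
anchored so the lowest included bin is zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .config import kbt
from .gamd import Trajectory

__all__ = ["PMFProfile", "reweight_pmf", "anharmonicity_check"]


@dataclass
class PMFProfile:
    """Binned, reweighted free-energy profile (kcal/mol).

    ``free_energy`` is NaN at excluded bins; the minimum over included bins
    is zero.
    """

    dimension: int
    bin_edges: tuple[np.ndarray, ...]
    free_energy: np.ndarray
    counts: np.ndarray
    excluded: np.ndarray
    temperature: float
    min_frames: int
    cumulant_order: int = 2

    def bin_centers(self, axis: int = 0) -> np.ndarray:
        e = self.bin_edges[axis]
        return 0.5 * (e[:-1] + e[1:])

    def minimum_location(self, window: Optional[tuple[float, float]] = None):
        """Coordinates of the lowest included bin (1D: a float), optionally
        restricted to a window on the first axis; None if no included bin."""
        f = self.free_energy.copy()
        f[self.excluded] = np.nan
        if window is not None:
            centers = self.bin_centers(0)
            mask = (centers < window[0]) | (centers > window[1])
            f[mask] = np.nan
        if np.all(np.isnan(f)):
            return None
        idx = np.unravel_index(np.nanargmin(f), f.shape)
        coords = tuple(self.bin_centers(ax)[i] for ax, i in enumerate(idx))
        return coords[0] if self.dimension == 1 else coords

    def local_minima(self) -> list[tuple[float, float]]:
        """1D only: (center, F) of included bins lower than both included
        neighbors."""
        if self.dimension != 1:
            raise ValueError("local_minima is defined for 1D profiles")
        centers = self.bin_centers(0)
        f = np.where(self.excluded, np.nan, self.free_energy)
        out = []
        for i in range(len(f)):
            if math.isnan(f[i]):
                continue
            left = f[i - 1] if i > 0 else np.nan
            right = f[i + 1] if i < len(f) - 1 else np.nan
            if (math.isnan(left) or f[i] <= left) and (math.isnan(right) or f[i] <= right):
                # require at least one real neighbor comparison
                if not (math.isnan(left) and math.isnan(right)):
                    out.append((float(centers[i]), float(f[i])))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        if self.dimension == 1:
            return pd.DataFrame({
                "bin_center": self.bin_centers(0),
                "free_energy_kcal_mol": self.free_energy,
                "frames": self.counts,
                "excluded": self.excluded,
            })
        c0 = self.bin_centers(0)
        c1 = self.bin_centers(1)
        g0, g1 = np.meshgrid(c0, c1, indexing="ij")
        return pd.DataFrame({
            "bin_center": g0.ravel(),
            "bin_center2": g1.ravel(),
            "free_energy_kcal_mol": self.free_energy.ravel(),
            "frames": self.counts.ravel(),
            "excluded": self.excluded.ravel(),
        })

    def write_csv(self, path) -> None:
        path = str(path)
        self.to_dataframe().to_csv(path, index=False)
        meta = {"dimension": self.dimension, "temperature": self.temperature,
                "cumulant_order": self.cumulant_order,
                "min_frames": self.min_frames}
        with open(path + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)


def _edges(values: np.ndarray, width: float) -> np.ndarray:
    lo = math.floor(values.min() / width) * width
    hi = math.ceil(values.max() / width) * width
    if hi <= lo:
        hi = lo + width
    n = int(round((hi - lo) / width))
    return lo + width * np.arange(n + 1)


def reweight_pmf(trajectories: Sequence[Trajectory], cv_indices=(0,),
                 bin_width=0.1, min_frames: int = 1,
                 temperature: Optional[float] = None) -> PMFProfile:
    """Pool frames from all trajectories and reweight into a 1D or 2D PMF.

    ``cv_indices`` selects the collective-variable columns; ``bin_width`` is
    a scalar or per-axis sequence in Å. The boost used for reweighting is the
    total applied boost (the sum of the dual-boost components), the quantity
    that biases the sampled distribution. Bins with fewer than ``min_frames``
    pooled frames are flagged excluded and carry no free energy.
    """
    if not trajectories:
        raise ValueError("no trajectories given")
    cv_indices = tuple(cv_indices)
    ndim = len(cv_indices)
    if ndim not in (1, 2):
        raise ValueError("only 1D and 2D profiles are supported")
    for traj in trajectories:
        if traj.cv.shape[1] <= max(cv_indices):
            raise ValueError(
                f"trajectory carries {traj.cv.shape[1]} collective variables; "
                f"cannot select {cv_indices}")
    if temperature is None:
        temperature = trajectories[0].temperature
    widths = ([float(bin_width)] * ndim if np.isscalar(bin_width)
              else [float(w) for w in bin_width])

    cv = np.concatenate([t.cv[:, list(cv_indices)] for t in trajectories])
    dv = np.concatenate([t.total_boost for t in trajectories])
    edges = tuple(_edges(cv[:, ax], widths[ax]) for ax in range(ndim))
    shape = tuple(len(e) - 1 for e in edges)

    # flat bin index per frame
    flat = np.zeros(len(cv), dtype=np.int64)
    for ax in range(ndim):
        idx = np.clip(np.searchsorted(edges[ax], cv[:, ax], side="right") - 1,
                      0, shape[ax] - 1)
        flat = flat * shape[ax] + idx

    size = int(np.prod(shape))
    counts = np.bincount(flat, minlength=size).astype(float)
    sum_dv = np.bincount(flat, weights=dv, minlength=size)
    sum_dv2 = np.bincount(flat, weights=dv * dv, minlength=size)

    with np.errstate(invalid="ignore", divide="ignore"):
        c1 = np.where(counts > 0, sum_dv / np.maximum(counts, 1), 0.0)
        # unbiased variance; single-frame bins get C2 = 0
        var_num = sum_dv2 - counts * c1 * c1
        c2 = np.where(counts > 1, var_num / np.maximum(counts - 1, 1), 0.0)
        c2 = np.maximum(c2, 0.0)

    kt = kbt(temperature)
    beta = 1.0 / kt
    excluded = counts < min_frames
    if np.all(excluded):
        raise ValueError("empty profile: no bin reaches the frame cutoff")
    with np.errstate(divide="ignore"):
        logp = np.where(counts > 0, np.log(counts / counts.sum()), -np.inf)
    f = -kt * logp - c1 - 0.5 * beta * c2
    f[excluded] = np.nan
    f = f - np.nanmin(f)

    return PMFProfile(
        dimension=ndim, bin_edges=edges,
        free_energy=f.reshape(shape), counts=counts.reshape(shape),
        excluded=excluded.reshape(shape), temperature=temperature,
        min_frames=min_frames)


def anharmonicity_check(dv_samples_per_bin: Sequence[np.ndarray],
                        sigma0: float, kurtosis_threshold: float = 1.0,
                        min_frames: int = 1) -> list[bool]:
    """Diagnostic guarding the second-order truncation: flags bins whose
    boost samples have SD above sigma0 or excess kurtosis above the
    threshold. Flagged bins are reported, never removed."""
    flags = []
    for samples in dv_samples_per_bin:
        samples = np.asarray(samples, float)
        if samples.size < max(min_frames, 2):
            flags.append(False)
            continue
        sd = float(np.std(samples, ddof=1))
        if sd == 0.0:
            flags.append(False)
            continue
        kurt = float(sp_stats.kurtosis(samples, fisher=True, bias=False))
        flags.append(sd > sigma0 or kurt > kurtosis_threshold)
    return flags
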