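"""Gaussian-accelerated Langevin dynamics engine.

Implements the boost-potential machinery of Gaussian accelerated MD (GaMD):
whenever the system potential V falls below a reference energy E, a harmonic
boost

    dV = 1/2 * k * (E - V)^2,   V < E   (else 0)

is added, with E and k determined automatically from running statistics of V
so that (i) the boosted surface preserves the energy ordering of states,
(ii) energy differences are contracted, and (iii) the SD of dV stays below a
user limit sigma0 so second-order cumulant reweighting remains accurate.

"Dual boost" applies one such boost to the dihedral energy component and a
second to the total potential. Dynamics are integrated with a BAOAB Langevin
splitting on the modified potential V* = V + dV; forces on V* are obtained by
scaling the unbiased forces analytically (no numerical differentiation).
"""

from __future__ import annotations

import json
import math
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import KB, ProtocolConfig, derive_seed, kbt

__all__ = [
    "PotentialModel",
    "PotentialStats",
    "RunningStats",
    "GaMDParams",
    "BoostSpec",
    "Trajectory",
    "ProtocolResult",
    "collect_statistics",
    "compute_boost_params",
    "boost_energy",
    "boost_force_scale",
    "propagate",
    "run_gamd_protocol",
]


# ---------------------------------------------------------------------------
# The system interface
# ---------------------------------------------------------------------------

class PotentialModel(ABC):
    """An evaluable energy surface with a separable dihedral-like component.

    Configurations are flat float arrays of length ``n_dof``. Models report
    their total potential and, separately, the dihedral energetic component
    (zero for collective-variable landscapes) so that the dual-boost scheme
    can treat the two independently.
    """

    n_dof: int

    @property
    def masses(self) -> np.ndarray:
        return np.ones(self.n_dof)

    @abstractmethod
    def components(self, x: np.ndarray) -> tuple[float, float, np.ndarray, np.ndarray]:
        """Return (v_total, v_dihedral, grad_total, grad_dihedral) at x."""

    def energy(self, x) -> float:
        return self.components(np.asarray(x, float))[0]

    def gradient(self, x) -> np.ndarray:
        return self.components(np.asarray(x, float))[2]

    def dihedral_energy(self, x) -> float:
        return self.components(np.asarray(x, float))[1]

    @abstractmethod
    def collective_variables(self, x: np.ndarray) -> np.ndarray:
        """Map a configuration to its collective-variable values."""

    @abstractmethod
    def initial_configuration(self) -> np.ndarray:
        """Default starting configuration for simulations."""

    @property
    def has_dihedral_component(self) -> bool:
        return False


# ---------------------------------------------------------------------------
# Potential-energy statistics
# ---------------------------------------------------------------------------

@dataclass
class PotentialStats:
    """Running summary of a potential-energy component: extrema, mean and
    population SD, recomputed every ``update_interval`` steps during
    adaptation."""

    v_max: float
    v_min: float
    v_avg: float
    sigma_v: float
    n_samples: int
    update_interval: int = 0

    def __post_init__(self):
        if not (self.v_min <= self.v_avg <= self.v_max):
            raise ValueError("requires v_min <= v_avg <= v_max")
        if self.sigma_v < 0:
            raise ValueError("sigma_v must be >= 0")


class RunningStats:
    """Accumulates energy samples; extrema are running (never reset) while
    mean/SD are over all accumulated samples."""

    def __init__(self):
        self.n = 0
        self._sum = 0.0
        self._sumsq = 0.0
        self.v_max = -math.inf
        self.v_min = math.inf

    def update(self, values: np.ndarray) -> None:
        values = np.asarray(values, float)
        if values.size == 0:
            return
        self.n += values.size
        self._sum += float(values.sum())
        self._sumsq += float((values * values).sum())
        self.v_max = max(self.v_max, float(values.max()))
        self.v_min = min(self.v_min, float(values.min()))

    def snapshot(self, update_interval: int = 0) -> PotentialStats:
        if self.n == 0:
            raise ValueError("insufficient statistics: no samples accumulated")
        mean = self._sum / self.n
        var = max(self._sumsq / self.n - mean * mean, 0.0)
        return PotentialStats(
            v_max=self.v_max, v_min=self.v_min, v_avg=mean,
            sigma_v=math.sqrt(var), n_samples=self.n,
            update_interval=update_interval,
        )


def collect_statistics(energy_series: Sequence[float],
                       update_interval: int = 0) -> PotentialStats:
    """Summarize an energy series into PotentialStats.

    sigma_v is the population SD (n denominator).
    """
    series = np.asarray(list(energy_series), float)
    if series.size == 0:
        raise ValueError("insufficient statistics: empty energy series")
    rs = RunningStats()
    rs.update(series)
    return rs.snapshot(update_interval)


# ---------------------------------------------------------------------------
# Boost parameters
# ---------------------------------------------------------------------------

@dataclass
class GaMDParams:
    """Adaptive boost parameters for one energy component.

    Satisfies v_max <= E <= v_min + 1/k with k = k0/(v_max - v_min),
    0 < k0 <= 1.
    """

    threshold_e: float
    k0: float
    force_constant_k: float
    sigma0: float
    bound_mode: str = "lower"
    # provenance: statistics the parameters were derived from
    v_max: float = math.nan
    v_min: float = math.nan

    def __post_init__(self):
        if not (0.0 < self.k0 <= 1.0):
            raise ValueError("k0 must lie in (0, 1]")
        if self.force_constant_k <= 0:
            raise ValueError("force constant must be positive")
        if math.isfinite(self.v_max) and math.isfinite(self.v_min):
            upper = self.v_min + 1.0 / self.force_constant_k
            if not (self.v_max <= self.threshold_e + 1e-9
                    and self.threshold_e <= upper + 1e-9):
                raise ValueError(
                    f"threshold E={self.threshold_e} violates "
                    f"v_max <= E <= v_min + 1/k = [{self.v_max}, {upper}]")

    def to_dict(self) -> dict:
        return {
            "threshold_e": self.threshold_e, "k0": self.k0,
            "force_constant_k": self.force_constant_k, "sigma0": self.sigma0,
            "bound_mode": self.bound_mode, "v_max": self.v_max,
            "v_min": self.v_min,
        }


def compute_boost_params(stats: PotentialStats, sigma0: float,
                         bound_mode: str = "lower") -> GaMDParams:
    """Determine E and k from potential statistics.

    lower mode: E = v_max and k0 = min(1, (sigma0/sigma_v) *
    (v_max - v_min)/(v_max - v_avg)).  upper mode: k0'' =
    (1 - sigma0/sigma_v) * (v_max - v_min)/(v_avg - v_min); if k0'' lies in
    (0, 1] it is used with E = v_min + 1/k, otherwise the lower-bound formula
    is the fallback.
    """
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    if bound_mode not in ("lower", "upper"):
        raise ValueError(f"unknown bound_mode {bound_mode!r}")
    vmax, vmin, vavg, sv = stats.v_max, stats.v_min, stats.v_avg, stats.sigma_v
    span = vmax - vmin
    if span <= 0:
        raise ValueError("degenerate statistics: v_max == v_min")

    def lower_params() -> GaMDParams:
        if sv == 0.0 or vmax == vavg:
            k0 = 1.0
        else:
            k0 = min(1.0, (sigma0 / sv) * span / (vmax - vavg))
        k = k0 / span
        return GaMDParams(threshold_e=vmax, k0=k0, force_constant_k=k,
                          sigma0=sigma0, bound_mode="lower",
                          v_max=vmax, v_min=vmin)

    if bound_mode == "lower":
        return lower_params()
    # upper bound: requires nonzero sigma_v and vavg > vmin
    if sv > 0.0 and vavg > vmin:
        k0pp = (1.0 - sigma0 / sv) * span / (vavg - vmin)
        if 0.0 < k0pp <= 1.0:
            k = k0pp / span
            return GaMDParams(threshold_e=vmin + 1.0 / k, k0=k0pp,
                              force_constant_k=k, sigma0=sigma0,
                              bound_mode="upper", v_max=vmax, v_min=vmin)
    return lower_params()


def boost_energy(v: float, params: GaMDParams) -> float:
    """dV = 1/2 k (E - V)^2 below the threshold, zero at or above it."""
    if v < params.threshold_e:
        d = params.threshold_e - v
        return 0.5 * params.force_constant_k * d * d
    return 0.0


def boost_force_scale(v: float, params: GaMDParams) -> float:
    """Factor scaling the unbiased force on the boosted surface:
    dV*/dV = 1 - k (E - V) for V < E, else 1."""
    if v < params.threshold_e:
        return 1.0 - params.force_constant_k * (params.threshold_e - v)
    return 1.0


@dataclass
class BoostSpec:
    """Dual-boost specification: independent parameters for the dihedral
    component and for the total potential."""

    total_params: Optional[GaMDParams] = None
    dihedral_params: Optional[GaMDParams] = None
    mode: str = "total_only"  # "dual" | "total_only"

    def __post_init__(self):
        if self.mode == "dual" and (self.total_params is None
                                    or self.dihedral_params is None):
            raise ValueError("dual mode needs both parameter sets")
        if self.mode == "total_only" and self.total_params is None:
            raise ValueError("total_only mode needs total_params")

    def boost(self, v_total: float, v_dihedral: float) -> tuple[float, float]:
        """Return (dV_total_term, dV_dihedral_term)."""
        dv_t = boost_energy(v_total, self.total_params)
        dv_d = (boost_energy(v_dihedral, self.dihedral_params)
                if self.mode == "dual" else 0.0)
        return dv_t, dv_d

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "total_params": self.total_params.to_dict() if self.total_params else None,
            "dihedral_params": (self.dihedral_params.to_dict()
                                if self.dihedral_params else None),
        }


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Frames recorded every ``stride`` steps of a Langevin run.

    ``dv_total``/``dv_dihedral`` are the two boost terms (both zero for
    unboosted runs); the total applied boost is their sum. Configurations are
    kept in memory for RMSD/RMSF analysis but are not persisted to CSV.
    """

    time: np.ndarray
    configurations: Optional[np.ndarray]
    v_total: np.ndarray
    v_dihedral: np.ndarray
    dv_total: np.ndarray
    dv_dihedral: np.ndarray
    cv: np.ndarray                     # (n_frames, n_cv)
    temperature: float
    seed: int
    stage: str
    dt: float
    stride: int
    replica: int = 0
    final_position: Optional[np.ndarray] = None
    final_velocity: Optional[np.ndarray] = None
    step_energies: Optional[tuple[np.ndarray, np.ndarray]] = None

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def total_boost(self) -> np.ndarray:
        return self.dv_total + self.dv_dihedral

    @property
    def frame_interval(self) -> float:
        return self.dt * self.stride

    def to_dataframe(self) -> pd.DataFrame:
        d = {
            "frame": np.arange(self.n_frames),
            "time": self.time,
            "V_total": self.v_total,
            "V_dihedral": self.v_dihedral,
            "dV_total": self.dv_total,
            "dV_dihedral": self.dv_dihedral,
        }
        for j in range(self.cv.shape[1]):
            d[f"cv{j + 1}"] = self.cv[:, j]
        return pd.DataFrame(d)

    def write_csv(self, path, boost: Optional[BoostSpec] = None,
                  extra_meta: Optional[dict] = None) -> None:
        """Columnar CSV plus a JSON sidecar with run metadata."""
        path = str(path)
        self.to_dataframe().to_csv(path, index=False)
        meta = {
            "temperature": self.temperature, "seed": self.seed,
            "stage": self.stage, "dt": self.dt, "stride": self.stride,
            "replica": self.replica,
            "boost": boost.to_dict() if boost else None,
        }
        if extra_meta:
            meta.update(extra_meta)
        with open(path + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def read_csv(cls, path) -> "Trajectory":
        path = str(path)
        df = pd.read_csv(path)
        with open(path + ".json") as fh:
            meta = json.load(fh)
        cv_cols = [c for c in df.columns if c.startswith("cv")]
        return cls(
            time=df["time"].to_numpy(), configurations=None,
            v_total=df["V_total"].to_numpy(),
            v_dihedral=df["V_dihedral"].to_numpy(),
            dv_total=df["dV_total"].to_numpy(),
            dv_dihedral=df["dV_dihedral"].to_numpy(),
            cv=df[cv_cols].to_numpy(),
            temperature=meta["temperature"], seed=meta["seed"],
            stage=meta["stage"], dt=meta["dt"], stride=meta["stride"],
            replica=meta.get("replica", 0),
        )


# ---------------------------------------------------------------------------
# Langevin (BAOAB) propagation on the boosted surface
# ---------------------------------------------------------------------------

def propagate(model: PotentialModel, start, boost: Optional[BoostSpec],
              steps: int, dt: float, temperature: float, friction: float,
              stride: int, seed: int, stage: str = "production",
              initial_velocity: Optional[np.ndarray] = None,
              replica: int = 0,
              keep_step_energies: bool = False) -> Trajectory:
    """BAOAB Langevin trajectory on V* (or on V when ``boost`` is None).

    Frames are recorded at the end of every ``stride``-th step. Identical
    inputs and seed give an identical trajectory. Raises on non-finite
    energies, naming the failing step.
    """
    if steps < stride:
        raise ValueError("steps must be >= stride")
    x = np.array(start, float).ravel().copy()
    if x.size != model.n_dof:
        raise ValueError(f"start has {x.size} dof, model needs {model.n_dof}")
    rng = np.random.default_rng(seed)
    m = model.masses
    kt = kbt(temperature)
    if initial_velocity is None:
        v = rng.normal(0.0, np.sqrt(kt / m))
    else:
        v = np.array(initial_velocity, float).copy()

    c1 = math.exp(-friction * dt)
    c2 = np.sqrt(kt * (1.0 - c1 * c1) / m)
    noise = rng.standard_normal((steps, x.size))

    n_frames = steps // stride
    t_out = np.empty(n_frames)
    x_out = np.empty((n_frames, x.size))
    vt_out = np.empty(n_frames)
    vd_out = np.empty(n_frames)
    dvt_out = np.empty(n_frames)
    dvd_out = np.empty(n_frames)
    cv0 = model.collective_variables(x)
    cv_out = np.empty((n_frames, cv0.size))
    if keep_step_energies:
        evt = np.empty(steps)
        evd = np.empty(steps)

    def force_and_energies(xc):
        v_tot, v_dih, g_tot, g_dih = model.components(xc)
        if boost is None:
            return -g_tot, v_tot, v_dih, 0.0, 0.0
        dv_t, dv_d = boost.boost(v_tot, v_dih)
        s_t = boost_force_scale(v_tot, boost.total_params)
        f = -(g_tot * s_t)
        if boost.mode == "dual":
            s_d = boost_force_scale(v_dih, boost.dihedral_params)
            f = f - g_dih * (s_d - 1.0)
        return f, v_tot, v_dih, dv_t, dv_d

    f, v_tot, v_dih, dv_t, dv_d = force_and_energies(x)
    half = 0.5 * dt
    frame = 0
    for step in range(steps):
        v += half * f / m
        x += half * v
        v = c1 * v + c2 * noise[step]
        x += half * v
        f, v_tot, v_dih, dv_t, dv_d = force_and_energies(x)
        v += half * f / m
        if not math.isfinite(v_tot):
            raise RuntimeError(
                f"non-finite potential energy at step {step + 1} "
                f"(stage={stage}, seed={seed}); reduce dt")
        if keep_step_energies:
            evt[step] = v_tot
            evd[step] = v_dih
        if (step + 1) % stride == 0:
            t_out[frame] = (step + 1) * dt
            x_out[frame] = x
            vt_out[frame] = v_tot
            vd_out[frame] = v_dih
            dvt_out[frame] = dv_t
            dvd_out[frame] = dv_d
            cv_out[frame] = model.collective_variables(x)
            frame += 1

    return Trajectory(
        time=t_out, configurations=x_out, v_total=vt_out, v_dihedral=vd_out,
        dv_total=dvt_out, dv_dihedral=dvd_out, cv=cv_out,
        temperature=temperature, seed=seed, stage=stage, dt=dt,
        stride=stride, replica=replica,
        final_position=x.copy(), final_velocity=v.copy(),
        step_energies=(evt, evd) if keep_step_energies else None,
    )


# ---------------------------------------------------------------------------
# Staged protocol: cMD -> boosted equilibration -> production replicas
# ---------------------------------------------------------------------------

@dataclass
class ProtocolResult:
    production: list[Trajectory]
    boost: BoostSpec
    cmd_trajectory: Trajectory
    equilibration: list[Trajectory]
    params_history: list[dict] = field(default_factory=list)


def _make_boost(model: PotentialModel, stats_total: RunningStats,
                stats_dih: RunningStats, cfg: ProtocolConfig) -> BoostSpec:
    total = compute_boost_params(stats_total.snapshot(cfg.update_interval),
                                 cfg.sigma0_total, cfg.bound_mode)
    dual = (model.has_dihedral_component
            and stats_dih.v_max > stats_dih.v_min)
    if dual:
        dih = compute_boost_params(stats_dih.snapshot(cfg.update_interval),
                                   cfg.sigma0_dihedral, cfg.bound_mode)
        return BoostSpec(total_params=total, dihedral_params=dih, mode="dual")
    return BoostSpec(total_params=total, mode="total_only")


def run_gamd_protocol(model: PotentialModel, cfg: ProtocolConfig,
                      master_seed: int, start=None,
                      label: str = "system") -> ProtocolResult:
    """Run the staged GaMD protocol on a model.

    Stage 1 (cMD) collects potential statistics unboosted; stage 2 applies
    the boost and refreshes E and k from accumulating statistics every
    ``update_interval`` steps; stage 3 runs ``n_replicas`` production
    trajectories with frozen parameters and randomized initial velocities.
    Dual boost is used when the model has a non-degenerate dihedral
    component, otherwise the run degrades gracefully to a total-potential
    boost only.
    """
    for name, steps in (("cmd", cfg.cmd_steps), ("equilibration", cfg.equil_steps),
                        ("production", cfg.production_steps)):
        if steps < cfg.update_interval:
            raise ValueError(
                f"{name} stage ({steps} steps) shorter than the update "
                f"interval ({cfg.update_interval})")

    if start is None:
        start = model.initial_configuration()

    # Stage 1: conventional MD for initial statistics
    cmd = propagate(model, start, None, cfg.cmd_steps, cfg.dt,
                    cfg.temperature, cfg.friction, cfg.stride,
                    seed=derive_seed(master_seed, label, "cmd"),
                    stage="cmd", keep_step_energies=True)
    stats_total = RunningStats()
    stats_dih = RunningStats()
    stats_total.update(cmd.step_energies[0])
    stats_dih.update(cmd.step_energies[1])

    # Stage 2: boosted equilibration, parameters refreshed every update point
    history: list[dict] = []
    equil_chunks: list[Trajectory] = []
    x, vel = cmd.final_position, cmd.final_velocity
    n_chunks = cfg.equil_steps // cfg.update_interval
    boost = _make_boost(model, stats_total, stats_dih, cfg)
    for i in range(n_chunks):
        history.append(boost.to_dict())
        chunk = propagate(model, x, boost, cfg.update_interval, cfg.dt,
                          cfg.temperature, cfg.friction, cfg.stride,
                          seed=derive_seed(master_seed, label, "equil", i),
                          stage="equilibration", initial_velocity=vel,
                          keep_step_energies=True)
        equil_chunks.append(chunk)
        if cfg.accumulate_statistics:
            stats_total.update(chunk.step_energies[0])
            stats_dih.update(chunk.step_energies[1])
        else:
            stats_total = RunningStats()
            stats_dih = RunningStats()
            stats_total.update(chunk.step_energies[0])
            stats_dih.update(chunk.step_energies[1])
        x, vel = chunk.final_position, chunk.final_velocity
        boost = _make_boost(model, stats_total, stats_dih, cfg)

    # Stage 3: production replicas with frozen parameters and fresh velocities
    prod_start = (np.array(start, float).ravel()
                  if cfg.production_start == "initial" else x)
    production = []
    for r in range(cfg.n_replicas):
        traj = propagate(model, prod_start, boost, cfg.production_steps, cfg.dt,
                         cfg.temperature, cfg.friction, cfg.stride,
                         seed=derive_seed(master_seed, label, "production", r),
                         stage="production", replica=r)
        production.append(traj)

    return ProtocolResult(production=production, boost=boost,
                          cmd_trajectory=cmd, equilibration=equil_chunks,
                          params_history=history)
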