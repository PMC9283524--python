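"""Shared constants, experiment configuration and seed derivation.

All energies are in kcal/mol, distances in Å, and toy dynamics run in
"toy ps" — an internal time unit related to the nanosecond axes of
all-atom GPCR simulations only through :data:`TOY_PS_PER_NS` (no claim of
physical time equivalence is made).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

# Boltzmann constant in kcal/mol/K; kB*T at 310 K is fixed at 0.61597 kcal/mol.
KB = 0.0019872041
DEFAULT_TEMPERATURE = 310.0
KBT_310 = 0.61597


def kbt(temperature: float) -> float:
    """kB*T in kcal/mol, pinned to 0.61597 at exactly 310 K."""
    if temperature == DEFAULT_TEMPERATURE:
        return KBT_310
    return KB * temperature


# One toy ps of production maps onto 1/6 ns of the all-atom axes
# (3000 toy ps of production per replica <-> 500 ns).
TOY_PS_PER_NS = 6.0

# TM3-TM6 Calpha distance landmarks (Å): inactive receptor vs the
# cryo-EM active band of the agonist-bound complexes.
INACTIVE_DISTANCE = 8.3
ACTIVE_BAND = (12.0, 14.0)
ACTIVE_CENTER = 13.0


def derive_seed(master_seed: int, *labels: object) -> int:
    """Deterministic sub-seed from a master seed plus stage/replica labels.

    Stable across processes (sha256-based, not Python hash()); always < 2**31
    so it can be fed back on a command line.
    """
    key = "|".join([str(int(master_seed))] + [str(x) for x in labels])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class ProtocolConfig:
    """Staged GaMD protocol settings (conventional MD -> boosted
    equilibration -> frozen-parameter production replicas)."""

    cmd_steps: int = 20_000
    equil_steps: int = 50_000
    production_steps: int = 150_000
    n_replicas: int = 3
    update_interval: int = 5_000
    sigma0_total: float = 6.0
    sigma0_dihedral: float = 6.0
    bound_mode: str = "lower"
    dt: float = 0.02           # toy ps
    friction: float = 1.0      # 1/toy ps
    temperature: float = DEFAULT_TEMPERATURE
    stride: int = 10
    accumulate_statistics: bool = True
    # "initial": production replicas restart from the stage-1 starting
    # configuration (the active-state complex) with randomized velocities;
    # "equilibrated": continue from the equilibration endpoint.
    production_start: str = "initial"


@dataclass
class AnalysisConfig:
    """Binning, smoothing and state-classification settings."""

    bin_width_1d: float = 0.1
    bin_width_2d: float = 1.0
    min_frames: int = 500
    smoothing_window: float = 12.0   # toy ps ~ 2 ns on the all-atom axis
    inactive_ref: float = INACTIVE_DISTANCE
    active_band: tuple[float, float] = ACTIVE_BAND
    inactive_margin: float = 1.0


@dataclass
class AssayConfig:
    """Synthetic biochemical / cellular assay settings."""

    association_f0: float = 100.0       # RFU
    association_fmax: float = 600.0     # RFU
    association_duration: float = 3600.0  # s
    association_interval: float = 12.0    # s
    association_noise_sd: float = 5.0     # RFU
    dose_n_concentrations: int = 8
    dose_decades: float = 3.0           # concentrations span EC50 * 10^(±decades)
    dose_replicates: int = 3
    dose_noise_sd: float = 3.0          # response units (% of full-agonist top)
    dose_top_full: float = 100.0
    dose_bottom: float = 0.0


@dataclass
class ExperimentConfig:
    """Everything run_comparison needs; fully YAML-serializable."""

    master_seed: int = 7
    outdir: str = "gamdpipe_out"
    profiles: list[dict[str, Any]] = field(default_factory=list)
    landscape: dict[str, Any] = field(default_factory=dict)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    assay: AssayConfig = field(default_factory=AssayConfig)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["analysis"]["active_band"] = list(d["analysis"]["active_band"])
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        d = dict(d)
        if "protocol" in d:
            d["protocol"] = ProtocolConfig(**d["protocol"])
        if "analysis" in d:
            a = dict(d["analysis"])
            if "active_band" in a:
                a["active_band"] = tuple(a["active_band"])
            d["analysis"] = AnalysisConfig(**a)
        if "assay" in d:
            d["assay"] = AssayConfig(**d["assay"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Stable hash embedded in every output for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
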