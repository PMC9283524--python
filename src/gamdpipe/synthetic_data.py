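"""Synthetic study-condition generators.

Everything the pipeline consumes is generated here with seeded randomness:

* ligand-class activation free-energy landscapes along a TM3-TM6-distance-like
  coordinate (inactive basin at 8.3 Å, active basin centered at 13.0 Å in the
  12-14 Å band observed for agonist-bound receptor complexes),
* a toy bonded chain whose dihedral energy term is separable, so the
  dual-boost scheme can be exercised,
* fluorescence association traces obeying one-phase exponential association,
* cAMP dose-response datasets with ligand-specific maximal response and EC50,
* miniature PDB-format structure fixtures.

The three default ligand profiles emulate a full agonist, a partial agonist
and a very weak partial agonist: the full agonist has the most favorable
active basin, the largest maximal cAMP response and the most stable
(longest-half-life) receptor-G-protein complex; the very weak partial agonist
the opposite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml
from scipy import optimize

from .assay_models import AssociationTrace, DoseResponseCurve
from .config import ACTIVE_CENTER, INACTIVE_DISTANCE, kbt
from .gamd import PotentialModel
from .structure_metrics import angle as _bond_angle
from .structure_metrics import dihedral_angle as _dihedral_deg

__all__ = [
    "LigandProfile",
    "LandscapeSpec",
    "DEFAULT_PROFILES",
    "default_profiles",
    "Landscape1D",
    "Landscape2D",
    "ToyChainPotential",
    "build_activation_landscape",
    "build_toy_chain",
    "simulate_association_trace",
    "simulate_dose_response",
    "write_fixture_pdb",
    "boltzmann_active_fraction",
    "load_profiles_yaml",
]


# ---------------------------------------------------------------------------
# Ligand profiles
# ---------------------------------------------------------------------------

@dataclass
class LigandProfile:
    """Ligand-class parameters tying the landscape to the assay models.

    landscape_bias is the active-minus-inactive basin free energy (kcal/mol,
    negative = active state favored); assay_relative_max is the fraction of
    the full agonist's maximal cAMP response; association_rate_k is the
    nucleotide-exchange rate constant (1/s) whose inverse sets the complex
    half-life.
    """

    name: str
    landscape_bias: float
    barrier_height: float
    assay_relative_max: float
    assay_ec50: float
    association_rate_k: float

    def __post_init__(self):
        if self.barrier_height <= 0:
            raise ValueError("barrier_height must be positive")
        if not (0.0 < self.assay_relative_max <= 1.0):
            raise ValueError("assay_relative_max must lie in (0, 1]")
        if self.assay_ec50 <= 0:
            raise ValueError("assay_ec50 must be positive")
        if self.association_rate_k <= 0:
            raise ValueError("association_rate_k must be positive")

    def to_dict(self) -> dict:
        return {"name": self.name, "landscape_bias": self.landscape_bias,
                "barrier_height": self.barrier_height,
                "assay_relative_max": self.assay_relative_max,
                "assay_ec50": self.assay_ec50,
                "association_rate_k": self.association_rate_k}


def default_profiles() -> list[LigandProfile]:
    """The three default ligand classes (isoproterenol-, dobutamine- and
    cyanopindolol-like in their ordering of efficacy, potency and complex
    stability; the very-weak class's 0.24 relative maximum matches the ~24%
    relative cAMP response of the weakest ligand)."""
    return [
        LigandProfile("full_agonist", landscape_bias=-2.5, barrier_height=8.0,
                      assay_relative_max=1.0, assay_ec50=1e-9,
                      association_rate_k=4e-4),
        LigandProfile("partial_agonist", landscape_bias=-1.2, barrier_height=5.0,
                      assay_relative_max=0.60, assay_ec50=1e-6,
                      association_rate_k=1.2e-3),
        LigandProfile("very_weak_partial", landscape_bias=2.5, barrier_height=3.0,
                      assay_relative_max=0.24, assay_ec50=1e-10,
                      association_rate_k=4e-3),
    ]


DEFAULT_PROFILES = default_profiles()


def load_profiles_yaml(path) -> list[LigandProfile]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [LigandProfile(**entry) for entry in raw]


@dataclass
class LandscapeSpec:
    """Geometry of the activation landscape along the TM3-TM6-like
    coordinate; a second (ligand-RMSD-like) coordinate is optional."""

    inactive_center: float = INACTIVE_DISTANCE
    active_center: float = ACTIVE_CENTER
    inactive_width: float = 1.0
    active_width: float = 1.0
    confinement: float = 0.15        # kcal/mol/Å^2, quadratic background
    second_coordinate: Optional[dict] = None

    def __post_init__(self):
        if self.inactive_center >= self.active_center:
            raise ValueError("inactive_center must lie below active_center")
        if self.active_center - self.inactive_center < (
                self.inactive_width + self.active_width):
            raise ValueError("overlapping wells: centers closer than the "
                             "sum of the well widths")

    def to_dict(self) -> dict:
        return {"inactive_center": self.inactive_center,
                "active_center": self.active_center,
                "inactive_width": self.inactive_width,
                "active_width": self.active_width,
                "confinement": self.confinement,
                "second_coordinate": self.second_coordinate}


# ---------------------------------------------------------------------------
# 1D double-well landscape: two inverted Gaussians on a quadratic background
# ---------------------------------------------------------------------------

class Landscape1D(PotentialModel):
    """Smooth double well V(d) = c (d-m)^2 - A_i g(d; mu_i, w_i)
    - A_a g(d; mu_a, w_a), calibrated so the local minima sit exactly at the
    requested basin centers, V(active) - V(inactive) equals the ligand's
    landscape_bias, and the saddle lies barrier_height above the lower well.
    """

    n_dof = 1

    def __init__(self, amps, mus, widths, confinement, conf_center,
                 inactive_center, active_center, bias, barrier):
        self.amps = np.asarray(amps, float)
        self.mus = np.asarray(mus, float)
        self.widths = np.asarray(widths, float)
        self.confinement = float(confinement)
        self.conf_center = float(conf_center)
        self.inactive_center = float(inactive_center)
        self.active_center = float(active_center)
        self.bias = float(bias)
        self.barrier = float(barrier)

    # -- scalar energy/gradient (also used by the propagator hot loop) -----
    def value(self, d: float) -> float:
        v = self.confinement * (d - self.conf_center) ** 2
        for A, mu, w in zip(self.amps, self.mus, self.widths):
            v -= A * math.exp(-((d - mu) ** 2) / (2.0 * w * w))
        return v

    def derivative(self, d: float) -> float:
        g = 2.0 * self.confinement * (d - self.conf_center)
        for A, mu, w in zip(self.amps, self.mus, self.widths):
            g += A * (d - mu) / (w * w) * math.exp(-((d - mu) ** 2) / (2.0 * w * w))
        return g

    def values(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, float)
        v = self.confinement * (d - self.conf_center) ** 2
        for A, mu, w in zip(self.amps, self.mus, self.widths):
            v = v - A * np.exp(-((d - mu) ** 2) / (2.0 * w * w))
        return v

    # -- PotentialModel interface ------------------------------------------
    def components(self, x):
        d = float(x[0])
        return self.value(d), 0.0, np.array([self.derivative(d)]), np.zeros(1)

    def collective_variables(self, x):
        return np.asarray(x, float)[:1]

    def initial_configuration(self):
        # simulations start from the active (cryo-EM-like) state
        return np.array([self.active_center])

    @property
    def cv_names(self):
        return ["tm3_tm6_distance"]


def _calibrate_double_well(inactive_center, active_center, widths, bias,
                           barrier, confinement):
    """Solve for Gaussian amplitudes and center offsets so that the stated
    basin positions, bias and barrier hold exactly."""
    m = 0.5 * (inactive_center + active_center)
    w_i, w_a = widths

    def make(params):
        a_i, a_a, mu_i, mu_a = params
        return Landscape1D([a_i, a_a], [mu_i, mu_a], [w_i, w_a],
                           confinement, m, inactive_center, active_center,
                           bias, barrier)

    def residuals(params):
        model = make(params)
        lo = min(model.value(inactive_center), model.value(active_center))
        res = optimize.minimize_scalar(
            lambda d: -model.value(d),
            bounds=(inactive_center, active_center), method="bounded")
        saddle = -res.fun
        return [
            model.derivative(inactive_center),
            model.derivative(active_center),
            (model.value(active_center) - model.value(inactive_center)) - bias,
            (saddle - lo) - barrier,
        ]

    if bias <= 0:       # active basin is the lower well
        a_a0 = barrier
        a_i0 = max(barrier + bias, 0.5)
    else:               # inactive basin is the lower well
        a_i0 = barrier
        a_a0 = max(barrier - bias, 0.5)
    x0 = [a_i0, a_a0, inactive_center, active_center]
    sol = optimize.least_squares(
        residuals, x0,
        bounds=([1e-3, 1e-3, inactive_center - 1.5, active_center - 1.5],
                [np.inf, np.inf, inactive_center + 1.5, active_center + 1.5]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    model = make(sol.x)
    if max(abs(r) for r in residuals(sol.x)) > 1e-6:
        raise RuntimeError("landscape calibration failed to converge")
    # both stationary points must be minima
    eps = 1e-4
    for c in (inactive_center, active_center):
        curv = (model.value(c + eps) - 2 * model.value(c) + model.value(c - eps)) / eps**2
        if curv <= 0:
            raise RuntimeError("calibrated landscape has a non-minimum basin")
    return model


class Landscape2D(PotentialModel):
    """Separable 2D landscape: the activation coordinate plus an independent
    ligand-RMSD-like double well."""

    n_dof = 2

    def __init__(self, primary: Landscape1D, secondary: Landscape1D):
        self.primary = primary
        self.secondary = secondary
        self.inactive_center = primary.inactive_center
        self.active_center = primary.active_center

    def components(self, x):
        d, r = float(x[0]), float(x[1])
        v = self.primary.value(d) + self.secondary.value(r)
        g = np.array([self.primary.derivative(d), self.secondary.derivative(r)])
        return v, 0.0, g, np.zeros(2)

    def collective_variables(self, x):
        return np.asarray(x, float)[:2]

    def initial_configuration(self):
        return np.array([self.primary.active_center,
                         self.secondary.inactive_center])

    @property
    def cv_names(self):
        return ["tm3_tm6_distance", "ligand_rmsd"]


def build_activation_landscape(profile: LigandProfile,
                               spec: Optional[LandscapeSpec] = None):
    """Construct the ligand's activation landscape.

    Returns a Landscape1D, or a Landscape2D when the spec defines a second
    coordinate. The analytic gradient is evaluable everywhere.
    """
    spec = spec or LandscapeSpec()
    primary = _calibrate_double_well(
        spec.inactive_center, spec.active_center,
        (spec.inactive_width, spec.active_width),
        profile.landscape_bias, profile.barrier_height, spec.confinement)
    if spec.second_coordinate is None:
        return primary
    sc = dict(spec.second_coordinate)
    secondary = _calibrate_double_well(
        sc.get("inactive_center", 1.0), sc.get("active_center", 3.5),
        (sc.get("inactive_width", 0.6), sc.get("active_width", 0.6)),
        sc.get("bias", 1.0), sc.get("barrier", 2.0),
        sc.get("confinement", 0.05))
    return Landscape2D(primary, secondary)


def boltzmann_active_fraction(model, temperature: float = 310.0,
                              grid: float = 0.001,
                              pad: float = 8.0) -> float:
    """Equilibrium active-state population of a landscape by direct
    numerical integration of the Boltzmann weight on a uniform grid,
    splitting the basins at the saddle point."""
    primary = model.primary if isinstance(model, Landscape2D) else model
    res = optimize.minimize_scalar(
        lambda d: -primary.value(d),
        bounds=(primary.inactive_center, primary.active_center),
        method="bounded")
    split = float(res.x)
    lo = primary.inactive_center - pad
    hi = primary.active_center + pad
    d = np.arange(lo, hi + grid, grid)
    w = np.exp(-(primary.values(d) - primary.values(d).min()) / kbt(temperature))
    total = np.trapezoid(w, d)
    active = np.trapezoid(w[d >= split], d[d >= split])
    return float(active / total)


# ---------------------------------------------------------------------------
# Toy bonded chain with a separable dihedral term
# ---------------------------------------------------------------------------

class ToyChainPotential(PotentialModel):
    """A bonded chain of >= 4 particles in 3D: harmonic bonds and angles plus
    a periodic dihedral term reported as a separate energy component, so the
    dual-boost path has a genuine "dihedral energetic term" to act on.

    All equilibrium internal coordinates are drawn deterministically from the
    seed; the reference geometry built from them has every term at its
    minimum (total energy zero).
    """

    def __init__(self, n_particles: int, seed: int,
                 k_bond: float = 100.0, k_angle: float = 30.0,
                 k_dihedral: float = 2.0):
        if n_particles < 4:
            raise ValueError("need at least 4 particles to define a dihedral")
        self.n_particles = n_particles
        self.n_dof = 3 * n_particles
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.k_bond = k_bond
        self.k_angle = k_angle
        self.k_dihedral = k_dihedral
        self.r0 = 1.5 + 0.1 * rng.uniform(-1, 1, n_particles - 1)
        self.theta0 = 1.911 + 0.1 * rng.uniform(-1, 1, n_particles - 2)
        self.phi0 = rng.uniform(-math.pi, math.pi, n_particles - 3)

    # -- geometry helpers ---------------------------------------------------
    def initial_configuration(self) -> np.ndarray:
        """Chain built by sequential internal-coordinate placement; every
        bonded term is exactly at its minimum."""
        pos = np.zeros((self.n_particles, 3))
        pos[1] = [self.r0[0], 0.0, 0.0]
        # place third atom in the xy plane at the first equilibrium angle
        th = math.pi - self.theta0[0]
        pos[2] = pos[1] + self.r0[1] * np.array([math.cos(th), math.sin(th), 0.0])
        for i in range(3, self.n_particles):
            pos[i] = _place_atom(pos[i - 3], pos[i - 2], pos[i - 1],
                                 self.r0[i - 1], self.theta0[i - 2],
                                 self.phi0[i - 3])
        return pos.ravel()

    def collective_variables(self, x):
        pos = np.asarray(x, float).reshape(-1, 3)
        return np.array([float(np.linalg.norm(pos[-1] - pos[0]))])

    @property
    def cv_names(self):
        return ["end_to_end_distance"]

    @property
    def has_dihedral_component(self) -> bool:
        return True

    # -- energies and analytic gradients -----------------------------------
    def components(self, x):
        pos = np.asarray(x, float).reshape(-1, 3)
        grad = np.zeros_like(pos)
        v_bonded = 0.0
        for i in range(self.n_particles - 1):
            d = pos[i + 1] - pos[i]
            r = np.linalg.norm(d)
            dr = r - self.r0[i]
            v_bonded += self.k_bond * dr * dr
            g = 2.0 * self.k_bond * dr * d / r
            grad[i + 1] += g
            grad[i] -= g
        for i in range(self.n_particles - 2):
            th = _bond_angle(pos[i], pos[i + 1], pos[i + 2])
            dth = th - self.theta0[i]
            v_bonded += self.k_angle * dth * dth
            g1, g2, g3 = _angle_grads(pos[i], pos[i + 1], pos[i + 2])
            coeff = 2.0 * self.k_angle * dth
            grad[i] += coeff * g1
            grad[i + 1] += coeff * g2
            grad[i + 2] += coeff * g3
        v_dih = 0.0
        grad_dih = np.zeros_like(pos)
        for i in range(self.n_particles - 3):
            quad = pos[i], pos[i + 1], pos[i + 2], pos[i + 3]
            phi = math.radians(_dihedral_deg(*quad))
            # k (1 + cos(phi - phi0 + pi)) has its minimum exactly at phi0
            v_dih += self.k_dihedral * (1.0 + math.cos(phi - self.phi0[i] + math.pi))
            dE = -self.k_dihedral * math.sin(phi - self.phi0[i] + math.pi)
            for j, g in enumerate(_dihedral_grads(*quad)):
                grad_dih[i + j] += dE * g
        total = v_bonded + v_dih
        return total, v_dih, (grad + grad_dih).ravel(), grad_dih.ravel()


def _place_atom(p1, p2, p3, bond, theta, phi):
    """NeRF placement: new atom at given bond length from p3, angle theta at
    p3 and torsion phi about the p2-p3 axis."""
    b1 = p2 - p1
    b2 = p3 - p2
    b2n = b2 / np.linalg.norm(b2)
    n = np.cross(b1, b2)
    n /= np.linalg.norm(n)
    m = np.cross(n, b2n)
    d = np.array([-bond * math.cos(theta),
                  bond * math.sin(theta) * math.cos(phi),
                  bond * math.sin(theta) * math.sin(phi)])
    return p3 + d[0] * b2n + d[1] * m + d[2] * n


def _angle_grads(p1, p2, p3):
    u = p1 - p2
    v = p3 - p2
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    uh, vh = u / nu, v / nv
    c = float(np.clip(np.dot(uh, vh), -1.0, 1.0))
    s = math.sqrt(max(1.0 - c * c, 1e-14))
    g1 = (c * uh - vh) / (nu * s)
    g3 = (c * vh - uh) / (nv * s)
    return g1, -(g1 + g3), g3


def _dihedral_grads(p1, p2, p3, p4):
    """d(phi)/d(r_i) in radians per Å (Blondel-Karplus form)."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    g1 = -nb2 / np.dot(n1, n1) * n1
    g4 = nb2 / np.dot(n2, n2) * n2
    f = np.dot(b1, b2) / (nb2 * nb2)
    h = np.dot(b3, b2) / (nb2 * nb2)
    g2 = -(1.0 + f) * g1 + h * g4
    g3 = f * g1 - (1.0 + h) * g4
    return g1, g2, g3, g4


def build_toy_chain(n_particles: int, seed: int, **force_constants) -> ToyChainPotential:
    """Deterministic toy chain; same seed gives bitwise-identical parameters."""
    return ToyChainPotential(n_particles, seed, **force_constants)


# ---------------------------------------------------------------------------
# Assay data generators
# ---------------------------------------------------------------------------

def simulate_association_trace(profile: LigandProfile, f0: float = 100.0,
                               fmax: float = 600.0, duration: float = 3600.0,
                               interval: float = 12.0, noise_sd: float = 5.0,
                               seed: int = 0) -> AssociationTrace:
    """One-phase exponential association trace with additive Gaussian noise.

    F(t) = f0 + (fmax - f0)(1 - e^{-kt}), sampled every ``interval`` seconds
    from 0 through ``duration`` (defaults: every 12 s for 60 min, 301 points).
    """
    if fmax <= f0:
        raise ValueError("fmax must exceed f0")
    if interval <= 0 or duration < interval:
        raise ValueError("need interval > 0 and duration >= interval")
    if noise_sd < 0:
        raise ValueError("noise_sd must be zero (noiseless) or positive")
    t = np.arange(0.0, duration + 0.5 * interval, interval)
    k = profile.association_rate_k
    f = f0 + (fmax - f0) * (1.0 - np.exp(-k * t))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, t.size)
    return AssociationTrace(time=t, rfu=f, label=profile.name)


def simulate_dose_response(profile: LigandProfile, concentrations,
                           replicates: int = 3, noise_sd: float = 3.0,
                           seed: int = 0, top_full: float = 100.0,
                           bottom: float = 0.0) -> DoseResponseCurve:
    """cAMP dose-response data from a unit-Hill three-parameter logistic.

    The ligand's plateau is top_full * assay_relative_max; responses get
    additive Gaussian noise per replicate point.
    """
    conc = np.asarray(concentrations, float)
    if conc.size == 0:
        raise ValueError("empty concentration list")
    if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be positive and sorted")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    if noise_sd < 0:
        raise ValueError("noise_sd must be zero (noiseless) or positive")
    top = top_full * profile.assay_relative_max
    mean = bottom + (top - bottom) / (
        1.0 + 10.0 ** (math.log10(profile.assay_ec50) - np.log10(conc)))
    rng = np.random.default_rng(seed)
    cc, rr, yy = [], [], []
    for rep in range(replicates):
        noise = rng.normal(0.0, noise_sd, conc.size) if noise_sd > 0 else 0.0
        cc.append(conc)
        rr.append(np.full(conc.size, rep))
        yy.append(mean + noise)
    return DoseResponseCurve(concentration=np.concatenate(cc),
                             replicate=np.concatenate(rr),
                             response=np.concatenate(yy), label=profile.name)


def default_concentrations(profile: LigandProfile, n: int = 8,
                           decades: float = 3.0) -> np.ndarray:
    """Log-spaced concentrations spanning the ligand's EC50 by +-decades."""
    lec = math.log10(profile.assay_ec50)
    return np.logspace(lec - decades, lec + decades, n)


# ---------------------------------------------------------------------------
# Miniature PDB fixtures
# ---------------------------------------------------------------------------

def write_fixture_pdb(atoms: list[dict], path) -> None:
    """Write a miniature synthetic PDB-format fixture.

    ``atoms`` is a list of dicts with keys: chain, res_id, res_name,
    atom_name, element, xyz (3 floats); optional occupancy and altloc.
    Coordinates outside the fixed-width field range (|x| too large for
    %8.3f) are rejected.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if not atoms:
        raise ValueError("no atoms given")
    arr = struc.AtomArray(len(atoms))
    occ = np.ones(len(atoms))
    alt = np.array([a.get("altloc", "") for a in atoms], dtype="U1")
    for i, a in enumerate(atoms):
        xyz = np.asarray(a["xyz"], float)
        if np.any(xyz >= 10000.0) or np.any(xyz <= -1000.0):
            raise ValueError(
                f"coordinate {xyz} outside the PDB fixed-width field range")
        arr.coord[i] = xyz
        arr.chain_id[i] = a.get("chain", "A")
        arr.res_id[i] = a["res_id"]
        arr.res_name[i] = a["res_name"]
        arr.atom_name[i] = a["atom_name"]
        arr.element[i] = a.get("element", a["atom_name"][0])
        arr.hetero[i] = a.get("hetero", False)
        occ[i] = a.get("occupancy", 1.0)
    arr.set_annotation("occupancy", occ)
    arr.set_annotation("altloc_id", alt)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
    if any(a != "" for a in alt):
        # splice altloc chars into column 17 of the fixed-width records
        lines = open(str(path)).read().splitlines(keepends=True)
        out, i = [], 0
        for line in lines:
            if line.startswith(("ATOM", "HETATM")):
                code = alt[i] if alt[i] else " "
                line = line[:16] + code + line[17:]
                i += 1
            out.append(line)
        with open(str(path), "w") as fh:
            fh.writelines(out)
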