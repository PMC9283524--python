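"""Coordinate-level structural measurements.

Reads PDB-format models (via biotite) and computes the quantities used to
compare receptor conformational states: Kabsch-superposition RMSD, labeled
Cα–Cα distances (with Ballesteros–Weinstein generic numbering resolved
through a per-structure mapping table), ionic-lock / salt-bridge detection,
and side-chain χ dihedrals. Hydrogens are ignored throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import yaml
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.transform import Rotation

__all__ = [
    "StructureModel",
    "DEFAULT_BW_MAP",
    "read_structure",
    "load_bw_map",
    "kabsch",
    "kabsch_rmsd",
    "labeled_distance",
    "ionic_lock_state",
    "sidechain_dihedral",
    "dihedral_angle",
    "angle",
]

# Ballesteros-Weinstein -> author residue number for turkey beta1-AR.
# 3.50 is the DRY arginine (Arg139); 6.34 the TM6 leucine used for the
# TM3-TM6 activation distance.
DEFAULT_BW_MAP: dict[str, int] = {
    "3.40": 129,
    "3.49": 138,
    "3.50": 139,
    "5.50": 219,
    "6.30": 285,
    "6.34": 289,
    "6.44": 299,
}

# chi_n atom quadruples per residue type (standard rotamer definitions)
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
}

_BASIC_SIDECHAIN = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",)}
_ACIDIC_SIDECHAIN = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}

Selector = tuple[Optional[str], Union[int, str], str]  # (chain, residue, atom)


@dataclass
class StructureModel:
    """Atoms of one model plus the BW-label -> author-number table."""

    atoms: AtomArray
    bw_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_BW_MAP))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def resolve_residue(self, residue: Union[int, str]) -> int:
        """Map a Ballesteros-Weinstein label like '3.50' to the author
        residue number; integers pass through."""
        if isinstance(residue, str) and "." in residue:
            if residue not in self.bw_map:
                raise KeyError(f"BW label {residue!r} not in the mapping table")
            return self.bw_map[residue]
        return int(residue)

    def atom_coord(self, chain: Optional[str], residue: Union[int, str],
                   atom_name: str) -> np.ndarray:
        res_id = self.resolve_residue(residue)
        mask = (self.atoms.res_id == res_id) & (self.atoms.atom_name == atom_name)
        if chain is not None:
            mask &= self.atoms.chain_id == chain
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise KeyError(
                f"atom not found: chain={chain!r} residue={residue!r} "
                f"atom={atom_name!r}")
        return np.asarray(self.atoms.coord[idx[0]], float)

    def residue_atoms(self, chain: Optional[str],
                      residue: Union[int, str]) -> AtomArray:
        res_id = self.resolve_residue(residue)
        mask = self.atoms.res_id == res_id
        if chain is not None:
            mask &= self.atoms.chain_id == chain
        return self.atoms[mask]

    def coords(self, selection=None) -> np.ndarray:
        if selection is None:
            return np.asarray(self.atoms.coord, float)
        return np.asarray(self.atoms.coord[selection], float)


def _prescan_pdb(path: str) -> None:
    """Light validation of fixed-width ATOM/HETATM records so malformed
    lines are reported with their line number."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ValueError(f"malformed PDB record at line {i}: too short")
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError:
                    raise ValueError(
                        f"malformed PDB record at line {i}: bad coordinates") from None


def read_structure(path, bw_map: Optional[dict[str, int]] = None,
                   model: int = 1) -> StructureModel:
    """Load ATOM/HETATM records from a PDB file.

    Alternate locations are resolved by highest occupancy (first on ties);
    hydrogens are dropped.
    """
    _prescan_pdb(str(path))
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=model, altloc="occupancy")
    if len(atoms) == 0:
        raise ValueError(f"no atoms found in {path}")
    atoms = atoms[atoms.element != "H"]
    return StructureModel(atoms=atoms,
                          bw_map=dict(bw_map) if bw_map else dict(DEFAULT_BW_MAP))


def load_bw_map(path) -> dict[str, int]:
    """Read a YAML table of Ballesteros-Weinstein label -> residue number."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {str(k): int(v) for k, v in raw.items()}


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of paired coordinate sets.

    Returns (rmsd, rotation_matrix, translation) such that
    ``mobile @ R.T + t`` best fits ``target``; the rotation is always proper
    (det +1).
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("selections must be paired (n, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("under-determined: need >= 3 atoms for a unique rotation")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-9) < 2 or np.linalg.matrix_rank(Q0, tol=1e-9) < 2:
        raise ValueError("under-determined: collinear or degenerate geometry")
    rot, _ = Rotation.align_vectors(Q0, P0)
    R = rot.as_matrix()
    t = qc - pc @ R.T
    # recompute the residual from the transform itself: scipy's rssd carries
    # O(1e-8) cancellation noise that would mask exact superpositions
    resid = P @ R.T + t - Q
    rmsd = math.sqrt(float(np.mean(np.sum(resid * resid, axis=1))))
    return rmsd, R, t


def kabsch_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """Post-superposition RMSD in Å."""
    return kabsch(mobile, target)[0]


# ---------------------------------------------------------------------------
# Distances and contacts
# ---------------------------------------------------------------------------

def labeled_distance(model: StructureModel, sel_a: Selector,
                     sel_b: Selector) -> float:
    """Euclidean distance (Å) between two labeled atoms; residue fields may
    be author numbers or BW labels like '3.50'."""
    a = model.atom_coord(*sel_a)
    b = model.atom_coord(*sel_b)
    return float(np.linalg.norm(a - b))


def ionic_lock_state(model: StructureModel, basic_res: tuple,
                     acidic_res: tuple, cutoff: float = 4.0):
    """Salt-bridge check between a basic (Arg/Lys) and an acidic (Asp/Glu)
    side chain.

    Returns ("present" | "broken", min_distance) where the minimum is over
    all guanidinium/amine nitrogen x carboxylate oxygen pairs; "present" iff
    the minimum distance is <= cutoff.
    """
    def side_atoms(res_sel, table, kind):
        chain, res = res_sel
        atoms = model.residue_atoms(chain, res)
        if len(atoms) == 0:
            raise KeyError(f"residue not found: {res_sel}")
        res_name = str(atoms.res_name[0])
        if res_name not in table:
            raise ValueError(f"{res_sel} is {res_name}, not a {kind} residue")
        wanted = table[res_name]
        coords, missing = [], []
        for name in wanted:
            hit = atoms[atoms.atom_name == name]
            if len(hit) == 0:
                missing.append(name)
            else:
                coords.append(np.asarray(hit.coord[0], float))
        if not coords:
            raise KeyError(f"missing side-chain atoms on {res_sel}: {missing}")
        return np.array(coords)

    basics = side_atoms(basic_res, _BASIC_SIDECHAIN, "basic")
    acidics = side_atoms(acidic_res, _ACIDIC_SIDECHAIN, "acidic")
    d = np.linalg.norm(basics[:, None, :] - acidics[None, :, :], axis=-1)
    dmin = float(d.min())
    return ("present" if dmin <= cutoff else "broken"), dmin


# ---------------------------------------------------------------------------
# Dihedrals
# ---------------------------------------------------------------------------

def angle(p1, p2, p3) -> float:
    """Bond angle at p2 in radians."""
    u = np.asarray(p1, float) - np.asarray(p2, float)
    v = np.asarray(p3, float) - np.asarray(p2, float)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed torsion angle in degrees, in (-180, 180].

    Standard atan2 construction: cis = 0°, trans = 180°.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    deg = math.degrees(math.atan2(y, x))
    if deg <= -180.0:
        deg += 360.0
    return deg


def sidechain_dihedral(model: StructureModel, residue: tuple,
                       chi_index: int) -> float:
    """Side-chain χ_n (degrees) for a residue given as (chain, number-or-BW).

    Raises for residue types without the requested χ (e.g. Ala/Gly).
    """
    chain, res = residue
    atoms = model.residue_atoms(chain, res)
    if len(atoms) == 0:
        raise KeyError(f"residue not found: {residue}")
    res_name = str(atoms.res_name[0])
    chis = CHI_ATOMS.get(res_name, [])
    if not (1 <= chi_index <= len(chis)):
        raise ValueError(f"no chi{chi_index} defined for {res_name}")
    names = chis[chi_index - 1]
    coords = []
    for name in names:
        hit = atoms[atoms.atom_name == name]
        if len(hit) == 0:
            raise KeyError(f"missing atom {name} on {residue} for chi{chi_index}")
        coords.append(np.asarray(hit.coord[0], float))
    return dihedral_angle(*coords)
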