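"""Solvent accessibility, distance statistics and rigid-body superposition.

SASA uses the Shrake–Rupley sphere-point method with a deterministic
golden-section spiral point set (no RNG), a fixed internal van der Waals
radius table and a fixed per-residue maximum-accessibility reference for
relative SASA.  Superposition is least-squares (Kabsch), delegated to
scipy's ``Rotation.align_vectors`` which already handles the reflection
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import ResidueKey, Structure, format_residue_key

__all__ = [
    "VDW_RADII",
    "MAX_ACCESSIBLE_AREA",
    "SasaResult",
    "SuperpositionResult",
    "DistanceStats",
    "DegenerateInputError",
    "golden_spiral_points",
    "shrake_rupley_sasa",
    "ca_distance_stats",
    "kabsch_superpose",
    "dihedral_angle",
]

# Fixed vdW radii (A); unknown elements fall back to carbon with a warning.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
DEFAULT_VDW_RADIUS = 1.70

# Theoretical maximum accessible areas per residue type (A^2), used to turn
# absolute SASA into relative SASA (fraction of the residue's maximum
# exposure in an extended context).
MAX_ACCESSIBLE_AREA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


class DegenerateInputError(ValueError):
    """Raised when a geometric operation receives degenerate input."""


@dataclass
class SasaResult:
    """Per-atom and per-residue solvent accessibility."""

    atom_area: np.ndarray                       # (n_atoms,) A^2, structure atom order
    residue_abs: dict[ResidueKey, float]        # A^2
    residue_rel: dict[ResidueKey, float]        # fraction of reference max (NaN if unknown type)
    surface: dict[ResidueKey, bool]
    probe_radius: float
    n_sphere_points: int
    surface_threshold: float

    def is_surface(self, key: ResidueKey) -> bool:
        return self.surface[tuple(key)]


@dataclass
class SuperpositionResult:
    """Proper rotation + translation minimizing RMSD, and the residual RMSD."""

    rotation: np.ndarray      # (3, 3), det = +1
    translation: np.ndarray   # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class DistanceStats:
    mean: float
    min: float
    n_pairs: int


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` near-uniform unit-sphere points on a golden-section spiral."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _atom_radii(structure: Structure) -> np.ndarray:
    radii = []
    unknown: set[str] = set()
    for res, atom in structure.atoms():
        r = VDW_RADII.get(atom.element.strip().upper())
        if r is None:
            unknown.add(atom.element or atom.name)
            r = DEFAULT_VDW_RADIUS
        radii.append(r)
    if unknown:
        warnings.warn(
            f"unknown element(s) {sorted(unknown)}: using default vdW radius "
            f"{DEFAULT_VDW_RADIUS} A",
            stacklevel=3,
        )
    return np.array(radii)


def shrake_rupley_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    surface_threshold: float = 0.25,
) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom's solvent-expanded sphere (vdW radius + probe) is sampled with
    ``n_sphere_points`` deterministic spiral points; the accessible fraction
    is the fraction of points not buried inside any neighbouring expanded
    sphere.  Residue SASA is the sum over its atoms; relative SASA divides by
    a per-residue-type reference maximum, and residues with relative SASA at
    or above ``surface_threshold`` are flagged as surface.
    """
    coords = structure.coords()
    if len(coords) == 0:
        raise ValueError("structure has no atoms")
    radii = _atom_radii(structure)
    expanded = radii + probe_radius
    unit = golden_spiral_points(n_sphere_points)

    n = len(coords)
    # pairwise neighbour lists (peptide-scale inputs: the dense matrix is fine)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    cutoff = (expanded[:, None] + expanded[None, :]) ** 2
    neighbor_mask = (d2 < cutoff) & ~np.eye(n, dtype=bool)

    atom_area = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        nbrs = np.nonzero(neighbor_mask[i])[0]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in nbrs:
            if not accessible.any():
                break
            dd = np.sum((pts[accessible] - coords[j]) ** 2, axis=1)
            buried = dd < expanded[j] ** 2
            idx = np.nonzero(accessible)[0]
            accessible[idx[buried]] = False
        frac = accessible.sum() / n_sphere_points
        atom_area[i] = frac * 4.0 * np.pi * expanded[i] ** 2

    residue_abs: dict[ResidueKey, float] = {}
    residue_rel: dict[ResidueKey, float] = {}
    surface: dict[ResidueKey, bool] = {}
    offset = 0
    for res in structure.residues:
        na = len(res.atoms)
        abs_area = float(atom_area[offset:offset + na].sum())
        offset += na
        residue_abs[res.key] = abs_area
        ref = MAX_ACCESSIBLE_AREA.get(res.res_name)
        rel = abs_area / ref if ref else float("nan")
        residue_rel[res.key] = rel
        surface[res.key] = bool(rel >= surface_threshold) if np.isfinite(rel) else False
    return SasaResult(
        atom_area, residue_abs, residue_rel, surface,
        probe_radius, n_sphere_points, surface_threshold,
    )


def ca_distance_stats(
    structure: Structure,
    query_residues: Iterable[ResidueKey],
    reference_residues: Iterable[ResidueKey],
) -> DistanceStats:
    """Mean and minimum C-alpha–C-alpha distance over query x reference pairs."""

    def ca_coords(keys: Iterable[ResidueKey]) -> np.ndarray:
        out = []
        for key in keys:
            res = structure[key]
            ca = res.ca
            if ca is None:
                raise ValueError(f"residue {format_residue_key(res.key)} has no CA atom")
            out.append(ca.coords)
        return np.array(out)

    q = ca_coords(query_residues)
    r = ca_coords(reference_residues)
    if len(q) == 0 or len(r) == 0:
        raise ValueError("query and reference residue sets must be non-empty")
    d = np.linalg.norm(q[:, None, :] - r[None, :, :], axis=-1)
    return DistanceStats(mean=float(d.mean()), min=float(d.min()), n_pairs=int(d.size))


def kabsch_superpose(
    mobile: np.ndarray,
    target: np.ndarray,
    weights: Sequence[float] | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the proper rotation (reflections excluded) and translation such
    that ``coords @ R.T + t`` best fits the target, plus the residual RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must be matching (n, 3) arrays")
    n = len(mobile)
    if n < 3:
        raise DegenerateInputError("superposition needs at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    wsum = w.sum()
    cm = (w[:, None] * mobile).sum(axis=0) / wsum
    ct = (w[:, None] * target).sum(axis=0) / wsum
    mc = mobile - cm
    tc = target - ct
    cov = (tc * w[:, None]).T @ mc
    if np.linalg.matrix_rank(cov, tol=1e-10) < 2:
        raise DegenerateInputError("rank-deficient covariance (collinear or degenerate points)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        rot, rssd = Rotation.align_vectors(tc, mc, weights=w)
    rmsd = float(rssd / np.sqrt(wsum))
    rotation = rot.as_matrix()
    translation = ct - rotation @ cm
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle in degrees in (-180, 180]; NaN for degenerate geometry."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1n = np.linalg.norm(n1)
    n2n = np.linalg.norm(n2)
    b2n = np.linalg.norm(b2)
    if n1n < 1e-9 or n2n < 1e-9 or b2n < 1e-9:
        return float("nan")
    m1 = np.cross(n1, b2 / b2n)
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang
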