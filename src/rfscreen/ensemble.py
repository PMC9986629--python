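"""Trajectory-style analytics on coordinate ensembles.

Covers the ensemble statistics used to compare a wild-type enzyme with a
rigidified mutant: superposition-based RMSD and RMSF, dynamic
cross-correlation matrices (DCCM), geometric hydrogen-bond and salt-bridge
detection with per-frame occupancies, and the constraint-network-analysis
(CNA) mapping from the hydrogen-bond energy cutoff at the rigid-to-flexible
transition to a transition temperature.

The rigidity network itself (pebble-game body-and-bar decomposition) is not
computed here: a P-infinity series is ingested from file (or synthesized)
and only the transition detection and the affine temperature map are
implemented.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import kabsch_superpose
from .structure import Ensemble, ResidueKey, Structure, format_residue_key

__all__ = [
    "BondObservation",
    "CnaPoint",
    "TransitionResult",
    "Dccm",
    "select_atoms",
    "rmsd_series",
    "rmsf_profile",
    "dccm",
    "detect_hydrogen_bonds",
    "hbond_count_series",
    "salt_bridge_occupancy",
    "cna_temperature",
    "find_transition",
    "load_cna_series",
]

SIDECHAIN_O = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
SIDECHAIN_N = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}

AMIDE_NH_LENGTH = 1.01  # A


# ---------------------------------------------------------------------------
# atom selections

def select_atoms(
    topology: Structure,
    selection: str | Sequence[int] | Callable = "ca",
) -> np.ndarray:
    """Resolve a selection to atom indices in topology order.

    Accepts 'ca', 'backbone', 'heavy', 'all', an explicit index sequence, or
    a predicate called as ``pred(residue, atom)``.
    """
    if isinstance(selection, str):
        sel = selection.lower()
        if sel == "ca":
            pred = lambda r, a: a.name == "CA"
        elif sel == "backbone":
            pred = lambda r, a: a.name in ("N", "CA", "C", "O")
        elif sel == "heavy":
            pred = lambda r, a: a.element != "H"
        elif sel == "all":
            pred = lambda r, a: True
        else:
            raise ValueError(f"unknown selection {selection!r}")
    elif callable(selection):
        pred = selection
    else:
        idx = np.asarray(selection, dtype=int)
        if idx.size == 0:
            raise ValueError("selection resolves to no atoms")
        return idx
    idx = [i for i, (r, a) in enumerate(topology.atoms()) if pred(r, a)]
    if not idx:
        raise ValueError(f"selection {selection!r} resolves to no atoms")
    return np.array(idx, dtype=int)


def _selection_residues(topology: Structure, indices: np.ndarray) -> list[ResidueKey]:
    ids = topology.atom_ids()
    return [ids[i][0] for i in indices]


def _fit_frames(
    frames: list[np.ndarray],
    reference: np.ndarray,
    fit_idx: np.ndarray,
) -> list[np.ndarray]:
    fitted = []
    for f in frames:
        sup = kabsch_superpose(f[fit_idx], reference[fit_idx])
        fitted.append(sup.apply(f))
    return fitted


def _iterative_mean(
    frames: list[np.ndarray], fit_idx: np.ndarray, tol: float = 1e-6, max_iter: int = 20
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Converged mean structure: superpose to the running mean until the mean
    shifts by less than ``tol`` A (capped at ``max_iter`` rounds)."""
    ref = frames[0]
    fitted = frames
    for _ in range(max_iter):
        fitted = _fit_frames(fitted, ref, fit_idx)
        new_ref = np.mean(fitted, axis=0)
        shift = float(np.max(np.linalg.norm(new_ref - ref, axis=1)))
        ref = new_ref
        if shift < tol:
            break
    return ref, fitted


# ---------------------------------------------------------------------------
# RMSD / RMSF / DCCM

def rmsd_series(
    ensemble: Ensemble,
    reference: str | int = "first",
    selection: str | Sequence[int] = "ca",
    fit_selection: str | Sequence[int] | None = None,
    superpose: bool = True,
) -> np.ndarray:
    """Per-frame RMSD to a reference ('first', 'mean', or a frame index),
    after least-squares superposition on ``fit_selection`` (defaults to the
    analysis selection)."""
    idx = select_atoms(ensemble.topology, selection)
    if len(idx) < 3:
        raise ValueError("selection resolves to fewer than 3 atoms")
    fit_idx = idx if fit_selection is None else select_atoms(ensemble.topology, fit_selection)
    if isinstance(reference, str):
        if reference == "first":
            ref = ensemble.frames[0]
        elif reference == "mean":
            ref, _ = _iterative_mean(ensemble.frames, fit_idx)
        else:
            raise ValueError(f"unknown reference {reference!r}")
    else:
        ref = ensemble.frames[int(reference)]
    out = np.empty(ensemble.n_frames)
    for i, f in enumerate(ensemble.frames):
        g = kabsch_superpose(f[fit_idx], ref[fit_idx]).apply(f) if superpose else f
        out[i] = float(np.sqrt(np.mean(np.sum((g[idx] - ref[idx]) ** 2, axis=1))))
    return out


def rmsf_profile(
    ensemble: Ensemble,
    selection: str | Sequence[int] = "ca",
    fit_selection: str | Sequence[int] | None = None,
    superpose: bool = True,
    tol: float = 1e-6,
    max_iter: int = 20,
) -> dict[ResidueKey, float]:
    """Per-residue RMSF about the converged mean structure.

    RMSF_i = sqrt(<|r_i - <r_i>|^2>) over frames, computed on the selection
    atoms (CA by default, so one value per residue) after iterative
    superposition onto the mean.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF is undefined for a single frame")
    idx = select_atoms(ensemble.topology, selection)
    fit_idx = idx if fit_selection is None else select_atoms(ensemble.topology, fit_selection)
    if superpose:
        _, fitted = _iterative_mean(ensemble.frames, fit_idx, tol, max_iter)
    else:
        fitted = ensemble.frames
    stack = np.array([f[idx] for f in fitted])          # (frames, sel, 3)
    mean = stack.mean(axis=0)
    msf = np.mean(np.sum((stack - mean) ** 2, axis=2), axis=0)
    rmsf = np.sqrt(msf)
    keys = _selection_residues(ensemble.topology, idx)
    out: dict[ResidueKey, list[float]] = {}
    for k, v in zip(keys, rmsf):
        out.setdefault(k, []).append(float(v))
    return {k: float(np.sqrt(np.mean(np.square(v)))) for k, v in out.items()}


@dataclass
class Dccm:
    """Normalized cross-correlations of residue displacement vectors."""

    matrix: np.ndarray
    residues: list[ResidueKey]

    def entry(self, key_a: ResidueKey, key_b: ResidueKey) -> float:
        ia = self.residues.index(tuple(key_a))
        ib = self.residues.index(tuple(key_b))
        return float(self.matrix[ia, ib])


def dccm(
    ensemble: Ensemble,
    selection: str | Sequence[int] = "ca",
    fit_selection: str | Sequence[int] | None = None,
    superpose: bool = True,
) -> Dccm:
    """Dynamic cross-correlation matrix C_ij = <dr_i . dr_j> /
    sqrt(<|dr_i|^2><|dr_j|^2>) with deviations taken from the superposed
    mean; +1 is in-phase, -1 anti-phase motion.  Zero-variance residues get
    NaN rows/columns."""
    if ensemble.n_frames < 2:
        raise ValueError("DCCM needs at least 2 frames")
    idx = select_atoms(ensemble.topology, selection)
    fit_idx = idx if fit_selection is None else select_atoms(ensemble.topology, fit_selection)
    if superpose:
        _, fitted = _iterative_mean(ensemble.frames, fit_idx)
    else:
        fitted = ensemble.frames
    stack = np.array([f[idx] for f in fitted])
    dev = stack - stack.mean(axis=0)                     # (frames, sel, 3)
    cov = np.einsum("fik,fjk->ij", dev, dev) / len(dev)  # <dr_i . dr_j>
    var = np.diag(cov).copy()
    zero = var < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(np.outer(var, var))
        matrix = cov / denom
    matrix[zero, :] = np.nan
    matrix[:, zero] = np.nan
    good = ~zero
    matrix[np.ix_(good, good)] = np.clip(matrix[np.ix_(good, good)], -1.0, 1.0)
    np.fill_diagonal(matrix, np.where(zero, np.nan, 1.0))
    return Dccm(matrix, _selection_residues(ensemble.topology, idx))


# ---------------------------------------------------------------------------
# hydrogen bonds and salt bridges

@dataclass
class BondObservation:
    """A donor/acceptor (or acidic/basic) pair tracked over frames."""

    kind: str                              # 'hydrogen_bond' or 'salt_bridge'
    donor: tuple[ResidueKey, str]          # (residue key, atom name)
    acceptor: tuple[ResidueKey, str]
    distance: list[float] = field(default_factory=list)   # per frame, A
    angle: list[float] = field(default_factory=list)      # per frame, deg (NaN if n/a)
    present: list[bool] = field(default_factory=list)
    distance_only: bool = False            # no H available: distance criterion only

    @property
    def occupancy(self) -> float:
        if not self.present:
            return float("nan")
        return sum(self.present) / len(self.present)


def _reconstruct_amide_h(
    n: np.ndarray, ca: np.ndarray, c_prev: np.ndarray
) -> np.ndarray:
    """Backbone amide H from N, CA and the preceding C: H sits on N, opposite
    the bisector of the two covalent neighbours."""
    u1 = c_prev - n
    u2 = ca - n
    u1 = u1 / np.linalg.norm(u1)
    u2 = u2 / np.linalg.norm(u2)
    d = -(u1 + u2)
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        return n + np.array([AMIDE_NH_LENGTH, 0.0, 0.0])
    return n + AMIDE_NH_LENGTH * d / norm


def _bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u = a - b
    v = c - b
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        return float("nan")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def _donor_inventory(topology: Structure, coords: np.ndarray) -> list[dict]:
    """Donor atoms (N/O) with their hydrogen positions: explicit H within
    1.3 A, else a reconstructed backbone amide H, else distance-only."""
    ids = topology.atom_ids()
    pos = {id_: coords[i] for i, id_ in enumerate(ids)}
    donors: list[dict] = []
    residues = topology.residues
    for ri, res in enumerate(residues):
        for atom in res.atoms:
            if atom.element not in ("N", "O"):
                continue
            aid = (res.key, atom.name)
            hydrogens = [
                pos[(res.key, a.name)]
                for a in res.atoms
                if a.element == "H"
                and np.linalg.norm(pos[(res.key, a.name)] - pos[aid]) <= 1.3
            ]
            if hydrogens:
                donors.append({"id": aid, "res_i": ri, "h": hydrogens, "fallback": False})
            elif atom.name == "N":
                if ri > 0 and residues[ri - 1].chain_id == res.chain_id:
                    c_prev = pos.get((residues[ri - 1].key, "C"))
                    ca = pos.get((res.key, "CA"))
                    if c_prev is not None and ca is not None:
                        h = _reconstruct_amide_h(pos[aid], ca, c_prev)
                        donors.append(
                            {"id": aid, "res_i": ri, "h": [h], "fallback": False}
                        )
                        continue
                # chain-terminal or incomplete backbone: distance-only
                donors.append({"id": aid, "res_i": ri, "h": [], "fallback": True})
            elif atom.name not in ("O", "OXT"):
                # side-chain O donor without explicit H: distance-only
                donors.append({"id": aid, "res_i": ri, "h": [], "fallback": True})
    return donors


def detect_hydrogen_bonds(
    topology: Structure,
    frame: np.ndarray | None = None,
    d_max_da: float = 3.5,
    angle_min: float = 120.0,
) -> list[BondObservation]:
    """Geometric hydrogen bonds in one frame.

    A bond requires donor-acceptor distance <= ``d_max_da`` and, when a
    hydrogen is present or reconstructable, D-H...A angle >= ``angle_min``;
    donors with no usable hydrogen fall back to the distance criterion alone
    and are flagged ``distance_only``.  Pairs within one residue and the
    covalent N(i)->O(i-1) peptide pair are excluded.
    """
    coords = topology.coords() if frame is None else np.asarray(frame, dtype=float)
    ids = topology.atom_ids()
    pos = {id_: coords[i] for i, id_ in enumerate(ids)}
    residues = topology.residues
    res_index = {r.key: i for i, r in enumerate(residues)}
    donors = _donor_inventory(topology, coords)
    acceptors = [
        ((r.key, a.name), res_index[r.key])
        for r in residues
        for a in r.atoms
        if a.element in ("N", "O")
    ]
    bonds: list[BondObservation] = []
    for don in donors:
        d_pos = pos[don["id"]]
        for acc_id, acc_ri in acceptors:
            if acc_id == don["id"] or acc_ri == don["res_i"]:
                continue
            # exclude the covalent peptide-bond pair N(i) -> O(i-1)
            if (
                don["id"][1] == "N"
                and acc_id[1] == "O"
                and acc_ri == don["res_i"] - 1
            ):
                continue
            a_pos = pos[acc_id]
            dist = float(np.linalg.norm(a_pos - d_pos))
            if dist > d_max_da or dist < 1.5:
                continue
            if don["h"]:
                angles = [_bond_angle(d_pos, h, a_pos) for h in don["h"]]
                best = float(np.nanmax(angles))
                if best < angle_min:
                    continue
                angle = best
                fallback = False
            else:
                angle = float("nan")
                fallback = True
            bonds.append(
                BondObservation(
                    kind="hydrogen_bond",
                    donor=don["id"],
                    acceptor=acc_id,
                    distance=[dist],
                    angle=[angle],
                    present=[True],
                    distance_only=fallback,
                )
            )
    bonds.sort(key=lambda b: (b.donor, b.acceptor))
    return bonds


def hbond_count_series(
    ensemble: Ensemble, d_max_da: float = 3.5, angle_min: float = 120.0
) -> np.ndarray:
    """Number of detected hydrogen bonds in each frame."""
    return np.array(
        [
            len(detect_hydrogen_bonds(ensemble.topology, f, d_max_da, angle_min))
            for f in ensemble.frames
        ],
        dtype=int,
    )


def salt_bridge_occupancy(
    ensemble: Ensemble,
    acidic_residue: ResidueKey,
    basic_residue: ResidueKey,
    d_cut: float = 4.0,
) -> BondObservation:
    """Occupancy of a salt bridge: fraction of frames in which the minimum
    side-chain O (Asp/Glu) to side-chain N (Arg/Lys/His) distance is within
    ``d_cut``.  The per-frame minimum-distance series is retained so that
    contact tightening can be reported alongside the occupancy."""
    topo = ensemble.topology
    acid = topo[acidic_residue]
    base = topo[basic_residue]
    if acid.res_name not in SIDECHAIN_O:
        raise ValueError(
            f"residue {format_residue_key(acid.key)} ({acid.res_name}) is not Asp/Glu"
        )
    if base.res_name not in SIDECHAIN_N:
        raise ValueError(
            f"residue {format_residue_key(base.key)} ({base.res_name}) is not Arg/Lys/His"
        )
    ids = topo.atom_ids()
    o_idx = [
        i for i, (k, n) in enumerate(ids)
        if k == acid.key and n in SIDECHAIN_O[acid.res_name]
    ]
    n_idx = [
        i for i, (k, n) in enumerate(ids)
        if k == base.key and n in SIDECHAIN_N[base.res_name]
    ]
    if not o_idx or not n_idx:
        raise ValueError("salt-bridge residues lack the required side-chain atoms")
    obs = BondObservation(
        kind="salt_bridge",
        donor=(base.key, SIDECHAIN_N[base.res_name][0]),
        acceptor=(acid.key, SIDECHAIN_O[acid.res_name][0]),
        distance_only=True,
    )
    for f in ensemble.frames:
        d = np.linalg.norm(f[o_idx][:, None, :] - f[n_idx][None, :, :], axis=-1)
        dmin = float(d.min())
        obs.distance.append(dmin)
        obs.angle.append(float("nan"))
        obs.present.append(dmin <= d_cut)
    return obs


# ---------------------------------------------------------------------------
# CNA transition temperature

@dataclass(frozen=True)
class CnaPoint:
    """One thermal-dilution point: hydrogen-bond energy cutoff (kcal/mol,
    <= 0) and rigidity order parameter P-infinity in [0, 1]."""

    e_cut: float
    p_inf: float


@dataclass
class TransitionResult:
    found: bool
    e_cut: float = float("nan")
    temperature: float = float("nan")
    drop: float = float("nan")


def cna_temperature(e_cut: float) -> float:
    """Map a hydrogen-bond energy cutoff (kcal/mol) to a transition
    temperature (K): T = -20 * E_cut + 300."""
    if not math.isfinite(e_cut):
        raise ValueError("e_cut must be finite")
    return -20.0 * e_cut + 300.0


def find_transition(series: Sequence[CnaPoint]) -> TransitionResult:
    """Locate the rigid-to-flexible transition on a P-infinity series.

    The transition is the e_cut at which the largest single-step drop in
    P-infinity lands (the first point of the collapsed regime); ties favour
    the larger (less negative) e_cut.  A series with no drop yields a
    no-transition result.
    """
    pts = list(series)
    if len(pts) < 3:
        raise ValueError("need at least 3 CNA points")
    e = [p.e_cut for p in pts]
    if any(e[i + 1] >= e[i] for i in range(len(e) - 1)):
        raise ValueError("CNA series must be ordered by strictly decreasing e_cut")
    drops = [pts[i].p_inf - pts[i + 1].p_inf for i in range(len(pts) - 1)]
    best = max(drops)
    if best <= 0:
        return TransitionResult(found=False)
    k = drops.index(best)  # earliest (largest e_cut) on ties
    e_t = pts[k + 1].e_cut
    return TransitionResult(
        found=True, e_cut=e_t, temperature=cna_temperature(e_t), drop=best
    )


def load_cna_series(text: str) -> list[CnaPoint]:
    """Two-column delimited text (e_cut kcal/mol, p_inf) -> ordered series."""
    df = pd.read_csv(io.StringIO(text), sep=r"\s+|\t|,", engine="python",
                     comment="#", header=None, names=["e_cut", "p_inf"])
    df = df.dropna()
    pts = [CnaPoint(float(r.e_cut), float(r.p_inf)) for r in df.itertuples()]
    pts.sort(key=lambda p: -p.e_cut)
    return pts
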