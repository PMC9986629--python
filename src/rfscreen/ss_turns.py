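"""Secondary-structure assignment and beta-turn detection/typing.

Secondary structure is assigned from backbone torsions alone (no hydrogen
atoms required): a helix is a run of >= 4 consecutive residues in the
alpha-helical phi/psi window, a sheet a run of >= 3 in the extended window,
everything else (including residues whose torsions are undefined) is loop.

A beta-turn is a four-residue window i..i+3 whose chain reverses direction:
CA(i)-CA(i+3) within a distance cutoff (7 A by default) with the two central
residues non-helical.  Turns are typed I/II/I'/II'/VIII from the central
residues' torsions against canonical values, falling back to the
miscellaneous type IV.  Position-specific amino-acid preferences (the reason
Xaa->Pro substitutions at i+1 rigidify turns so effectively) are served from
an embedded propensity table that can be overridden from delimited text.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import dihedral_angle
from .structure import (
    AA1_TO_3,
    AA3_TO_1,
    ResidueKey,
    ResidueRecord,
    Structure,
)

__all__ = [
    "SsAssignment",
    "BetaTurn",
    "TurnPreferenceTable",
    "TURN_POSITIONS",
    "CANONICAL_TURN_TYPES",
    "backbone_dihedrals",
    "assign_secondary_structure",
    "detect_beta_turns",
    "preference_score",
]

TURN_POSITIONS = ("i", "i+1", "i+2", "i+3")

# canonical (phi, psi) of the two central residues; matched in listed order
CANONICAL_TURN_TYPES: list[tuple[str, tuple[float, float], tuple[float, float]]] = [
    ("I", (-60.0, -30.0), (-90.0, 0.0)),
    ("II", (-60.0, 120.0), (80.0, 0.0)),
    ("I'", (60.0, 30.0), (90.0, 0.0)),
    ("II'", (60.0, -120.0), (-80.0, 0.0)),
    ("VIII", (-60.0, -30.0), (-120.0, 120.0)),
]

HELIX_PHI = (-90.0, -30.0)
HELIX_PSI = (-77.0, -17.0)
SHEET_PHI = (-170.0, -70.0)
# sheet psi: [80, 180) or (-180, -170]
PEPTIDE_BOND_MAX = 2.5  # A, C(i)-N(i+1) continuity cutoff


@dataclass
class SsAssignment:
    """Per-residue class: 'helix', 'sheet' or 'loop'."""

    classes: dict[ResidueKey, str]

    def __getitem__(self, key: ResidueKey) -> str:
        return self.classes[tuple(key)]

    def residues_in_class(self, ss_class: str) -> list[ResidueKey]:
        return [k for k, c in self.classes.items() if c == ss_class]


@dataclass
class BetaTurn:
    """Four-residue chain reversal i..i+3 with geometric type."""

    index: int                                   # 1-based, N-to-C
    residues: tuple[ResidueKey, ResidueKey, ResidueKey, ResidueKey]
    turn_type: str                               # I, II, I', II', VIII or IV
    ca_i_to_i3: float                            # A
    phi_psi: tuple[tuple[float, float], ...]     # four (phi, psi) pairs, deg

    def position_of(self, key: ResidueKey) -> str | None:
        key = tuple(key)
        for pos, res in zip(TURN_POSITIONS, self.residues):
            if res == key:
                return pos
        return None


# ---------------------------------------------------------------------------
# dihedrals

def _chain_runs(structure: Structure) -> list[list[ResidueRecord]]:
    """Split residues into covalently continuous runs (chain + peptide bond)."""
    runs: list[list[ResidueRecord]] = []
    current: list[ResidueRecord] = []
    for res in structure.residues:
        if current:
            prev = current[-1]
            c = prev.atom("C")
            n = res.atom("N")
            connected = (
                res.chain_id == prev.chain_id
                and c is not None
                and n is not None
                and float(np.linalg.norm(c.coords - n.coords)) <= PEPTIDE_BOND_MAX
            )
            if not connected:
                runs.append(current)
                current = []
        current.append(res)
    if current:
        runs.append(current)
    return runs


def backbone_dihedrals(structure: Structure) -> dict[ResidueKey, tuple[float, float]]:
    """Per-residue (phi, psi) in degrees; NaN where undefined (termini,
    missing backbone atoms, or degenerate geometry)."""
    out: dict[ResidueKey, tuple[float, float]] = {}
    for run in _chain_runs(structure):
        for idx, res in enumerate(run):
            n = res.atom("N")
            ca = res.atom("CA")
            c = res.atom("C")
            phi = psi = float("nan")
            if n is not None and ca is not None and c is not None:
                if idx > 0:
                    c_prev = run[idx - 1].atom("C")
                    if c_prev is not None:
                        phi = dihedral_angle(c_prev.coords, n.coords, ca.coords, c.coords)
                        if math.isnan(phi):
                            warnings.warn(
                                f"degenerate phi geometry at residue {res.key}", stacklevel=2
                            )
                if idx < len(run) - 1:
                    n_next = run[idx + 1].atom("N")
                    if n_next is not None:
                        psi = dihedral_angle(n.coords, ca.coords, c.coords, n_next.coords)
                        if math.isnan(psi):
                            warnings.warn(
                                f"degenerate psi geometry at residue {res.key}", stacklevel=2
                            )
            out[res.key] = (phi, psi)
    return out


# ---------------------------------------------------------------------------
# secondary structure

def _helix_compatible(phi: float, psi: float) -> bool:
    return (
        not math.isnan(phi) and not math.isnan(psi)
        and HELIX_PHI[0] <= phi <= HELIX_PHI[1]
        and HELIX_PSI[0] <= psi <= HELIX_PSI[1]
    )


def _sheet_compatible(phi: float, psi: float) -> bool:
    return (
        not math.isnan(phi) and not math.isnan(psi)
        and SHEET_PHI[0] <= phi <= SHEET_PHI[1]
        and (80.0 <= psi < 180.0 or -180.0 < psi <= -170.0)
    )


def assign_secondary_structure(
    structure: Structure,
    dihedrals: dict[ResidueKey, tuple[float, float]] | None = None,
) -> SsAssignment:
    """Three-class torsion-window assignment (helix / sheet / loop)."""
    if dihedrals is None:
        dihedrals = backbone_dihedrals(structure)
    classes: dict[ResidueKey, str] = {}
    for run in _chain_runs(structure):
        keys = [r.key for r in run]
        helix_ok = [_helix_compatible(*dihedrals[k]) for k in keys]
        sheet_ok = [_sheet_compatible(*dihedrals[k]) for k in keys]
        assigned = ["loop"] * len(keys)
        for ok, label, min_run in ((helix_ok, "helix", 4), (sheet_ok, "sheet", 3)):
            start = 0
            while start < len(keys):
                if not ok[start]:
                    start += 1
                    continue
                end = start
                while end < len(keys) and ok[end]:
                    end += 1
                if end - start >= min_run:
                    for j in range(start, end):
                        assigned[j] = label
                start = end
        classes.update(zip(keys, assigned))
    return SsAssignment(classes)


# ---------------------------------------------------------------------------
# beta-turn detection and typing

def _angle_diff(a: float, b: float) -> float:
    if math.isnan(a) or math.isnan(b):
        return float("inf")
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def _classify_turn(phi2: float, psi2: float, phi3: float, psi3: float) -> str:
    """Type from central torsions: all four within 30 deg of canonical with at
    most one excursion up to 45 deg; otherwise the miscellaneous type IV."""
    for name, (c_phi2, c_psi2), (c_phi3, c_psi3) in CANONICAL_TURN_TYPES:
        diffs = [
            _angle_diff(phi2, c_phi2),
            _angle_diff(psi2, c_psi2),
            _angle_diff(phi3, c_phi3),
            _angle_diff(psi3, c_psi3),
        ]
        if max(diffs) <= 45.0 and sum(d > 30.0 for d in diffs) <= 1:
            return name
    return "IV"


def detect_beta_turns(
    structure: Structure,
    ss: SsAssignment | None = None,
    distance_cutoff: float = 7.0,
    dihedrals: dict[ResidueKey, tuple[float, float]] | None = None,
) -> list[BetaTurn]:
    """Detect and type beta-turns; overlapping windows are all reported and
    numbered 1..n from the N terminus."""
    if dihedrals is None:
        dihedrals = backbone_dihedrals(structure)
    if ss is None:
        ss = assign_secondary_structure(structure, dihedrals)
    turns: list[BetaTurn] = []
    for run in _chain_runs(structure):
        for i in range(len(run) - 3):
            window = run[i:i + 4]
            cas = [r.ca for r in window]
            if any(ca is None for ca in cas):
                continue
            dist = float(np.linalg.norm(cas[0].coords - cas[3].coords))
            if dist > distance_cutoff:
                continue
            if ss[window[1].key] == "helix" or ss[window[2].key] == "helix":
                continue
            phi_psi = tuple(dihedrals[r.key] for r in window)
            turn_type = _classify_turn(
                phi_psi[1][0], phi_psi[1][1], phi_psi[2][0], phi_psi[2][1]
            )
            turns.append(
                BetaTurn(
                    index=0,
                    residues=tuple(r.key for r in window),
                    turn_type=turn_type,
                    ca_i_to_i3=dist,
                    phi_psi=phi_psi,
                )
            )
    for n, t in enumerate(turns, start=1):
        t.index = n
    return turns


# ---------------------------------------------------------------------------
# position-specific amino-acid preferences

# Embedded aggregate positional propensities (dimensionless, ~1 = average).
# The qualitative structure follows classical beta-turn statistics: proline
# dominates i+1, glycine i+3, and the polar turn formers (Asn/Asp/Ser) are
# enriched at i.
_DEFAULT_PREFERENCES: dict[str, tuple[float, float, float, float]] = {
    #        i     i+1   i+2   i+3
    "A": (0.80, 1.00, 0.70, 0.80),
    "R": (0.90, 0.90, 1.00, 0.90),
    "N": (1.60, 0.90, 1.50, 1.20),
    "D": (1.50, 1.40, 1.50, 0.90),
    "C": (1.10, 0.70, 0.90, 1.00),
    "Q": (0.90, 1.00, 0.80, 0.90),
    "E": (0.80, 1.10, 0.90, 0.90),
    "G": (1.20, 0.90, 1.90, 2.10),
    "H": (1.20, 0.90, 1.00, 1.10),
    "I": (0.60, 0.50, 0.40, 0.70),
    "L": (0.60, 0.60, 0.50, 0.70),
    "K": (0.90, 1.00, 1.10, 1.10),
    "M": (0.60, 0.70, 0.50, 0.80),
    "F": (0.80, 0.60, 0.60, 0.90),
    "P": (1.30, 2.80, 0.60, 0.40),
    "S": (1.40, 1.20, 1.30, 1.10),
    "T": (1.20, 1.10, 0.90, 1.00),
    "W": (0.90, 0.70, 0.60, 0.90),
    "Y": (1.00, 0.60, 0.70, 1.00),
    "V": (0.60, 0.50, 0.40, 0.70),
}


def _normalize_aa(aa: str) -> str:
    aa = aa.strip().upper()
    if len(aa) == 3:
        if aa not in AA3_TO_1:
            raise ValueError(f"unknown amino-acid code {aa!r}")
        return AA3_TO_1[aa]
    if len(aa) == 1 and aa in AA1_TO_3:
        return aa
    raise ValueError(f"unknown amino-acid code {aa!r}")


@dataclass
class TurnPreferenceTable:
    """Mapping (amino acid, turn position) -> propensity score (>= 0)."""

    scores: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for aa in _DEFAULT_PREFERENCES:
            for pos in TURN_POSITIONS:
                if (aa, pos) not in self.scores:
                    raise ValueError(f"preference table missing entry ({aa}, {pos})")
                if self.scores[(aa, pos)] < 0:
                    raise ValueError(f"negative propensity for ({aa}, {pos})")

    @classmethod
    def default(cls) -> "TurnPreferenceTable":
        scores = {
            (aa, pos): float(vals[j])
            for aa, vals in _DEFAULT_PREFERENCES.items()
            for j, pos in enumerate(TURN_POSITIONS)
        }
        return cls(scores)

    @classmethod
    def from_text(cls, text: str, sep: str | None = None) -> "TurnPreferenceTable":
        """Load from delimited text: header ``aa  i  i+1  i+2  i+3``,
        one row per amino acid (1- or 3-letter codes)."""
        df = pd.read_csv(io.StringIO(text), sep=sep or r"\s+|\t|,", engine="python")
        df.columns = [str(c).strip() for c in df.columns]
        missing = [p for p in TURN_POSITIONS if p not in df.columns]
        if missing:
            raise ValueError(f"preference table missing column(s) {missing}")
        scores: dict[tuple[str, str], float] = {}
        aa_col = df.columns[0]
        for _, row in df.iterrows():
            aa = _normalize_aa(str(row[aa_col]))
            for pos in TURN_POSITIONS:
                scores[(aa, pos)] = float(row[pos])
        return cls(scores)

    def score(self, amino_acid: str, turn_position: str) -> float:
        if turn_position not in TURN_POSITIONS:
            raise ValueError(
                f"turn position must be one of {TURN_POSITIONS}, got {turn_position!r}"
            )
        return self.scores[(_normalize_aa(amino_acid), turn_position)]


def preference_score(
    table: TurnPreferenceTable, substitution: str, turn_position: str
) -> float:
    """Positional propensity of placing ``substitution`` at ``turn_position``."""
    return table.score(substitution, turn_position)
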