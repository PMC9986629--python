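"""Deterministic, seeded generators for every input the pipeline consumes.

Each generator emits both the data and its planted ground truth, so that
analyses can be exercised as plant-and-recover experiments: peptides with
ideal backbone geometry and chosen secondary structure, coordinate ensembles
with planted per-residue mobility / correlated motion / bond occupancy
patterns, alignments with specified per-column conservation, saturation
ddG tables with a planted stable set, and noisy kinetics datasets.

Identical (spec, seed) always produces bit-identical output; all randomness
flows through a single ``numpy`` Generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import dihedral_angle
from .ss_turns import CANONICAL_TURN_TYPES, TURN_POSITIONS
from .structure import (
    AA1_TO_3,
    AA3_TO_1,
    Atom,
    Ensemble,
    ResidueKey,
    ResidueRecord,
    Structure,
    format_residue_key,
)

__all__ = [
    "build_peptide",
    "build_ensemble",
    "build_msa",
    "build_ddg_table",
    "build_assay_data",
    "build_screen_fixture",
    "PeptidePlant",
    "EnsemblePlant",
    "SaltBridgePlant",
    "HydrogenBondPlant",
    "CorrelatedBlock",
    "ScreenFixture",
]

# ideal backbone internal coordinates (A / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA = 180.0

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-120.0, 130.0)
# central-residue torsions for the miscellaneous type IV plant: compact but
# outside every canonical window
TYPE_IV_PHI_PSI = ((-150.0, -100.0), (-75.0, 0.0))

_CANONICAL = {name: (c2, c3) for name, c2, c3 in CANONICAL_TURN_TYPES}


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle: float, torsion: float,
) -> np.ndarray:
    """Internal-coordinate (NeRF) placement: the new atom d has |c-d| = bond,
    angle(b, c, d) = angle and torsion(a, b, c, d) = torsion (degrees)."""
    ang = math.radians(angle)
    tor = -math.radians(torsion)  # sign matches geometry.dihedral_angle
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


@dataclass
class PeptidePlant:
    """Ground truth emitted with a synthetic peptide."""

    sequence: str
    phi_psi: list[tuple[float, float]]                  # intended torsions
    planted_ss: list[str]                               # expected 3-class labels
    planted_turns: list[tuple[tuple[ResidueKey, ...], str]]   # (window, type)
    b_factors: list[float]


def _normalize_segments(segments) -> list[tuple]:
    out = []
    for seg in segments:
        kind = seg[0]
        if kind == "helix":
            out.append(("helix", int(seg[1])))
        elif kind == "strand":
            out.append(("strand", int(seg[1])))
        elif kind == "turn":
            ttype = seg[1]
            if ttype not in _CANONICAL and ttype != "IV":
                raise ValueError(f"unknown turn type {ttype!r}")
            out.append(("turn", ttype))
        elif kind == "loop":
            out.append(("loop", int(seg[1]), tuple(seg[2])))
        else:
            raise ValueError(f"unknown segment type {kind!r}")
    return out


def _segment_torsions(segments) -> tuple[list[tuple[float, float]], list[tuple[int, str]]]:
    """Per-residue (phi, psi) plus (start-index, type) of each planted turn.

    A turn segment contributes the two central residues (i+1, i+2) at the
    canonical torsions; the planted four-residue window spans the flanking
    residues of the neighbouring segments.
    """
    torsions: list[tuple[float, float]] = []
    turn_starts: list[tuple[int, str]] = []
    for seg in segments:
        if seg[0] == "helix":
            torsions.extend([HELIX_PHI_PSI] * seg[1])
        elif seg[0] == "strand":
            torsions.extend([STRAND_PHI_PSI] * seg[1])
        elif seg[0] == "loop":
            torsions.extend([seg[2]] * seg[1])
        else:
            ttype = seg[1]
            central = _CANONICAL.get(ttype, TYPE_IV_PHI_PSI)
            start = len(torsions) - 1
            if start < 0:
                raise ValueError("a turn segment cannot open the chain")
            turn_starts.append((start, ttype))
            torsions.extend([tuple(central[0]), tuple(central[1])])
    return torsions, turn_starts


def _build_backbone(torsions: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    n_res = len(torsions)
    res_atoms: list[dict[str, np.ndarray]] = [{} for _ in range(n_res)]
    ang = math.radians(180.0 - ANGLE_N_CA_C)
    res_atoms[0]["N"] = np.zeros(3)
    res_atoms[0]["CA"] = np.array([BOND_N_CA, 0.0, 0.0])
    res_atoms[0]["C"] = res_atoms[0]["CA"] + BOND_CA_C * np.array(
        [math.cos(ang), math.sin(ang), 0.0]
    )
    for i in range(n_res):
        n, ca, c = res_atoms[i]["N"], res_atoms[i]["CA"], res_atoms[i]["C"]
        psi = torsions[i][1]
        if i < n_res - 1:
            n_next = place_atom(n, ca, c, BOND_C_N, ANGLE_CA_C_N, psi)
            ca_next = place_atom(ca, c, n_next, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
            phi_next = torsions[i + 1][0]
            c_next = place_atom(c, n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phi_next)
            res_atoms[i + 1]["N"] = n_next
            res_atoms[i + 1]["CA"] = ca_next
            res_atoms[i + 1]["C"] = c_next
        res_atoms[i]["O"] = place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
    return res_atoms


_SIDECHAIN_RECIPES: dict[str, list[tuple[str, tuple[str, str, str], float, float, float]]] = {
    # atom, (a, b, c) reference atoms, bond, angle, torsion
    "ASP": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.0, 180.0),
        ("OD1", ("CA", "CB", "CG"), 1.25, 118.0, 0.0),
        ("OD2", ("CA", "CB", "CG"), 1.25, 118.0, 180.0),
    ],
    "GLU": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.0, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.52, 114.0, 180.0),
        ("OE1", ("CB", "CG", "CD"), 1.25, 118.0, 0.0),
        ("OE2", ("CB", "CG", "CD"), 1.25, 118.0, 180.0),
    ],
    "LYS": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.0, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.52, 114.0, 180.0),
        ("CE", ("CB", "CG", "CD"), 1.52, 112.0, 180.0),
        ("NZ", ("CG", "CD", "CE"), 1.49, 112.0, 180.0),
    ],
    "ARG": [
        ("CG", ("N", "CA", "CB"), 1.52, 114.0, 180.0),
        ("CD", ("CA", "CB", "CG"), 1.52, 114.0, 180.0),
        ("NE", ("CB", "CG", "CD"), 1.46, 112.0, 180.0),
        ("CZ", ("CG", "CD", "NE"), 1.33, 124.0, 180.0),
        ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0.0),
        ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 180.0),
    ],
}


def _add_sidechain(atoms: dict[str, np.ndarray], res_name: str) -> None:
    if res_name == "GLY":
        return
    atoms["CB"] = place_atom(
        atoms["C"], atoms["N"], atoms["CA"], 1.53, 110.5, -120.0
    )
    for name, (ra, rb, rc), bond, angle, torsion in _SIDECHAIN_RECIPES.get(res_name, []):
        atoms[name] = place_atom(atoms[ra], atoms[rb], atoms[rc], bond, angle, torsion)


def _expected_ss(torsions: list[tuple[float, float]]) -> list[str]:
    """Apply the torsion-window run rules to the planted angles (termini have
    an undefined phi or psi and therefore class loop)."""
    from .ss_turns import _helix_compatible, _sheet_compatible  # shared windows

    n = len(torsions)
    eff = []
    for i, (phi, psi) in enumerate(torsions):
        if i == 0 or i == n - 1:
            eff.append((float("nan"), float("nan")))
        else:
            eff.append((phi, psi))
    labels = ["loop"] * n
    for compat, label, min_run in (
        ([_helix_compatible(*t) for t in eff], "helix", 4),
        ([_sheet_compatible(*t) for t in eff], "sheet", 3),
    ):
        i = 0
        while i < n:
            if not compat[i]:
                i += 1
                continue
            j = i
            while j < n and compat[j]:
                j += 1
            if j - i >= min_run:
                for k in range(i, j):
                    labels[k] = label
            i = j
    return labels


def build_peptide(
    segments,
    seed: int = 0,
    sequence: str | None = None,
    b_factor_profile=None,
    chain_id: str = "A",
    start_res: int = 1,
    structure_id: str = "synthetic-peptide",
    sidechains: bool = True,
    turn_distance_cutoff: float = 7.0,
) -> tuple[Structure, PeptidePlant]:
    """Build an ideal-geometry peptide from secondary-structure segments.

    Segments: ``("helix", n)``, ``("strand", n)``, ``("loop", n, (phi, psi))``
    or ``("turn", type)`` where a turn contributes the two central residues
    at the canonical torsions of that type (I, II, I', II', VIII or IV) and
    the planted window spans the flanking residues.  The generator verifies
    the planted windows geometrically (CA(i)-CA(i+3) within the turn cutoff).
    """
    segs = _normalize_segments(segments)
    torsions, turn_starts = _segment_torsions(segs)
    n_res = len(torsions)
    if n_res < 4:
        raise ValueError("peptide must have at least 4 residues")
    if turn_starts and turn_starts[-1][0] + 3 >= n_res:
        raise ValueError("a turn segment cannot close the chain")
    rng = np.random.default_rng(seed)
    if sequence is None:
        aa1 = sorted(AA1_TO_3)
        sequence = "".join(rng.choice(aa1) for _ in range(n_res))
    if len(sequence) != n_res:
        raise ValueError(f"sequence length {len(sequence)} != residue count {n_res}")
    if b_factor_profile is None:
        b_factor_profile = [20.0] * n_res
    b_factor_profile = [float(b) for b in b_factor_profile]
    if len(b_factor_profile) != n_res:
        raise ValueError("b_factor_profile length mismatch")

    backbone = _build_backbone(torsions)
    residues: list[ResidueRecord] = []
    serial = 0
    for i, atoms in enumerate(backbone):
        res_name = AA1_TO_3[sequence[i].upper()]
        if sidechains:
            _add_sidechain(atoms, res_name)
        rec = ResidueRecord(chain_id, start_res + i, "", res_name, [])
        for name in ("N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NE", "CZ",
                     "NZ", "NH1", "NH2", "OD1", "OD2", "OE1", "OE2"):
            if name in atoms:
                serial += 1
                coords = np.round(atoms[name], 3)  # PDB-precision for round-trips
                rec.atoms.append(Atom(serial, name, name[0], coords, b_factor_profile[i]))
        residues.append(rec)
    structure = Structure(structure_id, residues, source=f"synthetic seed={seed}")

    # planted truth: every window qualifying under the planted torsions and
    # built geometry (turn segments guarantee their own windows; compact
    # overlapping windows are reported by design, so they are truth too)
    planted_ss = _expected_ss(torsions)
    ca = np.array([r.atom("CA").coords for r in residues])
    from .ss_turns import _classify_turn  # shared canonical windows

    planted_turns: list[tuple[tuple[ResidueKey, ...], str]] = []
    for i in range(n_res - 3):
        dist = float(np.linalg.norm(ca[i] - ca[i + 3]))
        if dist > turn_distance_cutoff:
            continue
        if planted_ss[i + 1] == "helix" or planted_ss[i + 2] == "helix":
            continue
        window = tuple(residues[i + j].key for j in range(4))
        ttype = _classify_turn(
            torsions[i + 1][0], torsions[i + 1][1],
            torsions[i + 2][0], torsions[i + 2][1],
        )
        planted_turns.append((window, ttype))
    segment_windows = {residues[start].key for start, _ in turn_starts}
    planted_window_starts = {w[0] for w, _ in planted_turns}
    missing = segment_windows - planted_window_starts
    if missing:
        raise ValueError(
            "planted turn segment(s) failed the geometric turn criterion at "
            + ", ".join(format_residue_key(k) for k in sorted(missing))
        )

    plant = PeptidePlant(
        sequence=sequence,
        phi_psi=torsions,
        planted_ss=planted_ss,
        planted_turns=planted_turns,
        b_factors=b_factor_profile,
    )
    return structure, plant


# ---------------------------------------------------------------------------
# ensembles

@dataclass
class CorrelatedBlock:
    """Residues sharing one latent displacement per frame (sign -1 = anti-phase)."""

    residues: list[ResidueKey]
    signs: list[int]
    sigma: float          # planted RMSF (A) of every member

    def __post_init__(self) -> None:
        if len(self.signs) != len(self.residues):
            raise ValueError("signs and residues must have equal length")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be +1 or -1")


@dataclass
class SaltBridgePlant:
    acidic: ResidueKey
    basic: ResidueKey
    frames_present: set[int]
    present_distance: float = 3.0
    absent_distance: float = 8.0


@dataclass
class HydrogenBondPlant:
    donor: ResidueKey                 # backbone amide N of this residue
    acceptor: ResidueKey
    acceptor_atom: str = "O"
    frames_present: set[int] = field(default_factory=set)
    present_distance: float = 2.9
    absent_distance: float = 6.0


@dataclass
class EnsemblePlant:
    rmsf: dict[ResidueKey, float]                    # planted per-residue RMSF (A)
    block_pairs: list[tuple[ResidueKey, ResidueKey, int]]   # (a, b, expected sign)
    occupancies: dict[tuple[ResidueKey, ResidueKey], float]


def _residue_atom_indices(structure: Structure) -> dict[ResidueKey, np.ndarray]:
    out: dict[ResidueKey, list[int]] = {}
    for i, (key, _) in enumerate(structure.atom_ids()):
        out.setdefault(key, []).append(i)
    return {k: np.array(v) for k, v in out.items()}


def _enforce_salt_bridge(
    frame: np.ndarray,
    structure: Structure,
    plant: SaltBridgePlant,
    present: bool,
    atom_idx: dict[ResidueKey, np.ndarray],
) -> None:
    from .ensemble import SIDECHAIN_N, SIDECHAIN_O

    acid = structure[plant.acidic]
    base = structure[plant.basic]
    ids = structure.atom_ids()
    o_idx = [i for i in atom_idx[acid.key] if ids[i][1] in SIDECHAIN_O[acid.res_name]]
    n_idx = [i for i in atom_idx[base.key] if ids[i][1] in SIDECHAIN_N[base.res_name]]

    def min_pair() -> tuple[float, np.ndarray]:
        d = np.linalg.norm(frame[o_idx][:, None, :] - frame[n_idx][None, :, :], axis=-1)
        io_, in_ = np.unravel_index(np.argmin(d), d.shape)
        vec = frame[n_idx[in_]] - frame[o_idx[io_]]
        return float(d[io_, in_]), vec

    target = plant.present_distance if present else plant.absent_distance
    for _ in range(20):
        dist, vec = min_pair()
        if present and abs(dist - target) < 1e-9:
            break
        if not present and dist >= target - 1e-9:
            break
        norm = np.linalg.norm(vec)
        u = vec / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        frame[atom_idx[base.key]] += (target - dist) * u
    dist, _ = min_pair()
    if present:
        assert dist <= plant.present_distance + 1e-6
    else:
        assert dist >= plant.absent_distance - 1e-6


def _enforce_hydrogen_bond(
    frame: np.ndarray,
    structure: Structure,
    plant: HydrogenBondPlant,
    present: bool,
    atom_positions: dict[tuple[ResidueKey, str], int],
) -> None:
    from .ensemble import _reconstruct_amide_h

    don = structure[plant.donor]
    don_i = structure.residues.index(don)
    if don_i == 0:
        raise ValueError("hydrogen-bond plant donor cannot be the first residue")
    prev = structure.residues[don_i - 1]
    n_pos = frame[atom_positions[(don.key, "N")]]
    ca_pos = frame[atom_positions[(don.key, "CA")]]
    c_prev = frame[atom_positions[(prev.key, "C")]]
    h = _reconstruct_amide_h(n_pos, ca_pos, c_prev)
    u = (h - n_pos) / np.linalg.norm(h - n_pos)
    acc_i = atom_positions[(tuple(plant.acceptor), plant.acceptor_atom)]
    if present:
        # collinear N-H...A geometry at the planted distance
        frame[acc_i] = n_pos + plant.present_distance * u
    else:
        # keep the acceptor at its natural position; push it out along its
        # own direction only if a random displacement strayed into range
        vec = frame[acc_i] - n_pos
        dist = float(np.linalg.norm(vec))
        if dist < plant.absent_distance:
            direction = vec / dist if dist > 1e-9 else u
            frame[acc_i] = n_pos + plant.absent_distance * direction


def build_ensemble(
    structure: Structure,
    n_frames: int,
    seed: int = 0,
    mobility_profile: dict[ResidueKey, float] | None = None,
    correlated_blocks: list[CorrelatedBlock] | None = None,
    bond_plants: list[SaltBridgePlant | HydrogenBondPlant] | None = None,
) -> tuple[Ensemble, EnsemblePlant]:
    """Build a coordinate ensemble with planted per-residue mobility,
    correlated-motion blocks and bond occupancy patterns.

    Each residue is rigidly displaced per frame by an isotropic Gaussian
    scaled so that its planted RMSF equals the requested sigma; residues in
    a correlated block share one latent vector (sign -1 = anti-phase).
    Bond plants are enforced geometrically after displacement sampling, so
    occupancies are exact counts, not probabilities.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    mobility = {tuple(k): float(v) for k, v in (mobility_profile or {}).items()}
    blocks = correlated_blocks or []
    plants = bond_plants or []
    for key in mobility:
        structure[key]
    block_of: dict[ResidueKey, tuple[int, int]] = {}
    for bi, block in enumerate(blocks):
        for key, sign in zip(block.residues, block.signs):
            key = tuple(key)
            structure[key]  # raises if unknown
            block_of[key] = (bi, sign)

    atom_idx = _residue_atom_indices(structure)
    atom_positions = {id_: i for i, id_ in enumerate(structure.atom_ids())}
    base = structure.coords()
    frames: list[np.ndarray] = []
    scale = 1.0 / math.sqrt(3.0)
    for f in range(n_frames):
        frame = base.copy()
        latents = [b.sigma * scale * rng.standard_normal(3) for b in blocks]
        for res in structure.residues:
            key = res.key
            if key in block_of:
                bi, sign = block_of[key]
                disp = sign * latents[bi]
            elif mobility.get(key, 0.0) > 0:
                disp = mobility[key] * scale * rng.standard_normal(3)
            else:
                continue
            frame[atom_idx[key]] += disp
        for plant in plants:
            present = f in plant.frames_present
            if isinstance(plant, SaltBridgePlant):
                _enforce_salt_bridge(frame, structure, plant, present, atom_idx)
            else:
                _enforce_hydrogen_bond(frame, structure, plant, present, atom_positions)
        frames.append(frame)

    rmsf: dict[ResidueKey, float] = {r.key: 0.0 for r in structure.residues}
    rmsf.update(mobility)
    pairs: list[tuple[ResidueKey, ResidueKey, int]] = []
    for block in blocks:
        for key, sign in zip(block.residues, block.signs):
            rmsf[tuple(key)] = block.sigma
        for a in range(len(block.residues)):
            for b in range(a + 1, len(block.residues)):
                pairs.append(
                    (
                        tuple(block.residues[a]),
                        tuple(block.residues[b]),
                        block.signs[a] * block.signs[b],
                    )
                )
    occupancies = {
        (tuple(p.acidic if isinstance(p, SaltBridgePlant) else p.donor),
         tuple(p.basic if isinstance(p, SaltBridgePlant) else p.acceptor)):
        len(p.frames_present) / n_frames
        for p in plants
    }
    return Ensemble(structure.copy(), frames), EnsemblePlant(rmsf, pairs, occupancies)


# ---------------------------------------------------------------------------
# alignments, ddG tables, assay data

def build_msa(
    query_sequence: str,
    match_counts,
    n_homologs: int = 13,
    seed: int = 0,
    query_id: str = "query",
) -> tuple[str, dict[int, float]]:
    """Aligned FASTA in which column ``c`` of the homologs matches the query
    residue in exactly ``match_counts[c]`` of ``n_homologs`` sequences.

    Returns the FASTA text and the planted per-column conservation
    fractions (1-based column -> fraction).
    """
    rng = np.random.default_rng(seed)
    query = query_sequence.upper()
    length = len(query)
    counts = list(match_counts)
    if len(counts) != length:
        raise ValueError("match_counts length must equal query length")
    if any(c < 0 or c > n_homologs for c in counts):
        raise ValueError("match counts must lie in [0, n_homologs]")
    aa_all = sorted(AA1_TO_3)
    homologs = [[""] * length for _ in range(n_homologs)]
    truth: dict[int, float] = {}
    for col in range(length):
        q = query[col]
        matching = rng.permutation(n_homologs)[: counts[col]]
        others = [a for a in aa_all if a != q]
        for h in range(n_homologs):
            if h in matching:
                homologs[h][col] = q
            else:
                homologs[h][col] = others[int(rng.integers(len(others)))]
        truth[col + 1] = counts[col] / n_homologs
    lines = [f">{query_id}", query]
    for h in range(n_homologs):
        lines.append(f">homolog_{h + 1:02d}")
        lines.append("".join(homologs[h]))
    return "\n".join(lines) + "\n", truth


def build_ddg_table(
    positions: list[tuple[ResidueKey, str]],
    stable_set: set[tuple[ResidueKey, str]],
    seed: int = 0,
    threshold: float = -0.5,
) -> tuple[str, set[tuple[ResidueKey, str]]]:
    """Saturation table (19 substitutions per position) whose planted-stable
    entries draw ddG <= threshold and all others draw ddG > threshold.

    Returns the delimited text and the planted stable set (normalized keys).
    """
    rng = np.random.default_rng(seed)
    stable = {(tuple(k), m.upper()) for k, m in stable_set}
    aa_all = sorted(AA1_TO_3)
    lines = ["position\twild\tmut\tddg"]
    emitted = set()
    for key, wild in positions:
        key = tuple(key)
        wild = wild.upper()
        for mut in aa_all:
            if mut == wild:
                continue
            if (key, mut) in stable:
                ddg = float(rng.uniform(-3.0, threshold))
                emitted.add((key, mut))
            else:
                ddg = float(rng.uniform(threshold + 0.05, 3.0))
            lines.append(f"{format_residue_key(key)}\t{wild}\t{mut}\t{ddg:.4f}")
    missing = stable - emitted
    if missing:
        raise ValueError(f"planted stable entries not in positions x substitutions: {missing}")
    return "\n".join(lines) + "\n", stable


def build_assay_data(
    kind: str,
    params: dict,
    noise_sd: float = 0.0,
    n: int = 10,
    seed: int = 0,
    noise_mode: str = "relative",
) -> tuple[str, dict]:
    """Noisy assay tables: Michaelis–Menten (substrate 1..n mg/mL, step 1)
    or first-order decay (times spanning 0-90 min).

    ``noise_mode='relative'`` scales the Gaussian noise by the model value
    (constant coefficient of variation, the usual behaviour of activity
    assays); ``'absolute'`` adds noise of fixed standard deviation.
    """
    if n < 3:
        raise ValueError("need at least 3 data points")
    if noise_mode not in ("relative", "absolute"):
        raise ValueError("noise_mode must be 'relative' or 'absolute'")
    rng = np.random.default_rng(seed)

    def noisy(model: np.ndarray) -> np.ndarray:
        eps = noise_sd * rng.standard_normal(len(model))
        return model + (model * eps if noise_mode == "relative" else eps)

    if kind == "mm":
        vmax = float(params["vmax"])
        km = float(params["km"])
        s = np.arange(1.0, n + 1.0)
        v = np.maximum(noisy(vmax * s / (km + s)), 0.0)
        lines = ["substrate\tvelocity"] + [f"{si:.4f}\t{vi:.6f}" for si, vi in zip(s, v)]
        truth = {"vmax": vmax, "km": km}
    elif kind == "decay":
        k = float(params["k"]) if "k" in params else math.log(2.0) / float(params["t_half"])
        a0 = float(params.get("a0", 100.0))
        t = np.linspace(0.0, 90.0, n)
        a = np.maximum(noisy(a0 * np.exp(-k * t)), 1e-9)
        lines = ["time\tactivity"] + [f"{ti:.4f}\t{ai:.6f}" for ti, ai in zip(t, a)]
        truth = {"k": k, "a0": a0, "t_half": math.log(2.0) / k}
    else:
        raise ValueError("kind must be 'mm' or 'decay'")
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# end-to-end screening fixtures

@dataclass
class ScreenFixture:
    """A complete screening problem plus its independently recounted truth.

    ``expected_pass`` is computed by a plain re-evaluation of each filter
    from the planted facts (planted secondary structure and turn windows,
    planted surface flags, drawn ddG values, planted conservation counts and
    directly recomputed CA distances) — independent of the filter-chain
    implementation under test.
    """

    structure: Structure
    plant: PeptidePlant
    surface_flags: dict[ResidueKey, bool]
    b_factors: dict[ResidueKey, float]
    ddg_text: str
    msa_text: str
    catalytic: tuple[ResidueKey, ...]
    min_catalytic_distance: float
    conservation_counts: dict[int, int]
    n_homologs: int
    expected_pass: set[tuple[ResidueKey, str]]


_TURN_TYPE_CHOICES = ["I", "II", "I'", "II'", "VIII", "IV"]


def build_screen_fixture(seed: int = 0) -> ScreenFixture:
    """Random peptide + ddG table + MSA with a planted filter-chain outcome."""
    rng = np.random.default_rng(seed)

    segments: list[tuple] = [("strand", int(rng.integers(4, 7)))]
    n_turns = int(rng.integers(2, 5))
    for _ in range(n_turns):
        segments.append(("turn", _TURN_TYPE_CHOICES[int(rng.integers(6))]))
        if rng.random() < 0.3:
            segments.append(("strand", int(rng.integers(3, 6))))
            segments.append(("helix", int(rng.integers(4, 8))))
        segments.append(("strand", int(rng.integers(3, 7))))
    n_res = sum(
        seg[1] if seg[0] in ("helix", "strand") else 2 for seg in segments
    )
    b_profile = rng.uniform(10.0, 40.0, size=n_res)
    structure, plant = build_peptide(
        segments, seed=int(rng.integers(2**31)), b_factor_profile=b_profile
    )
    residues = structure.residues
    keys = [r.key for r in residues]

    # catalytic pair in the first strand segment
    catalytic = (keys[0], keys[1])
    surface_flags = {k: bool(rng.random() < 0.65) for k in keys}
    b_factors = {k: float(b) for k, b in zip(keys, b_profile)}

    # saturation ddG over every planted-turn residue plus a few extras
    turn_members: list[ResidueKey] = []
    for window, _ in plant.planted_turns:
        for k in window:
            if k not in turn_members:
                turn_members.append(k)
    extras = [k for k in keys if k not in turn_members]
    rng.shuffle(extras)
    positions = turn_members + extras[:3]
    aa_all = sorted(AA1_TO_3)
    lines = ["position\twild\tmut\tddg"]
    ddg_values: dict[tuple[ResidueKey, str], float] = {}
    for key in positions:
        wild = structure[key].one_letter
        for mut in aa_all:
            if mut == wild:
                continue
            ddg = float(rng.uniform(-3.0, 3.0))
            ddg_values[(key, mut)] = ddg
            lines.append(f"{format_residue_key(key)}\t{wild}\t{mut}\t{ddg:.4f}")
    ddg_text = "\n".join(lines) + "\n"

    n_homologs = 13
    counts = [int(rng.integers(0, n_homologs + 1)) for _ in range(n_res)]
    msa_text, _ = build_msa(
        plant.sequence, counts, n_homologs=n_homologs, seed=int(rng.integers(2**31))
    )
    conservation_counts = {i + 1: c for i, c in enumerate(counts)}

    # distance threshold: median planted-turn distance splits near/far turns
    ca = {r.key: r.atom("CA").coords for r in residues}
    cat_ca = [ca[k] for k in catalytic]

    def mean_dist(window_keys) -> float:
        return float(
            np.mean(
                [
                    np.linalg.norm(ca[k] - c)
                    for k in window_keys
                    for c in cat_ca
                ]
            )
        )

    turn_dists = [mean_dist(w) for w, _ in plant.planted_turns]
    min_catalytic_distance = float(np.median(turn_dists))

    # independent recount of the filter chain
    index = {k: i for i, k in enumerate(keys)}
    expected_pass: set[tuple[ResidueKey, str]] = set()
    for (key, mut), ddg in ddg_values.items():
        in_turn = None
        for window, _ in plant.planted_turns:
            if key in window:
                in_turn = window
                break
        dist = mean_dist(in_turn) if in_turn is not None else mean_dist([key])
        cons = conservation_counts[key[1]] / n_homologs
        ok = (
            plant.planted_ss[index[key]] == "loop"
            and surface_flags[key]
            and in_turn is not None
            and dist >= min_catalytic_distance
            and ddg <= -0.5
            and cons < 0.80
        )
        if ok:
            expected_pass.add((key, mut))

    return ScreenFixture(
        structure=structure,
        plant=plant,
        surface_flags=surface_flags,
        b_factors=b_factors,
        ddg_text=ddg_text,
        msa_text=msa_text,
        catalytic=catalytic,
        min_catalytic_distance=min_catalytic_distance,
        conservation_counts=conservation_counts,
        n_homologs=n_homologs,
        expected_pass=expected_pass,
    )
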