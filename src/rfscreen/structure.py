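"""Protein structures and coordinate ensembles, read from and written to PDB text.

The data model is deliberately small: an :class:`Atom` carries coordinates,
B-factor and occupancy; a :class:`ResidueRecord` groups atoms under an author
residue key ``(chain_id, res_seq, i_code)``; a :class:`Structure` is an ordered
list of residues; an :class:`Ensemble` is one topology plus >= 1 congruent
coordinate frames (the stand-in for a saved trajectory).

Author residue numbering is preserved verbatim.  All cross-module references
use the residue key, never a list index, so that sites can be named the way
structural biologists name them (e.g. chain A, residue 84).
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "ResidueRecord",
    "Structure",
    "Ensemble",
    "PdbParseError",
    "PdbFormatError",
    "ResidueKey",
    "parse_pdb",
    "parse_multimodel_pdb",
    "write_pdb",
    "read_structure",
    "read_ensemble",
    "parse_residue_key",
    "format_residue_key",
]

ResidueKey = tuple  # (chain_id: str, res_seq: int, i_code: str)

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O", "SOL"}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


class PdbParseError(ValueError):
    """Raised when PDB text cannot be parsed (message names the line)."""


class PdbFormatError(ValueError):
    """Raised when a structure cannot be represented in fixed-column PDB."""


@dataclass(eq=False)
class Atom:
    """One atom: name, element, coordinates (A), B-factor (A^2), occupancy."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if self.b_factor < 0:
            warnings.warn(
                f"atom {self.name!r}: negative B-factor {self.b_factor} clamped to 0",
                stacklevel=2,
            )
            self.b_factor = 0.0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Atom):
            return NotImplemented
        return (
            self.name == other.name
            and self.element == other.element
            and np.array_equal(self.coords, other.coords)
            and self.b_factor == other.b_factor
            and self.occupancy == other.occupancy
        )


@dataclass(eq=False)
class ResidueRecord:
    """All atoms of one residue under its author key (chain, res_seq, i_code)."""

    chain_id: str
    res_seq: int
    i_code: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.res_seq, self.i_code)

    @property
    def is_standard(self) -> bool:
        return self.res_name in STANDARD_AA

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.res_name, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    def mean_b_factor(self) -> float:
        return float(np.mean([a.b_factor for a in self.atoms]))

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResidueRecord):
            return NotImplemented
        return (
            self.key == other.key
            and self.res_name == other.res_name
            and self.atoms == other.atoms
        )


@dataclass(eq=False)
class Structure:
    """Ordered residues of one model; residues resolvable by author key."""

    id: str
    residues: list[ResidueRecord]
    source: str = ""

    def __post_init__(self) -> None:
        self._index: dict[ResidueKey, ResidueRecord] = {}
        for r in self.residues:
            if r.key in self._index:
                raise ValueError(f"duplicate residue key {r.key}")
            if not r.atoms:
                raise ValueError(f"residue {r.key} has no atoms")
            self._index[r.key] = r

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[ResidueRecord]:
        return iter(self.residues)

    def __contains__(self, key: ResidueKey) -> bool:
        return tuple(key) in self._index

    def __getitem__(self, key: ResidueKey) -> ResidueRecord:
        try:
            return self._index[tuple(key)]
        except KeyError:
            raise KeyError(f"no residue with key {key!r} in structure {self.id!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Structure):
            return NotImplemented
        return self.residues == other.residues

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def atoms(self) -> Iterator[tuple[ResidueRecord, Atom]]:
        for r in self.residues:
            for a in r.atoms:
                yield r, a

    def coords(self) -> np.ndarray:
        """All atom coordinates, shape (n_atoms, 3), in residue/atom order."""
        return np.array([a.coords for _, a in self.atoms()])

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coords of shape ({self.n_atoms}, 3), got {coords.shape}")
        for i, (_, a) in enumerate(self.atoms()):
            a.coords = coords[i].copy()

    def atom_ids(self) -> list[tuple[ResidueKey, str]]:
        return [(r.key, a.name) for r, a in self.atoms()]

    def sequence(self, chain_id: str | None = None) -> str:
        return "".join(
            r.one_letter for r in self.residues if chain_id is None or r.chain_id == chain_id
        )

    def copy(self) -> "Structure":
        residues = [
            ResidueRecord(
                r.chain_id, r.res_seq, r.i_code, r.res_name,
                [Atom(a.serial, a.name, a.element, a.coords.copy(), a.b_factor,
                      a.occupancy, a.alt_loc) for a in r.atoms],
            )
            for r in self.residues
        ]
        return Structure(self.id, residues, self.source)


@dataclass
class Ensemble:
    """>= 1 coordinate frames sharing one topology (atom count and order)."""

    topology: Structure
    frames: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("an Ensemble needs at least one frame")
        n = self.topology.n_atoms
        checked = []
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise ValueError(
                    f"frame {i}: expected {n} atoms, got shape {f.shape} (congruence error)"
                )
            checked.append(f)
        self.frames = checked

    @property
    def n_frames(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# residue keys as text ("A:84" or "A:84B")

def parse_residue_key(text: str, default_chain: str = "A") -> ResidueKey:
    """Parse ``chain:resseq[icode]`` (chain optional) into a residue key."""
    text = text.strip()
    if ":" in text:
        chain, rest = text.split(":", 1)
    else:
        chain, rest = default_chain, text
    rest = rest.strip()
    i_code = ""
    if rest and rest[-1].isalpha():
        i_code = rest[-1]
        rest = rest[:-1]
    try:
        res_seq = int(rest)
    except ValueError:
        raise ValueError(f"cannot parse residue key {text!r}") from None
    return (chain.strip() or default_chain, res_seq, i_code)


def format_residue_key(key: ResidueKey) -> str:
    chain, seq, icode = key
    return f"{chain}:{seq}{icode}"


# ---------------------------------------------------------------------------
# parsing

def _infer_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if len(stripped) >= 2 and stripped[:2].upper() in {"FE", "ZN", "MG", "MN", "CA", "NA", "CL"}:
        # two-letter elements only when the name is left-justified in cols 13-14
        if len(name) == 4 and name[0] != " ":
            return stripped[:2].capitalize()
    return stripped[0].upper()


def _parse_atom_line(line: str, lineno: int) -> dict:
    if len(line) < 54:
        raise PdbParseError(f"line {lineno}: ATOM/HETATM record shorter than 54 columns")
    try:
        serial = int(line[6:11])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PdbParseError(f"line {lineno}: malformed fixed-column field ({exc})") from None
    try:
        occupancy = float(line[54:60]) if line[54:60].strip() else 1.0
    except ValueError:
        raise PdbParseError(f"line {lineno}: malformed occupancy field") from None
    try:
        b_factor = float(line[60:66]) if line[60:66].strip() else 0.0
    except ValueError:
        raise PdbParseError(f"line {lineno}: malformed B-factor field") from None
    try:
        res_seq = int(line[22:26])
    except ValueError:
        raise PdbParseError(f"line {lineno}: malformed residue sequence number") from None
    name = line[12:16]
    element = line[76:78].strip() if len(line) >= 78 else ""
    return {
        "record": line[0:6].strip(),
        "serial": serial,
        "name": name.strip(),
        "raw_name": name,
        "alt_loc": line[16].strip(),
        "res_name": line[17:20].strip(),
        "chain_id": line[21].strip() or "A",
        "res_seq": res_seq,
        "i_code": line[26].strip() if len(line) > 26 else "",
        "coords": np.array([x, y, z]),
        "occupancy": occupancy,
        "b_factor": b_factor,
        "element": element or _infer_element(name),
        "lineno": lineno,
    }


def parse_pdb(
    text: str,
    *,
    structure_id: str = "structure",
    include_hetatm: bool = False,
    include_waters: bool = False,
    source: str = "",
) -> Structure:
    """Parse fixed-column PDB text into a :class:`Structure`.

    HETATM records (waters in particular) are skipped unless requested; for
    alternate locations only the highest-occupancy conformer of each atom is
    retained; negative B-factors are clamped to zero with a warning.
    """
    raw: list[dict] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[0:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        parsed = _parse_atom_line(line, lineno)
        if rec == "HETATM":
            if parsed["res_name"] in WATER_NAMES and not include_waters:
                continue
            if parsed["res_name"] not in WATER_NAMES and not include_hetatm:
                continue
        elif parsed["res_name"] in WATER_NAMES and not include_waters:
            continue
        raw.append(parsed)
    if not raw:
        raise PdbParseError("no atoms parsed: input contains no usable ATOM/HETATM records")

    # group into residues (file order), resolving alt-locs by max occupancy
    residues: dict[ResidueKey, dict] = {}
    for a in raw:
        key = (a["chain_id"], a["res_seq"], a["i_code"])
        res = residues.setdefault(key, {"res_name": a["res_name"], "atoms": {}})
        existing = res["atoms"].get(a["name"])
        if existing is None or a["occupancy"] > existing["occupancy"]:
            res["atoms"][a["name"]] = a

    records = []
    for key in sorted(residues, key=lambda k: (k[0], k[1], k[2])):
        res = residues[key]
        atoms = [
            Atom(
                serial=a["serial"],
                name=a["name"],
                element=a["element"],
                coords=a["coords"],
                b_factor=a["b_factor"],
                occupancy=a["occupancy"],
                alt_loc=a["alt_loc"],
            )
            for a in res["atoms"].values()
        ]
        records.append(ResidueRecord(key[0], key[1], key[2], res["res_name"], atoms))
    return Structure(structure_id, records, source=source)


def parse_multimodel_pdb(text: str, *, structure_id: str = "ensemble", **kwargs) -> Ensemble:
    """Parse multi-model PDB text into an :class:`Ensemble`.

    The topology is taken from the first model; every later model must present
    the same atoms in the same order, otherwise a congruence error is raised.
    A file without MODEL records yields a single-frame ensemble.
    """
    lines = text.splitlines()
    blocks: list[list[str]] = []
    current: list[str] | None = None
    saw_model = False
    for line in lines:
        rec = line[0:6].strip()
        if rec == "MODEL":
            saw_model = True
            current = []
        elif rec == "ENDMDL":
            if current is None:
                raise PdbParseError("ENDMDL without a preceding MODEL record")
            blocks.append(current)
            current = None
        elif current is not None:
            current.append(line)
    if current is not None:
        blocks.append(current)
    if not saw_model:
        blocks = [lines]

    structures = [
        parse_pdb("\n".join(b), structure_id=f"{structure_id}/model{i + 1}", **kwargs)
        for i, b in enumerate(blocks)
    ]
    topo = structures[0]
    topo_ids = topo.atom_ids()
    frames = []
    for i, s in enumerate(structures):
        if s.atom_ids() != topo_ids:
            raise PdbParseError(
                f"model {i + 1} is not congruent with model 1 "
                f"({s.n_atoms} vs {topo.n_atoms} atoms or differing order)"
            )
        frames.append(s.coords())
    topo.id = structure_id
    return Ensemble(topo, frames)


# ---------------------------------------------------------------------------
# writing

def _format_atom_name(name: str) -> str:
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def _format_atom_line(
    record: str, serial: int, atom: Atom, res: ResidueRecord, b_override: float | None
) -> str:
    x, y, z = atom.coords
    for v in (x, y, z):
        if not (-999.999 <= v <= 9999.999):
            raise PdbFormatError(
                f"coordinate {v:.3f} of atom {atom.name!r} in residue {res.key} "
                "does not fit fixed PDB columns"
            )
    b = atom.b_factor if b_override is None else b_override
    return (
        f"{record:<6s}{serial % 100000:5d} {_format_atom_name(atom.name)}"
        f"{atom.alt_loc or ' ':1s}{res.res_name:>3s} {res.chain_id:1s}"
        f"{res.res_seq:4d}{res.i_code or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{b:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_pdb(
    structure: Structure,
    ensemble: Ensemble | None = None,
    b_factors: Mapping[ResidueKey, float] | None = None,
) -> str:
    """Serialize a structure (or every frame of an ensemble) as PDB text.

    ``b_factors`` maps residue keys to a scalar written into the B column of
    every atom of that residue — the hook used to export per-residue
    flexibility scores for visualization.
    """

    def model_lines(struct: Structure) -> list[str]:
        out = []
        serial = 0
        prev_chain = None
        for r in struct.residues:
            if prev_chain is not None and r.chain_id != prev_chain:
                out.append("TER")
            prev_chain = r.chain_id
            override = None if b_factors is None else b_factors.get(r.key)
            for a in r.atoms:
                serial += 1
                record = "ATOM" if r.is_standard else "HETATM"
                out.append(_format_atom_line(record, serial, a, r, override))
        out.append("TER")
        return out

    lines: list[str] = []
    if ensemble is None:
        lines.extend(model_lines(structure))
    else:
        work = ensemble.topology.copy()
        for i, frame in enumerate(ensemble.frames, start=1):
            work.set_coords(frame)
            lines.append(f"MODEL     {i:4d}")
            lines.extend(model_lines(work))
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# file helpers (plain or gzipped)

def _read_text(path: str | Path) -> str:
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            return fh.read()
    return path.read_text()


def read_structure(path: str | Path, **kwargs) -> Structure:
    return parse_pdb(_read_text(path), structure_id=Path(path).stem, **kwargs)


def read_ensemble(path: str | Path, **kwargs) -> Ensemble:
    return parse_multimodel_pdb(_read_text(path), structure_id=Path(path).stem, **kwargs)
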