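"""Flexibility-guided candidate selection for thermostabilizing mutations.

The pipeline mirrors the rigidifying-flexible-sites (RFS) strategy: locate
flexible regions via B-factor statistics (by secondary-structure class,
surface/buried, and near the catalytic site), restrict to surface-loop
beta-turns far enough from the catalytic residues to leave activity intact,
triage a virtual-saturation ddG table for predicted-stabilizing
substitutions (negative ddG = stabilizing, a ~0.5 kJ/mol calculation error
motivates the -0.5 kJ/mol default threshold), optionally veto positions
whose wild-type residue is conserved across thermostable homologs, and rank
the survivors.
"""

from __future__ import annotations

import hashlib
import io
import json
import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .conservation import ConservationProfile, conservation_at
from .geometry import SasaResult, ca_distance_stats
from .ss_turns import (
    BetaTurn,
    SsAssignment,
    TurnPreferenceTable,
    preference_score,
)
from .structure import (
    AA1_TO_3,
    AA3_TO_1,
    ResidueKey,
    Structure,
    format_residue_key,
    parse_residue_key,
)

__all__ = [
    "FlexibilityStats",
    "DdgRecord",
    "DdgTable",
    "MutationCandidate",
    "ScreenConfig",
    "flexibility_stats",
    "load_ddg_table",
    "ddg_filter",
    "aggregate_residue_ddg",
    "select_candidates",
    "rank_candidates",
    "screen_report",
    "parse_report",
]

KCAL_TO_KJ = 4.184

FILTER_NAMES = (
    "loop",
    "surface",
    "turn",
    "catalytic_distance",
    "ddg",
    "conservation",
    "preference",
)

RANK_FEATURES = ("b_factor", "neg_ddg", "catalytic_distance", "preference")


# ---------------------------------------------------------------------------
# flexibility statistics

@dataclass
class FlexibilityStats:
    """Mean per-residue B-factors by group (NaN marks an empty group)."""

    per_residue: dict[ResidueKey, float]
    class_means: dict[str, float]          # helix / sheet / loop
    surface_mean: float
    buried_mean: float
    shell_mean: float                      # residues near the catalytic site
    shell_residues: set[ResidueKey]
    policy: str                            # 'all_atom' or 'ca'
    shell_radius: float


def _group_mean(values: Sequence[float]) -> float:
    return float(np.mean(values)) if len(values) else float("nan")


def flexibility_stats(
    structure: Structure,
    ss: SsAssignment,
    sasa: SasaResult,
    catalytic: Iterable[ResidueKey],
    shell_radius: float = 5.0,
    b_factor_policy: str = "all_atom",
) -> FlexibilityStats:
    """Per-residue B-factors plus group means (secondary-structure class,
    surface vs buried, catalytic shell).

    The per-residue B-factor is the mean over the residue's atoms
    (``all_atom``) or the CA value (``ca``).  Shell membership is any-atom
    distance <= ``shell_radius`` to any atom of a catalytic residue; the
    catalytic residues themselves are not counted as their own neighbours.
    """
    catalytic = {tuple(k) for k in catalytic}
    for key in catalytic:
        structure[key]  # raises KeyError if unresolvable

    per_residue: dict[ResidueKey, float] = {}
    for res in structure.residues:
        if b_factor_policy == "all_atom":
            per_residue[res.key] = res.mean_b_factor()
        elif b_factor_policy == "ca":
            ca = res.ca
            per_residue[res.key] = ca.b_factor if ca is not None else res.mean_b_factor()
        else:
            raise ValueError(f"unknown B-factor policy {b_factor_policy!r}")

    cat_coords = np.vstack([structure[k].coords() for k in catalytic]) if catalytic else None
    shell: set[ResidueKey] = set()
    if cat_coords is not None:
        for res in structure.residues:
            if res.key in catalytic:
                continue
            d = np.linalg.norm(res.coords()[:, None, :] - cat_coords[None, :, :], axis=-1)
            if d.min() <= shell_radius:
                shell.add(res.key)

    class_means = {
        c: _group_mean([per_residue[k] for k in ss.residues_in_class(c) if k in per_residue])
        for c in ("helix", "sheet", "loop")
    }
    surface_vals = [b for k, b in per_residue.items() if sasa.surface.get(k, False)]
    buried_vals = [b for k, b in per_residue.items() if not sasa.surface.get(k, False)]
    shell_vals = [per_residue[k] for k in shell]
    return FlexibilityStats(
        per_residue=per_residue,
        class_means=class_means,
        surface_mean=_group_mean(surface_vals),
        buried_mean=_group_mean(buried_vals),
        shell_mean=_group_mean(shell_vals),
        shell_residues=shell,
        policy=b_factor_policy,
        shell_radius=shell_radius,
    )


# ---------------------------------------------------------------------------
# ddG table

@dataclass(frozen=True)
class DdgRecord:
    """One (position, substitution) with its unfolding ddG in kJ/mol
    (negative = predicted stabilizing)."""

    position: ResidueKey
    wild_aa: str     # 1-letter
    mut_aa: str      # 1-letter
    ddg: float

    def __post_init__(self) -> None:
        if self.wild_aa == self.mut_aa:
            raise ValueError(f"record at {self.position}: wild and mutant residue identical")
        if not math.isfinite(self.ddg):
            raise ValueError(f"record at {self.position}: ddG must be finite")


@dataclass
class DdgTable:
    records: list[DdgRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def positions(self) -> list[ResidueKey]:
        seen: dict[ResidueKey, None] = {}
        for r in self.records:
            seen.setdefault(r.position, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": [format_residue_key(r.position) for r in self.records],
                "wild": [r.wild_aa for r in self.records],
                "mut": [r.mut_aa for r in self.records],
                "ddg": [r.ddg for r in self.records],
            }
        )


def _norm_aa1(aa: str) -> str:
    aa = aa.strip().upper()
    if len(aa) == 3 and aa in AA3_TO_1:
        return AA3_TO_1[aa]
    if len(aa) == 1 and aa in AA1_TO_3:
        return aa
    raise ValueError(f"unknown amino-acid code {aa!r}")


def load_ddg_table(
    text: str,
    units: str = "kJ/mol",
    structure: Structure | None = None,
    default_chain: str = "A",
) -> DdgTable:
    """Load a delimited per-mutation ddG table (columns: position, wild, mut,
    ddg).  Values are stored in kJ/mol; wild-type identities are validated
    against the structure when one is supplied."""
    if units not in ("kJ/mol", "kcal/mol"):
        raise ValueError(f"units must be 'kJ/mol' or 'kcal/mol', got {units!r}")
    scale = KCAL_TO_KJ if units == "kcal/mol" else 1.0
    df = pd.read_csv(io.StringIO(text), sep=r"\s+|\t|,", engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in ("position", "wild", "mut", "ddg") if c not in df.columns]
    if missing:
        raise ValueError(f"ddG table missing column(s) {missing}")

    records: list[DdgRecord] = []
    seen: set[tuple[ResidueKey, str]] = set()
    mismatches: list[str] = []
    for _, row in df.iterrows():
        pos = parse_residue_key(str(row["position"]), default_chain=default_chain)
        wild = _norm_aa1(str(row["wild"]))
        mut = _norm_aa1(str(row["mut"]))
        if (pos, mut) in seen:
            raise ValueError(
                f"duplicate (position, substitution) entry {format_residue_key(pos)}->{mut}"
            )
        seen.add((pos, mut))
        if structure is not None:
            res = structure[pos]
            if res.one_letter != wild:
                mismatches.append(
                    f"{format_residue_key(pos)}: table wild {wild} vs structure {res.res_name}"
                )
                continue
        records.append(DdgRecord(pos, wild, mut, float(row["ddg"]) * scale))
    if mismatches:
        raise ValueError("wild-type mismatch in ddG table rows: " + "; ".join(mismatches))
    return DdgTable(records)


def ddg_filter(
    table: DdgTable, threshold: float = -0.5
) -> tuple[list[DdgRecord], list[DdgRecord]]:
    """Partition into (predicted-stable, neutral-or-deleterious).

    Stable means ddG <= threshold — the boundary is inclusive because the
    rejected class is defined by strictly exceeding the threshold.
    """
    stable = [r for r in table if r.ddg <= threshold]
    rest = [r for r in table if r.ddg > threshold]
    return stable, rest


def aggregate_residue_ddg(table: DdgTable, how: str = "min") -> dict[ResidueKey, float]:
    """Residue-level ddG summary over its substitutions (min: the most
    stabilizing achievable at the position; mean: the average effect)."""
    groups: dict[ResidueKey, list[float]] = {}
    for r in table:
        groups.setdefault(r.position, []).append(r.ddg)
    if how == "min":
        return {k: min(v) for k, v in groups.items()}
    if how == "mean":
        return {k: float(np.mean(v)) for k, v in groups.items()}
    raise ValueError(f"unknown aggregation {how!r} (use 'min' or 'mean')")


# ---------------------------------------------------------------------------
# candidate selection

@dataclass
class ScreenConfig:
    """Thresholds, toggles and weights of the filter chain.

    Each filter is independently toggleable; a ``None`` threshold disables
    the corresponding filter outright.
    """

    catalytic: tuple[ResidueKey, ...] = ()
    require_loop: bool = True
    require_surface: bool = True
    require_turn: bool = True
    min_catalytic_distance: float | None = 13.0     # A
    ddg_threshold: float | None = -0.5              # kJ/mol
    conservation_veto: float | None = 0.80          # fraction
    preference_floor: float | None = None           # propensity score
    rank_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    shell_radius: float = 5.0                       # A
    surface_threshold: float = 0.25
    b_factor_policy: str = "all_atom"
    residue_ddg_aggregation: str = "min"

    _RANGES = {
        "min_catalytic_distance": (0.0, 100.0),
        "ddg_threshold": (-100.0, 100.0),
        "conservation_veto": (0.0, 1.0),
        "preference_floor": (0.0, 100.0),
        "shell_radius": (0.0, 50.0),
        "surface_threshold": (0.0, 1.2),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if v is not None and not (lo <= v <= hi):
                raise ValueError(f"config {name}={v} outside documented range [{lo}, {hi}]")
        if len(self.rank_weights) != 4:
            raise ValueError("rank_weights must have 4 entries "
                             "(b_factor, -ddg, catalytic distance, preference)")
        if self.b_factor_policy not in ("all_atom", "ca"):
            raise ValueError("b_factor_policy must be 'all_atom' or 'ca'")
        if self.residue_ddg_aggregation not in ("min", "mean"):
            raise ValueError("residue_ddg_aggregation must be 'min' or 'mean'")

    @classmethod
    def from_text(cls, text: str, default_chain: str = "A") -> "ScreenConfig":
        """Parse a flat ``key = value`` config; unknown keys are rejected."""
        known = {f.name for f in fields(cls) if not f.name.startswith("_")}
        kwargs: dict = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in known:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            kwargs[key] = _parse_config_value(key, value, default_chain)
        return cls(**kwargs)

    def hash(self) -> str:
        payload = {f.name: repr(getattr(self, f.name)) for f in fields(self)}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _parse_config_value(key: str, value: str, default_chain: str):
    if key == "catalytic":
        return tuple(parse_residue_key(v, default_chain) for v in value.split(",") if v.strip())
    if key == "rank_weights":
        return tuple(float(v) for v in value.split(","))
    if key in ("b_factor_policy", "residue_ddg_aggregation"):
        return value
    if key.startswith("require_"):
        return value.lower() in ("1", "true", "yes", "on")
    if value.lower() in ("none", ""):
        return None
    return float(value)


@dataclass
class MutationCandidate:
    """A (position, substitution) annotated with everything the filter chain
    looked at, its per-filter pass/fail flags, and its rank score."""

    position: ResidueKey
    wild_aa: str
    mut_aa: str
    ddg: float
    b_factor: float
    surface: bool
    ss_class: str
    turn_index: int | None
    turn_position: str | None
    mean_catalytic_distance: float
    conservation: float            # NaN when no MSA supplied / no data
    preference: float              # NaN when not in a turn
    pro_preferred: bool
    filter_flags: dict[str, bool] = field(default_factory=dict)
    rank_score: float = float("nan")

    @property
    def passes(self) -> bool:
        return all(self.filter_flags.values())

    @property
    def label(self) -> str:
        return f"{self.wild_aa}{self.position[1]}{self.mut_aa}"


def _annotate(
    record: DdgRecord,
    structure: Structure,
    ss: SsAssignment,
    turns: Sequence[BetaTurn],
    sasa: SasaResult,
    stats: FlexibilityStats,
    profile: ConservationProfile | None,
    preference_table: TurnPreferenceTable,
    config: ScreenConfig,
    turn_distance: Mapping[int, float],
) -> MutationCandidate:
    key = tuple(record.position)
    structure[key]
    containing = [t for t in turns if key in t.residues]
    turn = containing[0] if containing else None
    if turn is not None:
        mean_dist = turn_distance[turn.index]
        turn_pos = turn.position_of(key)
        pref = preference_score(preference_table, record.mut_aa, turn_pos)
    else:
        if config.catalytic:
            mean_dist = ca_distance_stats(structure, [key], config.catalytic).mean
        else:
            mean_dist = float("nan")
        turn_pos = None
        pref = float("nan")
    cons = float("nan")
    if profile is not None:
        qpos = key[1]
        if qpos in profile.column_map:
            cons = conservation_at(profile, qpos)
    return MutationCandidate(
        position=key,
        wild_aa=record.wild_aa,
        mut_aa=record.mut_aa,
        ddg=record.ddg,
        b_factor=stats.per_residue[key],
        surface=sasa.surface.get(key, False),
        ss_class=ss[key],
        turn_index=turn.index if turn else None,
        turn_position=turn_pos,
        mean_catalytic_distance=mean_dist,
        conservation=cons,
        preference=pref,
        pro_preferred=(record.mut_aa == "P"),
    )


def _apply_filters(
    cand: MutationCandidate, config: ScreenConfig, has_profile: bool
) -> dict[str, bool]:
    flags: dict[str, bool] = {}
    if config.require_loop:
        flags["loop"] = cand.ss_class == "loop"
    if config.require_surface:
        flags["surface"] = cand.surface
    if config.require_turn:
        flags["turn"] = cand.turn_index is not None
    if config.min_catalytic_distance is not None:
        flags["catalytic_distance"] = (
            math.isfinite(cand.mean_catalytic_distance)
            and cand.mean_catalytic_distance >= config.min_catalytic_distance
        )
    if config.ddg_threshold is not None:
        flags["ddg"] = cand.ddg <= config.ddg_threshold
    if config.conservation_veto is not None and has_profile:
        # positions without conservation data cannot be vetoed
        flags["conservation"] = (
            not math.isfinite(cand.conservation)
            or cand.conservation < config.conservation_veto
        )
    if config.preference_floor is not None:
        flags["preference"] = (
            math.isfinite(cand.preference) and cand.preference >= config.preference_floor
        )
    return flags


def rank_candidates(
    candidates: list[MutationCandidate],
    weights: Sequence[float] = (1.0, 1.0, 1.0, 1.0),
    norms: Mapping[str, tuple[float, float]] | None = None,
) -> list[MutationCandidate]:
    """Score and sort candidates.

    rank_score is a weighted sum of z-scored features (B-factor, -ddG,
    catalytic distance, preference propensity), each favourable direction
    scoring positive.  Normalization statistics default to the candidate set
    itself but can be frozen via ``norms`` (feature -> (mean, std)) so that
    scores are monotone under single-candidate perturbations.  Ties are
    broken by lower ddG, then higher B-factor, then N-to-C position.
    """
    if not candidates:
        return []
    feats = {
        "b_factor": np.array([c.b_factor for c in candidates], dtype=float),
        "neg_ddg": np.array([-c.ddg for c in candidates], dtype=float),
        "catalytic_distance": np.array(
            [c.mean_catalytic_distance for c in candidates], dtype=float
        ),
        "preference": np.array([c.preference for c in candidates], dtype=float),
    }
    score = np.zeros(len(candidates))
    for w, name in zip(weights, RANK_FEATURES):
        x = feats[name]
        valid = np.isfinite(x)
        if norms is not None and name in norms:
            mu, sigma = norms[name]
        elif valid.any():
            mu, sigma = float(np.mean(x[valid])), float(np.std(x[valid]))
        else:
            mu, sigma = 0.0, 0.0
        z = np.zeros(len(candidates))
        if sigma > 0:
            z[valid] = (x[valid] - mu) / sigma
        score += w * z
    for c, s in zip(candidates, score):
        c.rank_score = float(s)
    order = sorted(
        range(len(candidates)),
        key=lambda i: (
            -candidates[i].rank_score,
            candidates[i].ddg,
            -candidates[i].b_factor,
            candidates[i].position,
        ),
    )
    return [candidates[i] for i in order]


def select_candidates(
    structure: Structure,
    ss: SsAssignment,
    turns: Sequence[BetaTurn],
    sasa: SasaResult,
    stats: FlexibilityStats,
    ddg_table: DdgTable,
    conservation: ConservationProfile | None = None,
    config: ScreenConfig | None = None,
    preference_table: TurnPreferenceTable | None = None,
) -> list[MutationCandidate]:
    """Run the filter chain over every ddG record and return the ranked
    candidates that pass all enabled filters."""
    config = config or ScreenConfig()
    preference_table = preference_table or TurnPreferenceTable.default()
    if config.min_catalytic_distance is not None and not config.catalytic:
        raise ValueError(
            "catalytic residue set is empty but the catalytic-distance filter is enabled"
        )
    turn_distance: dict[int, float] = {}
    if config.catalytic:
        for t in turns:
            turn_distance[t.index] = ca_distance_stats(
                structure, list(t.residues), config.catalytic
            ).mean
    else:
        turn_distance = {t.index: float("nan") for t in turns}

    annotated = [
        _annotate(r, structure, ss, turns, sasa, stats, conservation,
                  preference_table, config, turn_distance)
        for r in ddg_table
    ]
    passing = []
    for cand in annotated:
        cand.filter_flags = _apply_filters(cand, config, conservation is not None)
        if cand.passes:
            passing.append(cand)
    return rank_candidates(passing, config.rank_weights)


# ---------------------------------------------------------------------------
# reports

_REPORT_COLUMNS = [
    "rank", "position", "wild", "mut", "ddg", "b_factor", "surface", "ss_class",
    "turn_index", "turn_position", "mean_catalytic_distance", "conservation",
    "preference", "pro_preferred", "passes", "rank_score",
]


def _candidate_row(rank: int, c: MutationCandidate) -> dict:
    return {
        "rank": rank,
        "position": format_residue_key(c.position),
        "wild": c.wild_aa,
        "mut": c.mut_aa,
        "ddg": c.ddg,
        "b_factor": c.b_factor,
        "surface": c.surface,
        "ss_class": c.ss_class,
        "turn_index": c.turn_index,
        "turn_position": c.turn_position,
        "mean_catalytic_distance": c.mean_catalytic_distance,
        "conservation": c.conservation,
        "preference": c.preference,
        "pro_preferred": c.pro_preferred,
        "passes": c.passes,
        "rank_score": c.rank_score,
    }


def screen_report(candidates: Sequence[MutationCandidate], format: str = "tsv") -> str:
    """Serialize ranked candidates as TSV or JSON (deterministic columns)."""
    rows = [_candidate_row(i + 1, c) for i, c in enumerate(candidates)]
    if format == "json":
        return json.dumps(rows, indent=2, allow_nan=True) + "\n"
    if format == "tsv":
        df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
        return df.to_csv(sep="\t", index=False)
    raise ValueError(f"unknown report format {format!r}")


def parse_report(text: str, format: str = "tsv") -> pd.DataFrame:
    """Read a screen report back into a DataFrame (round-trip partner of
    :func:`screen_report`)."""
    if format == "json":
        rows = json.loads(text)
        df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    elif format == "tsv":
        df = pd.read_csv(io.StringIO(text), sep="\t")
    else:
        raise ValueError(f"unknown report format {format!r}")
    return df
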