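"""Alignment-column conservation for the consensus veto.

The screening question is evolutionary: is the wild-type residue at a
candidate position conserved across thermostable homologs?  Conservation is
therefore measured as identity-to-query — the fraction of homologs (gapped
positions excluded from the denominator) carrying the query's residue at
that column — rather than column-majority identity.  Positions whose
wild-type residue is highly conserved are vetoed, since mutating them works
against natural selection.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

from Bio import SeqIO

from .structure import AA1_TO_3

__all__ = [
    "Alignment",
    "ConservationProfile",
    "parse_alignment",
    "conservation_profile",
    "conservation_at",
    "profile_report",
]

GAP = "-"


@dataclass
class Alignment:
    """Uniform-length aligned sequences with a designated query."""

    sequences: list[tuple[str, str]]   # (id, aligned sequence)
    query_id: str

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            ragged = [sid for sid, s in self.sequences
                      if len(s) != len(self.sequences[0][1])]
            raise ValueError(f"ragged alignment: sequence length differs for {ragged}")
        if self.query_id not in {sid for sid, _ in self.sequences}:
            raise ValueError(f"query id {self.query_id!r} not present in alignment")

    @property
    def length(self) -> int:
        return len(self.sequences[0][1])

    @property
    def query(self) -> str:
        return next(s for sid, s in self.sequences if sid == self.query_id)

    @property
    def homologs(self) -> list[tuple[str, str]]:
        return [(sid, s) for sid, s in self.sequences if sid != self.query_id]


@dataclass
class ConservationProfile:
    """Per-column consensus + identity-to-query fraction, with the map from
    1-based query positions to 1-based alignment columns."""

    consensus: list[str]
    fraction: list[float]              # NaN where no homolog has a residue
    column_map: dict[int, int]         # query position (1-based) -> column (1-based)
    query_id: str

    @property
    def n_columns(self) -> int:
        return len(self.fraction)


def parse_alignment(text: str, query_id: str) -> Alignment:
    """Parse aligned FASTA; lowercase is uppercased and '.' gaps normalized."""
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise ValueError("no FASTA records found")
    sequences = [(r.id, str(r.seq).upper().replace(".", GAP)) for r in records]
    return Alignment(sequences, query_id)


def conservation_profile(alignment: Alignment) -> ConservationProfile:
    """Column-wise identity-to-query conservation over the non-query homologs."""
    query = alignment.query
    homologs = [s for _, s in alignment.homologs]
    consensus: list[str] = []
    fraction: list[float] = []
    for col in range(alignment.length):
        chars = [s[col] for s in homologs if s[col] != GAP]
        if chars:
            counts: dict[str, int] = {}
            for c in chars:
                counts[c] = counts.get(c, 0) + 1
            consensus.append(min(sorted(counts), key=lambda c: -counts[c]))
        else:
            consensus.append(GAP)
        q = query[col]
        if not chars or q == GAP:
            fraction.append(float("nan"))
        else:
            fraction.append(sum(c == q for c in chars) / len(chars))
    column_map: dict[int, int] = {}
    pos = 0
    for col, c in enumerate(query, start=1):
        if c != GAP:
            pos += 1
            column_map[pos] = col
    return ConservationProfile(consensus, fraction, column_map, alignment.query_id)


def conservation_at(profile: ConservationProfile, query_position: int) -> float:
    """Conservation fraction at a 1-based query position (NaN if the column
    has no aligned homolog residues)."""
    if query_position not in profile.column_map:
        raise ValueError(
            f"query position {query_position} out of range "
            f"(1..{max(profile.column_map, default=0)})"
        )
    return profile.fraction[profile.column_map[query_position] - 1]


def profile_report(profile: ConservationProfile) -> str:
    """Delimited text: column, consensus residue, conservation fraction."""
    lines = ["column\tconsensus\tfraction"]
    for col, (cons, frac) in enumerate(zip(profile.consensus, profile.fraction), start=1):
        frac_s = "" if frac != frac else f"{frac:.6f}"
        lines.append(f"{col}\t{cons}\t{frac_s}")
    return "\n".join(lines) + "\n"
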