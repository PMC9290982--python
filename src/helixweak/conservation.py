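"""Cross-structure weak-spot aggregation, motif scanning and logo statistics.

The central claim this module makes checkable is that the *location* of
helix weak spots (as a generic position) is conserved across receptors
even when the sequence mechanisms causing them differ: the per-position
weakening fraction of an ensemble should exceed the frequency of any
single causal mechanism at that position.
"""

from __future__ import annotations

import dataclasses
import math
import re
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO

from .numbering import GenericNumber
from .weakspots import WeakSpot

__all__ = [
    "Alignment",
    "AlignmentColumnStats",
    "ConservationProfile",
    "PositionStats",
    "read_alignment",
    "column_information",
    "motif_scan",
    "pgdnst_profile",
    "aggregate_weak_spots",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PGDNST = set("PGDNST")
MAX_BITS = math.log2(20.0)
HELIX_PHASE_DEG = 100.0   # canonical alpha-helix rotation per residue


@dataclasses.dataclass
class Alignment:
    ids: list[str]
    rows: list[str]      # uppercase, '-' gaps, equal length

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, index: int) -> str:
        return "".join(row[index] for row in self.rows)


@dataclasses.dataclass
class AlignmentColumnStats:
    column: int
    frequencies: dict[str, float]   # over non-gap residues
    gap_fraction: float
    information: float | None       # bits; None for all-gap columns
    flagged: bool                   # > 50% gap or all-gap


@dataclasses.dataclass
class PositionStats:
    generic: str
    n_structures: int
    n_weakened: int
    fraction: float
    mechanisms: dict[str, int]
    face_angle: float               # helix-face phase in degrees [0, 360)


@dataclasses.dataclass
class ConservationProfile:
    positions: dict[str, PositionStats]
    n_structures: int
    excluded: int                   # weak spots without generic numbers
    face_groups: dict[int, list[str]] = dataclasses.field(default_factory=dict)

    def weakened_positions(self, threshold: float = 0.5) -> list[str]:
        return sorted(g for g, p in self.positions.items() if p.fraction >= threshold)


class AlignmentFormatError(Exception):
    pass


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file; sequences are uppercased, '-' is the gap.

    Ragged (unequal-length) inputs are a format error.
    """
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise AlignmentFormatError(f"{path}: {exc}") from exc
    ids = [rec.id for rec in aln]
    rows = [str(rec.seq).upper() for rec in aln]
    if not rows:
        raise AlignmentFormatError(f"{path}: empty alignment")
    return Alignment(ids=ids, rows=rows)


def column_information(alignment: Alignment, column: int) -> AlignmentColumnStats:
    """Shannon information of one column: R = log2(20) - H(residues).

    Gaps are excluded from the distribution; columns over 50% gap are
    flagged, and an all-gap column has undefined (None) information.  No
    small-sample correction is applied.
    """
    if not 0 <= column < alignment.n_columns:
        raise IndexError(f"column {column} out of range")
    col = alignment.column(column)
    residues = [c for c in col if c != "-"]
    gap_fraction = 1.0 - len(residues) / len(col)
    if not residues:
        return AlignmentColumnStats(column, {}, 1.0, None, True)
    freqs: dict[str, float] = {}
    for c in residues:
        freqs[c] = freqs.get(c, 0.0) + 1.0
    n = len(residues)
    freqs = {c: v / n for c, v in sorted(freqs.items())}
    entropy = -sum(p * math.log2(p) for p in freqs.values())
    return AlignmentColumnStats(column, freqs, gap_fraction,
                                MAX_BITS - entropy, gap_fraction > 0.5)


def motif_scan(sequence: str, pattern: str) -> list[int]:
    """All (possibly overlapping) 0-based start positions of a motif.

    Patterns use residue letters, ``X`` for any residue and bracketed
    character classes (e.g. ``[ST]``).
    """
    seq = sequence.upper()
    regex_parts: list[str] = []
    i = 0
    pat = pattern.upper()
    while i < len(pat):
        c = pat[i]
        if c == "X":
            regex_parts.append("[A-Z]")
            i += 1
        elif c == "[":
            end = pat.find("]", i)
            if end == -1:
                raise ValueError(f"unclosed character class in pattern {pattern!r}")
            inner = pat[i + 1:end]
            if not inner or any(ch not in AMINO_ACIDS for ch in inner):
                raise ValueError(f"invalid character class [{inner}] in {pattern!r}")
            regex_parts.append(f"[{inner}]")
            i = end + 1
        elif c in AMINO_ACIDS:
            regex_parts.append(c)
            i += 1
        else:
            raise ValueError(f"invalid pattern character {c!r} in {pattern!r}")
    regex = re.compile("(?=(" + "".join(regex_parts) + "))")
    return [m.start() for m in regex.finditer(seq)]


def pgdnst_profile(alignment: Alignment, columns: Iterable[int] | None = None) -> dict[int, float]:
    """Per-column fraction of non-gap residues in {P, G, D, N, S, T}."""
    cols = list(columns) if columns is not None else range(alignment.n_columns)
    out: dict[int, float] = {}
    for c in cols:
        col = [ch for ch in alignment.column(c) if ch != "-"]
        out[c] = sum(1 for ch in col if ch in PGDNST) / len(col) if col else 0.0
    return out


def _face_angle(generic: GenericNumber) -> float:
    return (generic.position * HELIX_PHASE_DEG) % 360.0


def aggregate_weak_spots(
    per_structure: Sequence[tuple[str, Sequence[WeakSpot]]],
    n_structures: int | None = None,
) -> ConservationProfile:
    """Aggregate numbered weak spots across an ensemble of structures.

    ``per_structure`` holds ``(structure id, weak spots)`` pairs; weak
    spots must carry generic numbers (those without are counted in
    ``excluded`` with a diagnostic, never silently dropped).  The profile
    reports, per generic position, how many structures are weakened there
    and the mechanism breakdown; positions on the same helix are
    additionally grouped by helix face (canonical 100 deg/residue phase,
    +/- 1 residue window) to expose same-face dispersion of mechanisms.
    """
    n_structures = n_structures if n_structures is not None else len(per_structure)
    counts: dict[str, set[str]] = {}
    mechanisms: dict[str, dict[str, int]] = {}
    excluded = 0
    for sid, spots in per_structure:
        for spot in spots:
            if not spot.generic:
                excluded += 1
                continue
            counts.setdefault(spot.generic, set()).add(sid)
            mech = mechanisms.setdefault(spot.generic, {})
            mech[spot.mechanism] = mech.get(spot.mechanism, 0) + 1
    positions: dict[str, PositionStats] = {}
    for generic, sids in counts.items():
        gn = GenericNumber.parse(generic)
        positions[generic] = PositionStats(
            generic=generic, n_structures=n_structures, n_weakened=len(sids),
            fraction=len(sids) / n_structures if n_structures else 0.0,
            mechanisms=dict(sorted(mechanisms[generic].items())),
            face_angle=_face_angle(gn))
    # same-helix face grouping: positions within one residue of phase
    face_groups: dict[int, list[str]] = {}
    group_id = 0
    by_helix: dict[int, list[str]] = {}
    for generic in sorted(positions):
        by_helix.setdefault(GenericNumber.parse(generic).helix, []).append(generic)
    for helix, gens in sorted(by_helix.items()):
        remaining = sorted(gens, key=lambda g: GenericNumber.parse(g).position)
        while remaining:
            seed = remaining.pop(0)
            seed_angle = positions[seed].face_angle
            group = [seed]
            for other in list(remaining):
                d = abs(positions[other].face_angle - seed_angle) % 360.0
                if min(d, 360.0 - d) <= HELIX_PHASE_DEG:
                    group.append(other)
                    remaining.remove(other)
            face_groups[group_id] = group
            group_id += 1
    return ConservationProfile(positions=positions, n_structures=n_structures,
                               excluded=excluded, face_groups=face_groups)
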