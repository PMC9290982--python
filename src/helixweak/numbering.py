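"""GPCRdb-style generic residue numbers (helix x position, x50-anchored).

Weak spots from different receptors are only comparable once residues are
named by their position relative to each helix's most conserved residue
(the x50 anchor): Leu 2x46 is the residue four before the TM2 anchor in
every class A receptor, whatever its author number.

Numbering here is linear from the anchor within a detected helix segment.
The full structure-based scheme additionally renumbers across bulges and
constrictions; that requires family-wide alignment infrastructure, so this
module instead flags any pi-bulge or 3-10 constriction lying between the
anchor and a numbered residue (``bulge_warning``) — for the x40-x60 span
the analysis uses, linear numbering is exact whenever no such flag is set.
Anchors are user-supplied configuration, not detected by alignment.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

from .structures_io import AA3TO1, Residue, Structure
from .weakspots import HelixSegment

__all__ = [
    "GenericNumber",
    "Anchor",
    "AnchorConfig",
    "NumberingError",
    "GenericNumbering",
    "assign_generic_numbers",
    "read_anchor_config",
]


class NumberingError(Exception):
    pass


@dataclasses.dataclass(frozen=True)
class GenericNumber:
    helix: int       # 1..8
    position: int    # x50-relative, e.g. 46

    def __str__(self) -> str:
        return f"{self.helix}x{self.position}"

    @classmethod
    def parse(cls, text: str) -> "GenericNumber":
        try:
            helix, pos = text.lower().split("x")
            return cls(int(helix), int(pos))
        except (ValueError, AttributeError) as exc:
            raise NumberingError(f"malformed generic number {text!r}") from exc


@dataclasses.dataclass
class Anchor:
    helix: int
    chain: str
    seqnum: int              # author number of the x50 residue
    expected: str = ""       # 1-letter expected residue type, "" = unchecked


@dataclasses.dataclass
class AnchorConfig:
    anchors: list[Anchor]

    def __post_init__(self) -> None:
        helices = [a.helix for a in self.anchors]
        if len(helices) != len(set(helices)):
            raise NumberingError("more than one anchor for the same helix")


@dataclasses.dataclass
class GenericNumbering:
    """Bidirectional residue <-> generic number map for one structure."""
    by_residue: dict[tuple[str, int], GenericNumber]   # (chain, internal index)
    by_generic: dict[GenericNumber, Residue]
    warnings: list[str]

    def lookup(self, generic: GenericNumber | str) -> Residue | None:
        if isinstance(generic, str):
            generic = GenericNumber.parse(generic)
        return self.by_generic.get(generic)

    def number_of(self, res: Residue) -> GenericNumber | None:
        return self.by_residue.get((res.chain_id, res.index))


def assign_generic_numbers(
    structure: Structure,
    segments: dict[int, HelixSegment] | list[tuple[int, HelixSegment]],
    config: AnchorConfig,
) -> GenericNumbering:
    """Number every residue of each anchored segment linearly from its x50.

    ``segments`` maps helix index (1..7, or 8) to the detected segment.  A
    mismatch between the observed anchor residue type and the expected one
    is a warning, not an error (GPCR structures are routinely mutated); an
    anchor lying outside its segment is an anchoring error.  Within one
    structure the numbering is a bijection; duplicates raise.
    """
    seg_map = dict(segments) if not isinstance(segments, dict) else segments
    by_residue: dict[tuple[str, int], GenericNumber] = {}
    by_generic: dict[GenericNumber, Residue] = {}
    warnings: list[str] = []
    for anchor in config.anchors:
        segment = seg_map.get(anchor.helix)
        if segment is None:
            raise NumberingError(f"no segment supplied for helix {anchor.helix}")
        candidates = [r for r in segment.residues
                      if r.chain_id == anchor.chain and r.seqnum == anchor.seqnum]
        if not candidates:
            raise NumberingError(
                f"anchor {anchor.chain}{anchor.seqnum} (helix {anchor.helix}) "
                f"lies outside the detected segment {segment.start}-{segment.end}")
        anchor_res = candidates[0]
        if anchor.expected:
            observed = AA3TO1.get(anchor_res.name, "X")
            if observed != anchor.expected.upper():
                warnings.append(
                    f"helix {anchor.helix} anchor {anchor.chain}{anchor.seqnum}: "
                    f"expected {anchor.expected.upper()}, observed {observed}")
        bulges = [ir for ir in segment.irregularities if ir.kind in ("pi_bulge", "three10")]
        for res in segment.residues:
            gen = GenericNumber(anchor.helix, 50 + res.index - anchor_res.index)
            lo, hi = sorted((res.index, anchor_res.index))
            for ir in bulges:
                if lo <= ir.position <= hi:
                    warnings.append(
                        f"{ir.kind} at index {ir.position} between anchor and {gen}: "
                        f"linear numbering may be shifted")
                    break
            key = (res.chain_id, res.index)
            if key in by_residue or gen in by_generic:
                raise NumberingError(f"duplicate generic number {gen}")
            by_residue[key] = gen
            by_generic[gen] = res
    return GenericNumbering(by_residue, by_generic, warnings)


def read_anchor_config(path: str | Path) -> AnchorConfig:
    """Parse the anchor file: one ``helix chain seqnum [expected]`` line per
    helix; '#' starts a comment."""
    anchors = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) not in (3, 4):
            raise NumberingError(f"{path}:{lineno}: expected 'helix chain seqnum [expected]'")
        anchors.append(Anchor(helix=int(parts[0]), chain=parts[1], seqnum=int(parts[2]),
                              expected=parts[3] if len(parts) == 4 else ""))
    return AnchorConfig(anchors)
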