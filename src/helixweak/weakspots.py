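"""Helix detection, irregularity annotation and weak-spot calling.

A *weak spot* is a helix position whose expected i -> i+4 backbone
hydrogen bond is weakened or absent.  Each weak spot is attributed to a
causal mechanism in a fixed priority order:

1. ``proline``         - the donor is a proline (no amide proton: the bond
                         cannot exist),
2. ``sidechain_clamp`` - a small polar side chain (Ser/Thr/Asn/Asp/Cys)
                         hydrogen-bonds the weakened carbonyl or amide,
                         pulling the backbone out of register,
3. ``glycine_flex``    - a glycine at or adjacent to the donor lets the
                         backbone adopt off-helical torsions,
4. ``pushed_backbone`` - another helix presses on the local backbone
                         (heavy-atom contact < 3.8 A at donor +/- 1),
5. ``unexplained``     - none of the above.

The proximity rules operationalizing "caused by" (donor +/- 1 for glycine
and contacts; clamp must touch the weakened bond's own carbonyl or amide)
are design choices of this module and are surfaced in the report metadata.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .geometry import axis_angle_deg, dihedral, fit_axis
from .hbond import HBondOptions, SidechainHBond, backbone_hbond_map, sidechain_backbone_hbonds
from .structures_io import Residue, Structure

__all__ = [
    "HelixSegment",
    "WeakSpot",
    "DetectOptions",
    "detect_helices",
    "annotate_irregularities",
    "call_weak_spots",
    "weakspot_table",
    "ATTRIBUTION_RULES",
]

ATTRIBUTION_RULES = (
    "mechanism priority: proline > sidechain_clamp > glycine_flex > "
    "pushed_backbone > unexplained; glycine window donor+-1; inter-helix "
    "push contact < 3.8 A at donor+-1; clamp must contact the weakened "
    "bond's carbonyl or amide"
)

PHI_WINDOW = (-120.0, -20.0)
PSI_WINDOW = (-80.0, 10.0)


@dataclasses.dataclass
class DetectOptions:
    min_length: int = 6
    donor_fraction: float = 0.7
    kink_angle: float = 20.0      # degrees
    axis_window: int = 7          # residues per axis fit
    push_cutoff: float = 3.8      # A, inter-helix backbone contact
    hbond: HBondOptions = dataclasses.field(default_factory=HBondOptions)


@dataclasses.dataclass
class Irregularity:
    position: int     # internal residue index
    kind: str         # pi_bulge | three10 | kink
    detail: str = ""


@dataclasses.dataclass
class HelixSegment:
    chain: str
    start: int        # internal index, inclusive
    end: int          # internal index, inclusive
    residues: list[Residue]
    hbond_map: dict = dataclasses.field(default_factory=dict)
    irregularities: list[Irregularity] = dataclasses.field(default_factory=list)
    kink_checked: bool = True

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, index: int) -> bool:
        return self.start <= index <= self.end


@dataclasses.dataclass
class WeakSpot:
    chain: str
    donor_index: int          # internal index of the weakened donor
    acceptor_index: int
    donor_seqnum: int         # author numbering
    klass: str                # weak | missing
    energy: float
    mechanism: str
    causal: list[str]         # residue descriptors, e.g. "A:SER:8"
    generic: str | None = None


def _torsion_ok(residues: Sequence[Residue], i: int) -> bool:
    """Residue at list position i has helical phi/psi (missing neighbors pass)."""
    ok = True
    res = residues[i]
    if i > 0 and residues[i - 1].index == res.index - 1 and \
            residues[i - 1].complete_backbone and res.complete_backbone:
        phi = dihedral(residues[i - 1].coord("C"), res.coord("N"),
                       res.coord("CA"), res.coord("C"))
        ok &= PHI_WINDOW[0] <= phi <= PHI_WINDOW[1]
    if i + 1 < len(residues) and residues[i + 1].index == res.index + 1 and \
            residues[i + 1].complete_backbone and res.complete_backbone:
        psi = dihedral(res.coord("N"), res.coord("CA"), res.coord("C"),
                       residues[i + 1].coord("N"))
        ok &= PSI_WINDOW[0] <= psi <= PSI_WINDOW[1]
    return ok


def detect_helices(
    structure: Structure,
    chain: str,
    options: DetectOptions | None = None,
) -> list[HelixSegment]:
    """Maximal helical runs of a chain.

    A residue is *helical* when its phi/psi lie in the broad helical window
    (phi in [-120, -20], psi in [-80, +10]).  Runs are merged across
    single-residue breaks, must be at least ``min_length`` long, and at
    least ``donor_fraction`` of their donors must have a helical partner
    (offset -3/-4/-5 not classified missing).
    """
    opts = options or DetectOptions()
    residues = [r for r in structure.chain(chain) if not r.het and r.complete_backbone]
    if len(residues) < opts.min_length:
        return []
    helical = [_torsion_ok(residues, i) for i in range(len(residues))]
    # merge single-residue breaks
    for i in range(1, len(helical) - 1):
        if not helical[i] and helical[i - 1] and helical[i + 1]:
            helical[i] = True
    segments: list[HelixSegment] = []
    i = 0
    full_map = backbone_hbond_map(residues, opts.hbond)
    while i < len(residues):
        if not helical[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(residues) and helical[j + 1] and \
                residues[j + 1].index == residues[j].index + 1:
            j += 1
        run = residues[i:j + 1]
        if len(run) >= opts.min_length:
            donors = [full_map[r.index] for r in run if r.index in full_map]
            good = [d for d in donors
                    if any(rec.klass != "missing" for rec in d["records"].values())]
            if donors and len(good) / len(donors) >= opts.donor_fraction:
                seg = HelixSegment(chain=chain, start=run[0].index, end=run[-1].index,
                                   residues=run,
                                   hbond_map={r.index: full_map[r.index]
                                              for r in run if r.index in full_map})
                segments.append(seg)
        i = j + 1
    return segments


def annotate_irregularities(
    segment: HelixSegment,
    options: DetectOptions | None = None,
) -> HelixSegment:
    """Mark pi-bulges, 3-10 constrictions and kinks on a segment.

    * pi_bulge: >= 2 consecutive donors prefer the -5 register,
    * three10:  >= 2 consecutive donors prefer the -3 register,
    * kink: the angle between helix axes fitted to the ``axis_window``
      residues before and after a position exceeds ``kink_angle`` degrees.

    Segments shorter than 9 residues skip kink detection (flagged on the
    segment, not an error).
    """
    opts = options or DetectOptions()
    segment.irregularities = []
    prefs = {i: rec["best"].offset for i, rec in segment.hbond_map.items()}
    for kind, offset in (("pi_bulge", -5), ("three10", -3)):
        indices = sorted(i for i, off in prefs.items() if off == offset)
        run: list[int] = []
        for idx in indices + [None]:
            if run and (idx is None or idx != run[-1] + 1):
                if len(run) >= 2:
                    segment.irregularities.append(Irregularity(run[0], kind))
                run = []
            if idx is not None:
                run.append(idx)
    # kinks
    w = opts.axis_window
    if len(segment) < max(9, 2 * w):
        segment.kink_checked = False
        return segment
    segment.kink_checked = True
    cas = np.array([r.coord("CA") for r in segment.residues])
    best_angle, best_pos = 0.0, None
    for k in range(w, len(cas) - w + 1):
        _, d1 = fit_axis(cas[k - w:k])
        _, d2 = fit_axis(cas[k:k + w])
        ang = axis_angle_deg(d1, d2)
        if ang > best_angle:
            best_angle, best_pos = ang, k
    if best_pos is not None and best_angle > opts.kink_angle:
        segment.irregularities.append(
            Irregularity(segment.residues[best_pos].index, "kink",
                         detail=f"{best_angle:.1f} deg"))
    return segment


def _descr(res: Residue) -> str:
    return f"{res.chain_id}:{res.name}:{res.seqnum}"


def call_weak_spots(
    segment: HelixSegment,
    sidechain_bonds: Sequence[SidechainHBond] | None = None,
    other_segments: Sequence[HelixSegment] = (),
    options: DetectOptions | None = None,
) -> list[WeakSpot]:
    """Weak spots of one annotated segment.

    Every interior canonical (-4) bond classified weak or missing becomes a
    WeakSpot; the mechanism is attributed in the fixed priority order (see
    module docstring).  ``other_segments`` supplies the inter-helix contacts
    for the pushed_backbone mechanism.
    """
    opts = options or DetectOptions()
    if sidechain_bonds is None:
        sidechain_bonds = sidechain_backbone_hbonds(segment.residues, opts.hbond)
    by_index = {r.index: r for r in segment.residues}
    spots: list[WeakSpot] = []
    other_atoms = None
    for donor_idx in sorted(segment.hbond_map):
        rec = segment.hbond_map[donor_idx]["canonical"]
        if rec is None or rec.klass == "normal":
            continue
        if not (segment.contains(donor_idx) and segment.contains(donor_idx - 4)):
            continue
        donor = by_index[donor_idx]
        acceptor = by_index[donor_idx - 4]
        mechanism, causal = "unexplained", []
        if donor.name == "PRO":
            mechanism, causal = "proline", [_descr(donor)]
        else:
            clamp = [b for b in sidechain_bonds
                     if (b.partner.index == acceptor.index and b.partner_atom == "O")
                     or (b.partner.index == donor.index and b.partner_atom == "N")]
            glycines = [by_index[i] for i in (donor_idx - 1, donor_idx, donor_idx + 1)
                        if i in by_index and by_index[i].name == "GLY"]
            if clamp:
                mechanism = "sidechain_clamp"
                causal = sorted({_descr(b.residue) for b in clamp})
            elif glycines:
                mechanism, causal = "glycine_flex", [_descr(g) for g in glycines]
            else:
                if other_atoms is None:
                    other_atoms = [
                        (seg.chain, r, a)
                        for seg in other_segments
                        for r in seg.residues for a in r.atoms if a.element != "H"
                    ]
                pushers = set()
                local = [by_index[i] for i in (donor_idx - 1, donor_idx, donor_idx + 1)
                         if i in by_index]
                for res in local:
                    for atom in res.atoms:
                        for _, other_res, other_atom in other_atoms:
                            if np.linalg.norm(atom.pos - other_atom.pos) < opts.push_cutoff:
                                pushers.add(_descr(other_res))
                if pushers:
                    mechanism, causal = "pushed_backbone", sorted(pushers)
        spots.append(WeakSpot(
            chain=segment.chain, donor_index=donor_idx, acceptor_index=acceptor.index,
            donor_seqnum=donor.seqnum, klass=rec.klass, energy=rec.energy,
            mechanism=mechanism, causal=causal))
    return spots


def weakspot_table(
    structure: Structure,
    chains: Sequence[str] | None = None,
    options: DetectOptions | None = None,
) -> list[WeakSpot]:
    """Weak spots for several chains, stably sorted by chain then position."""
    opts = options or DetectOptions()
    chains = list(chains) if chains is not None else sorted(structure.chains)
    all_segments: dict[str, list[HelixSegment]] = {}
    for chain in chains:
        segs = detect_helices(structure, chain, opts)
        for seg in segs:
            annotate_irregularities(seg, opts)
        all_segments[chain] = segs
    rows: list[WeakSpot] = []
    for chain in chains:
        others = [s for c, segs in all_segments.items() for s in segs if c != chain]
        for seg in all_segments[chain]:
            sc = sidechain_backbone_hbonds(seg.residues, opts.hbond)
            rows.extend(call_weak_spots(seg, sc, others, opts))
    rows.sort(key=lambda w: (w.chain, w.donor_index))
    return rows
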