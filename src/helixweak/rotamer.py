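"""Side-chain chi angles, the Leu 2x46 gate assessment, and the
pentamer-backbone rotamer-distribution search.

The gate assessment operationalizes the sodium-escape logic: the escape
channel below the conserved Leu 2x46 is tested once with the side chain as
observed and once rebuilt at an alternative rotamer.  In the inactive
receptor the *closed* rotamer blocks the channel, and the *open* rotamer —
the one seen in activated structures — cannot be reached because Asp 2x50
and Tyr 7x53 occupy its volume; both facts are reported (verdict per
rotamer, blocking contacts for the alternative).

The pentamer search reproduces the classic fragment-based rotamer
distribution method: database stretches of five residues with a backbone
very similar to the local structure and the same middle residue are
superposed onto the query; the middle side chains, carried into the query
frame, sample the plausible rotamers at that position.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .cavity import VDW_RADII, DEFAULT_VDW, EscapeResult, escape_channel_test
from .geometry import dihedral, place_atom
from .structures_io import Atom, Residue, Structure
from .superpose import superpose
from .synthetic_structures import SIDECHAIN_TEMPLATES, _resolve_dihedral, Fragment

__all__ = [
    "ChiAngles",
    "RotamerHit",
    "GateAssessment",
    "chi_angles",
    "classify_rotamer",
    "rebuild_sidechain",
    "gate_assessment",
    "pentamer_search",
    "rotamer_distribution",
]

# IUPAC chi-defining atom quadruples per residue type (as far as this
# package builds side chains).
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
}

BACKBONE = ("N", "CA", "C", "O")


@dataclasses.dataclass
class ChiAngles:
    residue: Residue
    chis: tuple[float | None, ...]   # None where defining atoms are absent
    missing: tuple[str, ...] = ()    # names of absent atoms

    def defined(self) -> tuple[float, ...]:
        return tuple(c for c in self.chis if c is not None)


@dataclasses.dataclass
class RotamerHit:
    frag_id: str
    rmsd: float
    sidechain: list[tuple[str, np.ndarray]]  # middle side chain, query frame
    chis: tuple[float, ...]
    label: str


@dataclasses.dataclass
class GateAssessment:
    residue: Residue
    current_label: str | None
    current_verdict: str
    alt_label: str | None
    alt_verdict: str | None
    alt_reachable: bool
    blocking_contacts: list[tuple[str, float]]  # (residue descriptor, overlap A)
    diagnostics: list[str]
    current_escape: EscapeResult | None = None
    alt_escape: EscapeResult | None = None


def chi_angles(residue: Residue) -> ChiAngles:
    """Measure the defined chi angles of a residue; absent atoms are flagged
    and yield ``None`` for the affected angle."""
    quads = CHI_ATOMS.get(residue.name, [])
    chis: list[float | None] = []
    missing: list[str] = []
    for quad in quads:
        atoms = [residue.atom(n) for n in quad]
        if any(a is None for a in atoms):
            missing.extend(n for n, a in zip(quad, atoms) if a is None)
            chis.append(None)
            continue
        chis.append(dihedral(*(a.pos for a in atoms)))
    return ChiAngles(residue=residue, chis=tuple(chis), missing=tuple(dict.fromkeys(missing)))


_BIN_CENTERS = {"m": -60.0, "t": 180.0, "p": 60.0}


def classify_rotamer(chis: Sequence[float | None]) -> str:
    """Canonical rotamer label: each chi binned to m (-60), t (180) or
    p (+60) by nearest center (circular distance; boundary to the nearer
    center).  Undefined chis terminate the label."""
    label = ""
    for chi in chis:
        if chi is None:
            break
        best = min(_BIN_CENTERS, key=lambda k: _circ_dist(chi, _BIN_CENTERS[k]))
        label += best
    return label


def _circ_dist(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def rebuild_sidechain(residue: Residue, chis: Sequence[float]) -> Residue:
    """Rebuild a residue's side chain at the stated chi angles from ideal
    internal coordinates (no refinement), keeping backbone + CB fixed."""
    if residue.name not in SIDECHAIN_TEMPLATES:
        raise ValueError(f"no side-chain template for {residue.name}")
    out = Residue(residue.chain_id, residue.seqnum, residue.icode, residue.name,
                  [Atom(a.name, a.element, a.pos.copy()) for a in residue.atoms
                   if a.name in BACKBONE + ("CB",)], het=residue.het)
    out.index = residue.index
    coords = {a.name: a.pos for a in out.atoms}
    chis = tuple(chis) + (-60.0,) * 2
    for name, (ra, rb, rc), bond, ang, dih_spec in SIDECHAIN_TEMPLATES[residue.name][1:]:
        dih = _resolve_dihedral(dih_spec, chis)
        pos = place_atom(coords[ra], coords[rb], coords[rc], bond, ang, dih)
        coords[name] = pos
        element = "O" if name.startswith("O") else "N" if name.startswith("N") \
            else "S" if name.startswith("S") else "C"
        out.atoms.append(Atom(name, element, pos))
    return out


def _clash_contacts(moved: Residue, structure: Structure, slack: float = 0.4,
                    moved_atoms: Sequence[str] | None = None,
                    highlight: Sequence[str] = ()) -> list[tuple[str, float]]:
    """Residues with atoms closer than (vdW sum - slack) to the moved
    side-chain atoms, sorted by overlap depth."""
    targets = [a for a in moved.atoms
               if (moved_atoms is None and a.name not in BACKBONE + ("CB",))
               or (moved_atoms is not None and a.name in moved_atoms)]
    contacts: dict[str, float] = {}
    for res in structure.iter_residues():
        if res.chain_id == moved.chain_id and res.index == moved.index:
            continue
        for atom in res.atoms:
            r_other = VDW_RADII.get(atom.element, DEFAULT_VDW)
            for t in targets:
                r_t = VDW_RADII.get(t.element, DEFAULT_VDW)
                limit = r_other + r_t - slack
                d = float(np.linalg.norm(atom.pos - t.pos))
                if d < limit:
                    descr = f"{res.chain_id}:{res.name}:{res.seqnum}"
                    overlap = limit - d
                    contacts[descr] = max(contacts.get(descr, 0.0), overlap)
    ordered = sorted(contacts.items(), key=lambda kv: -kv[1])
    return [(d, round(o, 3)) for d, o in ordered]


def gate_assessment(
    structure: Structure,
    numbering,
    alt_chis: tuple[float, float],
    gate: str = "2x46",
    triad: tuple[str, ...] = ("2x46", "3x43", "6x40"),
    clash_slack: float = 0.4,
    **escape_kwargs,
) -> GateAssessment:
    """Assess the Leu 2x46 escape gate in its current and alternative rotamer.

    Runs the escape-channel test with the side chain as observed, rebuilds
    it at ``alt_chis``, and reruns.  Atoms of any residue overlapping the
    rebuilt side chain by more than the soft-clash allowance are reported
    as blocking contacts (the alternative rotamer is then flagged
    unreachable and its verdict reflects geometry only).  Missing triad
    residues degrade the assessment with a diagnostic instead of failing.
    """
    diagnostics: list[str] = []
    for t in triad:
        if numbering.lookup(t) is None:
            diagnostics.append(f"triad residue {t} missing")
    residue = numbering.lookup(gate)
    if residue is None:
        return GateAssessment(residue=None, current_label=None, current_verdict="closed",
                              alt_label=None, alt_verdict=None, alt_reachable=False,
                              blocking_contacts=[], diagnostics=diagnostics + [f"{gate} missing"])
    cur_chi = chi_angles(residue)
    cur_label = classify_rotamer(cur_chi.chis) or None
    current = escape_channel_test(structure, numbering, start=gate, **escape_kwargs)

    rebuilt = rebuild_sidechain(residue, alt_chis)
    contacts = _clash_contacts(rebuilt, structure, slack=clash_slack)
    # a rebuilt side chain driven deep into another residue's backbone is an
    # invalid model, not merely a blocked rotamer
    side = [a for a in rebuilt.atoms if a.name not in BACKBONE + ("CB",)]
    for res in structure.iter_residues():
        if res.het or (res.chain_id == rebuilt.chain_id and res.index == rebuilt.index):
            continue
        for name in BACKBONE:
            atom = res.atom(name)
            if atom is None:
                continue
            for t in side:
                if np.linalg.norm(atom.pos - t.pos) < 1.5:
                    raise ValueError(
                        f"side-chain rebuild clashes with backbone of "
                        f"{res.chain_id}:{res.name}:{res.seqnum}")

    # swap the rebuilt residue in, rerun, swap back
    chain = structure.chains[residue.chain_id]
    pos = chain.index(residue)
    chain[pos] = rebuilt

    class _AltNumbering:
        def lookup(self, g):
            base = numbering.lookup(g)
            if base is residue:
                return rebuilt
            return base

    try:
        alt = escape_channel_test(structure, _AltNumbering(), start=gate, **escape_kwargs)
    finally:
        chain[pos] = residue
    alt_label = classify_rotamer(chi_angles(rebuilt).chis) or None
    return GateAssessment(
        residue=residue, current_label=cur_label, current_verdict=current.verdict,
        alt_label=alt_label, alt_verdict=alt.verdict,
        alt_reachable=not contacts, blocking_contacts=contacts,
        diagnostics=diagnostics, current_escape=current, alt_escape=alt)


def pentamer_search(
    structure: Structure,
    chain: str,
    center_index: int,
    db: Sequence[Fragment],
    rmsd_threshold: float = 0.5,
) -> list[RotamerHit]:
    """Fragments with the query's middle residue type and a very similar
    5-residue backbone, superposed into the query frame.

    The query backbone is the 20 atoms N, CA, C, O of residues
    center-2 .. center+2; hits are sorted by ascending RMSD.
    """
    residues = structure.chain(chain)
    by_index = {r.index: r for r in residues}
    window = [by_index.get(center_index + d) for d in range(-2, 3)]
    if any(r is None or not r.complete_backbone for r in window):
        raise ValueError("center residue needs two complete-backbone neighbors on each side")
    center = window[2]
    query_bb = np.array([r.coord(a) for r in window for a in BACKBONE])
    hits: list[RotamerHit] = []
    for frag in db:
        if frag.middle_type != center.name:
            continue
        result = superpose(frag.backbone, query_bb)
        if result.rmsd <= rmsd_threshold:
            side = [(name, result.transform(pos)) for name, pos in frag.sidechain]
            hits.append(RotamerHit(frag_id=frag.frag_id, rmsd=result.rmsd,
                                   sidechain=side, chis=frag.chis,
                                   label=classify_rotamer(frag.chis)))
    hits.sort(key=lambda h: h.rmsd)
    return hits


def rotamer_distribution(hits: Sequence[RotamerHit]) -> dict[str, float]:
    """Frequency of canonical rotamer labels among hits (sums to 1)."""
    if not hits:
        return {}
    counts: dict[str, int] = {}
    for h in hits:
        counts[h.label] = counts.get(h.label, 0) + 1
    total = len(hits)
    return {label: counts[label] / total for label in sorted(counts)}
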