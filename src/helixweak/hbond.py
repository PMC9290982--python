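"""Backbone amide hydrogen placement, hydrogen-bond energies and classes.

The central observable of the whole pipeline is the state of each expected
helical i -> i+4 backbone hydrogen bond.  Energies use the Kabsch-Sander
electrostatic model

    E = 27.888 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol, r in A]

between the donor amide (N-H) and the acceptor carbonyl (C=O).  Amide
hydrogens are rebuilt uniformly: H sits 1.0 A from N along the direction
opposite the preceding residue's carbonyl O -> C vector; proline has no
amide proton and is donor-incapable, which is exactly why it always costs
the helix one hydrogen bond.

Bonds are classified by energy into ``normal`` / ``weak`` / ``missing``.
The "very weak" category has no numeric definition in the literature this
implements, so the two thresholds are explicit, configurable parameters:
defaults are chosen so that ideal-helix bonds are normal and bonds whose
donor-acceptor geometry is over-stretched by roughly 0.4-0.8 A fall in the
weak band.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np

from .structures_io import Residue

__all__ = [
    "HBondRecord",
    "SidechainHBond",
    "HBondOptions",
    "MISSING_ENERGY",
    "place_amide_hydrogens",
    "hbond_energy",
    "classify_hbond",
    "backbone_hbond_map",
    "sidechain_backbone_hbonds",
]

KS_CONSTANT = 27.888      # kcal/mol * A, Kabsch-Sander coupling constant
MISSING_ENERGY = math.inf  # sentinel for donor-incapable pairs

HELICAL_OFFSETS = (-4, -3, -5)  # canonical first

# Polar side-chain atoms that can clamp the local backbone.
POLAR_SIDECHAIN_ATOMS = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "ASN": ("OD1", "ND2"),
    "ASP": ("OD1", "OD2"),
    "CYS": ("SG",),
    "TYR": ("OH",),
}


@dataclasses.dataclass
class HBondOptions:
    e_strong: float = -1.2   # kcal/mol; E <= e_strong -> normal
    e_weak: float = -0.5     # kcal/mol; e_strong < E <= e_weak -> weak
    sidechain_cutoff: float = 3.5  # A, distance criterion for side-chain clamps

    def __post_init__(self) -> None:
        if self.e_strong > self.e_weak:
            raise ValueError("e_strong must be <= e_weak")


@dataclasses.dataclass
class HBondRecord:
    donor: Residue
    acceptor: Residue
    offset: int              # acceptor index - donor index
    r_no: float              # N...O distance, A
    r_ho: float              # H...O distance, A (nan if no H)
    energy: float            # kcal/mol; +inf when the donor has no proton
    klass: str               # normal | weak | missing

    @property
    def donor_index(self) -> int:
        return self.donor.index

    @property
    def acceptor_index(self) -> int:
        return self.acceptor.index


@dataclasses.dataclass
class SidechainHBond:
    residue: Residue         # residue providing the polar side-chain atom
    sidechain_atom: str
    partner: Residue         # backbone partner residue
    partner_atom: str        # "O" or "N"
    distance: float
    energy: float | None = None
    weak_donor: bool = False  # e.g. cysteine SG


def place_amide_hydrogens(residues: Sequence[Residue]) -> dict[int, np.ndarray]:
    """Compute backbone amide H positions for a chain-ordered residue run.

    Returns a map from residue ``index`` to the H coordinate.  The first
    residue of the run and prolines get no entry (donor-incapable); residues
    with incomplete backbones are skipped.
    """
    hydrogens: dict[int, np.ndarray] = {}
    for prev, res in zip(residues, residues[1:]):
        if res.name == "PRO":
            continue
        if not (res.complete_backbone and prev.complete_backbone):
            continue
        if res.index != prev.index + 1:
            continue  # sequence break: no defined peptide bond
        direction = prev.coord("C") - prev.coord("O")
        norm = np.linalg.norm(direction)
        if norm < 1e-9:
            continue
        hydrogens[res.index] = res.coord("N") + direction / norm
    return hydrogens


def hbond_energy(
    donor: Residue,
    acceptor: Residue,
    h_pos: np.ndarray | None,
) -> tuple[float, float, float]:
    """Kabsch-Sander energy of donor N-H ... O=C acceptor.

    Returns ``(energy, r_NO, r_HO)``.  A donor without an amide proton
    (proline, chain start) yields the +inf sentinel and nan for r_HO.
    """
    n = donor.coord("N")
    c = acceptor.coord("C")
    o = acceptor.coord("O")
    r_no = float(np.linalg.norm(n - o))
    if h_pos is None:
        return MISSING_ENERGY, r_no, float("nan")
    r_oh = float(np.linalg.norm(h_pos - o))
    r_ch = float(np.linalg.norm(h_pos - c))
    r_cn = float(np.linalg.norm(n - c))
    if min(r_no, r_oh, r_ch, r_cn) < 0.5:
        raise ValueError(
            f"overlapping atoms between donor {donor.chain_id}{donor.seqnum} "
            f"and acceptor {acceptor.chain_id}{acceptor.seqnum}")
    energy = KS_CONSTANT * (1.0 / r_no + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return float(energy), r_no, r_oh


def classify_hbond(energy: float, options: HBondOptions | None = None) -> str:
    """Map an energy to ``normal`` / ``weak`` / ``missing``.

    Monotone step function: the class can only degrade as energy increases;
    the +inf sentinel (no donor proton) is always ``missing``.
    """
    opts = options or HBondOptions()
    if energy <= opts.e_strong:
        return "normal"
    if energy <= opts.e_weak:
        return "weak"
    return "missing"


def backbone_hbond_map(
    residues: Sequence[Residue],
    options: HBondOptions | None = None,
) -> dict[int, dict]:
    """Evaluate helical-register hydrogen bonds for every potential donor.

    For each donor residue the energy to the acceptors at offsets -3, -4, -5
    is computed.  The result maps donor ``index`` to::

        {"best": HBondRecord, "canonical": HBondRecord | None,
         "records": {offset: HBondRecord}, "donor_capable": bool}

    ``canonical`` is the i -> i-4 record (the bond a regular alpha-helix
    would form) and is kept even when another register is energetically
    preferred.  Donor-incapable residues (proline, chain start) yield
    records with the +inf sentinel, classified ``missing``.
    """
    opts = options or HBondOptions()
    by_index = {r.index: r for r in residues}
    hydrogens = place_amide_hydrogens(residues)
    out: dict[int, dict] = {}
    first_index = residues[0].index if residues else 0
    for res in residues:
        if not res.complete_backbone:
            continue
        if res.index == first_index:
            continue  # no preceding residue: never a donor
        h_pos = hydrogens.get(res.index)
        donor_capable = h_pos is not None
        records: dict[int, HBondRecord] = {}
        for offset in HELICAL_OFFSETS:
            acc = by_index.get(res.index + offset)
            if acc is None or not acc.complete_backbone:
                continue
            energy, r_no, r_ho = hbond_energy(res, acc, h_pos)
            records[offset] = HBondRecord(
                donor=res, acceptor=acc, offset=offset, r_no=r_no, r_ho=r_ho,
                energy=energy, klass=classify_hbond(energy, opts))
        if -4 not in records:
            continue  # a donor is only evaluated once its canonical partner exists
        best = min(records.values(), key=lambda r: r.energy)
        out[res.index] = {
            "best": best,
            "canonical": records.get(-4),
            "records": records,
            "donor_capable": donor_capable,
        }
    return out


def sidechain_backbone_hbonds(
    residues: Sequence[Residue],
    options: HBondOptions | None = None,
) -> list[SidechainHBond]:
    """Distance-criterion side-chain-to-backbone hydrogen bonds.

    A polar side-chain atom (Ser OG, Thr OG1, Asn OD1/ND2, Asp OD1/OD2,
    Cys SG, Tyr OH) within ``sidechain_cutoff`` of a backbone O or N of a
    residue i-4 .. i+4 in the same run is reported.  The residue's own
    backbone is excluded (those proximities are fixed by covalent geometry,
    not by an interaction); i-1 and i+1 partners are kept — the serine
    contact to the preceding turn's carbonyl is the textbook helix clamp.
    Pure distance criterion, no angular term.  Cysteine records are
    flagged weak donors.
    """
    opts = options or HBondOptions()
    by_index = {r.index: r for r in residues}
    out: list[SidechainHBond] = []
    for res in residues:
        polar = POLAR_SIDECHAIN_ATOMS.get(res.name, ())
        for atom_name in polar:
            atom = res.atom(atom_name)
            if atom is None:
                continue
            for delta in range(-4, 5):
                if delta == 0:
                    continue
                partner = by_index.get(res.index + delta)
                if partner is None or not partner.complete_backbone:
                    continue
                for backbone_atom in ("O", "N"):
                    dist = float(np.linalg.norm(atom.pos - partner.coord(backbone_atom)))
                    if dist <= opts.sidechain_cutoff:
                        out.append(SidechainHBond(
                            residue=res, sidechain_atom=atom_name,
                            partner=partner, partner_atom=backbone_atom,
                            distance=dist, weak_donor=(res.name == "CYS")))
    out.sort(key=lambda b: (b.residue.index, b.partner.index, b.partner_atom))
    return out
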