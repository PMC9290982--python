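"""Macromolecular structure reading/writing and the in-memory data model.

Parsing of PDB and mmCIF goes through gemmi; this module reduces whatever a
crystallographic file contains to the single-conformer, hydrogen-free model
the downstream hydrogen-bond analysis needs:

* alternate locations are resolved to the highest-occupancy conformer at
  parse time (ties broken by altloc label order),
* hydrogens present in the input are discarded (the hbond module rebuilds
  amide hydrogens with one uniform convention),
* waters and other heteroatoms are kept but flagged,
* author residue numbering is preserved verbatim while every residue also
  receives a 0-based sequential index within its chain, which is what all
  i -> i+4 arithmetic uses (GPCR entries have numbering gaps and fusions).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "StructureError",
    "ParseError",
    "FormatError",
    "read_structure",
    "write_structure",
    "backbone_view",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
AA1TO3 = {v: k for k, v in AA3TO1.items()}


class StructureError(Exception):
    """Base class for structure-model errors."""


class ParseError(StructureError):
    """Input file could not be parsed under the named standard."""


class FormatError(StructureError):
    """Structure cannot be represented in the requested output format."""


@dataclasses.dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # (3,) float, Angstrom

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise StructureError(f"atom {self.name}: position must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.name}: empty element symbol")


@dataclasses.dataclass
class Residue:
    chain_id: str
    seqnum: int          # author numbering, preserved verbatim
    icode: str
    name: str            # 3-letter code
    atoms: list[Atom]
    het: bool = False    # water or other heteroatom record
    index: int = -1      # 0-based sequential index within the chain

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coord(self, name: str) -> np.ndarray:
        a = self.atom(name)
        if a is None:
            raise StructureError(f"residue {self.chain_id}{self.seqnum} {self.name}: no atom {name}")
        return a.pos

    @property
    def complete_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in BACKBONE_ATOMS)

    @property
    def is_amino_acid(self) -> bool:
        return not self.het and (self.name in STANDARD_AA or self.complete_backbone)

    def one_letter(self) -> str:
        return AA3TO1.get(self.name, "X")


@dataclasses.dataclass
class Structure:
    ident: str
    chains: dict[str, list[Residue]]
    source_format: str = "synthetic"

    def __post_init__(self) -> None:
        self.reindex()

    def reindex(self) -> None:
        for residues in self.chains.values():
            for i, res in enumerate(residues):
                res.index = i

    def chain(self, chain_id: str) -> list[Residue]:
        if chain_id not in self.chains:
            raise KeyError(f"no chain {chain_id!r} in structure {self.ident}")
        return self.chains[chain_id]

    def iter_residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.iter_residues():
            for atom in res.atoms:
                yield res, atom

    def atom_coords(self, heavy_only: bool = True) -> np.ndarray:
        coords = [a.pos for _, a in self.iter_atoms() if not (heavy_only and a.element == "H")]
        if not coords:
            return np.empty((0, 3))
        return np.array(coords)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues())


def _element_from_name(name: str) -> str:
    # PDB atom names start with the element, possibly after a digit ("1HB").
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if len(stripped) >= 2 and stripped[:2].capitalize() in ("Cl", "Br", "Fe", "Zn", "Mg", "Na", "Se"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc order."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = by_name.get(atom.name)
        if prev is None or atom.occ > prev.occ + 1e-9:
            by_name[prev.name if prev else atom.name] = atom
    return list(by_name.values())


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into the uniform data model.

    ``format`` is one of ``pdb``, ``mmcif``, ``auto``.  Only the first model
    of multi-model (NMR) entries is used.  Hydrogens are discarded; altlocs
    are resolved to the highest-occupancy conformer.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    fmt = {"pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif,
           "auto": gemmi.CoorFormat.Detect}.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    try:
        gst = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    gst.setup_entities()
    if len(gst) == 0:
        raise ParseError(f"{path}: empty structure (no models)")
    model = gst[0]
    chains: dict[str, list[Residue]] = {}
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            het = gres.het_flag == "H" or gres.is_water()
            atoms: list[Atom] = []
            for gatom in _resolve_altlocs(gres):
                if gatom.element.is_hydrogen:
                    continue
                element = gatom.element.name if gatom.element.name not in ("", "X") \
                    else _element_from_name(gatom.name)
                atoms.append(Atom(gatom.name, element, np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z])))
            if atoms:
                residues.append(Residue(gchain.name, gres.seqid.num, gres.seqid.icode.strip(),
                                        gres.name, atoms, het=het))
        if residues:
            chains[gchain.name] = residues
    if not chains:
        raise ParseError(f"{path}: no coordinate records found")
    src = "mmcif" if (format == "mmcif" or path.suffix.lower() in (".cif", ".mmcif")) else "pdb"
    return Structure(path.stem, chains, source_format=src)


def write_structure(s: Structure, path: str | Path, format: str = "pdb") -> None:
    """Write the structure as a standard PDB file (coordinates at 3 decimals)."""
    if format != "pdb":
        raise ValueError(f"unsupported output format {format!r}")
    if s.n_atoms > 99999:
        raise FormatError(f"{s.n_atoms} atoms exceed the PDB serial-number capacity (99999)")
    gst = gemmi.Structure()
    gst.name = s.ident
    model = gemmi.Model("1")
    for chain_id, residues in s.chains.items():
        gchain = gemmi.Chain(chain_id or "A")
        for res in residues:
            if len(res.name) > 3:
                raise FormatError(
                    f"residue name {res.name!r} exceeds the 3-character PDB field width")
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seqnum, res.icode or " ")
            gres.het_flag = "H" if res.het else "A"
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(*atom.pos)
                gatom.occ = 1.0
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    gst.add_model(model)
    gst.setup_entities()
    gst.write_pdb(str(path))


def backbone_view(s: Structure, chain: str) -> list[tuple[Residue, bool]]:
    """Residues of one chain restricted to backbone analysis.

    Returns ``(residue, complete)`` pairs in chain order for all non-het
    residues.  Residues missing any of N/CA/C/O are flagged incomplete (and
    must be excluded from hydrogen-bond analysis) but keep their position in
    the numbering — they are never silently dropped.
    """
    out = []
    for res in s.chain(chain):
        if res.het:
            continue
        out.append((res, res.complete_backbone))
    return out
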