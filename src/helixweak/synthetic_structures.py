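"""Deterministic generators for every class of synthetic test input.

The analysis modules are validated against structures whose ground truth is
known by construction:

* ideal and distorted alpha / 3-10 / pi helices built from internal
  coordinates (NeRF-style chain growth) with full side chains for the
  residues whose weakening mechanisms matter (L, S, T, N, D, C, Y, W) and
  CB stubs for the rest,
* 7-helix bundle phantoms with weak spots planted at chosen generic
  positions through distinct mechanisms (proline vs. Ser/Thr side-chain
  clamp vs. glycine flexibility),
* tube / hollow-sphere / gate phantoms of known channel geometry for the
  voxel-grid cavity detector,
* small pentamer fragment databases with planted conformers for the
  rotamer-distribution search.

All builders are deterministic: a seed only drives optional coordinate
noise and background randomization, never the planted truth.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .geometry import dihedral, place_atom
from .structures_io import AA1TO3, Atom, Residue, Structure, StructureError

__all__ = [
    "Distortion",
    "HelixSpec",
    "ChannelPhantomSpec",
    "BundleSpec",
    "PlantedWeakSpot",
    "PentamerSpec",
    "build_helix",
    "build_channel_phantom",
    "build_sphere_phantom",
    "build_gate_phantom",
    "build_bundle",
    "build_fragment_db",
    "merge_structures",
    "ALPHA", "THREE10", "PI",
]

# Backbone internal coordinates (A / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5

# Canonical helical torsions (phi, psi).
ALPHA = (-57.0, -47.0)
THREE10 = (-49.0, -26.0)
PI = (-57.0, -70.0)

# Side-chain internal-coordinate templates.  Each entry: atom name,
# (a, b, c) reference atom names, bond, angle, dihedral.  Dihedrals may be
# "chi1"/"chi2" (optionally with +offset) or a number.
_CB = ("CB", ("C", "N", "CA"), 1.530, 110.5, 122.55)

SIDECHAIN_TEMPLATES: dict[str, list[tuple]] = {
    "ALA": [_CB],
    "LEU": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.530, 116.3, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.521, 110.7, "chi2"),
        ("CD2", ("CA", "CB", "CG"), 1.521, 110.7, "chi2+120"),
    ],
    "SER": [_CB, ("OG", ("N", "CA", "CB"), 1.417, 110.8, "chi1")],
    "THR": [
        _CB,
        ("OG1", ("N", "CA", "CB"), 1.433, 109.6, "chi1"),
        ("CG2", ("N", "CA", "CB"), 1.521, 110.5, "chi1-120"),
    ],
    "CYS": [_CB, ("SG", ("N", "CA", "CB"), 1.808, 113.8, "chi1")],
    "ASN": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, "chi1"),
        ("OD1", ("CA", "CB", "CG"), 1.231, 120.8, "chi2"),
        ("ND2", ("CA", "CB", "CG"), 1.328, 116.4, "chi2+180"),
    ],
    "ASP": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.516, 112.6, "chi1"),
        ("OD1", ("CA", "CB", "CG"), 1.249, 118.4, "chi2"),
        ("OD2", ("CA", "CB", "CG"), 1.249, 118.4, "chi2+180"),
    ],
    "TYR": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.512, 113.9, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.389, 120.8, "chi2"),
        ("CD2", ("CA", "CB", "CG"), 1.389, 120.8, "chi2+180"),
        ("CE1", ("CB", "CG", "CD1"), 1.382, 121.2, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.382, 121.2, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.378, 119.6, 0.0),
        ("OH", ("CD1", "CE1", "CZ"), 1.376, 119.9, 180.0),
    ],
    "TRP": [
        _CB,
        ("CG", ("N", "CA", "CB"), 1.498, 113.6, "chi1"),
        ("CD1", ("CA", "CB", "CG"), 1.365, 126.9, "chi2"),
        ("CD2", ("CA", "CB", "CG"), 1.433, 126.7, "chi2+180"),
        ("NE1", ("CB", "CG", "CD1"), 1.374, 110.2, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.409, 107.2, 180.0),
        ("CE3", ("CB", "CG", "CD2"), 1.398, 133.9, 0.0),
        ("CZ2", ("CG", "CD2", "CE2"), 1.394, 122.4, 180.0),
        ("CZ3", ("CG", "CD2", "CE3"), 1.382, 118.6, 180.0),
        ("CH2", ("CD2", "CE3", "CZ3"), 1.400, 121.1, 0.0),
    ],
}

DEFAULT_CHIS: dict[str, tuple[float, ...]] = {
    "LEU": (-60.0, 180.0),
    "SER": (-60.0,),
    "THR": (-60.0,),
    "CYS": (-60.0,),
    "ASN": (-60.0, -20.0),
    "ASP": (-60.0, -20.0),
    "TYR": (-60.0, 90.0),
    "TRP": (-60.0, 90.0),
}

VDW_CARBON = 1.70

DISTORTION_KINDS = ("proline", "pi_bulge", "three10", "sidechain_clamp", "glycine_flex")


@dataclasses.dataclass
class Distortion:
    position: int                 # 0-based residue index within the helix
    kind: str
    # amide-displacement magnitude for clamp/glycine kinds (A); calibrated so
    # the canonical bond lands mid-way into the weak energy band
    pull: float = 0.9

    def __post_init__(self) -> None:
        if self.kind not in DISTORTION_KINDS:
            raise ValueError(f"unknown distortion kind {self.kind!r}")


@dataclasses.dataclass
class HelixSpec:
    sequence: str
    phi: float = ALPHA[0]
    psi: float = ALPHA[1]
    omega: float = 180.0
    distortions: tuple[Distortion, ...] = ()
    torsions: Sequence[tuple[float, float]] | None = None  # per-residue override
    chis: dict[int, tuple[float, ...]] = dataclasses.field(default_factory=dict)
    noise: float = 0.0            # gaussian coordinate jitter, A

    def __post_init__(self) -> None:
        if abs(self.phi) > 180 or abs(self.psi) > 180:
            raise ValueError("phi/psi must lie in [-180, 180]")
        for code in self.sequence:
            if code.upper() not in AA1TO3:
                raise ValueError(f"unknown residue code {code!r}")
        for d in self.distortions:
            if not 0 <= d.position < len(self.sequence):
                raise ValueError(f"distortion position {d.position} outside sequence")


def _resolve_dihedral(spec, chis: tuple[float, ...]) -> float:
    if isinstance(spec, (int, float)):
        return float(spec)
    base = spec[:4]
    offset = float(spec[4:] or 0.0)
    idx = {"chi1": 0, "chi2": 1}[base]
    if idx >= len(chis):
        raise ValueError(f"{base} required but not provided")
    ang = chis[idx] + offset
    return (ang + 180.0) % 360.0 - 180.0


def _build_sidechain(res: Residue, chis: tuple[float, ...]) -> None:
    templates = SIDECHAIN_TEMPLATES.get(res.name, [] if res.name == "GLY" else [_CB])
    coords = {a.name: a.pos for a in res.atoms}
    for name, (ra, rb, rc), bond, ang, dih_spec in templates:
        dih = _resolve_dihedral(dih_spec, chis)
        pos = place_atom(coords[ra], coords[rb], coords[rc], bond, ang, dih)
        coords[name] = pos
        element = "O" if name.startswith("O") else "N" if name.startswith("N") \
            else "S" if name.startswith("S") else "C"
        res.atoms.append(Atom(name, element, pos))


def build_peptide(
    sequence: str,
    torsions: Sequence[tuple[float, float]],
    omega: float = 180.0,
    chis: dict[int, tuple[float, ...]] | None = None,
    chain_id: str = "A",
    ident: str = "peptide",
) -> Structure:
    """Build an all-atom peptide from per-residue (phi, psi) torsions.

    The first residue's phi and the last residue's psi only orient terminal
    atoms.  Side chains are built from the internal-coordinate templates at
    the requested (or default) chi angles; residues without a template get a
    CB stub; glycine gets none.
    """
    n = len(sequence)
    if len(torsions) != n:
        raise ValueError("need one (phi, psi) pair per residue")
    chis = chis or {}
    # Backbone trace: N, CA, C per residue.
    bb = np.zeros((n, 3, 3))
    bb[0, 0] = (0.0, 0.0, 0.0)
    bb[0, 1] = (BOND_N_CA, 0.0, 0.0)
    ang = math.radians(180.0 - ANGLE_N_CA_C)
    bb[0, 2] = bb[0, 1] + BOND_CA_C * np.array([math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n):
        phi_i, _ = torsions[i]
        _, psi_prev = torsions[i - 1]
        bb[i, 0] = place_atom(bb[i - 1, 0], bb[i - 1, 1], bb[i - 1, 2],
                              BOND_C_N, ANGLE_CA_C_N, psi_prev)
        bb[i, 1] = place_atom(bb[i - 1, 1], bb[i - 1, 2], bb[i, 0],
                              BOND_N_CA, ANGLE_C_N_CA, omega)
        bb[i, 2] = place_atom(bb[i - 1, 2], bb[i, 0], bb[i, 1],
                              BOND_CA_C, ANGLE_N_CA_C, phi_i)
    residues: list[Residue] = []
    for i, code in enumerate(sequence):
        name = AA1TO3[code.upper()]
        _, psi_i = torsions[i]
        o_pos = place_atom(bb[i, 0], bb[i, 1], bb[i, 2], BOND_C_O, ANGLE_CA_C_O,
                           psi_i - 180.0)
        atoms = [
            Atom("N", "N", bb[i, 0]),
            Atom("CA", "C", bb[i, 1]),
            Atom("C", "C", bb[i, 2]),
            Atom("O", "O", o_pos),
        ]
        res = Residue(chain_id, i + 1, "", name, atoms)
        res.index = i
        residues.append(res)
        _build_sidechain(res, chis.get(i, DEFAULT_CHIS.get(name, (-60.0, 180.0))))
    return Structure(ident, {chain_id: residues})


def _clamp_chi1(res: Residue, target: np.ndarray, contact: float = 2.9) -> float:
    """Chi1 (2-degree grid) that puts the first polar/branch atom at the
    hydrogen-bonding ``contact`` distance from ``target`` (closest match)."""
    n, ca, cb = res.coord("N"), res.coord("CA"), res.coord("CB")
    _, _, bond, ang, _ = SIDECHAIN_TEMPLATES[res.name][1]

    def miss(chi: float) -> float:
        d = float(np.linalg.norm(place_atom(n, ca, cb, bond, ang, chi) - target))
        return abs(d - contact)

    return min((float(c) for c in range(-180, 180, 2)), key=miss)


def build_helix(spec: HelixSpec, seed: int = 0) -> Structure:
    """Build a helix from a :class:`HelixSpec`.

    Deterministic for a given spec; ``seed`` only drives the optional
    coordinate noise (``spec.noise`` > 0).  Distortions:

    * ``proline``  - the residue becomes PRO (donor-incapable; the bond it
      donates in a regular helix goes missing),
    * ``pi_bulge`` / ``three10`` - a 4-residue torsion window switches to
      pi / 3-10 values so donors prefer the -5 / -3 register,
    * ``sidechain_clamp`` - the residue at i-3 (one turn above the acceptor)
      becomes SER, the acceptor carbonyl O of residue i-4 is pulled ``pull``
      A away from the donor amide (over-stretching the canonical i -> i-4
      bond into the weak band) and the serine chi1 is aimed so that OG sits
      at hydrogen-bond distance from the displaced carbonyl — the textbook
      Ser/Thr backbone clamp,
    * ``glycine_flex`` - the residue i+1 of the weakened donor becomes GLY
      and the acceptor carbonyl is pulled the same way.

    ``Distortion.position`` is always the donor of the weakened bond.
    """
    seq = list(spec.sequence.upper())
    torsions = list(spec.torsions) if spec.torsions is not None else \
        [(spec.phi, spec.psi)] * len(seq)
    torsions = [tuple(t) for t in torsions]
    chis = dict(spec.chis)

    for d in spec.distortions:
        if d.kind == "proline":
            seq[d.position] = "P"
        elif d.kind == "pi_bulge":
            for j in range(d.position, min(d.position + 4, len(seq))):
                torsions[j] = PI
        elif d.kind == "three10":
            for j in range(d.position, min(d.position + 4, len(seq))):
                torsions[j] = THREE10
        elif d.kind == "sidechain_clamp":
            if d.position < 4:
                raise ValueError("sidechain_clamp needs position >= 4")
            if seq[d.position - 3] not in ("S", "T"):
                seq[d.position - 3] = "S"
        elif d.kind == "glycine_flex":
            if d.position + 1 < len(seq):
                seq[d.position + 1] = "G"

    structure = build_peptide("".join(seq), torsions, omega=spec.omega, chis=chis,
                              ident="helix")
    residues = structure.chains["A"]

    # Post-build geometric edits for clamp-style mechanisms.
    for d in spec.distortions:
        if d.kind not in ("sidechain_clamp", "glycine_flex"):
            continue
        p = d.position
        if p < 4:
            raise ValueError(f"{d.kind} needs position >= 4 (acceptor at i-4)")
        donor, acceptor = residues[p], residues[p - 4]
        # Pull the donor amide nitrogen away from the acceptor carbonyl:
        # over-stretches the canonical i -> i-4 bond while leaving every
        # other donor's geometry (and every H placement) untouched.
        n_atom = donor.atom("N")
        away = n_atom.pos - acceptor.coord("O")
        n_atom.pos = n_atom.pos + d.pull * away / np.linalg.norm(away)
        if d.kind == "sidechain_clamp":
            # aim the clamp residue's chi1 so its polar atom hydrogen-bonds
            # the displaced carbonyl
            clamp_res = residues[p - 3]
            chi1 = _clamp_chi1(clamp_res, acceptor.coord("O"))
            clamp_res.atoms = [a for a in clamp_res.atoms
                               if a.name in ("N", "CA", "C", "O", "CB")]
            coords = {a.name: a.pos for a in clamp_res.atoms}
            for name, (ra, rb, rc), bond, ang, dih_spec in \
                    SIDECHAIN_TEMPLATES[clamp_res.name][1:]:
                dih = _resolve_dihedral(dih_spec, (chi1, -60.0))
                pos = place_atom(coords[ra], coords[rb], coords[rc], bond, ang, dih)
                coords[name] = pos
                element = "O" if name.startswith("O") else "N" if name.startswith("N") \
                    else "S" if name.startswith("S") else "C"
                clamp_res.atoms.append(Atom(name, element, pos))

    if spec.noise > 0:
        rng = np.random.default_rng(seed)
        for res in residues:
            for atom in res.atoms:
                atom.pos = atom.pos + rng.normal(0.0, spec.noise, 3)
    return structure


# --------------------------------------------------------------------------
# Channel / cavity phantoms
# --------------------------------------------------------------------------

@dataclasses.dataclass
class ChannelPhantomSpec:
    radius: float                # open channel radius (to the vdW surface), A
    length: float = 20.0
    wall_spacing: float = 0.8    # <= 1.0 so walls are voxel-tight
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    wall_thickness: int = 2      # concentric atom shells

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("radius and length must be positive")
        if self.wall_spacing > 1.0:
            raise ValueError("wall atom spacing must be <= 1.0 A for voxel-tight walls")


def _wall_structure(points: np.ndarray, ident: str) -> Structure:
    residues = []
    chunk = 100
    for ri in range(0, len(points), chunk):
        atoms = [Atom("C", "C", p) for p in points[ri:ri + chunk]]
        residues.append(Residue("W", ri // chunk + 1, "", "WAL", atoms, het=True))
    return Structure(ident, {"W": residues})


def _tube_points(spec: ChannelPhantomSpec, origin: np.ndarray) -> np.ndarray:
    pts = []
    nz = int(round(spec.length / spec.wall_spacing)) + 1
    for shell in range(spec.wall_thickness):
        r_wall = spec.radius + VDW_CARBON + shell * spec.wall_spacing
        ntheta = max(8, int(round(2 * math.pi * r_wall / spec.wall_spacing)))
        for iz in range(nz):
            z = iz * spec.length / (nz - 1)
            stagger = 0.5 * (iz % 2) * 2 * math.pi / ntheta
            for it in range(ntheta):
                th = 2 * math.pi * it / ntheta + stagger
                pts.append([r_wall * math.cos(th), r_wall * math.sin(th), z])
    pts = np.array(pts)
    axis = np.asarray(spec.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if not np.allclose(axis, [0, 0, 1]):
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(z, axis)
        c = float(np.dot(z, axis))
        if np.linalg.norm(v) < 1e-12:
            rot = -np.eye(3) if c < 0 else np.eye(3)
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
            rot = np.eye(3) + vx + vx @ vx / (1 + c)
        pts = pts @ rot.T
    return pts + origin


def build_channel_phantom(
    spec: ChannelPhantomSpec,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    spacing: float = 1.0,
    probe: float = 1.4,
) -> tuple[Structure, int, dict]:
    """Closed tube of carbon atoms around an empty cylindrical channel.

    Returns ``(structure, expected_open_voxels, info)`` where the expected
    count is evaluated independently of the cavity module by the literal
    marking rule (distance to every wall atom, brute force) on the grid the
    phantom recommends.  ``info`` carries the recommended grid bounds (tight
    along the axis so the lumen stays separated from the exterior), an
    on-axis seed point and the analytic channel radius.
    """
    if spec.radius <= probe:
        raise ValueError(
            f"channel radius {spec.radius} <= probe {probe}: phantom would hold no open voxels")
    origin = np.asarray(origin, dtype=float)
    pts = _tube_points(spec, origin)
    structure = _wall_structure(pts, "tube_phantom")
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    axis = np.asarray(spec.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    pad = np.full(3, probe + 2.0) * (1.0 - np.abs(axis))  # no padding along the axis
    bounds = (lo - pad, hi + pad)
    expected = _brute_force_open_count(pts, bounds, spacing, probe + VDW_CARBON)
    info = {
        "bounds": bounds,
        "seed_point": origin + axis * spec.length / 2.0,
        "channel_radius": spec.radius,
        "axis": axis,
    }
    return structure, expected, info


def _brute_force_open_count(points: np.ndarray, bounds, spacing: float,
                            exclusion: float) -> int:
    """Count grid voxels farther than ``exclusion`` from every wall atom.

    Deliberately a plain all-pairs evaluation: this is the oracle the
    accelerated cavity marking is checked against.
    """
    lo, hi = bounds
    axes = [np.arange(lo[k], hi[k] + 1e-9, spacing) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    open_mask = np.ones(len(centers), dtype=bool)
    for chunk in range(0, len(points), 500):
        block = points[chunk:chunk + 500]
        d2 = ((centers[:, None, :] - block[None, :, :]) ** 2).sum(axis=2)
        open_mask &= (d2.min(axis=1) > exclusion ** 2)
    return int(open_mask.sum())


def build_sphere_phantom(inner_radius: float, wall_spacing: float = 0.8) -> tuple[Structure, dict]:
    """Sealed hollow sphere: carbon shell whose vdW surface sits at
    ``inner_radius`` from the center.  The enclosed open volume (default
    marking rule, probe 1.4) is analytically (4/3) pi (inner_radius - probe)^3."""
    r_shell = inner_radius + VDW_CARBON
    n = max(64, int(4 * math.pi * r_shell ** 2 / wall_spacing ** 2))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    pts = []
    for shell in range(2):
        r = r_shell + shell * wall_spacing
        for i in range(n):
            y = 1.0 - 2.0 * (i + 0.5) / n
            rad = math.sqrt(max(0.0, 1.0 - y * y))
            th = golden * i
            pts.append([r * math.cos(th) * rad, r * y, r * math.sin(th) * rad])
    structure = _wall_structure(np.array(pts), "sphere_phantom")
    info = {"center": np.zeros(3), "inner_radius": inner_radius}
    return structure, info


# --------------------------------------------------------------------------
# Gate phantom: a channel guarded by a leucine whose rotamer opens/closes it
# --------------------------------------------------------------------------

GATE_CLOSED_CHIS = (45.0, 60.0)
GATE_OPEN_CHIS = (-90.0, -60.0)
GATE_CA_HEIGHT = 3.0   # A above the cytosolic tube mouth


def _gate_leucine(chis: tuple[float, float], channel_radius: float) -> Residue:
    """The gate leucine: CA just outside the wall near the cytosolic mouth,
    CB aimed at the channel axis and slightly downward."""
    ca = np.array([channel_radius + VDW_CARBON + 0.4, 0.0, GATE_CA_HEIGHT])
    down_in = np.array([-math.cos(math.radians(25)), 0.0, -math.sin(math.radians(25))])
    cb = ca + 1.53 * down_in
    n = ca + BOND_N_CA * np.array([0.25, 0.9, 0.35]) / np.linalg.norm([0.25, 0.9, 0.35])
    c = ca + BOND_CA_C * np.array([0.35, -0.85, 0.4]) / np.linalg.norm([0.35, -0.85, 0.4])
    o = c + BOND_C_O * np.array([0.8, -0.4, 0.4]) / np.linalg.norm([0.8, -0.4, 0.4])
    res = Residue("G", 1, "", "LEU", [
        Atom("N", "N", n), Atom("CA", "C", ca), Atom("C", "C", c),
        Atom("O", "O", o), Atom("CB", "C", cb),
    ])
    res.index = 0
    _grow_leucine(res, chis)
    return res


def build_gate_phantom(
    channel_radius: float = 2.5,
    length: float = 24.0,
    closed_chis: tuple[float, float] = GATE_CLOSED_CHIS,
    open_chis: tuple[float, float] = GATE_OPEN_CHIS,
    rotamer: str = "closed",
    with_blockers: bool = False,
) -> tuple[Structure, dict]:
    """Tube phantom whose cytosolic mouth is guarded by a leucine gate.

    The leucine sits just outside the wall near the bottom (cytosolic, -z)
    opening with CB aimed at the axis — the same arrangement as the
    conserved Leu 2x46 above the sodium exit.  At ``closed_chis`` the side
    chain reaches across the lumen and occludes the exit region (the escape
    test finds no open voxel near its seed); at ``open_chis`` it lies along
    the wall (a patch of which is carved away to receive it) and the
    channel is passable.  With ``with_blockers`` two bulky residues (an
    aspartate and a tyrosine, mimicking the Asp 2x50 / Tyr 7x53 cage) fill
    the open-rotamer volume so that conformation is sterically unreachable.

    Returns ``(structure, info)``; info records the gate residue's
    chain/index, both chi sets, the recommended grid bounds (clipped inside
    the wall so the exterior cannot short-circuit the verdict) and the
    analytic channel radius.
    """
    spec = ChannelPhantomSpec(radius=channel_radius, length=length)
    pts = _tube_points(spec, np.zeros(3))
    # receive the open rotamer: carve the wall around its side chain so the
    # rebuilt conformation is clash-free (> vdW sum - 0.4 from every wall atom)
    open_env = np.array([_gate_leucine(open_chis, channel_radius).coord(a)
                         for a in ("CG", "CD1", "CD2")])
    d2 = ((pts[:, None, :] - open_env[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    pts = pts[d2 > 3.2 ** 2]

    chis = closed_chis if rotamer == "closed" else open_chis
    res = _gate_leucine(chis, channel_radius)
    structure = _wall_structure(pts, "gate_phantom")
    structure.chains["G"] = [res]
    structure.reindex()

    if with_blockers:
        structure.chains["B"] = _gate_blockers(res, open_chis, channel_radius)
        structure.reindex()

    b = channel_radius + VDW_CARBON + 0.4
    info = {
        "gate_chain": "G",
        "gate_index": 0,
        "closed_chis": closed_chis,
        "open_chis": open_chis,
        "bounds": (np.array([-b, -b, 0.0]), np.array([b, b, length])),
        "channel_radius": channel_radius,
    }
    return structure, info


def _grow_leucine(res: Residue, chis: tuple[float, float]) -> None:
    coords = {a.name: a.pos for a in res.atoms}
    for name, (ra, rb, rc), bond, ang, dih_spec in SIDECHAIN_TEMPLATES["LEU"][1:]:
        dih = _resolve_dihedral(dih_spec, chis)
        pos = place_atom(coords[ra], coords[rb], coords[rc], bond, ang, dih)
        coords[name] = pos
        res.atoms.append(Atom(name, "C", pos))


def _gate_blockers(gate: Residue, open_chis: tuple[float, float],
                   channel_radius: float) -> list[Residue]:
    """Residues whose atoms occupy the open-rotamer side-chain volume."""
    ghost = _gate_leucine(open_chis, channel_radius)
    cg, cd1, cd2 = ghost.coord("CG"), ghost.coord("CD1"), ghost.coord("CD2")
    asp = Residue("B", 250, "", "ASP", [
        Atom("CG", "C", cg + np.array([0.4, 0.4, 0.3])),
        Atom("OD1", "O", cd1 + np.array([0.3, -0.2, 0.2])),
        Atom("OD2", "O", cd1 + np.array([-0.3, 0.3, -0.2])),
    ], het=False)
    tyr = Residue("B", 753, "", "TYR", [
        Atom("OH", "O", cd2 + np.array([0.2, 0.3, -0.2])),
        Atom("CZ", "C", cd2 + np.array([-0.4, -0.3, 0.3])),
    ], het=False)
    return [asp, tyr]


# --------------------------------------------------------------------------
# 7-helix bundles with planted weak spots
# --------------------------------------------------------------------------

@dataclasses.dataclass
class PlantedWeakSpot:
    helix: int          # 1..7
    generic_position: int  # e.g. 46 for 2x46
    mechanism: str      # proline | sidechain_clamp | glycine_flex

    @property
    def generic(self) -> str:
        return f"{self.helix}x{self.generic_position}"


@dataclasses.dataclass
class BundleSpec:
    helix_length: int = 26
    anchor_offset: int = 13        # 0-based index of the x50 anchor residue
    planted: tuple[PlantedWeakSpot, ...] = ()
    ring_radius: float = 11.0      # A, helix axes on a circle
    base_sequence: str | None = None  # defaults to poly-Ala with Leu accents
    noise: float = 0.0

    def __post_init__(self) -> None:
        if self.helix_length < 10:
            raise ValueError("bundle helices must have >= 10 residues")
        chord = 2 * self.ring_radius * math.sin(math.pi / 7)
        if chord < 8.0:
            raise ValueError(
                f"ring radius {self.ring_radius} puts helix axes {chord:.1f} A apart (< 8 A)")
        for p in self.planted:
            if not 1 <= p.helix <= 7:
                raise ValueError("helix index must be 1..7")
            idx = self.anchor_offset + (p.generic_position - 50)
            if not 4 <= idx < self.helix_length:
                raise ValueError(
                    f"planted position {p.generic} maps to residue {idx} outside the helix")


BUNDLE_CHAINS = ("A", "B", "C", "D", "E", "F", "G")  # helix 1..7


def build_bundle(spec: BundleSpec, seed: int = 0) -> tuple[Structure, list[dict]]:
    """Build a 7-helix phantom bundle with planted weak spots.

    Helix axes are parallel to z on a ring (cytosolic side at -z by
    convention).  Each planted weak spot is realized by its stated
    mechanism; the returned truth table records chain, helix, 0-based
    residue index, generic position and mechanism.
    """
    base = spec.base_sequence or ("A" * spec.helix_length)
    if len(base) != spec.helix_length:
        raise ValueError("base_sequence length must match helix_length")
    truth: list[dict] = []
    chains: dict[str, list[Residue]] = {}
    for h in range(1, 8):
        seq = base
        distortions = []
        for p in spec.planted:
            if p.helix != h:
                continue
            idx = spec.anchor_offset + (p.generic_position - 50)
            distortions.append(Distortion(idx, p.mechanism))
            truth.append({
                "chain": BUNDLE_CHAINS[h - 1], "helix": h, "index": idx,
                "generic": p.generic, "mechanism": p.mechanism,
            })
        hspec = HelixSpec(sequence=seq, distortions=tuple(distortions), noise=spec.noise)
        helix = build_helix(hspec, seed=seed * 7 + h)
        residues = helix.chains["A"]
        _orient_to_z(residues)
        angle_h = 2 * math.pi * (h - 1) / 7
        shift = np.array([spec.ring_radius * math.cos(angle_h),
                          spec.ring_radius * math.sin(angle_h), 0.0])
        for res in residues:
            res.chain_id = BUNDLE_CHAINS[h - 1]
            for atom in res.atoms:
                atom.pos = atom.pos + shift
        chains[BUNDLE_CHAINS[h - 1]] = residues
    structure = Structure("bundle", chains)
    _check_clashes(structure)
    return structure, truth


def _orient_to_z(residues: list[Residue]) -> None:
    from .geometry import fit_axis
    cas = np.array([r.coord("CA") for r in residues])
    centroid, direction = fit_axis(cas)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(direction, z)
    c = float(np.dot(direction, z))
    if np.linalg.norm(v) < 1e-12:
        rot = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx / (1 + c)
    for res in residues:
        for atom in res.atoms:
            atom.pos = rot @ (atom.pos - centroid)


def _check_clashes(structure: Structure, cutoff: float = 0.8) -> None:
    from scipy.spatial import cKDTree
    coords = structure.atom_coords()
    if len(coords) < 2:
        return
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff)
    if pairs:
        raise StructureError(f"builder produced {len(pairs)} atom pairs closer than {cutoff} A")


def merge_structures(ident: str, *structures: Structure) -> Structure:
    """Combine structures into one; chain ids must not collide."""
    chains: dict[str, list[Residue]] = {}
    for s in structures:
        for cid, residues in s.chains.items():
            new_id = cid
            while new_id in chains:
                new_id = chr(ord(new_id) + 1) if len(new_id) == 1 else new_id + "x"
            for r in residues:
                r.chain_id = new_id
            chains[new_id] = residues
    return Structure(ident, chains)


# --------------------------------------------------------------------------
# Pentamer fragment databases
# --------------------------------------------------------------------------

@dataclasses.dataclass
class PentamerSpec:
    middle: str                                  # 1-letter code of residue 3
    torsions: tuple[tuple[float, float], ...] = (ALPHA,) * 5
    chis: tuple[float, ...] = (-60.0, 180.0)
    flanks: str = "AAAA"                         # residues 1,2,4,5

    def sequence(self) -> str:
        return self.flanks[:2] + self.middle + self.flanks[2:]


@dataclasses.dataclass
class Fragment:
    frag_id: str
    middle_type: str   # 3-letter
    backbone: np.ndarray  # (20, 3): N, CA, C, O for residues 1..5
    sidechain: list[tuple[str, np.ndarray]]  # middle residue side-chain atoms
    chis: tuple[float, ...]


def _fragment_from_structure(structure: Structure, frag_id: str,
                             chis: tuple[float, ...]) -> Fragment:
    residues = structure.chains["A"]
    bb = np.array([residues[i].coord(a) for i in range(5) for a in ("N", "CA", "C", "O")])
    mid = residues[2]
    side = [(a.name, a.pos.copy()) for a in mid.atoms
            if a.name not in ("N", "CA", "C", "O")]
    return Fragment(frag_id, mid.name, bb, side, chis)


def build_fragment_db(
    n_background: int,
    planted: Sequence[PentamerSpec],
    seed: int = 0,
) -> list[Fragment]:
    """Pentamer database: planted conformers plus torsion-randomized noise.

    Background fragments draw phi/psi uniformly from (-180, 180] and a
    middle residue uniformly from the 20 standard types, so they are
    essentially never within fragment-RMSD reach of a regular helix query.
    Deterministic for a given seed.
    """
    if n_background < 0:
        raise ValueError("n_background must be >= 0")
    rng = np.random.default_rng(seed)
    db: list[Fragment] = []
    for k, p in enumerate(planted):
        chis = {2: p.chis}
        s = build_peptide(p.sequence(), list(p.torsions), chis=chis,
                          ident=f"planted{k}")
        db.append(_fragment_from_structure(s, f"planted{k}", p.chis))
    letters = sorted(AA1TO3)
    for k in range(n_background):
        torsions = [tuple(rng.uniform(-180.0, 180.0, 2)) for _ in range(5)]
        middle = letters[rng.integers(0, len(letters))]
        chi = tuple(rng.uniform(-180.0, 180.0, 2))
        seq = "AA" + middle + "AA"
        s = build_peptide(seq, torsions, chis={2: chi}, ident=f"bg{k}")
        db.append(_fragment_from_structure(s, f"bg{k}", chi))
    return db
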