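"""Grid-based cavity and escape-channel detection.

A regular grid (default 1 A spacing) is laid over the structure and every
voxel farther than a probe radius (default 1.4 A, a water probe) from the
protein is marked open.  Two marking modes exist:

* ``vdw`` (default): a voxel is open when its distance to the nearest atom
  *center* exceeds r_vdw(element) + probe — the standard solvent-probe
  convention (C 1.70, N 1.55, O 1.52, S 1.80 A).
* ``literal``: open when the distance to the nearest atom center exceeds
  the probe alone.  This reproduces the historical density-contouring
  recipe exactly, but ignores atomic size, so it can mark points inside
  van der Waals envelopes as open; it is kept for fidelity, not for
  open/closed decisions.

Open voxels are grouped into connected components (6-connectivity by
default, so a channel cannot leak diagonally through a one-voxel wall) and
classified as enclosed cavity, channel (boundary contact at >= 2 disjoint
loci) or open cleft.  The escape-channel test seeds just below a chosen
residue (by default the conserved Leu 2x46 sodium gate) and asks whether
that component reaches the cytosolic face of the grid with a bottleneck
wide enough for a sodium ion (Pauling radius 1.02 A).

The membrane convention is configuration: helix axes along z, cytosol at
-z.  Synthetic phantoms are built in this frame; experimental structures
must be oriented first (e.g. by superposition onto an oriented reference).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structures_io import Structure

__all__ = [
    "GridMap",
    "ChannelResult",
    "EscapeResult",
    "VDW_RADII",
    "mark_open_voxels",
    "label_components",
    "classify_component",
    "escape_channel_test",
    "write_dx",
]

VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}
DEFAULT_VDW = 1.70
SODIUM_RADIUS = 1.02


@dataclasses.dataclass
class GridMap:
    origin: np.ndarray           # (3,) corner voxel center
    spacing: float
    shape: tuple[int, int, int]
    open: np.ndarray             # bool, shape
    clearance: np.ndarray        # float, distance to nearest atom surface (A)
    labels: np.ndarray | None = None
    n_components: int = 0
    mode: str = "vdw"

    def voxel_center(self, idx: Sequence[int]) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(idx, dtype=float)

    def nearest_voxel(self, point: np.ndarray) -> tuple[int, int, int]:
        idx = np.round((np.asarray(point) - self.origin) / self.spacing).astype(int)
        idx = np.clip(idx, 0, np.array(self.shape) - 1)
        return tuple(idx)

    @property
    def voxel_volume(self) -> float:
        return self.spacing ** 3


@dataclasses.dataclass
class ChannelResult:
    component: int
    voxel_count: int
    volume: float                    # A^3
    boundary_loci: int               # disjoint boundary-contact patches
    touches_faces: tuple[str, ...]   # e.g. ("z-", "z+")
    min_pore_radius: float | None    # A, bottleneck between boundary loci
    verdict: str                     # enclosed_cavity | channel | open_cleft


@dataclasses.dataclass
class EscapeResult:
    verdict: str                     # "open" | "closed"
    reason: str
    seed_voxel: tuple[int, int, int] | None
    channel: ChannelResult | None
    min_pore_radius: float | None    # bottleneck from seed to cytosolic face


def _grid_axes(lo: np.ndarray, hi: np.ndarray, spacing: float):
    counts = np.floor((hi - lo) / spacing + 1e-9).astype(int) + 1
    return lo, counts


def mark_open_voxels(
    structure: Structure,
    spacing: float = 1.0,
    probe: float = 1.4,
    mode: str = "vdw",
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> GridMap:
    """Mark solvent-accessible voxels of a regular grid over the structure.

    ``bounds`` (lo, hi voxel-center corners) defaults to the atom extent
    padded by probe + 2 A on every side.  ``clearance`` stores, per voxel,
    the distance to the nearest atom surface (vdw mode) or atom center
    (literal mode); a voxel is open when clearance > probe.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    if mode not in ("literal", "vdw"):
        raise ValueError(f"unknown marking mode {mode!r}")
    coords = []
    radii = []
    for _, atom in structure.iter_atoms():
        coords.append(atom.pos)
        radii.append(VDW_RADII.get(atom.element, DEFAULT_VDW))
    if not coords:
        raise ValueError("structure has no atoms")
    coords = np.array(coords)
    radii = np.array(radii)
    if bounds is None:
        pad = probe + 2.0
        lo, hi = coords.min(axis=0) - pad, coords.max(axis=0) + pad
    else:
        lo, hi = np.asarray(bounds[0], dtype=float), np.asarray(bounds[1], dtype=float)
    origin, counts = _grid_axes(lo, hi, spacing)
    axes = [origin[k] + spacing * np.arange(counts[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    if mode == "literal":
        dist, _ = cKDTree(coords).query(centers, workers=-1)
        clearance = dist
    else:
        clearance = np.full(len(centers), np.inf)
        for r in np.unique(radii):
            subset = coords[radii == r]
            dist, _ = cKDTree(subset).query(centers, workers=-1)
            clearance = np.minimum(clearance, dist - r)
    clearance = clearance.reshape(tuple(counts))
    return GridMap(origin=origin, spacing=spacing, shape=tuple(counts),
                   open=clearance > probe, clearance=clearance, mode=mode)


def label_components(grid: GridMap, connectivity: int = 6) -> GridMap:
    """Label maximal connected open components (6- or 26-connectivity)."""
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    struct = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)
    labels, n = ndimage.label(grid.open, structure=struct)
    grid.labels = labels
    grid.n_components = int(n)
    return grid


def _boundary_mask(shape: tuple[int, int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        sl[ax] = 0
        mask[tuple(sl)] = True
        sl[ax] = shape[ax] - 1
        mask[tuple(sl)] = True
    return mask


def _touched_faces(voxels: np.ndarray, shape: tuple[int, int, int]) -> tuple[str, ...]:
    faces = []
    for ax, name in enumerate("xyz"):
        if np.any(voxels[:, ax] == 0):
            faces.append(f"{name}-")
        if np.any(voxels[:, ax] == shape[ax] - 1):
            faces.append(f"{name}+")
    return tuple(faces)


def _bottleneck_radius(grid: GridMap, comp_mask: np.ndarray,
                       is_source: np.ndarray, is_target: np.ndarray,
                       connectivity: int = 6) -> float | None:
    """Largest clearance threshold at which a source voxel still connects to
    a target voxel within the component (binary search over thresholds)."""
    struct = ndimage.generate_binary_structure(3, 1 if connectivity == 6 else 3)

    def connects(threshold: float) -> bool:
        keep = comp_mask & (grid.clearance >= threshold)
        if not (np.any(keep & is_source) and np.any(keep & is_target)):
            return False
        labels, _ = ndimage.label(keep, structure=struct)
        source_labels = np.unique(labels[keep & is_source])
        target_labels = np.unique(labels[keep & is_target])
        return bool(np.intersect1d(source_labels[source_labels > 0],
                                   target_labels[target_labels > 0]).size)

    values = np.unique(grid.clearance[comp_mask])
    if not connects(values[0]):
        return None
    lo_i, hi_i = 0, len(values) - 1
    while lo_i < hi_i:                    # invariant: connects(values[lo_i])
        mid = (lo_i + hi_i + 1) // 2
        if connects(values[mid]):
            lo_i = mid
        else:
            hi_i = mid - 1
    return float(values[lo_i])


def classify_component(grid: GridMap, component: int,
                       connectivity: int = 6) -> ChannelResult:
    """Classify one labeled component as cavity / channel / open cleft.

    A channel contacts the grid boundary at >= 2 disjoint loci (patches of
    boundary voxels, clustered with 26-connectivity); its minimum pore
    radius is the bottleneck clearance along the widest path between two
    different loci.
    """
    if grid.labels is None:
        raise ValueError("grid has no component labels; run label_components first")
    comp_mask = grid.labels == component
    count = int(comp_mask.sum())
    if count == 0:
        raise ValueError(f"no voxels with label {component}")
    boundary = _boundary_mask(grid.shape)
    contact = comp_mask & boundary
    voxels = np.argwhere(comp_mask)
    faces = _touched_faces(np.argwhere(contact), grid.shape) if contact.any() else ()
    if not contact.any():
        verdict, loci_count, pore = "enclosed_cavity", 0, None
    else:
        struct26 = ndimage.generate_binary_structure(3, 3)
        loci, loci_count = ndimage.label(contact, structure=struct26)
        if loci_count >= 2:
            verdict = "channel"
            # bottleneck between the two largest loci
            sizes = ndimage.sum_labels(np.ones_like(loci), loci, range(1, loci_count + 1))
            order = np.argsort(sizes)[::-1] + 1
            pore = _bottleneck_radius(grid, comp_mask,
                                      loci == order[0], loci == order[1],
                                      connectivity)
        else:
            verdict, pore = "open_cleft", None
    return ChannelResult(component=component, voxel_count=count,
                         volume=count * grid.voxel_volume,
                         boundary_loci=loci_count, touches_faces=faces,
                         min_pore_radius=pore, verdict=verdict)


def sidechain_centroid(residue) -> np.ndarray:
    side = [a.pos for a in residue.atoms if a.name not in ("N", "CA", "C", "O")]
    if side:
        return np.mean(side, axis=0)
    return residue.coord("CA")


def escape_channel_test(
    structure: Structure,
    numbering,
    start: str = "2x46",
    ion_radius: float = SODIUM_RADIUS,
    spacing: float = 1.0,
    probe: float = 1.4,
    mode: str = "vdw",
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    seed_offset: float = 2.0,
    grid: GridMap | None = None,
) -> EscapeResult:
    """Can an ion escape from just below ``start`` to the cytosol?

    Seeds at the open voxel nearest to a point ``seed_offset`` A below (-z)
    the side-chain centroid of the start residue, then asks whether the
    seeded component reaches the cytosolic grid face (z-) through a
    bottleneck of clearance >= ``ion_radius``.  ``numbering`` may be a
    GenericNumbering or any object with ``lookup(str) -> residue``.

    The default grid uses the membrane-slab convention: xy padded by
    probe + 2 A, z clipped to the atom extent, so the lumen of a
    transmembrane bundle touches the z faces without wrapping around the
    outside of the protein.
    """
    residue = numbering.lookup(start) if hasattr(numbering, "lookup") else numbering
    if residue is None:
        return EscapeResult("closed", f"residue {start} not present in numbering",
                            None, None, None)
    if grid is None:
        if bounds is None:
            coords = structure.atom_coords()
            pad_xy = probe + 2.0
            lo = coords.min(axis=0) - np.array([pad_xy, pad_xy, 0.0])
            hi = coords.max(axis=0) + np.array([pad_xy, pad_xy, 0.0])
            bounds = (lo, hi)
        grid = mark_open_voxels(structure, spacing=spacing, probe=probe,
                                mode=mode, bounds=bounds)
    if grid.labels is None:
        label_components(grid)
    seed_point = sidechain_centroid(residue) - np.array([0.0, 0.0, seed_offset])
    open_idx = np.argwhere(grid.open)
    if len(open_idx) == 0:
        return EscapeResult("closed", "no open voxels in grid", None, None, None)
    centers = grid.origin + grid.spacing * open_idx
    dists = np.linalg.norm(centers - seed_point, axis=1)
    nearest = int(np.argmin(dists))
    if dists[nearest] > 5.0:
        return EscapeResult("closed",
                            f"no open voxel within 5 A of seed point (nearest {dists[nearest]:.1f} A)",
                            None, None, None)
    seed_voxel = tuple(open_idx[nearest])
    component = int(grid.labels[seed_voxel])
    comp_mask = grid.labels == component
    result = classify_component(grid, component)
    cytosol = np.zeros(grid.shape, dtype=bool)
    cytosol[:, :, 0] = True
    is_seed = np.zeros(grid.shape, dtype=bool)
    is_seed[seed_voxel] = True
    pore = _bottleneck_radius(grid, comp_mask, is_seed, cytosol & comp_mask)
    if pore is None:
        return EscapeResult("closed", "seeded component does not reach the cytosolic face",
                            seed_voxel, result, None)
    verdict = "open" if pore >= ion_radius else "closed"
    reason = (f"bottleneck {pore:.2f} A vs ion radius {ion_radius:.2f} A")
    return EscapeResult(verdict, reason, seed_voxel, result, pore)


def write_dx(grid: GridMap, path, field: str = "open") -> None:
    """Export a grid field as OpenDX text, readable by PyMOL/Chimera."""
    data = {"open": grid.open.astype(float),
            "clearance": grid.clearance,
            "labels": None if grid.labels is None else grid.labels.astype(float)}[field]
    if data is None:
        raise ValueError("grid has no labels to export")
    nx, ny, nz = grid.shape
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.3f} {:.3f} {:.3f}\n".format(*grid.origin))
        fh.write(f"delta {grid.spacing:.3f} 0 0\ndelta 0 {grid.spacing:.3f} 0\n"
                 f"delta 0 0 {grid.spacing:.3f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {data.size} data follows\n")
        flat = data.ravel()
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.3f}" for v in flat[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n'
                 'object "density" class field\n')
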