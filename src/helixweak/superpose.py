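"""Least-squares rigid-body superposition (Kabsch) with robust trimming.

Used by the pentamer rotamer search to bring database fragments into the
query frame, and for inactive/active structure comparisons.  The rotation
is always proper (determinant +1): a mirror image is never returned, it
just scores a worse RMSD.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .geometry import kabsch
from .structures_io import Structure

__all__ = ["SuperpositionResult", "superpose", "apply_transform", "iterative_superpose"]


class GeometryError(Exception):
    pass


@dataclasses.dataclass
class SuperpositionResult:
    rotation: np.ndarray      # (3,3), orthonormal, det +1
    translation: np.ndarray   # (3,)
    rmsd: float               # A
    n_pairs: int
    mask: np.ndarray | None = None   # retained pairs (iterative variant)

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def _validate(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise GeometryError("coordinate sets must be equal-shape (n, 3)")
    if mob.shape[0] < 3:
        raise GeometryError("need at least 3 atom pairs")
    for pts in (mob, ref):
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise GeometryError("degenerate (collinear) configuration")
    return mob, ref


def superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """RMSD-optimal proper rigid transform taking mobile onto reference."""
    mob, ref = _validate(mobile, reference)
    rot, t, rmsd = kabsch(mob, ref)
    return SuperpositionResult(rotation=rot, translation=t, rmsd=rmsd, n_pairs=len(mob))


def apply_transform(structure: Structure, result: SuperpositionResult) -> Structure:
    """Transform every atom in place; returns the structure for chaining."""
    for _, atom in structure.iter_atoms():
        atom.pos = result.rotation @ atom.pos + result.translation
    return structure


def iterative_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    cutoff: float = 3.5,
    max_cycles: int = 10,
) -> SuperpositionResult:
    """Superpose, then iteratively drop pairs with residual > cutoff.

    Stops when the retained set is stable or after ``max_cycles``.  With an
    infinite cutoff this is identical to :func:`superpose` with a full
    mask.  Fewer than 3 surviving pairs is a convergence error.
    """
    mob, ref = _validate(mobile, reference)
    mask = np.ones(len(mob), dtype=bool)
    result = None
    for _ in range(max_cycles):
        if mask.sum() < 3:
            raise GeometryError("fewer than 3 pairs retained; cutoff too aggressive")
        rot, t, _ = kabsch(mob[mask], ref[mask])
        residuals = np.linalg.norm(mob @ rot.T + t - ref, axis=1)
        new_mask = residuals <= cutoff
        core = np.sqrt(np.mean(residuals[new_mask] ** 2)) if new_mask.sum() else np.inf
        result = SuperpositionResult(rotation=rot, translation=t, rmsd=float(core),
                                     n_pairs=int(new_mask.sum()), mask=new_mask)
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
    if result is None or result.n_pairs < 3:
        raise GeometryError("fewer than 3 pairs retained; cutoff too aggressive")
    return result
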