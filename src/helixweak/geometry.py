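"""Low-level vector geometry shared by the builders and analysis modules.

Internal-coordinate atom placement (NeRF-style), torsion measurement and
principal-axis fitting.  Everything here is plain numpy on (3,) / (n, 3)
float arrays in Angstrom.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral",
    "angle",
    "place_atom",
    "fit_axis",
    "axis_angle_deg",
    "kabsch",
]


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Bond angle a-b-c in degrees."""
    u, v = _unit(a - b), _unit(c - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed torsion angle a-b-c-d in degrees, IUPAC convention (-180, 180]."""
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, _unit(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    theta: float,
    phi: float,
) -> np.ndarray:
    """Place atom d so that |c-d| = bond, angle(b,c,d) = theta and
    dihedral(a,b,c,d) = phi (both in degrees)."""
    th = np.radians(theta)
    ph = np.radians(phi)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(th),
            bond * np.sin(th) * np.cos(ph),
            -bond * np.sin(th) * np.sin(ph),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def fit_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal axis of an (n,3) point set.

    Returns (centroid, unit direction); the direction is oriented so that it
    points from the first toward the last point.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points to fit an axis")
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    direction = vt[0]
    if np.dot(direction, pts[-1] - pts[0]) < 0:
        direction = -direction
    return centroid, direction


def axis_angle_deg(d1: np.ndarray, d2: np.ndarray) -> float:
    """Angle between two direction vectors in degrees, in [0, 180]."""
    return float(np.degrees(np.arccos(np.clip(np.dot(_unit(d1), _unit(d2)), -1.0, 1.0))))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation/translation mapping mobile onto reference.

    Returns (R, t, rmsd) with x' = R @ x + t.  Reflections are excluded by
    the usual determinant sign correction.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    h = (mob - mc).T @ (ref - rc)
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    t = rc - rot @ mc
    moved = mob @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rot, t, rmsd
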