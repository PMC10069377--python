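"""Numeric substrate of the lossy codec: dihedrals, rigid superposition,
and internal-coordinate atom placement.

Angles are degrees at every API boundary (the 1-byte torsion code maps
degrees through 127/180); radians appear only inside functions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, ValidationError

_EPS = 1e-12


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation``."""

    rotation: np.ndarray  # (3, 3), det +1
    translation: np.ndarray  # (3,)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 about the p2-p3 axis, in degrees,
    IUPAC sign convention, range (-180, 180].

    Raises ``DegenerateGeometryError`` for coincident consecutive points or
    collinear triples (the rotation axis frame is undefined there).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for v in (b1, b2, b3):
        if np.dot(v, v) < _EPS:
            raise DegenerateGeometryError("coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.dot(n1, n1) < _EPS or np.dot(n2, n2) < _EPS:
        raise DegenerateGeometryError("collinear points: dihedral undefined")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m, n2)
    ang = np.degrees(np.arctan2(y, x))
    # atan2 returns [-180, 180]; fold -180 into +180 for a half-open range
    if ang <= -180.0:
        ang = 180.0
    return float(ang)


def bond_angle(p1, p2, p3) -> float:
    """Angle p1-p2-p3 in degrees."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    v1 = p1 - p2
    v2 = p3 - p2
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom ``d`` from three reference points and internal coordinates
    (NeRF): ``|d - c| = bond``, ``angle(b, c, d) = angle`` and
    ``dihedral(a, b, c, d) = torsion`` (degrees).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    if bond <= 0:
        raise ValidationError("bond length must be positive")
    bc = c - b
    nbc = np.linalg.norm(bc)
    if nbc < _EPS:
        raise DegenerateGeometryError("coincident frame points b, c")
    bc /= nbc
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _EPS:
        raise DegenerateGeometryError("collinear frame points a, b, c")
    n /= nn
    m = np.cross(n, bc)
    ang = np.radians(angle)
    tor = np.radians(torsion)
    d_local = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(tor),
        -np.sin(ang) * np.sin(tor),
    ])
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def superpose_lsq(ref: np.ndarray, mov: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch) of ``mov`` onto ``ref``.

    Returns the transform minimising the RMSD of the moved points to the
    reference, and that minimal RMSD (Å).  SVD formulation with the
    determinant guard against reflections.  Requires n >= 3 paired points.
    """
    ref = np.asarray(ref, dtype=float)
    mov = np.asarray(mov, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValidationError("point sets must both be (n, 3)")
    if ref.shape[0] < 3:
        raise ValidationError("superposition requires at least 3 points")
    t, rmsd = _kabsch(ref, mov)
    return t, rmsd


def _kabsch(ref: np.ndarray, mov: np.ndarray) -> tuple[RigidTransform, float]:
    """Kabsch core without the n >= 3 guard (used by fragment fitting,
    where 1- and 2-point degenerate windows fall back on it)."""
    cr = ref.mean(axis=0)
    cm = mov.mean(axis=0)
    h = (mov - cm).T @ (ref - cr)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cr - rot @ cm
    moved = mov @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return RigidTransform(rot, trans), rmsd
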