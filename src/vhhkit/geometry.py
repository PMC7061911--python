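"""Low-level 3D geometry: torsion measurement and internal-coordinate placement.

All angles are degrees in (-180, 180]; coordinates are Ångström. These two
primitives are deliberately the only place vector algebra happens: the torsion
measurement is shared by the backbone, cysteine and disulfide analytics, and
NeRF placement is its exact inverse, which is what makes the synthetic
builders round-trip against the analytics.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral",
    "angle",
    "place_atom",
    "wrap_angle",
    "circular_mean_deg",
]


def wrap_angle(deg):
    """Wrap angle(s) in degrees into (-180, 180]."""
    a = np.asarray(deg, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    # map -180 -> 180 to keep the half-open convention
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    if np.isscalar(deg) or getattr(deg, "ndim", 1) == 0:
        return float(wrapped)
    return wrapped


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Planar angle a-b-c in degrees."""
    u = np.asarray(a, float) - np.asarray(b, float)
    v = np.asarray(c, float) - np.asarray(b, float)
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle of the p0-p1-p2-p3 chain, IUPAC sign convention, degrees.

    Positive when, looking from p1 towards p2, p3 is rotated clockwise
    relative to p0. Returns a value in (-180, 180].
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    # components perpendicular to the central bond
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond_length: float, bond_angle: float,
               torsion: float) -> np.ndarray:
    """Place atom d so that |cd| = bond_length, angle(b,c,d) = bond_angle and
    dihedral(a,b,c,d) = torsion (degrees). Standard NeRF construction."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(bond_angle)
    chi = np.radians(torsion)
    # local displacement in the frame of the last three atoms
    d_local = bond_length * np.array([
        -np.cos(theta),
        -np.sin(theta) * np.cos(chi),
        -np.sin(theta) * np.sin(chi),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def circular_mean_deg(angles, weights=None) -> float:
    """Circular mean of angles in degrees (vector averaging)."""
    a = np.radians(np.asarray(angles, dtype=float))
    if weights is None:
        s, c = np.sin(a).mean(), np.cos(a).mean()
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        s, c = np.sum(w * np.sin(a)), np.sum(w * np.cos(a))
    return wrap_angle(np.degrees(np.arctan2(s, c)))
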