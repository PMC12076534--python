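"""Low-level 3D geometry: internal-coordinate placement, angles, dihedrals, rotations.

The internal-coordinate convention used throughout the package is the classic
NeRF (natural extension reference frame) one: an atom D is placed relative to
three previously placed atoms ``(a, b, c)`` such that

* ``|D - a| = r``             (bond length, Å)
* ``angle(D, a, b) = theta``  (degrees)
* ``dihedral(D, a, b, c) = phi`` (degrees, IUPAC sign convention)
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "bond_length",
    "bond_angle",
    "dihedral",
    "place_atom",
    "rotation_about_axis",
    "rotation_aligning",
]


def bond_length(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(p) - np.asarray(q)))


def bond_angle(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> float:
    """Angle p-q-r in degrees."""
    u = np.asarray(p, float) - np.asarray(q, float)
    v = np.asarray(r, float) - np.asarray(q, float)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180].

    Positive when, looking down the p1->p2 axis, p3 is rotated clockwise
    from p0 (the IUPAC convention).
    """
    p0, p1, p2, p3 = (np.asarray(x, float) for x in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return float(ang if ang > -180.0 else 180.0)


def place_atom(a, b, c, r: float, theta: float, phi: float) -> np.ndarray:
    """Place atom D with |D-a| = r, angle(D,a,b) = theta, dihedral(D,a,b,c) = phi.

    theta and phi in degrees. a, b, c must not be collinear.
    """
    a, b, c = (np.asarray(x, float) for x in (a, b, c))
    th = np.radians(theta)
    ph = np.radians(phi)
    ab = a - b
    abn = ab / np.linalg.norm(ab)
    cb = b - c
    n = np.cross(cb, abn)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms in internal-coordinate placement")
    n /= nn
    m = np.cross(n, abn)
    # local frame at a: x along b->a, y in (c,b,a) plane, z = n
    d = np.array(
        [
            -r * np.cos(th),
            r * np.sin(th) * np.cos(ph),
            r * np.sin(th) * np.sin(ph),
        ]
    )
    return a + d[0] * abn + d[1] * m + d[2] * n


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis through the origin."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def rotation_aligning(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix carrying unit-normalized u onto unit-normalized v."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    axis = np.cross(u, v)
    s = np.linalg.norm(axis)
    c = float(np.dot(u, v))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any axis perpendicular to u
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        return rotation_about_axis(perp, np.pi)
    return rotation_about_axis(axis, float(np.arctan2(s, c)))
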