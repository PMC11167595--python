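"""Low-level 3D geometry: dihedrals, NeRF atom placement, rigid transforms."""

from __future__ import annotations

import numpy as np

__all__ = [
    "dihedral_angle",
    "bond_angle",
    "place_atom",
    "random_rotation_matrix",
    "rotation_about_axis",
    "wrap_angle",
]


def wrap_angle(deg: float | np.ndarray) -> float | np.ndarray:
    """Map an angle in degrees onto the interval (-180, 180]."""
    wrapped = -np.remainder(-np.asarray(deg, dtype=float) + 180.0, 360.0) + 180.0
    if np.ndim(deg) == 0:
        return float(wrapped)
    return wrapped


def bond_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle p0-p1-p2 in degrees."""
    a = p0 - p1
    b = p2 - p1
    cosang = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, IUPAC convention (cis = 0)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(
    ci: np.ndarray,
    cj: np.ndarray,
    ck: np.ndarray,
    bond: float,
    angle_deg: float,
    dihedral_deg: float,
) -> np.ndarray:
    """Place a new atom l at distance `bond` from k, angle j-k-l, dihedral i-j-k-l.

    Natural-extension-reference-frame construction; the returned point
    reproduces `dihedral_deg` under :func:`dihedral_angle`.
    """
    theta = np.radians(angle_deg)
    phi = np.radians(dihedral_deg)
    bc = ck - cj
    bc = bc / np.linalg.norm(bc)
    ab = cj - ci
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(phi),
            bond * np.sin(theta) * np.sin(phi),
        ]
    )
    return ck + d[0] * bc + d[1] * m + d[2] * n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about a (not necessarily unit) axis, Rodrigues form."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(t) * k + (1.0 - np.cos(t)) * (k @ k)


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via a random unit quaternion."""
    q = rng.normal(size=4)
    q = q / np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
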