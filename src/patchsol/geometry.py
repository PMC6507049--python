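"""Small rigid-body / internal-coordinate geometry helpers.

These are deliberately minimal: Kabsch superposition for mapping ideal
residue templates onto a backbone, axis rotations for rotamer generation,
and NeRF-style atom placement for building ideal helices.
"""

from __future__ import annotations

import numpy as np


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (R, t) minimising ||R @ mobile_i + t - target_i||.

    Both arrays are (n, 3) with matched rows.  The rotation is proper
    (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    return R, t


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation of `angle` radians about
    the (not necessarily unit) vector `axis`."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in radians, IUPAC sign convention."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.arctan2(y, x))


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle: float, dihedral_angle: float,
) -> np.ndarray:
    """NeRF placement: position a new atom D with |CD| = bond, angle(B,C,D) =
    `angle` and dihedral(A,B,C,D) = `dihedral_angle` (radians)."""
    a, b, c = (np.asarray(v, dtype=float) for v in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral_angle),
            bond * np.sin(angle) * np.sin(dihedral_angle),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def fit_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares line through a point cloud: returns (centroid, unit
    direction), direction oriented along increasing row index."""
    points = np.asarray(points, dtype=float)
    centroid = points.mean(axis=0)
    _, _, Vt = np.linalg.svd(points - centroid)
    direction = Vt[0]
    if (points[-1] - points[0]) @ direction < 0:
        direction = -direction
    return centroid, direction
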