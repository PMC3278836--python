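"""Small rigid-body geometry helpers shared across modules."""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalize a zero vector")
    return v / n


def fit_plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through ``points`` (n x 3)."""
    centered = points - points.mean(axis=0)
    # smallest singular vector of the centered cloud
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[-1]


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees (IUPAC convention)."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, unit(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return float(np.degrees(np.arctan2(y, x)))


def angle_deg(a, b, c) -> float:
    """Angle a-b-c at vertex b, degrees."""
    v1 = unit(np.asarray(a) - np.asarray(b))
    v2 = unit(np.asarray(c) - np.asarray(b))
    return float(np.degrees(np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0))))


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about ``axis`` by ``angle_rad`` (Rodrigues)."""
    k = unit(np.asarray(axis, dtype=float))
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
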