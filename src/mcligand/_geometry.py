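"""Small rigid-body geometry helpers shared across modules."""

from __future__ import annotations

import numpy as np


def coordinate_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two coordinate sets in the same frame (no superposition).

    Both arrays must be (N, 3) with identical atom ordering.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rotation_matrix(axis: str | np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about a Cartesian axis ('x','y','z') or a unit vector."""
    if isinstance(axis, str):
        axis = {"x": np.array([1.0, 0, 0]),
                "y": np.array([0, 1.0, 0]),
                "z": np.array([0, 0, 1.0])}[axis]
    u = np.asarray(axis, dtype=float)
    u = u / np.linalg.norm(u)
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    ux, uy, uz = u
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * K + (1 - c) * np.outer(u, u)


def rotate_about_centroid(coords: np.ndarray, R: np.ndarray,
                          center: np.ndarray | None = None) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if center is None:
        center = coords.mean(axis=0)
    return (coords - center) @ R.T + center


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of `mobile` onto `target`.

    Returns (R, t) such that mobile @ R.T + t approximates target.
    Proper rotation only (reflections excluded).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - pc @ R.T
    return R, t


def align(mobile_all: np.ndarray, mobile_sel: np.ndarray,
          target_sel: np.ndarray) -> np.ndarray:
    """Transform `mobile_all` by the superposition fitted on a selected subset."""
    R, t = kabsch(mobile_sel, target_sel)
    return np.asarray(mobile_all, dtype=float) @ R.T + t
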