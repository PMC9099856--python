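"""Small geometric primitives shared across modules.

All coordinates are Angstrom, angles degrees unless noted.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    dihedral: float,
) -> np.ndarray:
    """Natural extension reference frame (NeRF) placement.

    Returns the position of atom D bonded to ``c`` with bond length
    ``bond``, angle B-C-D = ``angle`` and dihedral A-B-C-D = ``dihedral``
    (degrees).
    """
    a, b, c = np.asarray(a, float), np.asarray(b, float), np.asarray(c, float)
    theta = np.deg2rad(angle)
    phi = np.deg2rad(dihedral)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        # collinear reference frame: pick an arbitrary perpendicular
        n = np.cross(bc, [1.0, 0.0, 0.0])
        if np.linalg.norm(n) < 1e-10:
            n = np.cross(bc, [0.0, 1.0, 0.0])
        nn = np.linalg.norm(n)
    n /= nn
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ d_local


def best_fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares plane through points.

    Returns (centroid, unit normal, max absolute out-of-plane deviation).
    """
    pts = np.asarray(points, float)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    dev = float(np.abs(centered @ normal).max()) if len(pts) else 0.0
    return centroid, normal, dev


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between two planes from their normals, folded into [0, 90] deg."""
    a = angle_between(n1, n2)
    return min(a, 180.0 - a)


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> Rotation:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis)


def rotation_aligning(u: np.ndarray, v: np.ndarray) -> Rotation:
    """Minimal rotation taking direction u onto direction v."""
    u = np.asarray(u, float) / np.linalg.norm(u)
    v = np.asarray(v, float) / np.linalg.norm(v)
    cross = np.cross(u, v)
    dot = float(np.dot(u, v))
    if np.linalg.norm(cross) < 1e-12:
        if dot > 0:
            return Rotation.identity()
        # antiparallel: rotate pi about any perpendicular
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        return Rotation.from_rotvec(np.pi * perp / np.linalg.norm(perp))
    axis = cross / np.linalg.norm(cross)
    return Rotation.from_rotvec(np.arccos(np.clip(dot, -1.0, 1.0)) * axis)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors on the sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """RMSD of q onto p after optimal rigid superposition (Kabsch)."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    rot, _ = Rotation.align_vectors(pc, qc)
    diff = pc - rot.apply(qc)
    return float(np.sqrt((diff**2).sum() / len(p)))
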