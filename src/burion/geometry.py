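"""Internal-coordinate geometry: placing atoms from bond/angle/dihedral (NeRF) and
measuring distances, angles and dihedrals on Cartesian coordinates."""

from __future__ import annotations

import numpy as np


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D bonded to ``c`` with |DC| = bond, angle(D,c,b) = angle and
    dihedral(D,c,b,a) = dihedral (natural extension reference frame)."""
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        # colinear reference: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(phi),
        bond * np.sin(theta) * np.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    """Angle p0-p1-p2 in degrees."""
    u = p0 - p1
    v = p2 - p1
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about a (non-zero) axis through the origin."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    C = 1.0 - c
    return np.array([
        [x * x * C + c, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, y * y * C + c, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, z * z * C + c],
    ])


def align_vectors(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit direction of v_from onto unit direction of v_to."""
    a = np.asarray(v_from, float) / np.linalg.norm(v_from)
    b = np.asarray(v_to, float) / np.linalg.norm(v_to)
    cross = np.cross(a, b)
    dot = float(np.dot(a, b))
    if np.linalg.norm(cross) < 1e-12:
        if dot > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        helper = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, helper)
        return rotation_about_axis(axis, np.pi)
    axis = cross / np.linalg.norm(cross)
    return rotation_about_axis(axis, float(np.arccos(np.clip(dot, -1, 1))))
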