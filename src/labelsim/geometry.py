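"""Small vector-geometry helpers: dihedrals, angle wrapping, forward
kinematics (NeRF-style atom placement) used by the label templates."""

from __future__ import annotations

import numpy as np


def wrap_deg(angle):
    """Wrap angle(s) in degrees into [-180, 180)."""
    return (np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0


def angular_rmsd(a, b) -> float:
    """Root-mean-square of wrapped per-component angular differences (deg)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = wrap_deg(a - b)
    return float(np.sqrt(np.mean(d * d)))


def dihedral_deg(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees (IUPAC convention)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def bond_angle_deg(p0, p1, p2) -> float:
    """Bond angle p0-p1-p2 in degrees."""
    p0, p1, p2 = (np.asarray(p, dtype=float) for p in (p0, p1, p2))
    v1 = p0 - p1
    v2 = p2 - p1
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle_deg: float, dihedral: float):
    """Place atom X bonded to c with |cX| = bond, angle(b,c,X) = angle_deg
    and dihedral(a,b,c,X) = dihedral (degrees).

    Standard natural-extension (NeRF) construction; raises if a, b, c are
    collinear.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-10:
        raise ValueError("collinear reference atoms for placement")
    n /= n_norm
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral)
    d = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(dih), -np.sin(ang) * np.sin(dih)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def ideal_cb_position(n, ca, c, bond: float = 1.53):
    """Construct a C-beta at ideal tetrahedral geometry from backbone N/CA/C.

    Used both to rebuild glycine C-beta on label attachment and for the
    canonical local frame of rotamer libraries.
    """
    # tetrahedral branch: dihedral C-N-CA-CB ~ +122.5 deg, angle N-CA-CB 110.5
    return place_atom(c, n, ca, bond, 110.5, 122.5)


def kabsch_transform(mobile, target):
    """Least-squares rigid transform (R, t) mapping `mobile` onto `target`.

    Returns (rotation 3x3, translation 3, rmsd). Uses the SVD (Kabsch)
    solution with proper-rotation correction.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = tc - rot @ mc
    moved = mobile @ rot.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return rot, t, rmsd
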