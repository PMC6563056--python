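"""Periodic-angle arithmetic and small-molecule geometry primitives.

All dihedral-valued quantities live in the canonical range [-180, 180).
Cartesian positions are in nm.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def wrap_angle(angle):
    """Map angle(s) in degrees to the canonical range [-180, 180)."""
    return (np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0


def angular_difference(a, b):
    """Signed nearest-image difference a - b in degrees, in [-180, 180)."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def measure_distance(p1, p2):
    return float(np.linalg.norm(np.asarray(p1) - np.asarray(p2)))


def measure_angle(p1, p2, p3):
    """Angle at p2 in degrees, in [0, 180]."""
    v1 = np.asarray(p1) - np.asarray(p2)
    v2 = np.asarray(p3) - np.asarray(p2)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def measure_dihedral(p1, p2, p3, p4):
    """IUPAC-signed dihedral p1-p2-p3-p4 in degrees, in [-180, 180).

    Invariant under reversal of the atom order.
    """
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b3 = np.asarray(p4) - np.asarray(p3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def place_atom(p1, p2, p3, bond_length, bond_angle, dihedral):
    """Place a fourth atom by internal coordinates (NeRF construction).

    Returns the position X such that |X-p3| == bond_length, the angle
    X-p3-p2 == bond_angle (deg) and the dihedral X-p3-p2-p1 == dihedral (deg).
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    theta = np.radians(bond_angle)
    chi = np.radians(dihedral)
    d = bond_length * np.array(
        [
            -np.cos(theta),
            np.sin(theta) * np.cos(chi),
            -np.sin(theta) * np.sin(chi),
        ]
    )
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    ab = p2 - p1
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return p3 + frame @ d


def kabsch_rotation(mobile, reference):
    """Optimal rotation matrix superposing centred ``mobile`` onto centred ``reference``.

    Both inputs are (n, 3) arrays; centring is the caller's responsibility.
    """
    rot, _ = Rotation.align_vectors(reference, mobile)
    return rot.as_matrix()


def superposed_rmsd(coords_i, coords_j, fit_idx, calc_idx):
    """RMSD over ``calc_idx`` atoms after least-squares fit on ``fit_idx`` atoms.

    Frame j is superposed onto frame i using the fit selection; the RMSD is
    then evaluated over the (possibly different) calc selection.
    """
    fi = coords_i[fit_idx]
    fj = coords_j[fit_idx]
    ci_com = fi.mean(axis=0)
    cj_com = fj.mean(axis=0)
    rot = kabsch_rotation(fj - cj_com, fi - ci_com)
    moved = (coords_j - cj_com) @ rot.T + ci_com
    diff = moved[calc_idx] - coords_i[calc_idx]
    return float(np.sqrt((diff**2).sum() / len(calc_idx)))
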