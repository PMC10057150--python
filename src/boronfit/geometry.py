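"""Internal-coordinate measurement on Cartesian coordinates (Å, degrees).

Torsions follow the IUPAC sign convention: the cis (eclipsed) arrangement is
0°, trans is 180°, and the angle is positive when, looking down the j→k bond,
the far bond k→l is rotated clockwise from the near bond j→i. Values are
reported in (−180°, 180°].
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError

_EPS = 1e-12


def wrap_angle(deg):
    """Wrap an angle (or array) in degrees to (−180, 180]."""
    wrapped = -np.remainder(-np.asarray(deg, dtype=float) + 180.0, 360.0) + 180.0
    return wrapped if wrapped.ndim else float(wrapped)


def measure_bond(coords: np.ndarray, i: int, j: int) -> float:
    if i == j:
        raise DegenerateGeometryError(f"bond indices must differ: {i}, {j}")
    return float(np.linalg.norm(coords[j] - coords[i]))


def measure_angle(coords: np.ndarray, i: int, j: int, k: int) -> float:
    """Interior angle i-j-k in degrees, in [0, 180]."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS or nv < _EPS:
        raise DegenerateGeometryError(f"zero-length vector at angle {i}-{j}-{k}")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def measure_torsion(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Torsion angle i-j-k-l in degrees, in (−180, 180].

    Satisfies the reversal symmetry tau(i,j,k,l) == tau(l,k,j,i).
    """
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    nb2 = np.linalg.norm(b2)
    if nb2 < _EPS:
        raise DegenerateGeometryError(f"zero-length axis bond {j}-{k}")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _EPS or np.linalg.norm(n2) < _EPS:
        raise DegenerateGeometryError(
            f"collinear atoms make torsion {i}-{j}-{k}-{l} undefined"
        )
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    phi = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if phi <= -180.0 else phi


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about ``axis`` (need not be normalized)."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < _EPS:
        raise DegenerateGeometryError("rotation axis has zero length")
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(np.radians(angle_deg) * axis / norm).as_matrix()


def nerf_place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    r: float, theta_deg: float, phi_deg: float,
) -> np.ndarray:
    """Place a new atom D at bond length ``r`` from C, angle ``theta`` B-C-D
    and torsion ``phi`` A-B-C-D (natural-extension reference frame).

    The inverse of torsion measurement: ``measure_torsion`` over A,B,C,D
    returns ``phi_deg`` for the placed point.
    """
    theta = np.radians(theta_deg)
    phi = np.radians(phi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _EPS:
        raise DegenerateGeometryError("collinear reference frame in placement")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -r * np.cos(theta),
            r * np.sin(theta) * np.cos(phi),
            r * np.sin(theta) * np.sin(phi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
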