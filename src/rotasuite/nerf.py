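"""Internal-coordinate to Cartesian construction (NeRF placement).

Natural extension reference frame: each new atom D is placed from three
previously placed atoms A, B, C given the bond length C-D, the bond angle
B-C-D and the torsion A-B-C-D.  Used to build idealized dinucleotide
templates and test chains; never to fit experimental data.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["place_atom", "rotation_about_axis"]


def place_atom(a, b, c, bond_length: float, bond_angle: float, torsion: float) -> np.ndarray:
    """Place atom D given A, B, C (3-vectors), degrees for angles."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = math.radians(bond_angle)
    phi = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:
        raise ValueError("collinear reference atoms in NeRF placement")
    n /= norm
    m = np.cross(n, bc)
    # sign of the out-of-plane term chosen so that the torsion measured by
    # geometry.dihedral on (A, B, C, D) equals the requested value
    d_local = np.array(
        [
            -bond_length * math.cos(theta),
            bond_length * math.sin(theta) * math.cos(phi),
            bond_length * math.sin(theta) * math.sin(phi),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about a unit-normalized axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    x, y, z = axis
    k = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return c * np.eye(3) + s * k + (1.0 - c) * np.outer(axis, axis)
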