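"""Small rigid-body and internal-coordinate geometry helpers.

Coordinates are numpy float arrays in Å.  Rotations are 3×3 matrices acting
on column order (points @ R.T + t).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rotation_about_axis",
    "random_rotation",
    "place_atom",
    "build_backbone",
    "frame_from_points",
    "transform_between_frames",
    "apply_transform",
    "rmsd",
]


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis`` (radians)."""
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


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation (axis uniform on the sphere, angle uniform)."""
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return rotation_about_axis(v, rng.uniform(-np.pi, np.pi))


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle: float, dihedral: float,
) -> np.ndarray:
    """Place atom D given atoms A-B-C, the C-D bond length, the B-C-D bond
    angle and the A-B-C-D dihedral (NeRF construction; angles in radians)."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


# idealized backbone geometry (Å, degrees)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANG_C_N_CA = np.deg2rad(121.7)
_ANG_N_CA_C = np.deg2rad(111.2)
_ANG_CA_C_N = np.deg2rad(116.2)
_OMEGA = np.pi  # trans peptide


def build_backbone(
    anchor: np.ndarray, phi_psi: np.ndarray
) -> np.ndarray:
    """Grow an idealized polypeptide backbone from an anchor residue.

    ``anchor`` is a (3, 3) array with the N, CA, C coordinates of the residue
    preceding the flexible stretch; ``phi_psi`` is (n_res, 2) with one
    (φ, ψ) pair per grown residue, in radians.  Returns (n_res, 3, 3) with
    N, CA, C per grown residue.  ω is fixed trans.
    """
    phi_psi = np.asarray(phi_psi, dtype=float)
    n_prev, ca_prev, c_prev = anchor
    # ψ of the anchor residue is not sampled: the first new N is placed with a
    # fixed dihedral, which only sets the overall frame of the chain.
    psi_prev = np.pi
    out = np.empty((len(phi_psi), 3, 3))
    for i, (phi, psi) in enumerate(phi_psi):
        n = place_atom(n_prev, ca_prev, c_prev, _BOND_C_N, _ANG_CA_C_N, psi_prev)
        ca = place_atom(ca_prev, c_prev, n, _BOND_N_CA, _ANG_C_N_CA, _OMEGA)
        c = place_atom(c_prev, n, ca, _BOND_CA_C, _ANG_N_CA_C, phi)
        out[i, 0], out[i, 1], out[i, 2] = n, ca, c
        n_prev, ca_prev, c_prev = n, ca, c
        psi_prev = psi
    return out


def frame_from_points(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray):
    """Orthonormal frame (R, origin) from three non-collinear points.

    Origin at p1; x-axis along p1→p2; z normal to the plane.  Columns of R
    are the axes, so local coordinates are (x - origin) @ R.
    """
    ex = p2 - p1
    ex = ex / np.linalg.norm(ex)
    v = p0 - p1
    ez = np.cross(ex, v)
    ez = ez / np.linalg.norm(ez)
    ey = np.cross(ez, ex)
    return np.column_stack([ex, ey, ez]), np.asarray(p1, dtype=float)


def transform_between_frames(frame_a, frame_b) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (R, t) mapping points from frame_a's pose to frame_b's.

    For a point x expressed in the world while the body sits at frame_a,
    ``x @ R.T + t`` is its position once the body sits at frame_b.
    """
    Ra, oa = frame_a
    Rb, ob = frame_b
    R = Rb @ Ra.T
    t = ob - oa @ R.T
    return R, t


def apply_transform(points: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(points) @ R.T + t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two equally-indexed coordinate sets without fitting."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
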