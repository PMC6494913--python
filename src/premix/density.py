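"""Reweighted atomic probability density maps.

Each heavy atom of ensemble member k deposits its member's (renormalized)
population weight into a 3-D grid through an isotropic Gaussian kernel;
contributions from multiple independent ensembles are averaged.  The map
visualizes where the mobile binding partner resides relative to the fixed
partner, and is exported in CCP4/MRC and OpenDX text formats for rendering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GridSpec",
    "DensityMap",
    "compute_map",
    "contour_report",
    "write_dx",
    "write_ccp4",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular grid: origin (Å), isotropic voxel size (Å), dims (nx, ny, nz)."""

    origin: tuple[float, float, float]
    voxel_size: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        if any(d < 1 for d in self.dims):
            raise ValueError("grid dims must be >= 1")

    @classmethod
    def around(cls, coords: np.ndarray, voxel_size: float = 2.0, padding: float = 8.0):
        """Grid covering ``coords`` with a margin (default 4σ for σ = voxel)."""
        coords = np.asarray(coords, dtype=float)
        lo = coords.min(axis=0) - padding
        hi = coords.max(axis=0) + padding
        dims = tuple(int(np.ceil((hi[i] - lo[i]) / voxel_size)) + 1 for i in range(3))
        return cls(tuple(lo), voxel_size, dims)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = np.asarray(self.origin)
        return tuple(
            o[i] + self.voxel_size * np.arange(self.dims[i]) for i in range(3)
        )


@dataclass
class DensityMap:
    """Atomic probability density on a regular grid.

    ``normalization`` is ``"unit_max"`` (max voxel = 1; the convention used
    for the ρ-level contour) or ``"unit_integral"`` (Σ ρ·voxel³ = 1) or
    ``"raw"``.
    """

    grid: GridSpec
    values: np.ndarray
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.dims):
            raise ValueError("values shape does not match grid dims")
        if np.any(self.values < 0):
            raise ValueError("density values must be nonnegative")

    def normalized(self, mode: str) -> "DensityMap":
        if mode == "unit_max":
            m = self.values.max()
            vals = self.values / m if m > 0 else self.values
        elif mode == "unit_integral":
            integral = self.values.sum() * self.grid.voxel_size**3
            vals = self.values / integral if integral > 0 else self.values
        elif mode == "raw":
            vals = self.values.copy()
        else:
            raise ValueError(f"unknown normalization {mode!r}")
        return DensityMap(self.grid, vals, mode)

    @property
    def integral(self) -> float:
        return float(self.values.sum() * self.grid.voxel_size**3)


def _deposit(
    grid: GridSpec,
    coords: np.ndarray,
    weights: np.ndarray,
    sigma: float,
    cutoff_sigmas: float | None,
) -> np.ndarray:
    """Sum of normalized Gaussian kernels on the grid.

    With ``cutoff_sigmas=None`` every atom contributes to every voxel (exact,
    used for small maps and oracle checks); otherwise kernels are truncated
    at ``cutoff_sigmas``·σ for speed.
    """
    ax, ay, az = grid.axes()
    out = np.zeros(grid.dims)
    norm = (2.0 * np.pi * sigma**2) ** -1.5
    inv2s2 = 1.0 / (2.0 * sigma**2)
    if cutoff_sigmas is None:
        gx = np.exp(-inv2s2 * (ax[None, :] - coords[:, 0:1]) ** 2)
        gy = np.exp(-inv2s2 * (ay[None, :] - coords[:, 1:2]) ** 2)
        gz = np.exp(-inv2s2 * (az[None, :] - coords[:, 2:3]) ** 2)
        # separable kernel: accumulate per atom
        for a in range(len(coords)):
            out += weights[a] * np.einsum("i,j,k->ijk", gx[a], gy[a], gz[a])
        return norm * out
    r = cutoff_sigmas * sigma
    for a in range(len(coords)):
        c = coords[a]
        sl = []
        for axis, axvals in zip(range(3), (ax, ay, az)):
            i0 = int(np.searchsorted(axvals, c[axis] - r, side="left"))
            i1 = int(np.searchsorted(axvals, c[axis] + r, side="right"))
            if i0 >= i1:
                sl = None
                break
            sl.append((i0, i1))
        if sl is None:
            continue
        (x0, x1), (y0, y1), (z0, z1) = sl
        gx = np.exp(-inv2s2 * (ax[x0:x1] - c[0]) ** 2)
        gy = np.exp(-inv2s2 * (ay[y0:y1] - c[1]) ** 2)
        gz = np.exp(-inv2s2 * (az[z0:z1] - c[2]) ** 2)
        out[x0:x1, y0:y1, z0:z1] += weights[a] * (
            gx[:, None, None] * gy[None, :, None] * gz[None, None, :]
        )
    return norm * out


def compute_map(
    ensembles: list[tuple[np.ndarray, list[np.ndarray]]],
    grid: GridSpec,
    sigma: float | None = None,
    normalization: str = "unit_max",
    kernel_cutoff_sigmas: float | None = None,
) -> DensityMap:
    """Reweighted atomic probability density over one or more ensembles.

    ``ensembles`` is a list of ``(weights, member_coords)`` pairs: per
    ensemble, ``weights`` has one entry per member and ``member_coords`` one
    (n_atoms, 3) heavy-atom array per member.  Weights are renormalized
    within each ensemble, each atom deposits its member's weight via a
    Gaussian kernel of width σ (default: the voxel size), and the per-ensemble
    maps are averaged.
    """
    if not ensembles:
        raise ValueError("no ensembles given")
    sigma = sigma if sigma is not None else grid.voxel_size
    total = np.zeros(grid.dims)
    for weights, member_coords in ensembles:
        weights = np.asarray(weights, dtype=float)
        if len(weights) != len(member_coords):
            raise ValueError("one weight per ensemble member required")
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        wsum = weights.sum()
        wn = weights / wsum if wsum > 0 else weights
        coords, atom_w = [], []
        for w, xyz in zip(wn, member_coords):
            xyz = np.asarray(xyz, dtype=float)
            if xyz.size == 0:
                raise ValueError("empty atom selection for an ensemble member")
            coords.append(xyz)
            atom_w.append(np.full(len(xyz), w))
        total += _deposit(
            grid,
            np.concatenate(coords),
            np.concatenate(atom_w),
            sigma,
            kernel_cutoff_sigmas,
        )
    total /= len(ensembles)
    return DensityMap(grid, total, "raw").normalized(normalization)


def contour_report(dmap: DensityMap, level: float = 0.05) -> dict:
    """Occupied volume at a contour level of a unit-max normalized map."""
    if dmap.normalization != "unit_max":
        raise ValueError("contour_report expects a unit_max normalized map")
    if not (0 < level <= 1):
        raise ValueError("contour level must lie in (0, 1]")
    mask = dmap.values >= level
    n = int(mask.sum())
    report = {
        "level": level,
        "voxels": n,
        "volume_A3": n * dmap.grid.voxel_size**3,
    }
    if n:
        idx = np.argwhere(mask)
        o = np.asarray(dmap.grid.origin)
        v = dmap.grid.voxel_size
        report["bbox_min"] = (o + idx.min(axis=0) * v).tolist()
        report["bbox_max"] = (o + idx.max(axis=0) * v).tolist()
    return report


def write_dx(dmap: DensityMap, path) -> None:
    """Write the map in OpenDX scalar-field text format."""
    nx, ny, nz = dmap.grid.dims
    o = dmap.grid.origin
    v = dmap.grid.voxel_size
    with open(path, "w") as fh:
        fh.write(f"# premix density map, normalization={dmap.normalization}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {o[0]:.4f} {o[1]:.4f} {o[2]:.4f}\n")
        fh.write(f"delta {v:.4f} 0 0\ndelta 0 {v:.4f} 0\ndelta 0 0 {v:.4f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
        )
        flat = dmap.values.ravel(order="C")
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{x:.6e}" for x in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


def write_ccp4(dmap: DensityMap, path) -> None:
    """Write the map in CCP4/MRC format (via gemmi)."""
    import gemmi

    nx, ny, nz = dmap.grid.dims
    v = dmap.grid.voxel_size
    grid = gemmi.FloatGrid(nx, ny, nz)
    grid.set_unit_cell(gemmi.UnitCell(nx * v, ny * v, nz * v, 90, 90, 90))
    arr = np.array(grid, copy=False)
    arr[...] = dmap.values.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    # record the real-space origin so viewers overlay the fixed frame correctly
    m.set_header_float(50, float(dmap.grid.origin[0]))
    m.set_header_float(51, float(dmap.grid.origin[1]))
    m.set_header_float(52, float(dmap.grid.origin[2]))
    m.write_ccp4_map(str(path))
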