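"""Density maps: simulation from structures, MRC I/O, cross-correlation,
Gaussian blurring, and the map-derived biasing potential with forces.

A map is a regular 3-D grid ``data[ix, iy, iz]`` with an origin (Å position
of the centre of voxel (0,0,0)) and per-axis voxel sizes. Simulated maps
place an isotropic Gaussian of integrated weight equal to the atomic mass on
every non-hydrogen atom; the kernel width follows the common convention that
the full width at half maximum equals the nominal resolution,
sigma = R / (2 sqrt(2 ln 2)). Alternative conventions ("sigma=R/2",
"sigma=0.356R") are accepted wherever a resolution is taken.

The biasing potential rescales the target map so that the highest-density
voxel sits at zero energy and the lowest at ``gscale`` kcal/mol; each
selected atom feels this potential scaled by its mass, with forces from the
analytic gradient of the trilinear interpolant.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
from scipy import ndimage

__all__ = [
    "DensityMap", "PotentialGrid",
    "sigma_from_resolution", "simulate_map", "read_map", "write_map",
    "cross_correlation", "cc_structure", "blur_map",
    "potential_grid", "em_forces",
]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def sigma_from_resolution(resolution: float, convention: str = "fwhm") -> float:
    """Gaussian sigma in Å for a nominal resolution."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if convention == "fwhm":
        return resolution / _FWHM
    if convention == "sigma=R/2":
        return resolution / 2.0
    if convention == "sigma=0.356R":
        return 0.356 * resolution
    raise ValueError(f"unknown sigma convention {convention!r}")


@dataclass
class DensityMap:
    """Regular 3-D scalar grid. ``data[ix, iy, iz]``, x fastest-varying axis
    first; ``origin`` is the Å position of the centre of voxel (0,0,0)."""

    data: np.ndarray
    voxel: np.ndarray
    origin: np.ndarray
    resolution: float | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("map grid must be 3-D with all dimensions >= 1")
        self.voxel = np.broadcast_to(np.asarray(self.voxel, dtype=float), (3,)).copy()
        if not np.all(self.voxel > 0):
            raise ValueError("voxel sizes must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("grid values must be finite")

    @property
    def shape(self):
        return self.data.shape

    def congruent(self, other: "DensityMap") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.voxel, other.voxel, atol=1e-6)
                and np.allclose(self.origin, other.origin, atol=1e-6))

    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel))

    def copy(self) -> "DensityMap":
        return DensityMap(self.data.copy(), self.voxel.copy(),
                          self.origin.copy(), self.resolution)


def simulate_map(s, resolution: float, voxel=1.0, padding: float = 8.0,
                 like: DensityMap | None = None,
                 convention: str = "fwhm") -> DensityMap:
    """Simulate a density map from a structure at a nominal resolution.

    Every non-hydrogen atom contributes an isotropic Gaussian centred on its
    position, integrating to the atomic mass. With ``like`` given, the map
    is generated directly on that map's grid geometry (no resampling step);
    otherwise the grid covers the structure bounding box plus ``padding`` Å.
    """
    sigma = sigma_from_resolution(resolution, convention)
    voxel = np.broadcast_to(np.asarray(voxel, dtype=float), (3,)).copy()
    if like is not None:
        voxel = like.voxel
        origin = like.origin
        shape = like.shape
    else:
        if np.any(voxel > resolution / 2.0):
            raise ValueError(
                f"voxel {voxel} undersamples resolution {resolution} "
                "(need voxel <= resolution/2)")
        if padding < 0:
            raise ValueError("padding must be non-negative")
        lo = s.coords.min(axis=0) - padding
        hi = s.coords.max(axis=0) + padding
        origin = lo
        shape = tuple(int(np.ceil((hi[a] - lo[a]) / voxel[a])) + 1
                      for a in range(3))

    data = np.zeros(shape, dtype=np.float64)
    heavy = np.flatnonzero(s.elements != "H")
    amp = 1.0 / ((2.0 * np.pi) ** 1.5 * sigma ** 3)
    cut = 4.0 * sigma
    axes_pts = [origin[a] + voxel[a] * np.arange(shape[a]) for a in range(3)]
    for i in heavy:
        r = s.coords[i]
        m = s.masses[i]
        sub, gauss = [], []
        skip = False
        for a in range(3):
            j0 = max(0, int(np.ceil((r[a] - cut - origin[a]) / voxel[a])))
            j1 = min(shape[a] - 1, int(np.floor((r[a] + cut - origin[a]) / voxel[a])))
            if j1 < j0:
                skip = True
                break
            d = axes_pts[a][j0:j1 + 1] - r[a]
            sub.append(slice(j0, j1 + 1))
            gauss.append(np.exp(-d * d / (2.0 * sigma * sigma)))
        if skip:
            continue
        data[tuple(sub)] += (m * amp) * (
            gauss[0][:, None, None] * gauss[1][None, :, None] * gauss[2][None, None, :])
    return DensityMap(data, voxel, origin, resolution=resolution)


def write_map(m: DensityMap, path) -> None:
    """Write as MRC2014/CCP4 mode-2 (float32); origin in the ORIGIN fields."""
    ccp4 = gemmi.Ccp4Map()
    nx, ny, nz = m.shape
    ccp4.grid = gemmi.FloatGrid(nx, ny, nz)
    arr = np.array(ccp4.grid, copy=False)
    arr[...] = m.data.astype(np.float32)
    ccp4.grid.unit_cell = gemmi.UnitCell(
        nx * m.voxel[0], ny * m.voxel[1], nz * m.voxel[2], 90, 90, 90)
    ccp4.grid.spacegroup = gemmi.find_spacegroup_by_name("P1")
    ccp4.update_ccp4_header()
    for k, v in zip((50, 51, 52), m.origin):
        ccp4.set_header_float(k, float(v))
    ccp4.write_ccp4_map(str(path))


def read_map(path) -> DensityMap:
    """Read an MRC2014/CCP4 map; axes are normalised to x,y,z order.

    The origin is taken from the ORIGIN header fields, falling back to
    NXSTART/NYSTART/NZSTART times the voxel size when ORIGIN is all zero.
    """
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise IOError(f"cannot read map {path}: {exc}") from exc
    origin = np.array([ccp4.header_float(k) for k in (50, 51, 52)])
    starts = np.array([ccp4.header_i32(k) for k in (5, 6, 7)], dtype=float)
    ccp4.setup(float("nan"))  # reorders MAPC/MAPR/MAPS to x,y,z
    grid = ccp4.grid
    data = np.array(grid, copy=True).astype(np.float64)
    cell = grid.unit_cell
    voxel = np.array([cell.a / grid.nu, cell.b / grid.nv, cell.c / grid.nw])
    if np.allclose(origin, 0.0) and not np.allclose(starts, 0.0):
        origin = starts * voxel
    if not np.all(np.isfinite(data)):
        raise IOError(f"{path}: map contains non-finite or missing values")
    return DensityMap(data, voxel, origin)


def _resample_onto(target: DensityMap, source: DensityMap) -> np.ndarray:
    """Trilinearly sample ``source`` at the voxel centres of ``target``."""
    idx = np.indices(target.shape, dtype=float)
    pos = [target.origin[a] + target.voxel[a] * idx[a] for a in range(3)]
    u = [(pos[a] - source.origin[a]) / source.voxel[a] for a in range(3)]
    return ndimage.map_coordinates(source.data, np.stack(u), order=1,
                                   mode="constant", cval=0.0)


def cross_correlation(a: DensityMap, b: DensityMap, threshold: float = 0.0,
                      mean_subtract: bool = False) -> float:
    """Cross-correlation coefficient of two maps over voxels where
    ``a >= threshold`` (default 0, i.e. all voxels of a non-negative map).

    The default is the overlap form sum(ab)/sqrt(sum(a^2) sum(b^2));
    ``mean_subtract=True`` gives the Pearson form instead.
    """
    bv = b.data if a.congruent(b) else _resample_onto(a, b)
    mask = a.data >= threshold
    av, bv = a.data[mask], bv[mask]
    if mean_subtract:
        av = av - av.mean()
        bv = bv - bv.mean()
    denom = np.sqrt(np.sum(av * av) * np.sum(bv * bv))
    if denom == 0:
        raise ValueError("cross-correlation undefined: zero-norm map")
    return float(np.sum(av * bv) / denom)


def cc_structure(s, tm: DensityMap, resolution: float,
                 threshold: float = 0.0, convention: str = "fwhm") -> float:
    """Cross-correlation between the synthetic map of a structure (built on
    the target map's grid) and the target map — the fitting objective.

    A structure entirely outside the map support contributes no density on
    the grid; its correlation is 0 by continuity.
    """
    synth = simulate_map(s, resolution, like=tm, convention=convention)
    if not np.any(synth.data):
        return 0.0
    return cross_correlation(tm, synth, threshold=threshold)


def blur_map(m: DensityMap, from_res: float, to_res: float,
             convention: str = "fwhm") -> DensityMap:
    """Blur a map from one nominal resolution to a coarser one.

    Uses the Gaussian semigroup property: convolving with
    sigma_extra^2 = sigma(to)^2 - sigma(from)^2 turns an R_from-resolution
    map into an R_to-resolution map.
    """
    if to_res <= from_res:
        raise ValueError("to_res must exceed from_res")
    s0 = sigma_from_resolution(from_res, convention)
    s1 = sigma_from_resolution(to_res, convention)
    extra = np.sqrt(s1 * s1 - s0 * s0)
    # Fourier-domain Gaussian: transfer functions multiply, so blurring in
    # one step or several identical-total-width steps agree to round-off.
    ft = np.fft.rfftn(m.data)
    ft = ndimage.fourier_gaussian(ft, sigma=extra / m.voxel,
                                  n=m.data.shape[-1])
    data = np.fft.irfftn(ft, s=m.data.shape, axes=(0, 1, 2))
    return DensityMap(data, m.voxel.copy(), m.origin.copy(), resolution=to_res)


@dataclass
class PotentialGrid:
    """Map-derived biasing potential: 0 kcal/mol at the densest voxel,
    ``gscale`` at/below the floor density. Atom weights are masses."""

    potential: np.ndarray
    voxel: np.ndarray
    origin: np.ndarray
    gscale: float

    def __post_init__(self):
        self.potential = np.asarray(self.potential, dtype=np.float64)
        self.voxel = np.broadcast_to(np.asarray(self.voxel, dtype=float), (3,)).copy()
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)


def potential_grid(tm: DensityMap, gscale: float = 0.3,
                   floor: float = 0.0) -> PotentialGrid:
    """Turn a target map into the biasing potential
    V = gscale * (1 - (rho - floor)/(rho_max - floor)), clamped to
    [0, gscale]; voxels below the floor sit at the ceiling gscale."""
    rho_max = float(tm.data.max())
    if rho_max <= floor:
        raise ValueError("map maximum must exceed the floor density")
    v = gscale * (1.0 - (tm.data - floor) / (rho_max - floor))
    v = np.clip(v, 0.0, gscale)
    return PotentialGrid(v, tm.voxel.copy(), tm.origin.copy(), gscale)


def _trilinear(pg: PotentialGrid, pts: np.ndarray):
    """Value and gradient (per Å) of the potential at Cartesian points.

    Points outside the grid are clamped to the boundary for interpolation;
    the caller adds the boundary restraint on top.
    """
    V = pg.potential
    n = np.array(V.shape)
    u = (pts - pg.origin) / pg.voxel
    uc = np.clip(u, 0.0, n - 1.0)
    i0 = np.floor(uc).astype(int)
    i0 = np.minimum(i0, n - 2)
    i0 = np.maximum(i0, 0)
    f = uc - i0
    ix, iy, iz = i0[:, 0], i0[:, 1], i0[:, 2]
    fx, fy, fz = f[:, 0], f[:, 1], f[:, 2]

    c = np.empty((8,) + (pts.shape[0],))
    for b, (dx, dy, dz) in enumerate(
            [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
             (0, 0, 1), (1, 0, 1), (0, 1, 1), (1, 1, 1)]):
        c[b] = V[ix + dx, iy + dy, iz + dz]
    wx0, wy0, wz0 = 1 - fx, 1 - fy, 1 - fz
    val = (c[0] * wx0 * wy0 * wz0 + c[1] * fx * wy0 * wz0
           + c[2] * wx0 * fy * wz0 + c[3] * fx * fy * wz0
           + c[4] * wx0 * wy0 * fz + c[5] * fx * wy0 * fz
           + c[6] * wx0 * fy * fz + c[7] * fx * fy * fz)
    dx_ = ((c[1] - c[0]) * wy0 * wz0 + (c[3] - c[2]) * fy * wz0
           + (c[5] - c[4]) * wy0 * fz + (c[7] - c[6]) * fy * fz) / pg.voxel[0]
    dy_ = ((c[2] - c[0]) * wx0 * wz0 + (c[3] - c[1]) * fx * wz0
           + (c[6] - c[4]) * wx0 * fz + (c[7] - c[5]) * fx * fz) / pg.voxel[1]
    dz_ = ((c[4] - c[0]) * wx0 * wy0 + (c[5] - c[1]) * fx * wy0
           + (c[6] - c[2]) * wx0 * fy + (c[7] - c[3]) * fx * fy) / pg.voxel[2]
    grad = np.stack([dx_, dy_, dz_], axis=1)
    # Å displacement from the clamped (in-grid) point, zero inside
    out = (u - uc) * pg.voxel
    return val, grad, out


def em_forces_coords(pg: PotentialGrid, coords: np.ndarray,
                     masses: np.ndarray, sel: np.ndarray):
    """Coordinate-level core of :func:`em_forces` (no Structure needed)."""
    forces = np.zeros_like(coords)
    if sel.size == 0:
        return forces, 0.0
    m = masses[sel]
    val, grad, out = _trilinear(pg, coords[sel])
    energy = float(np.sum(m * val))
    f = -m[:, None] * grad
    # boundary restraint for out-of-grid atoms
    energy += float(np.sum(0.5 * pg.gscale * m * np.sum(out * out, axis=1)))
    f -= (pg.gscale * m)[:, None] * out
    forces[sel] = f
    return forces, energy


def em_forces(pg: PotentialGrid, s, sel=None):
    """Biasing energy and forces on the selected atoms (default: heavy atoms).

    energy = sum_i m_i V(r_i); force_i = -m_i grad V by the analytic
    gradient of the trilinear interpolant. Atoms outside the grid feel a
    harmonic restraint toward the nearest grid face (stiffness
    gscale * mass per Å^2) added to the boundary value, which keeps forces
    continuous across the boundary.
    """
    if sel is None:
        sel = np.flatnonzero(s.elements != "H")
    sel = np.asarray(sel, dtype=int)
    return em_forces_coords(pg, s.coords, s.masses, sel)
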