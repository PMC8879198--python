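"""Density maps: MRC/CCP4 I/O, simulated density, CCC, segmentation.

Simulated density follows the Gaussian-kernel convention used by
cross-correlation-based fitting engines: each heavy atom n contributes

    g_n(r) = exp( -(3 / (2 sigma^2)) |r - r_n|^2 ),

and the value of voxel (i,j,k) is the exact volume integral of the summed
kernels over the voxel, evaluated as a product of three 1-D error-function
differences.  ``sigma`` is taken to be the stated map resolution in
Angstrom, verbatim -- no FWHM or half-resolution conversion is applied
(conventions differ between packages; this one is deliberate and the
whole-kernel integral (2 pi sigma^2 / 3)^(3/2) per atom depends on it).

Grid convention: ``origin`` is the world coordinate of the CENTER of voxel
(0,0,0); voxel (i,j,k) spans origin + (i - 1/2 .. i + 1/2) * spacing per
axis; array axis order is (x, y, z).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.spatial import cKDTree
from scipy.special import erf

from emfit.errors import ConfigError, DegenerateInputError, FormatError, GridError
from emfit.structures import AtomicModel

__all__ = [
    "DensityMap", "DensitySimParams", "read_map", "write_map",
    "simulate_density", "ccc", "segment_map_zone", "crop_map",
]


@dataclass
class DensityMap:
    """3-D intensity grid with world-space origin and per-axis spacing."""

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if self.values.ndim != 3:
            raise GridError("map values must be a 3-D array")
        if np.any(self.spacing <= 0):
            raise GridError("voxel spacing must be positive on every axis")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def axis_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.dims[axis]) * self.spacing[axis]

    def voxel_centers(self) -> np.ndarray:
        """(n_voxels, 3) array of voxel-center world coordinates."""
        xs, ys, zs = (self.axis_centers(i) for i in range(3))
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def same_geometry(self, other: "DensityMap", tol: float = 1e-6) -> bool:
        return (self.dims == other.dims
                and np.allclose(self.origin, other.origin, atol=tol)
                and np.allclose(self.spacing, other.spacing, atol=tol))

    def copy(self) -> "DensityMap":
        return DensityMap(self.values.copy(), self.origin.copy(),
                          self.spacing.copy(), dict(self.metadata))


@dataclass
class DensitySimParams:
    """Parameters of the simulated-density kernel.

    sigma: map resolution in Angstrom (kernel width; see module docstring).
    truncation_radius: kernel cutoff in units of sigma (>= 3).
    margin: Angstrom of padding around the model bounding box when the grid
        is auto-generated; default (None) uses truncation_radius * sigma.
    voxel_size: spacing of auto-generated grids; default sigma / 3.
    """

    sigma: float
    truncation_radius: float = 4.0
    margin: float | None = None
    voxel_size: float | None = None

    def __post_init__(self):
        if self.sigma <= 0:
            raise ConfigError("sigma must be positive")
        if self.truncation_radius < 3:
            raise ConfigError("truncation_radius must be >= 3 sigma")

    @property
    def effective_margin(self) -> float:
        return self.truncation_radius * self.sigma if self.margin is None \
            else self.margin

    @property
    def effective_voxel(self) -> float:
        return self.sigma / 3.0 if self.voxel_size is None else self.voxel_size


def read_map(path) -> DensityMap:
    """Read an MRC/CCP4 2014 map; axes reordered to (x, y, z).

    The world origin comes from the MRC2014 ORIGIN header if set, otherwise
    from the NC/NR/NS start indices times the spacing.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, SystemError, FileNotFoundError, ValueError) as exc:
        raise FormatError(f"cannot read map {path}: {exc}") from exc
    cell = m.grid.unit_cell
    if not (math.isclose(cell.alpha, 90, abs_tol=1e-3)
            and math.isclose(cell.beta, 90, abs_tol=1e-3)
            and math.isclose(cell.gamma, 90, abs_tol=1e-3)):
        raise FormatError("non-orthogonal unit cell is unsupported")
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    values = np.array(m.grid, copy=True).astype(float)
    mx, my, mz = (m.header_i32(8), m.header_i32(9), m.header_i32(10))
    spacing = np.array([cell.a / mx, cell.b / my, cell.c / mz])
    origin = np.array([m.header_float(50), m.header_float(51),
                       m.header_float(52)], dtype=float)
    if np.all(origin == 0.0):
        start = np.array([m.header_i32(5), m.header_i32(6), m.header_i32(7)],
                         dtype=float)
        origin = start * spacing
    return DensityMap(values, origin, spacing, {"source": str(path)})


def write_map(dmap: DensityMap, path) -> None:
    """Write a map as MRC/CCP4 2014 (float32, canonical axis order)."""
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(
        np.ascontiguousarray(dmap.values, dtype=np.float32))
    nx, ny, nz = dmap.dims
    sx, sy, sz = dmap.spacing
    m.grid.unit_cell = gemmi.UnitCell(nx * sx, ny * sy, nz * sz, 90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for word, v in zip((50, 51, 52), dmap.origin):
        m.set_header_float(word, float(v))
    m.write_ccp4_map(str(path))


def _auto_grid(model: AtomicModel, params: DensitySimParams) -> DensityMap:
    coords = model.coords
    pad = params.effective_margin
    vox = params.effective_voxel
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    dims = np.maximum(np.ceil((hi - lo) / vox).astype(int) + 1, 1)
    return DensityMap(np.zeros(dims), lo, np.full(3, vox))


def _atom_axis_factors(xn, origin, spacing, n, a, radius):
    """Per-axis voxel integrals and face Gaussians for one atom.

    Returns (start index, I, dI) where I[m] is the 1-D integral of
    exp(-a (x - xn)^2) over voxel start+m and dI[m] its derivative with
    respect to xn (difference of the kernel at the voxel faces).
    """
    i0 = max(int(math.floor((xn - radius - origin) / spacing + 0.5)), 0)
    i1 = min(int(math.ceil((xn + radius - origin) / spacing - 0.5)), n - 1)
    if i1 < i0:
        return i0, np.zeros(0), np.zeros(0)
    centers = origin + np.arange(i0, i1 + 1) * spacing
    lo = centers - 0.5 * spacing - xn
    hi = centers + 0.5 * spacing - xn
    sa = math.sqrt(a)
    c = 0.5 * math.sqrt(math.pi / a)
    I = c * (erf(sa * hi) - erf(sa * lo))
    dI = np.exp(-a * lo**2) - np.exp(-a * hi**2)
    return i0, I, dI


def simulate_density(
    model: AtomicModel,
    grid: DensityMap | str = "auto",
    params: DensitySimParams | None = None,
) -> DensityMap:
    """Simulate a density map from an atomic model (exact voxel integrals).

    ``grid`` is either an existing :class:`DensityMap` whose geometry is
    reused (its values are ignored) or ``"auto"`` to build a grid covering
    the model with ``params.margin`` padding.  Kernel contributions are
    truncated beyond ``truncation_radius * sigma`` of each atom.
    """
    if params is None:
        raise ConfigError("DensitySimParams required")
    if isinstance(grid, str):
        if grid != "auto":
            raise ConfigError(f"unknown grid spec {grid!r}")
        out = _auto_grid(model, params)
    else:
        out = DensityMap(np.zeros(grid.dims), grid.origin.copy(),
                         grid.spacing.copy())
    a = 3.0 / (2.0 * params.sigma**2)
    radius = params.truncation_radius * params.sigma
    vals = out.values
    for pos in model.coords:
        fac = [_atom_axis_factors(pos[ax], out.origin[ax], out.spacing[ax],
                                  out.dims[ax], a, radius)
               for ax in range(3)]
        (i0, Ix, _), (j0, Iy, _), (k0, Iz, _) = fac
        if Ix.size and Iy.size and Iz.size:
            vals[i0:i0 + Ix.size, j0:j0 + Iy.size, k0:k0 + Iz.size] += (
                Ix[:, None, None] * Iy[None, :, None] * Iz[None, None, :])
    out.metadata.update(sigma=params.sigma, n_atoms=len(model))
    return out


def ccc(map_a: DensityMap, map_b: DensityMap) -> float:
    """Non-centered cross-correlation coefficient of two maps.

    CCC = sum(a b) / sqrt(sum(a^2) sum(b^2)) over all voxels; scale
    invariant and bounded by 1 in magnitude.
    """
    if not map_a.same_geometry(map_b):
        raise GridError("maps must share grid geometry for CCC")
    a = map_a.values.ravel()
    b = map_b.values.ravel()
    na = float(np.dot(a, a))
    nb = float(np.dot(b, b))
    if na == 0.0 or nb == 0.0:
        raise DegenerateInputError("CCC undefined for an all-zero map")
    return float(np.dot(a, b) / math.sqrt(na * nb))


def _anchor_points(anchor) -> np.ndarray:
    if isinstance(anchor, AtomicModel):
        return anchor.coords
    pts = np.asarray(anchor, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(1, 3)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("anchor must be an AtomicModel or (n, 3) points")
    return pts


def zone_mask(dmap: DensityMap, anchor, radius: float) -> np.ndarray:
    """Boolean voxel mask: centers within ``radius`` of any anchor point."""
    if radius <= 0:
        raise ConfigError("zone radius must be positive")
    pts = _anchor_points(anchor)
    tree = cKDTree(pts)
    d, _ = tree.query(dmap.voxel_centers(), k=1)
    return (d <= radius).reshape(dmap.dims)


def segment_map_zone(dmap: DensityMap, anchor, radius: float) -> DensityMap:
    """Zero the map outside spheres of ``radius`` around the anchor points.

    The grid is unchanged; ``metadata["zone_voxels"]`` records how many
    voxels were retained.  Raises when the zone misses the map entirely.
    """
    mask = zone_mask(dmap, anchor, radius)
    kept = int(mask.sum())
    if kept == 0:
        raise GridError("segmentation zone contains no voxels")
    out = dmap.copy()
    out.values[~mask] = 0.0
    out.metadata["zone_voxels"] = kept
    return out


def crop_map(dmap: DensityMap, box) -> DensityMap:
    """Crop to an index box ((i0,i1), (j0,j1), (k0,k1)), ends exclusive."""
    box = [(int(b0), int(b1)) for b0, b1 in box]
    for (b0, b1), n in zip(box, dmap.dims):
        if not (0 <= b0 < b1 <= n):
            raise GridError(f"crop box {box} outside grid dims {dmap.dims}")
    (i0, i1), (j0, j1), (k0, k1) = box
    start = np.array([i0, j0, k0], dtype=float)
    return DensityMap(dmap.values[i0:i1, j0:j1, k0:k1].copy(),
                      dmap.origin + start * dmap.spacing,
                      dmap.spacing.copy(), dict(dmap.metadata))
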