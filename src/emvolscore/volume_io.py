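"""Density-map containers, MRC/CCP4 I/O and grid manipulation.

A :class:`DensityMap` is a 3D scalar grid with a physical geometry:
voxel ``(ix, iy, iz)`` (x fastest) has its center at
``origin + (ix*sx, iy*sy, iz*sz)``.  Internally the data array is stored
in ``(z, y, x)`` index order regardless of the axis permutation recorded
in a map file header, so all scoring code sees a single convention.

File I/O goes through gemmi, which understands the MRC2014/CCP4 dialect
(modes 0/1/2, ``mapc/mapr/maps`` axis permutations, ``nstart`` offsets
and the ``ORIGIN`` header words).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy import ndimage

__all__ = [
    "DensityMap",
    "RigidTransform",
    "MapFormatError",
    "read_map",
    "write_map",
    "lowpass_filter",
    "resample",
    "apply_transform",
    "common_grid",
    "make_grid",
]

#: real-space Gaussian sigma (in units of the resolution) whose Fourier
#: transform falls to half amplitude at spatial frequency 1/resolution
SIGMA_PER_RESOLUTION = float(np.sqrt(np.log(2) / 2.0) / np.pi)


class MapFormatError(ValueError):
    """Raised when a map file cannot be interpreted as MRC2014/CCP4."""


@dataclass
class DensityMap:
    """3D scalar density grid.

    Parameters
    ----------
    data:
        Array of shape ``(nz, ny, nx)`` holding finite density values.
    spacing:
        Voxel edge lengths ``(sx, sy, sz)`` in Angstrom, all positive.
    origin:
        Physical position of voxel ``(0, 0, 0)`` in Angstrom.
    resolution:
        Nominal map resolution in Angstrom (metadata; may be ``None``).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    resolution: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("density data must be a 3D array with all dims >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("density values must be finite")
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=float), (3,)
        ).copy()
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive on every axis")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when given")

    # -- geometry helpers -------------------------------------------------

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        nz, ny, nx = self.data.shape
        return (nx, ny, nz)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Bounding box of voxel centers: (lower corner, upper corner) in Å."""
        n = np.array(self.shape_xyz, dtype=float)
        return self.origin.copy(), self.origin + (n - 1) * self.spacing

    def voxel_centers(self) -> np.ndarray:
        """Physical (x, y, z) coordinates of every voxel, shape (nz, ny, nx, 3)."""
        nz, ny, nx = self.data.shape
        iz, iy, ix = np.meshgrid(
            np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
        )
        idx = np.stack([ix, iy, iz], axis=-1).astype(float)
        return self.origin + idx * self.spacing

    def index_coords(self, points: np.ndarray) -> np.ndarray:
        """Fractional (z, y, x) array indices of physical xyz ``points``."""
        pts = np.asarray(points, dtype=float)
        frac = (pts - self.origin) / self.spacing
        return frac[..., ::-1]

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at physical xyz points; 0 outside the grid."""
        coords = self.index_coords(points)
        return ndimage.map_coordinates(
            self.data.astype(float),
            coords.reshape(-1, 3).T,
            order=1,
            mode="constant",
            cval=0.0,
        ).reshape(np.asarray(points).shape[:-1])

    def copy_with(self, data: np.ndarray) -> "DensityMap":
        return DensityMap(
            data=data,
            spacing=self.spacing,
            origin=self.origin,
            resolution=self.resolution,
        )


@dataclass
class RigidTransform:
    """Proper rigid motion ``p -> R p + t`` acting on physical coordinates (Å)."""

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    _ORTHO_TOL = 1e-6

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        rtr = self.rotation.T @ self.rotation
        if not np.allclose(rtr, np.eye(3), atol=self._ORTHO_TOL):
            raise ValueError("rotation is not orthogonal within tolerance")
        if abs(np.linalg.det(self.rotation) - 1.0) > self._ORTHO_TOL:
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(rinv, -rinv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    # -- JSON serialization ----------------------------------------------

    def to_dict(self) -> dict:
        return {
            "rotation": [float(v) for v in self.rotation.ravel()],
            "translation": [float(v) for v in self.translation],
            "units": "angstrom",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        rot = np.asarray(d["rotation"], dtype=float).reshape(3, 3)
        return cls(rot, np.asarray(d["translation"], dtype=float))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# file I/O


def read_map(path: str | Path, resolution: float | None = None) -> DensityMap:
    """Read an MRC2014/CCP4 density map.

    The file's axis order (``mapc/mapr/maps``) is normalized to the internal
    ``(z, y, x)`` storage convention.  The physical origin is taken from the
    ORIGIN header words; when those are all zero it falls back to
    ``nstart * spacing`` as is conventional for CCP4-style maps.

    ``resolution`` attaches nominal-resolution metadata (Å); the MRC header
    itself carries none.
    """
    path = Path(path)
    if not path.is_file():
        raise MapFormatError(f"no such map file: {path}")
    try:
        m = gemmi.read_ccp4_map(str(path))
        m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"cannot parse {path} as an MRC/CCP4 map: {exc}") from exc
    grid = m.grid
    data_xyz = np.array(grid, copy=True)
    if not np.all(np.isfinite(data_xyz)):
        raise MapFormatError(f"{path} contains non-finite density values")
    cell = grid.unit_cell
    # sampling counts along the crystal axes (header words 8-10, reordered)
    mxyz = np.array([m.header_i32(i) for i in (8, 9, 10)], dtype=float)
    if np.any(mxyz <= 0):
        mxyz = np.array(data_xyz.shape, dtype=float)
    spacing = np.array([cell.a, cell.b, cell.c]) / mxyz
    origin = np.array([m.header_float(i) for i in (50, 51, 52)], dtype=float)
    if np.all(origin == 0.0):
        nstart = np.array([m.header_i32(i) for i in (5, 6, 7)], dtype=float)
        origin = nstart * spacing
    return DensityMap(
        data=data_xyz.transpose(2, 1, 0),
        spacing=spacing,
        origin=origin,
        resolution=resolution,
    )


def write_map(dmap: DensityMap, path: str | Path) -> None:
    """Write ``dmap`` as an MRC2014 mode-2 (float32) file.

    Cell dimensions are ``dims * spacing``; the physical origin goes into
    the ORIGIN header words, so ``read_map`` round-trips bit-exactly.
    """
    path = Path(path)
    if str(path) == "" or path.is_dir():
        raise ValueError(f"invalid output path: {path!r}")
    nx, ny, nz = dmap.shape_xyz
    grid = gemmi.FloatGrid(nx, ny, nz)
    arr = np.array(grid, copy=False)
    arr[:] = dmap.data.transpose(2, 1, 0).astype(np.float32)
    sx, sy, sz = dmap.spacing
    grid.set_unit_cell(gemmi.UnitCell(nx * sx, ny * sy, nz * sz, 90, 90, 90))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), dmap.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# grid manipulation


def lowpass_filter(dmap: DensityMap, target_resolution: float) -> DensityMap:
    """Fourier-space Gaussian low-pass *to* a nominal resolution.

    The total Gaussian blur of the output reaches half amplitude at spatial
    frequency ``1/target_resolution``.  Because Gaussian variances add, a map
    already carrying resolution metadata is blurred only by the increment
    between its current and the target resolution; a map without resolution
    metadata receives the full kernel.  This makes filtering idempotent —
    filtering twice to the same resolution equals filtering once — and
    preserves the mean density (zero frequency is untouched).  Only blurring
    is allowed: the target must not be finer than the current resolution.
    """
    if target_resolution <= 0:
        raise ValueError("target resolution must be positive")
    current = dmap.resolution
    if current is not None and target_resolution < current - 1e-9:
        raise ValueError(
            "low-pass target is finer than the map resolution (no sharpening)"
        )
    # incremental squared width: sigma^2 scales with resolution^2
    res2_inc = target_resolution**2 - (current**2 if current is not None else 0.0)
    nz, ny, nx = dmap.data.shape
    sx, sy, sz = dmap.spacing
    fz = np.fft.fftfreq(nz, d=sz)[:, None, None]
    fy = np.fft.fftfreq(ny, d=sy)[None, :, None]
    fx = np.fft.rfftfreq(nx, d=sx)[None, None, :]
    f2 = fx**2 + fy**2 + fz**2
    h = np.exp(-np.log(2.0) * res2_inc * f2)  # 0.5 at |f|^2 = 1/res2_inc
    out = np.fft.irfftn(
        np.fft.rfftn(dmap.data.astype(float)) * h,
        s=(nz, ny, nx),
        axes=(0, 1, 2),
    )
    out_map = dmap.copy_with(out)
    out_map.resolution = target_resolution
    return out_map


def make_grid(
    shape_xyz: tuple[int, int, int],
    spacing,
    origin=(0.0, 0.0, 0.0),
    resolution: float | None = None,
) -> DensityMap:
    """Empty (all-zero) map defining a sampling grid."""
    nx, ny, nz = shape_xyz
    return DensityMap(
        data=np.zeros((nz, ny, nx), dtype=np.float32),
        spacing=spacing,
        origin=origin,
        resolution=resolution,
    )


def resample(dmap: DensityMap, target_spacing) -> DensityMap:
    """Trilinear resampling onto a grid with the given spacing.

    The new grid keeps the origin and covers the same physical extent
    (bounding box of voxel centers).
    """
    new_spacing = np.broadcast_to(np.asarray(target_spacing, dtype=float), (3,))
    if np.any(new_spacing <= 0):
        raise ValueError("target spacing must be positive")
    if np.allclose(new_spacing, dmap.spacing):
        return dmap.copy_with(dmap.data.copy())
    n_old = np.array(dmap.shape_xyz, dtype=float)
    span = (n_old - 1) * dmap.spacing
    n_new = np.floor(span / new_spacing + 1e-9).astype(int) + 1
    target = make_grid(tuple(n_new), new_spacing, dmap.origin, dmap.resolution)
    return apply_transform(dmap, RigidTransform.identity(), target)


def apply_transform(
    dmap: DensityMap, t: RigidTransform, target_grid: DensityMap
) -> DensityMap:
    """Sample ``t(dmap)`` on the target grid.

    Target voxel centers are pulled back through ``t⁻¹`` and the source map
    is interpolated trilinearly there; points falling outside the source
    extent read as 0 (background).
    """
    tinv = t.inverse()
    centers = target_grid.voxel_centers()
    src_pts = tinv.apply(centers.reshape(-1, 3))
    vals = dmap.interpolate(src_pts).reshape(target_grid.data.shape)
    out = target_grid.copy_with(vals)
    out.resolution = dmap.resolution
    return out


def common_grid(
    map1: DensityMap,
    map2: DensityMap,
    t: RigidTransform,
    spacing: float | None = None,
) -> tuple[DensityMap, DensityMap]:
    """Resample both maps onto one grid so voxels compare one-to-one.

    ``t`` maps ``map2`` physical coordinates into the ``map1`` frame.  The
    grid covers the union of the two physical extents (the second transformed
    by ``t``) at ``spacing`` Å; when not given, spacing defaults to a quarter
    of the coarser of the two nominal resolutions, the sampling rate the
    scoring pipeline uses after low-pass filtering to that resolution.
    """
    if spacing is None:
        if map1.resolution is None or map2.resolution is None:
            raise ValueError(
                "common_grid needs an explicit spacing when resolutions are unset"
            )
        spacing = max(map1.resolution, map2.resolution) / 4.0
    lo1, hi1 = map1.extent
    lo2, hi2 = map2.extent
    corners2 = np.array(
        [[x, y, z] for x in (lo2[0], hi2[0]) for y in (lo2[1], hi2[1]) for z in (lo2[2], hi2[2])]
    )
    moved = t.apply(corners2)
    lo = np.minimum(lo1, moved.min(axis=0))
    hi = np.maximum(hi1, moved.max(axis=0))
    n = np.floor((hi - lo) / spacing + 1e-9).astype(int) + 1
    res = None
    if map1.resolution is not None and map2.resolution is not None:
        res = max(map1.resolution, map2.resolution)
    grid = make_grid(tuple(n), spacing, lo, res)
    out1 = apply_transform(map1, RigidTransform.identity(), grid)
    out2 = apply_transform(map2, t, grid)
    out1.resolution = map1.resolution
    out2.resolution = map2.resolution
    return out1, out2
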