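"""Surface extraction and surface-comparison scores.

Three surface definitions select voxels of a contoured map:

* **T** — voxels whose density lies within ±10% of σ around the contour
  threshold (a thin density band straddling the iso-surface);
* **A** — in-contour voxels with at least one background voxel among their
  26 neighbours (face, edge and corner contacts);
* **M** — in-contour voxels whose *exposure* — the mean of the binary mask
  over three orthogonal 1D windows centred on the voxel — falls below a
  cutoff, picking the most solvent-exposed points.

On the extracted point sets: the Chamfer distance (mean nearest-neighbour
distance), its GDT-style weighted cumulative-fraction variant, and the
normal-vector score comparing density-gradient directions of the two maps
at the target's surface points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .contouring import ContourSpec
from .volume_io import DensityMap

__all__ = [
    "SurfaceExtractionError",
    "SurfacePointSet",
    "ExposureField",
    "surface_T",
    "surface_A",
    "exposure_filter",
    "surface_M",
    "extract_surface",
    "chamfer_distance",
    "cd_gdt",
    "gradient_normals",
    "normal_vector_score",
]


class SurfaceExtractionError(ValueError):
    """No surface points could be extracted under the given definition."""


@dataclass
class SurfacePointSet:
    """Surface voxels of a map as physical points.

    ``points`` are xyz coordinates in Å (voxel centers of the source map);
    ``voxel_indices`` are the corresponding ``(z, y, x)`` array indices;
    ``normals`` optionally holds one unit vector per point.
    """

    points: np.ndarray
    definition: str
    voxel_indices: np.ndarray | None = None
    normals: np.ndarray | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.voxel_indices is not None:
            self.voxel_indices = np.asarray(self.voxel_indices, dtype=np.int64)
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("normals must be unit vectors")

    def __len__(self) -> int:
        return self.points.shape[0]

    # -- export for visual inspection ------------------------------------

    def to_csv(self, path: str | Path) -> None:
        cols = self.points
        header = "x,y,z"
        if self.normals is not None:
            cols = np.hstack([self.points, self.normals])
            header = "x,y,z,nx,ny,nz"
        np.savetxt(path, cols, delimiter=",", header=header, comments="")

    def to_pdb(self, path: str | Path) -> None:
        """Pseudo-atom HETATM file, one dummy atom per surface point."""
        lines = []
        for i, (x, y, z) in enumerate(self.points, start=1):
            serial = i % 100000
            lines.append(
                f"HETATM{serial:5d}  C   SRF A{(i % 10000):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        lines.append("END")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class ExposureField:
    """Mean-filter exposure values on the full grid (valid inside the mask).

    Values lie in [0, 1]: highly exposed voxels approach 0, voxels deep
    inside a large solid approach 1.
    """

    values: np.ndarray
    mask: np.ndarray
    window: int = 21


def _points_from_mask(dmap: DensityMap, mask: np.ndarray, definition: str) -> SurfacePointSet:
    idx_zyx = np.argwhere(mask)
    pts = dmap.origin + idx_zyx[:, ::-1].astype(float) * dmap.spacing
    return SurfacePointSet(pts, definition, voxel_indices=idx_zyx)


def surface_T(dmap: DensityMap, c: ContourSpec) -> SurfacePointSet:
    """Density-band surface: voxels within contour ± 10% σ."""
    if c.sigma <= 0:
        raise ValueError("surface definition T needs a positive sigma")
    band = 0.1 * c.sigma
    mask = (dmap.data >= c.threshold - band) & (dmap.data <= c.threshold + band)
    if not mask.any():
        raise SurfaceExtractionError(
            f"no voxel density within {c.threshold:+.4g} ± {band:.4g}"
        )
    return _points_from_mask(dmap, mask, "T")


def surface_A(dmap: DensityMap, c: ContourSpec) -> SurfacePointSet:
    """All contour-surface points: in-contour voxels touching background.

    Background contact is checked over the full 26-neighbourhood; the
    outside of the grid counts as background, so in-contour voxels on the
    map boundary are surface.
    """
    mask = dmap.data >= c.threshold
    if not mask.any():
        raise SurfaceExtractionError("contoured region is empty")
    interior = ndimage.binary_erosion(
        mask, structure=np.ones((3, 3, 3), dtype=bool), border_value=0
    )
    return _points_from_mask(dmap, mask & ~interior, "A")


def exposure_filter(
    dmap: DensityMap, c: ContourSpec, window: int = 21
) -> ExposureField:
    """Extent-of-burial filter on the contour mask.

    Each in-contour voxel's value is the mean of the binary mask over three
    axis-aligned windows of ``window`` voxels centred on it — a multiset of
    ``3·window − 2`` samples, the centre counted once.  Samples beyond the
    grid count as background (0).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    mask = (dmap.data >= c.threshold).astype(float)
    total = np.zeros_like(mask)
    for axis in range(3):
        total += window * ndimage.uniform_filter1d(
            mask, size=window, axis=axis, mode="constant", cval=0.0
        )
    total -= 2.0 * mask  # centre voxel was counted three times
    values = np.clip(total / (3 * window - 2), 0.0, 1.0)
    values[mask == 0] = 0.0
    return ExposureField(values=values, mask=mask.astype(bool), window=window)


def surface_M(
    dmap: DensityMap,
    c: ContourSpec,
    cutoff: float = 0.3,
    window: int = 21,
) -> SurfacePointSet:
    """Mean-filter surface: in-contour voxels with exposure below ``cutoff``."""
    field_ = exposure_filter(dmap, c, window)
    sel = field_.mask & (field_.values < cutoff)
    if not sel.any():
        raise SurfaceExtractionError(
            f"no in-contour voxel has exposure < {cutoff} (window {window}); "
            "the contoured body may be too bulky for this cutoff"
        )
    return _points_from_mask(dmap, sel, "M")


_EXTRACTORS = {"T": surface_T, "A": surface_A, "M": surface_M}


def extract_surface(dmap: DensityMap, c: ContourSpec, definition: str, **kw) -> SurfacePointSet:
    """Dispatch on surface definition letter T/A/M."""
    try:
        fn = _EXTRACTORS[definition.upper()]
    except KeyError:
        raise ValueError(f"unknown surface definition {definition!r}") from None
    return fn(dmap, c, **kw)


# ---------------------------------------------------------------------------
# scores on point sets


def chamfer_distance(
    target: SurfacePointSet, probe: SurfacePointSet, symmetric: bool = False
) -> float:
    """Mean nearest-neighbour distance from target to probe surface (Å).

    The default is one-directional (each *target* point to its nearest
    probe point); ``symmetric=True`` averages the two directional means.
    """
    if len(target) == 0 or len(probe) == 0:
        raise ValueError("surface point sets must be nonempty")
    d_tp = cKDTree(probe.points).query(target.points)[0]
    if not symmetric:
        return float(d_tp.mean())
    d_pt = cKDTree(target.points).query(probe.points)[0]
    return float(0.5 * (d_tp.mean() + d_pt.mean()))


def cd_gdt(
    target: SurfacePointSet,
    probe: SurfacePointSet,
    d_max: float = 30.0,
    k: int = 30,
) -> float:
    """GDT-weighted cumulative-fraction score of nearest-neighbour distances.

    With distance limits ``D(i) = i·d_max/k`` and ``P_i`` the fraction of
    target points whose nearest probe point lies within ``D(i)``, the score
    is ``Σ (k−i+1)·P_i / (k(k+1)/2)``: weights fall linearly with distance,
    reaching zero beyond ``d_max``.  1 is a perfect match, 0 means every
    nearest neighbour is farther than ``d_max``.
    """
    if len(target) == 0 or len(probe) == 0:
        raise ValueError("surface point sets must be nonempty")
    if d_max <= 0 or k < 1:
        raise ValueError("d_max must be positive and k >= 1")
    d = cKDTree(probe.points).query(target.points)[0]
    i = np.arange(1, k + 1)
    limits = i * d_max / k
    p = (d[None, :] <= limits[:, None]).mean(axis=1)
    weights = (k - i + 1).astype(float)
    return float(np.sum(weights * p) / (k * (k + 1) / 2.0))


def _gradients_at(dmap: DensityMap, idx_zyx: np.ndarray) -> np.ndarray:
    """Central-difference density gradient (xyz order, per Å) at voxels."""
    sx, sy, sz = dmap.spacing
    gz, gy, gx = np.gradient(dmap.data.astype(float), sz, sy, sx)
    z, y, x = idx_zyx[:, 0], idx_zyx[:, 1], idx_zyx[:, 2]
    return np.stack([gx[z, y, x], gy[z, y, x], gz[z, y, x]], axis=1)


def gradient_normals(dmap: DensityMap, points: SurfacePointSet) -> SurfacePointSet:
    """Attach unit density-gradient normals to a surface point set.

    Points with a vanishing gradient carry no direction and are dropped;
    their count is reported on the returned set (``n_dropped``).
    """
    if points.voxel_indices is None:
        raise ValueError("surface point set lacks voxel indices")
    g = _gradients_at(dmap, points.voxel_indices)
    norms = np.linalg.norm(g, axis=1)
    keep = norms > 0
    if not keep.any():
        raise ValueError("all gradients vanish: normals undefined")
    return SurfacePointSet(
        points.points[keep],
        points.definition,
        voxel_indices=points.voxel_indices[keep],
        normals=g[keep] / norms[keep, None],
        n_dropped=int((~keep).sum()),
    )


def normal_vector_score(
    map1: DensityMap, map2: DensityMap, target_surface: SurfacePointSet
) -> float:
    """Mean angle between the two maps' gradient normals at surface points.

    Both maps must live on the same grid as the surface's source (map1).
    The angle at each point is normalized by π, so 0 means perfectly
    aligned parallel surfaces and 1 antiparallel ones.  Points where either
    gradient vanishes are excluded.
    """
    if map1.data.shape != map2.data.shape:
        raise ValueError("maps must share a common grid")
    if target_surface.voxel_indices is None:
        raise ValueError("surface point set lacks voxel indices")
    g1 = _gradients_at(map1, target_surface.voxel_indices)
    g2 = _gradients_at(map2, target_surface.voxel_indices)
    n1 = np.linalg.norm(g1, axis=1)
    n2 = np.linalg.norm(g2, axis=1)
    keep = (n1 > 0) & (n2 > 0)
    if not keep.any():
        raise ValueError("no surface point has nonzero gradients in both maps")
    cosang = np.sum(g1[keep] * g2[keep], axis=1) / (n1[keep] * n2[keep])
    angles = np.arccos(np.clip(cosang, -1.0, 1.0))
    return float(np.mean(angles) / np.pi)
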