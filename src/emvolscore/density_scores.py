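"""Voxel-density comparison scores.

Global cross-correlation (CCC), its restriction to the overlap region
(SCCC), the zero-mean product-moment variant (SMOC), and the
mutual-information family (local MI over the overlap region, global
normalized MI) computed on Sturges-binned densities.

The *overlap region* is the set of voxels above the chosen contour in
both maps on a shared grid; all local scores are evaluated there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .contouring import ContourSpec
from .volume_io import DensityMap

__all__ = [
    "NoOverlapError",
    "OverlapRegion",
    "BinnedDensity",
    "overlap_region",
    "ccc",
    "sccc",
    "smoc",
    "sturges_bins",
    "bin_density",
    "mutual_information",
    "lmi",
    "nmi",
]


class NoOverlapError(ValueError):
    """The contoured regions share no (or too few) voxels for a local score."""


@dataclass
class OverlapRegion:
    """Boolean mask on a common grid, true where both maps exceed contour."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class BinnedDensity:
    """Equal-width density binning of the voxels in a region.

    ``indices`` holds one bin index in ``[0, k)`` per region voxel; ``edges``
    are the ``k+1`` monotone bin boundaries actually used.
    """

    indices: np.ndarray
    k: int
    edges: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.indices.size and (
            self.indices.min() < 0 or self.indices.max() >= self.k
        ):
            raise ValueError("bin indices out of range")


def overlap_region(
    map1: DensityMap, map2: DensityMap, c1: ContourSpec, c2: ContourSpec
) -> OverlapRegion:
    """Voxels within the contour of both maps (maps must share a grid)."""
    if map1.data.shape != map2.data.shape:
        raise ValueError("maps must share a common grid")
    mask = (map1.data >= c1.threshold) & (map2.data >= c2.threshold)
    return OverlapRegion(mask)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x.astype(float)
    y = y.astype(float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(np.dot(xc, xc)) * float(np.dot(yc, yc)))
    if denom == 0.0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.dot(xc, yc) / denom)


def ccc(map1: DensityMap, map2: DensityMap) -> float:
    """Global cross-correlation: Pearson over all common-grid voxels."""
    if map1.data.shape != map2.data.shape:
        raise ValueError("maps must share a common grid")
    return _pearson(map1.data.ravel(), map2.data.ravel())


def sccc(map1: DensityMap, map2: DensityMap, region: OverlapRegion) -> float:
    """Local cross-correlation: Pearson restricted to the overlap region."""
    if region.n_voxels < 2:
        raise NoOverlapError("overlap region has fewer than 2 voxels")
    x = map1.data[region.mask]
    y = map2.data[region.mask]
    try:
        return _pearson(x, y)
    except ValueError as exc:
        raise NoOverlapError(f"degenerate overlap region: {exc}") from exc


def smoc(map1: DensityMap, map2: DensityMap, region: OverlapRegion) -> float:
    """Manders-style product moment about zero over the overlap region."""
    if region.n_voxels < 1:
        raise NoOverlapError("empty overlap region")
    x = map1.data[region.mask].astype(float)
    y = map2.data[region.mask].astype(float)
    denom = math.sqrt(float(np.dot(x, x)) * float(np.dot(y, y)))
    if denom == 0.0:
        raise NoOverlapError("all-zero density within the overlap region")
    return float(np.dot(x, y) / denom)


def sturges_bins(n: int) -> int:
    """Sturges bin count ``k = ceil(log2 n) + 1``.

    At a typical overlap region of 80³ voxels this gives k = 20.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    return int(math.ceil(math.log2(n))) + 1 if n > 1 else 1


def bin_density(dmap: DensityMap, region: OverlapRegion, k: int) -> BinnedDensity:
    """Equal-width binning of the map's densities over the region voxels.

    Bins span the region's min..max; the maximum value lands in the top
    bin.  A constant region occupies a single bin (entropy 0 downstream).
    """
    if region.n_voxels < 1:
        raise NoOverlapError("cannot bin an empty region")
    if k < 1:
        raise ValueError("bin count must be >= 1")
    vals = dmap.data[region.mask].astype(float)
    lo, hi = float(vals.min()), float(vals.max())
    edges = np.linspace(lo, hi if hi > lo else lo + 1.0, k + 1)
    if hi > lo:
        idx = np.floor((vals - lo) / (hi - lo) * k).astype(np.int64)
        np.clip(idx, 0, k - 1, out=idx)
    else:
        idx = np.zeros(vals.size, dtype=np.int64)
    return BinnedDensity(idx, k, edges)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def mutual_information(bx: BinnedDensity, by: BinnedDensity) -> float:
    """MI = H_X + H_Y − H_XY of two binnings over the same voxel set (bits).

    Marginal and joint entropies use base-2 logs with the convention
    ``0·log 0 = 0``.
    """
    if bx.indices.size != by.indices.size:
        raise ValueError("binned densities cover different voxel sets")
    n = bx.indices.size
    joint = np.bincount(
        bx.indices * by.k + by.indices, minlength=bx.k * by.k
    ).astype(float) / n
    joint = joint.reshape(bx.k, by.k)
    hx = _entropy(joint.sum(axis=1))
    hy = _entropy(joint.sum(axis=0))
    hxy = _entropy(joint.ravel())
    mi = hx + hy - hxy
    return max(mi, 0.0)


def lmi(map1: DensityMap, map2: DensityMap, region: OverlapRegion) -> float:
    """Local mutual information over the overlap region.

    The bin count comes from the Sturges rule on the region's voxel count
    and is shared by both maps.
    """
    if region.n_voxels < 1:
        raise NoOverlapError("empty overlap region")
    k = sturges_bins(region.n_voxels)
    bx = bin_density(map1, region, k)
    by = bin_density(map2, region, k)
    return mutual_information(bx, by)


def nmi(map1: DensityMap, map2: DensityMap) -> float:
    """Global normalized mutual information ``(H_X + H_Y) / H_XY``.

    Computed over *all* common-grid voxels (no contour masking), with the
    Sturges bin count on the total voxel count.  Ranges from 1 (independent)
    to 2 (identical binnings).
    """
    if map1.data.shape != map2.data.shape:
        raise ValueError("maps must share a common grid")
    full = OverlapRegion(np.ones(map1.data.shape, dtype=bool))
    k = sturges_bins(full.n_voxels)
    bx = bin_density(map1, full, k)
    by = bin_density(map2, full, k)
    n = bx.indices.size
    joint = np.bincount(
        bx.indices * by.k + by.indices, minlength=bx.k * by.k
    ).astype(float) / n
    joint = joint.reshape(bx.k, by.k)
    hx = _entropy(joint.sum(axis=1))
    hy = _entropy(joint.sum(axis=0))
    hxy = _entropy(joint.ravel())
    if hxy == 0.0:
        raise ValueError("both maps constant: NMI undefined")
    return float((hx + hy) / hxy)
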