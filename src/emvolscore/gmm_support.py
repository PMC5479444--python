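"""Heuristic Gaussian-count selection for GMM map representations.

External fitters approximate a density map by a mixture of 3D Gaussians;
the number of components controls how much detail survives.  The
heuristic here divides the molecular volume by an effective per-segment
volume — the volume of a 100-residue protein (100 × 110 Da × 1.21 Å³/Da)
scaled by the map resolution in Å — so lower-resolution maps get fewer
Gaussians.  The count is clamped to [3, 240].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .contouring import VOLUME_PER_DALTON, ContourSpec
from .volume_io import DensityMap

__all__ = ["SegmentEstimate", "expected_gaussians", "gaussians_from_mass", "gaussians_from_map"]

#: volume of a 100-residue protein segment, Å³ (100 aa × 110 Da/aa × 1.21 Å³/Da)
SEGMENT_VOLUME = 100 * 110 * VOLUME_PER_DALTON

MIN_GAUSSIANS = 3
MAX_GAUSSIANS = 240


@dataclass(frozen=True)
class SegmentEstimate:
    """Expected segment count for a molecular volume at a resolution."""

    sv: float
    n_expected: float
    n_gaussians: int

    def to_dict(self) -> dict:
        return {
            "segment_volume": float(self.sv),
            "n_expected": float(self.n_expected),
            "n_gaussians": int(self.n_gaussians),
        }


def expected_gaussians(molecular_volume: float, resolution: float) -> SegmentEstimate:
    """Number of Gaussians to represent a volume at a given resolution.

    ``sv = (100·110·1.21)·r`` Å³ is the resolution-scaled segment volume;
    the expected count is ``molecular_volume / sv``, floored and clamped
    to [3, 240].
    """
    if molecular_volume <= 0 or resolution <= 0:
        raise ValueError("molecular volume and resolution must be positive")
    sv = SEGMENT_VOLUME * resolution
    n_expected = molecular_volume / sv
    n = min(MAX_GAUSSIANS, max(MIN_GAUSSIANS, math.floor(n_expected)))
    return SegmentEstimate(sv=sv, n_expected=n_expected, n_gaussians=n)


def gaussians_from_mass(molecular_weight: float, resolution: float) -> SegmentEstimate:
    """Gaussian count from molecular weight (Da) via 1.21 Å³/Da."""
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be positive")
    return expected_gaussians(molecular_weight * VOLUME_PER_DALTON, resolution)


def gaussians_from_map(
    dmap: DensityMap, c: ContourSpec, resolution: float | None = None
) -> SegmentEstimate:
    """Gaussian count from the contoured voxel volume of a map."""
    res = resolution if resolution is not None else dmap.resolution
    if res is None:
        raise ValueError("a resolution is required")
    vol = float(np.sum(dmap.data >= c.threshold)) * dmap.voxel_volume
    if vol <= 0:
        raise ValueError("contoured region is empty")
    return expected_gaussians(vol, res)
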