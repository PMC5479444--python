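"""Overlap score and MAD-normalized combined scores.

OVR is the fraction of shared in-contour voxels relative to the smaller
contoured volume.  Because OVR lives on a different scale than the local
density scores, combining them requires putting OVR on the local score's
scale first: it is multiplied by the ratio of median absolute deviations
(MAD) across the fit ensemble and shifted by the difference of medians.
The combined score for each fit is then the plain average of the local
score and the rescaled OVR.

Combined scores are therefore *ensemble-level* quantities: the scale and
shift come from the whole population of candidate fits, so a combined
score for a single isolated fit is undefined.
"""

from __future__ import annotations

import numpy as np

from .contouring import ContourSpec
from .volume_io import DensityMap

__all__ = [
    "ovr",
    "mad",
    "normalize_ovr",
    "combined_score",
    "combine_with_overlap",
]


def ovr(
    map1: DensityMap, map2: DensityMap, c1: ContourSpec, c2: ContourSpec
) -> float:
    """Fraction of overlapping in-contour voxels over the smaller volume."""
    if map1.data.shape != map2.data.shape:
        raise ValueError("maps must share a common grid")
    a = map1.data >= c1.threshold
    b = map2.data >= c2.threshold
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        raise ValueError("a contoured region is empty: OVR undefined")
    return float(np.logical_and(a, b).sum() / min(na, nb))


def mad(values) -> float:
    """Median absolute deviation about the median."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("MAD of an empty vector")
    med = np.median(v)
    return float(np.median(np.abs(v - med)))


def normalize_ovr(ovr_values, local_values, median_aligned: bool = False):
    """Rescale raw OVR values onto a local score's distribution.

    ``scale = MAD(local)/MAD(ovr)``, ``shift = median(local) − median(ovr)``
    and ``OVRnorm = ovr·scale + shift``.  Note the shift uses the *unscaled*
    OVR median; pass ``median_aligned=True`` for the variant
    ``shift = median(local) − scale·median(ovr)`` that makes the medians
    coincide exactly.
    """
    o = np.asarray(ovr_values, dtype=float)
    loc = np.asarray(local_values, dtype=float)
    if o.shape != loc.shape or o.size < 2:
        raise ValueError("score vectors must have equal length >= 2")
    mad_o = mad(o)
    if mad_o == 0.0:
        raise ValueError("degenerate overlap distribution (MAD = 0)")
    scale = mad(loc) / mad_o
    if median_aligned:
        shift = float(np.median(loc)) - scale * float(np.median(o))
    else:
        shift = float(np.median(loc)) - float(np.median(o))
    return o * scale + shift


def combined_score(local_values, ovrnorm_values):
    """Element-wise mean of a local score and the rescaled OVR."""
    loc = np.asarray(local_values, dtype=float)
    on = np.asarray(ovrnorm_values, dtype=float)
    if loc.shape != on.shape:
        raise ValueError("score vectors must have equal length")
    return 0.5 * (loc + on)


def combine_with_overlap(local_values, ovr_values, median_aligned: bool = False):
    """Combined score for an ensemble from raw local and OVR vectors.

    Fits where either value is non-finite (e.g. no overlap) are excluded
    from the median/MAD statistics and assigned the minimum combined score
    of the valid fits, so they rank last.
    """
    loc = np.asarray(local_values, dtype=float)
    o = np.asarray(ovr_values, dtype=float)
    if loc.shape != o.shape:
        raise ValueError("score vectors must have equal length")
    valid = np.isfinite(loc) & np.isfinite(o)
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid fits for a combined score")
    on_valid = normalize_ovr(o[valid], loc[valid], median_aligned=median_aligned)
    comb_valid = combined_score(loc[valid], on_valid)
    out = np.empty_like(loc)
    out[valid] = comb_valid
    out[~valid] = comb_valid.min()
    return out
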