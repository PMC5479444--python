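"""Iso-contour threshold selection.

All scores need a contour level separating molecular density from
background noise.  The primary estimate derives the threshold from the
molecular weight: a protein of mass M Da occupies roughly 1.21 Å³/Da
(partial specific volume ~0.73 cm³/g), so the contour is placed where the
enclosed volume matches M × 1.21 Å³.  A sanity cascade falls back to an
author-suggested level and finally to ``peak + 1.5 σ``, where the peak is
the mode of the density histogram and σ is the spread of density values
about it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .volume_io import DensityMap

__all__ = [
    "ContourSpec",
    "VOLUME_PER_DALTON",
    "background_peak",
    "sigma_about_peak",
    "contour_from_mass",
    "select_contour",
]

#: average protein volume per unit molecular weight, Å³/Da
VOLUME_PER_DALTON = 1.21


@dataclass(frozen=True)
class ContourSpec:
    """A chosen iso-contour threshold plus provenance.

    ``method`` records which branch of the selection cascade fired:
    ``molecular_weight``, ``author`` or ``sigma_fallback``.
    """

    threshold: float
    method: str
    background_peak: float
    sigma: float
    warning: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise ValueError("contour threshold must be finite")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.method not in {"molecular_weight", "author", "sigma_fallback"}:
            raise ValueError(f"unknown contour method {self.method!r}")

    def to_dict(self) -> dict:
        d = {
            "threshold": float(self.threshold),
            "method": self.method,
            "background_peak": float(self.background_peak),
            "sigma": float(self.sigma),
        }
        if self.warning:
            d["warning"] = self.warning
        return d


def _sturges(n: int) -> int:
    return int(math.ceil(math.log2(n))) + 1 if n > 1 else 1


def background_peak(dmap: DensityMap) -> float:
    """Mode of the density histogram (center of the most populated bin).

    Bin count follows the Sturges rule on the total voxel count.  A constant
    map has no background/foreground distinction and raises ``ValueError``.
    """
    vals = dmap.data.ravel()
    if vals.max() == vals.min():
        raise ValueError("constant map: background peak undefined")
    k = _sturges(vals.size)
    counts, edges = np.histogram(vals, bins=k)
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


def sigma_about_peak(dmap: DensityMap, peak: float) -> float:
    """RMS deviation of density values about the background peak."""
    v = dmap.data.astype(float).ravel()
    return float(np.sqrt(np.mean((v - peak) ** 2)))


def contour_from_mass(dmap: DensityMap, molecular_weight: float) -> tuple[float, bool]:
    """Threshold enclosing the volume implied by the molecular weight.

    Returns ``(threshold, clipped)``: the density value such that voxels at
    or above it occupy ``molecular_weight * 1.21`` Å³ (ties broken toward
    including more voxels), and a flag set when the requested volume exceeds
    the whole map, in which case the map minimum is returned.
    """
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be positive")
    target_volume = molecular_weight * VOLUME_PER_DALTON
    voxvol = dmap.voxel_volume
    vals = np.sort(dmap.data.ravel())[::-1]
    n_needed = target_volume / voxvol
    if n_needed >= vals.size:
        return float(vals[-1]), True
    m = int(math.ceil(n_needed - 1e-9))
    if m < 1:
        return float(vals[0]), False
    return float(vals[m - 1]), False


def select_contour(
    dmap: DensityMap,
    molecular_weight: float | None = None,
    author_level: float | None = None,
) -> ContourSpec:
    """Contour-selection cascade.

    With background peak ``p`` and spread ``s``, a candidate level is *sane*
    when it lies in ``[p, p + 5 s]``.  The cascade:

    1. if a molecular-weight level exists, is sane, but disagrees with a
       given author level by more than 3 σ — trust the author level;
    2. otherwise a sane molecular-weight level wins;
    3. otherwise a sane author level wins;
    4. otherwise fall back to ``p + 1.5 σ``.
    """
    p = background_peak(dmap)
    s = sigma_about_peak(dmap, p)

    def sane(level: float) -> bool:
        return p <= level <= p + 5.0 * s

    c_mw = None
    warning = None
    if molecular_weight is not None:
        c_mw, clipped = contour_from_mass(dmap, molecular_weight)
        if clipped:
            warning = "molecular-weight volume exceeds map volume"

    if c_mw is not None and sane(c_mw):
        if author_level is not None and abs(c_mw - author_level) > 3.0 * s:
            return ContourSpec(author_level, "author", p, s, warning)
        return ContourSpec(c_mw, "molecular_weight", p, s, warning)
    if author_level is not None and sane(author_level):
        return ContourSpec(author_level, "author", p, s, warning)
    return ContourSpec(p + 1.5 * s, "sigma_fallback", p, s, warning)
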