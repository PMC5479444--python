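"""Scoring pipeline: contour → low-pass → common grid → per-fit scores.

Ties the individual score modules into the workflow used to assess a set
of candidate rigid fits between two maps: both maps are low-pass filtered
to the coarser of the two nominal resolutions, contour levels are chosen,
and for every candidate transform the maps are interpolated onto a common
grid (spacing = resolution/4) where all requested scores are evaluated.
Combined scores (``*_OV``) need the whole ensemble and are added when two
or more fits are scored together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import density_scores as ds
from . import overlap_combined as oc
from . import surface_scores as ss
from .contouring import ContourSpec, select_contour
from .volume_io import DensityMap, RigidTransform, common_grid, lowpass_filter

__all__ = [
    "SCORE_REGISTRY",
    "COMBINED_PARENTS",
    "score_fit_pair",
    "score_ensemble",
]

#: registry of score names -> True when greater is better (distance-like
#: scores are negated before ROC sweeps so "greater = positive" holds).
SCORE_REGISTRY: dict[str, bool] = {
    "CCC": True,
    "SCCC": True,
    "SMOC": True,
    "LMI": True,
    "NMI": True,
    "OVR": True,
    "CDT": False,
    "CDA": False,
    "CDM": False,
    "CDT_GDT": True,
    "CDA_GDT": True,
    "CDM_GDT": True,
    "NVT": False,
    "NVA": False,
    "NVM": False,
    "SCCC_OV": True,
    "SMOC_OV": True,
    "LMI_OV": True,
}

#: combined score -> the local score it averages with rescaled OVR
COMBINED_PARENTS = {"SCCC_OV": "SCCC", "SMOC_OV": "SMOC", "LMI_OV": "LMI"}


@dataclass
class PreparedPair:
    """Low-passed maps with chosen contours, ready for per-fit gridding."""

    map1: DensityMap
    map2: DensityMap
    c1: ContourSpec
    c2: ContourSpec
    grid_spacing: float


def prepare_pair(
    map1: DensityMap,
    map2: DensityMap,
    mw1: float | None = None,
    mw2: float | None = None,
    author_level1: float | None = None,
    author_level2: float | None = None,
) -> PreparedPair:
    """Low-pass both maps to the coarser resolution and pick contours."""
    if map1.resolution is None or map2.resolution is None:
        raise ValueError("both maps need a nominal resolution")
    target_res = max(map1.resolution, map2.resolution)
    m1 = lowpass_filter(map1, target_res)
    m2 = lowpass_filter(map2, target_res)
    c1 = select_contour(m1, mw1, author_level1)
    c2 = select_contour(m2, mw2, author_level2)
    return PreparedPair(m1, m2, c1, c2, grid_spacing=target_res / 4.0)


def score_fit_pair(
    prepared: PreparedPair,
    t: RigidTransform,
    scores: list[str],
    surface_window: int = 21,
) -> dict[str, float]:
    """All requested per-fit scores for one candidate transform.

    Scores that cannot be computed (empty overlap, empty surface) come
    back as NaN; ensemble-level machinery ranks such fits last.
    """
    base = [s for s in scores if s not in COMBINED_PARENTS]
    needed = set(base) | {COMBINED_PARENTS[s] for s in scores if s in COMBINED_PARENTS}
    if any(s in COMBINED_PARENTS for s in scores):
        needed.add("OVR")
    unknown = needed - set(SCORE_REGISTRY)
    if unknown:
        raise ValueError(f"unknown scores requested: {sorted(unknown)}")

    g1, g2 = common_grid(
        prepared.map1, prepared.map2, t, spacing=prepared.grid_spacing
    )
    c1, c2 = prepared.c1, prepared.c2
    out: dict[str, float] = {}
    region = ds.overlap_region(g1, g2, c1, c2)

    def safe(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except (ValueError, ds.NoOverlapError, ss.SurfaceExtractionError):
            return float("nan")

    for name in sorted(needed):
        if name == "CCC":
            out[name] = safe(ds.ccc, g1, g2)
        elif name == "SCCC":
            out[name] = safe(ds.sccc, g1, g2, region)
        elif name == "SMOC":
            out[name] = safe(ds.smoc, g1, g2, region)
        elif name == "LMI":
            out[name] = safe(ds.lmi, g1, g2, region)
        elif name == "NMI":
            out[name] = safe(ds.nmi, g1, g2)
        elif name == "OVR":
            out[name] = safe(oc.ovr, g1, g2, c1, c2)
        elif name.startswith(("CD", "NV")):
            defn = name[2]
            kw = {"window": surface_window} if defn == "M" else {}
            s1 = safe(ss.extract_surface, g1, c1, defn, **kw)
            if isinstance(s1, float):  # extraction failed
                out[name] = float("nan")
                continue
            if name.startswith("NV"):
                out[name] = safe(ss.normal_vector_score, g1, g2, s1)
            else:
                s2 = safe(ss.extract_surface, g2, c2, defn, **kw)
                if isinstance(s2, float):
                    out[name] = float("nan")
                elif name.endswith("_GDT"):
                    out[name] = safe(ss.cd_gdt, s1, s2)
                else:
                    out[name] = safe(ss.chamfer_distance, s1, s2)
    return out


def score_ensemble(
    prepared: PreparedPair,
    fits: list[RigidTransform],
    scores: list[str],
    surface_window: int = 21,
) -> pd.DataFrame:
    """Score table for an ensemble of candidate fits (one row per fit).

    Combined ``*_OV`` columns are computed from the raw local and OVR
    vectors across the ensemble; they require at least two fits.
    """
    combined = [s for s in scores if s in COMBINED_PARENTS]
    if combined and len(fits) < 2:
        raise ValueError("combined scores need an ensemble of >= 2 fits")
    rows = [score_fit_pair(prepared, t, scores, surface_window) for t in fits]
    df = pd.DataFrame(rows)
    for name in combined:
        parent = COMBINED_PARENTS[name]
        df[name] = oc.combine_with_overlap(
            df[parent].to_numpy(), df["OVR"].to_numpy()
        )
    keep = [s for s in SCORE_REGISTRY if s in df.columns]
    df = df[keep]
    df.insert(0, "fit_id", np.arange(len(fits)))
    return df


def oriented_for_roc(values, name: str):
    """Score vector with 'greater = better' orientation and NaNs ranked last."""
    v = np.asarray(values, dtype=float).copy()
    if not SCORE_REGISTRY.get(name, True):
        v = -v
    bad = ~np.isfinite(v)
    if bad.any():
        finite = v[~bad]
        fill = (finite.min() - 1.0) if finite.size else -1.0
        v[bad] = fill
    return v
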