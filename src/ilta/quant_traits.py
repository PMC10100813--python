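"""Quantitative leaf traits: outline measurements, leaf mass per area,
and phenology inference.

Leaf mass per area (LM_A, g/m²) cannot be weighed on a fossil, but for
dicots it is well predicted by an allometry between the petiole's
cross-section and the lamina area it must support:

    log10(LM_A) = 3.070 + 0.382 * log10(petiole_width² / leaf_area)

with petiole width in mm (measured at the lamina insertion point) and leaf
area in mm².  Mean LM_A of a fossil-species in turn proxies leaf economics
and hence phenology: below 87 g/m² deciduous, 87–129 g/m² intermediate,
above 129 g/m² evergreen.

Outline measurements operate on a pair of digitised lamina polygons — the
preserved (minimum) outline and the reconstructed (maximum) outline — and
yield area (shoelace), length/width (extent along the principal axis of
the outline and its orthogonal), and the area index IA = preserved /
reconstructed area, the preservation criterion of the dataset cascade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

__all__ = [
    "LMA_INTERCEPT",
    "LMA_SLOPE",
    "DECIDUOUS_MAX_LMA",
    "EVERGREEN_MIN_LMA",
    "OutlinePair",
    "polygon_measurements",
    "lma",
    "petiole_width_for_lma",
    "phenology_from_lma",
    "species_summary",
]

#: coefficients of the dicot petiole allometry (log10 scale)
LMA_INTERCEPT = 3.070
LMA_SLOPE = 0.382

#: mean-LM_A phenology thresholds (g/m²); boundaries are inclusive to
#: the intermediate class
DECIDUOUS_MAX_LMA = 87.0
EVERGREEN_MIN_LMA = 129.0


@dataclass(frozen=True)
class OutlinePair:
    """Preserved (minimum) and reconstructed (maximum) lamina outlines.

    Each ring is a sequence of (x, y) vertices in mm; rings must be simple
    (non-self-intersecting) and the preserved area must not exceed the
    reconstructed area.
    """

    preserved: Sequence[tuple[float, float]]
    reconstructed: Sequence[tuple[float, float]]


def _ring_polygon(ring: Sequence[tuple[float, float]], which: str) -> Polygon:
    poly = Polygon(ring)
    if not poly.is_valid or poly.area == 0:
        raise ValueError(f"{which} outline is not a valid simple ring")
    return poly


def polygon_measurements(outline: OutlinePair) -> dict[str, float]:
    """Measure area, length, width and area index from an outline pair.

    Area is the planar (shoelace) area of the reconstructed ring.  Length
    is the extent of the reconstructed ring along the principal axis of
    its vertex cloud — an orientation-free stand-in for the midrib axis —
    and width the extent along the orthogonal axis; both are invariant
    under rotation and translation.  ``area_index`` is preserved area /
    reconstructed area.
    """
    pre = _ring_polygon(outline.preserved, "preserved")
    rec = _ring_polygon(outline.reconstructed, "reconstructed")
    if pre.area > rec.area * (1 + 1e-12):
        raise ValueError(
            "preserved outline area exceeds the reconstructed outline area"
        )

    coords = np.asarray(rec.exterior.coords[:-1], dtype=float)
    centred = coords - coords.mean(axis=0)
    # principal axis of the vertex cloud
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    projected = centred @ vt.T
    length = float(projected[:, 0].max() - projected[:, 0].min())
    width = float(projected[:, 1].max() - projected[:, 1].min())
    if width > length:  # degenerate clouds; length is the longer extent
        length, width = width, length
    return {
        "area_mm2": float(rec.area),
        "length_mm": length,
        "width_mm": width,
        "area_index": float(pre.area / rec.area),
    }


def lma(petiole_width_mm: float, leaf_area_mm2: float) -> float:
    """Leaf mass per area (g/m²) from petiole width (mm) and leaf area (mm²).

    Evaluates ``10**(3.070 + 0.382 * log10(pw² / area))``; both inputs must
    be strictly positive.  The formula depends only on the ratio pw²/area,
    so it is invariant under the isometric rescaling pw → c·pw,
    area → c²·area.
    """
    if petiole_width_mm <= 0 or leaf_area_mm2 <= 0:
        raise ValueError(
            "petiole width and leaf area must be strictly positive, got "
            f"pw={petiole_width_mm}, area={leaf_area_mm2}"
        )
    ratio = petiole_width_mm**2 / leaf_area_mm2
    return 10.0 ** (LMA_INTERCEPT + LMA_SLOPE * math.log10(ratio))


def petiole_width_for_lma(lma_gm2: float, leaf_area_mm2: float) -> float:
    """Invert the allometry: the petiole width (mm) that yields a given
    LM_A for a given leaf area.  Exact inverse of :func:`lma` (round-trips
    to ~1e-9 relative error); used by the synthetic-assemblage generator."""
    if lma_gm2 <= 0 or leaf_area_mm2 <= 0:
        raise ValueError("LM_A and leaf area must be strictly positive")
    log_ratio = (math.log10(lma_gm2) - LMA_INTERCEPT) / LMA_SLOPE
    return math.sqrt(leaf_area_mm2 * 10.0**log_ratio)


def phenology_from_lma(mean_lma_gm2: float) -> str:
    """Phenology class from a fossil-species mean LM_A (g/m²).

    ``< 87`` deciduous, ``87–129`` (inclusive) intermediate, ``> 129``
    evergreen.  The mean should be taken over at least five leaves; that
    eligibility is enforced by :func:`species_summary`, not here.
    """
    if mean_lma_gm2 <= 0:
        raise ValueError("mean LM_A must be strictly positive")
    if mean_lma_gm2 < DECIDUOUS_MAX_LMA:
        return "deciduous"
    if mean_lma_gm2 <= EVERGREEN_MIN_LMA:
        return "intermediate"
    return "evergreen"


def species_summary(a, min_n: int = 5) -> pd.DataFrame:
    """Per-fossil-species means of leaf area and LM_A, with phenology.

    A species enters a metric's column only with at least ``min_n``
    measured leaves for that metric (enforced separately per metric, so a
    species may have a mean area but no mean LM_A).  LM_A-based phenology
    is reported where the LM_A mean is available.

    Parameters
    ----------
    a : Assemblage
        Any assemblage whose specimens carry ``fossil_species`` and
        (partially) measured traits.
    """
    frame = a.to_frame()
    frame = frame[frame["fossil_species"].notna()]
    rows = []
    for species, grp in frame.groupby("fossil_species", sort=True):
        area = grp["leaf_area_mm2"].dropna()
        lma_vals = grp["lma_gm2"].dropna()
        row: dict = {
            "fossil_species": species,
            "n_leaves": len(grp),
            "n_area": len(area),
            "n_lma": len(lma_vals),
            "mean_area_mm2": float(area.mean()) if len(area) >= min_n else None,
            "mean_lma_gm2": (
                float(lma_vals.mean()) if len(lma_vals) >= min_n else None
            ),
        }
        row["phenology_lma"] = (
            phenology_from_lma(row["mean_lma_gm2"])
            if row["mean_lma_gm2"] is not None
            else None
        )
        if row["mean_area_mm2"] is not None or row["mean_lma_gm2"] is not None:
            rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["fossil_species", "n_leaves", "n_area", "n_lma",
                 "mean_area_mm2", "mean_lma_gm2", "phenology_lma"],
    )
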