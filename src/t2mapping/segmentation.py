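"""Myocardial annulus masking and AHA-segment partitioning.

The myocardium in a short-axis slice is the annulus between a manually
drawn endocardial and epicardial contour.  A pixel belongs to the
annulus iff its center lies inside the epicardial polygon and outside
the endocardial polygon (even-odd rule; for the simple polygons required
here this coincides with the winding rule used by the rasteriser).

Segments follow the 16-segment AHA convention without the apex cap:
6 equal angular sectors at the basal and midventricular levels, 4 at the
apical level.  Sector 1 starts at the RV-insertion reference ray and
numbering proceeds counterclockwise *as displayed* (image rows increase
downward, so the pixel angle is computed as atan2(-(row - row_c),
col - col_c); this makes "counterclockwise" mean what a viewer of the
image sees).  A pixel whose angle falls exactly on a sector boundary is
assigned to the lower-numbered of the two adjacent segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from shapely.geometry import Polygon as ShapelyPolygon

__all__ = [
    "ContourPair",
    "SegmentLabelMap",
    "annulus_mask",
    "aha_segments",
    "segment_stats",
    "SEGMENTS_PER_LEVEL",
    "GLOBAL_SEGMENT_ID",
]

SEGMENTS_PER_LEVEL = {"basal": 6, "mid": 6, "apical": 4}

#: segment_id used for the whole-myocardium summary row in stats tables
GLOBAL_SEGMENT_ID = 0


@dataclass(frozen=True)
class ContourPair:
    """Closed endo- and epicardial polygons in (x, y) pixel coordinates.

    x is the column coordinate and y the row coordinate of a vertex;
    vertices are ordered along the contour (closure is implicit).
    """

    endo: np.ndarray
    epi: np.ndarray

    def __post_init__(self) -> None:
        endo = np.asarray(self.endo, dtype=float)
        epi = np.asarray(self.epi, dtype=float)
        for name, poly in (("endo", endo), ("epi", epi)):
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError(f"{name} contour must be an (n>=3, 2) vertex array")
        object.__setattr__(self, "endo", endo)
        object.__setattr__(self, "epi", epi)
        endo_p = ShapelyPolygon(endo)
        epi_p = ShapelyPolygon(epi)
        if not endo_p.is_simple or not epi_p.is_simple:
            raise ValueError("contours must be simple (non-self-intersecting)")
        if endo_p.equals(epi_p):
            return  # degenerate but allowed: produces an empty annulus
        if not epi_p.contains(endo_p):
            raise ValueError("endocardial contour must lie strictly inside epicardial")


def _pixel_centers(shape: tuple[int, int]) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    # polygon vertices are (x, y) = (col, row)
    return np.column_stack([cols.ravel(), rows.ravel()]).astype(float)


def _inside(polygon: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    path = MplPath(polygon, closed=False)
    return path.contains_points(_pixel_centers(shape)).reshape(shape)


def annulus_mask(contours: ContourPair, shape: tuple[int, int]) -> np.ndarray:
    """Boolean myocardium mask: inside epi AND outside endo, pixel centers."""
    if ShapelyPolygon(contours.endo).equals(ShapelyPolygon(contours.epi)):
        warnings.warn("endo and epi contours coincide; empty annulus", stacklevel=2)
        return np.zeros(shape, dtype=bool)
    return _inside(contours.epi, shape) & ~_inside(contours.endo, shape)


@dataclass
class SegmentLabelMap:
    """Integer AHA-segment label per pixel (0 = not myocardium)."""

    labels: np.ndarray
    slice_level: str
    rv_insertion_angle: float

    @property
    def n_segments(self) -> int:
        return SEGMENTS_PER_LEVEL[self.slice_level]


def aha_segments(
    mask: np.ndarray,
    center: tuple[float, float],
    rv_insertion_angle: float = 90.0,
    slice_level: str = "mid",
) -> SegmentLabelMap:
    """Partition an annulus mask into equal angular AHA sectors.

    Parameters
    ----------
    center
        (row, col) of the LV center the sector rays emanate from.
    rv_insertion_angle
        Angle (degrees) of the anterior RV-insertion reference ray where
        segment 1 begins, measured counterclockwise-as-displayed from
        the +x (rightward) image axis.
    slice_level
        "basal" or "mid" (6 segments) or "apical" (4 segments).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if slice_level not in SEGMENTS_PER_LEVEL:
        raise ValueError(f"unknown slice level {slice_level!r}")
    k = SEGMENTS_PER_LEVEL[slice_level]
    width = 360.0 / k

    rr, cc = np.nonzero(mask)
    # y increases downward in image coordinates; negate to make the
    # angle counterclockwise in the displayed image
    theta = np.degrees(np.arctan2(-(rr - center[0]), cc - center[1]))
    delta = np.mod(theta - rv_insertion_angle, 360.0)
    idx = np.ceil(delta / width).astype(int)
    idx[idx == 0] = 1  # exactly on the reference ray -> segment 1
    labels = np.zeros(mask.shape, dtype=int)
    labels[rr, cc] = idx
    return SegmentLabelMap(labels, slice_level, float(rv_insertion_angle))


def segment_stats(t2_map: np.ndarray, labels: SegmentLabelMap) -> pd.DataFrame:
    """Per-segment T2 statistics plus a whole-myocardium row.

    Missing pixels (NaN in the map) are ignored for the mean and SD but
    counted in ``n_pixels`` (so per-segment pixel counts always sum to
    the annulus size); ``n_valid`` counts the pixels actually averaged.
    The whole-myocardium row (``segment_id == 0``) averages over all
    myocardial pixels, i.e. it is the pixel-count-weighted mean of the
    segment means, not their unweighted average.  SD uses the n-1
    denominator; a segment with fewer than 2 valid pixels gets NaN SD.
    """
    t2_map = np.asarray(t2_map, dtype=float)
    lab = labels.labels
    if t2_map.shape != lab.shape:
        raise ValueError(f"map shape {t2_map.shape} != label shape {lab.shape}")
    rows = []
    seg_ids = list(range(1, labels.n_segments + 1))
    for seg in [GLOBAL_SEGMENT_ID] + seg_ids:
        sel = (lab > 0) if seg == GLOBAL_SEGMENT_ID else (lab == seg)
        vals = t2_map[sel]
        valid = vals[~np.isnan(vals)]
        mean = float(np.mean(valid)) if valid.size else np.nan
        sd = float(np.std(valid, ddof=1)) if valid.size >= 2 else np.nan
        rows.append(
            {
                "segment_id": seg,
                "n_pixels": int(sel.sum()),
                "n_valid": int(valid.size),
                "mean_t2_ms": mean,
                "sd_t2_ms": sd,
            }
        )
    return pd.DataFrame(rows)
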