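"""Tissue-region rasterization and point-to-region assignment.

Region delineation is a manual (or ground-truth) input: polygons arrive as
``(region_class, polygon)`` pairs in pixel coordinates (x = column,
y = row).  Rasterization paints each pixel whose *center* lies inside the
polygon, resolving overlaps by the fixed precedence
EXCLUDED > ICL > SI_V > SI_N, and everything else is BACKGROUND.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

from .types import RASTER_PAINT_ORDER, RegionClass, RegionLabelMap, as_region

__all__ = [
    "rasterize_regions",
    "assign_points",
    "PointAssignment",
    "villus_shape_check",
    "region_areas",
    "as_polygon",
]


def as_polygon(polygon) -> Polygon:
    """Coerce an Nx2 coordinate array (or shapely polygon) to a Polygon.

    An open ring is closed implicitly.  Degenerate (< 3 distinct vertices)
    polygons are rejected.
    """
    if isinstance(polygon, Polygon):
        return polygon
    coords = np.asarray(polygon, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("polygon must be an Nx2 array of (x, y) vertices")
    if len(coords) > 1 and np.array_equal(coords[0], coords[-1]):
        coords = coords[:-1]
    if len(coords) < 3:
        raise ValueError("degenerate polygon: fewer than 3 distinct vertices")
    return Polygon(coords)


def _pixel_mask(poly: Polygon, shape: tuple[int, int]) -> tuple[np.ndarray, ...]:
    """Indices of pixels whose integer-coordinate center is inside ``poly``.

    Restricted to the polygon's bounding box for speed; coordinates beyond
    the image are clipped away by the same restriction.
    """
    nrows, ncols = shape
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(0, int(np.ceil(minx)))
    c1 = min(ncols - 1, int(np.floor(maxx)))
    r0 = max(0, int(np.ceil(miny)))
    r1 = min(nrows - 1, int(np.floor(maxy)))
    if c0 > c1 or r0 > r1:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    xx, yy = np.meshgrid(cols, rows)
    inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)
    rr, cc = np.nonzero(inside)
    return rr + r0, cc + c0


def rasterize_regions(
    region_polygons: Iterable[tuple],
    image_shape: tuple[int, int],
    pixel_size_um: float,
) -> RegionLabelMap:
    """Rasterize labelled region polygons into a single label map.

    Parameters
    ----------
    region_polygons
        Iterable of ``(region_class, polygon)`` where polygon is an Nx2
        (x, y) vertex array or a shapely Polygon (holes honoured).
    image_shape
        ``(rows, cols)`` of the target raster.
    pixel_size_um
        Isotropic pixel edge length in micrometres.

    A pixel belongs to a region iff its center lies strictly inside the
    polygon; overlapping classes are resolved by painting in increasing
    precedence (EXCLUDED wins over ICL over SI_V over SI_N).  Multiple
    polygons of one class are allowed.  Self-intersecting polygons are
    rejected with their feature index.
    """
    items: list[tuple[RegionClass, Polygon]] = []
    for i, (cls, polygon) in enumerate(region_polygons):
        cls = as_region(cls)
        if cls == RegionClass.BACKGROUND:
            raise ValueError(f"feature {i}: BACKGROUND is not a paintable region")
        poly = as_polygon(polygon)
        if not poly.is_valid:
            raise ValueError(
                f"feature {i} ({cls.name}): invalid (self-intersecting?) polygon"
            )
        items.append((cls, poly))

    labels = np.zeros(image_shape, dtype=np.uint8)
    for cls in RASTER_PAINT_ORDER:
        for c, poly in items:
            if c is not cls:
                continue
            rr, cc = _pixel_mask(poly, image_shape)
            labels[rr, cc] = int(cls)
    return RegionLabelMap(labels=labels, pixel_size_um=pixel_size_um)


@dataclass
class PointAssignment:
    """Result of mapping points onto a region label map.

    ``region_codes[i]`` is the RegionClass integer of the pixel containing
    point ``i`` (BACKGROUND for out-of-bounds points); ``assigned[i]`` is
    True only for points landing on a tissue region (not EXCLUDED,
    BACKGROUND, or out of bounds).
    """

    region_codes: np.ndarray
    assigned: np.ndarray
    n_out_of_bounds: int

    def regions(self) -> list[RegionClass]:
        return [RegionClass(int(c)) for c in self.region_codes]


def assign_points(points, labels: RegionLabelMap) -> PointAssignment:
    """Assign each (x, y) point to the region of the pixel containing it.

    The containing pixel is ``(floor(y), floor(x))``.  Points on EXCLUDED or
    BACKGROUND pixels, and out-of-bounds points, are flagged unassigned
    (never silently dropped); the out-of-bounds count is reported.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    nrows, ncols = labels.shape
    cols = np.floor(pts[:, 0]).astype(np.int64)
    rows = np.floor(pts[:, 1]).astype(np.int64)
    in_bounds = (rows >= 0) & (rows < nrows) & (cols >= 0) & (cols < ncols)
    codes = np.zeros(len(pts), dtype=np.int64)
    codes[in_bounds] = labels.labels[rows[in_bounds], cols[in_bounds]]
    assigned = in_bounds & np.isin(
        codes, [int(r) for r in (RegionClass.ICL, RegionClass.SI_V, RegionClass.SI_N)]
    )
    return PointAssignment(
        region_codes=codes,
        assigned=assigned,
        n_out_of_bounds=int((~in_bounds).sum()),
    )


def villus_shape_check(polygon) -> bool:
    """True iff the polygon's bounding-box height strictly exceeds its width.

    A synovial villus is morphologically taller than wide; a square
    bounding box fails the strict inequality.
    """
    poly = as_polygon(polygon)
    minx, miny, maxx, maxy = poly.bounds
    return (maxy - miny) > (maxx - minx)


def region_areas(labels: RegionLabelMap) -> dict[str, float]:
    """Area in mm^2 for every region class present in the map."""
    return {r.name: labels.area_mm2(r) for r in RegionClass}
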