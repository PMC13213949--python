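"""Per-sample, per-region metrics.

All area-type outputs are percentages of the region's pixel area
(dimensionless, 0–100 %); densities carry the mm^2 denominator derived from
the pixel size.  EXCLUDED pixels never enter a numerator or a denominator.
Undefined ratios (empty parent mask within the region) propagate as missing
values, never as 0 or 100, so they cannot bias downstream group statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .roi import as_polygon, assign_points
from .segmentation import colocalize, count_seed_density
from .types import (
    TISSUE_REGIONS,
    BinaryMask,
    CalibratedImage,
    CellLabelMap,
    MeasurementRow,
    RegionClass,
    RegionLabelMap,
    SampleMeasurements,
    as_region,
)

__all__ = [
    "positive_area_fraction",
    "coloc_ratio",
    "vessel_metrics",
    "VesselMetrics",
    "measure_sample",
    "per_cell_marker_positivity",
]

DEFAULT_COLOC_PAIRS = (("CD14", "CD16"), ("CD14", "CD206"))


def _mask_array(mask) -> np.ndarray:
    return mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)


def positive_area_fraction(
    mask, labels: RegionLabelMap, region: "RegionClass | str"
) -> float:
    """Signal-positive area as a percentage of the region's area.

    ``100 * |mask AND region| / |region|``; raises (naming the region) if
    the region is empty.
    """
    m = _mask_array(mask)
    if m.shape != labels.shape:
        raise ValueError(f"shape mismatch: mask {m.shape} vs labels {labels.shape}")
    region = as_region(region)
    region_mask = labels.region_mask(region)
    denom = int(region_mask.sum())
    if denom == 0:
        raise ValueError(f"region {region.name} is empty")
    return 100.0 * int((m & region_mask).sum()) / denom


def coloc_ratio(
    parent_mask, coloc_mask, labels: RegionLabelMap, region: "RegionClass | str"
) -> float:
    """Double-positive area as a percentage of the parent marker's area.

    Within the region, ``100 * |coloc| / |parent|``.  The co-localization
    mask must be contained in the parent mask (it is, by construction, when
    produced by :func:`synoquant.segmentation.colocalize`); a violation is
    an internal-consistency error.  An empty parent yields NaN — a flagged
    missing value, excluded from downstream statistics.
    """
    parent = _mask_array(parent_mask)
    coloc = _mask_array(coloc_mask)
    if parent.shape != coloc.shape or parent.shape != labels.shape:
        raise ValueError("parent, coloc and labels must share one shape")
    region = as_region(region)
    region_mask = labels.region_mask(region)
    if np.any(coloc & ~parent & region_mask):
        raise ValueError(
            "co-localization mask is not a subset of the parent mask "
            f"within region {region.name}"
        )
    n_parent = int((parent & region_mask).sum())
    if n_parent == 0:
        return math.nan
    n_coloc = int((coloc & region_mask).sum())
    return 100.0 * n_coloc / n_parent


@dataclass
class VesselMetrics:
    """Per-region vessel counts, densities and mean perimeters."""

    table: pd.DataFrame  # region, n_vessels, density_per_mm2, mean_perimeter_um
    n_unassigned: int

    def density(self, region: "RegionClass | str") -> float:
        region = as_region(region)
        row = self.table[self.table["region"] == region.name]
        return float(row["density_per_mm2"].iloc[0])


def vessel_metrics(
    vessel_polygons: Sequence, labels: RegionLabelMap
) -> VesselMetrics:
    """Vessel density (count/mm^2) and mean outline perimeter per region.

    Each vessel outline polygon is assigned to the region of the pixel
    containing its centroid; centroids falling on BACKGROUND or EXCLUDED
    pixels are reported unassigned.  Perimeter is the polygon arc length
    converted to micrometres.
    """
    polys = [as_polygon(p) for p in vessel_polygons]
    counts: dict[RegionClass, int] = {r: 0 for r in TISSUE_REGIONS}
    perims: dict[RegionClass, list[float]] = {r: [] for r in TISSUE_REGIONS}
    n_unassigned = 0
    if polys:
        centroids = [(p.centroid.x, p.centroid.y) for p in polys]
        assignment = assign_points(centroids, labels)
        for poly, code, ok in zip(
            polys, assignment.region_codes, assignment.assigned
        ):
            if not ok:
                n_unassigned += 1
                continue
            region = RegionClass(int(code))
            counts[region] += 1
            perims[region].append(poly.exterior.length * labels.pixel_size_um)
    records = []
    for region in TISSUE_REGIONS:
        area = labels.area_mm2(region)
        records.append(
            {
                "region": region.name,
                "n_vessels": counts[region],
                "density_per_mm2": (counts[region] / area) if area > 0 else math.nan,
                "mean_perimeter_um": (
                    float(np.mean(perims[region])) if perims[region] else math.nan
                ),
            }
        )
    return VesselMetrics(table=pd.DataFrame(records), n_unassigned=n_unassigned)


def measure_sample(
    image: CalibratedImage,
    masks: Mapping[str, BinaryMask],
    seeds,
    labels: RegionLabelMap,
    vessels: Sequence = (),
    group: str = "",
    cell_labels: "CellLabelMap | None" = None,
    coloc_pairs: Sequence[tuple[str, str]] = DEFAULT_COLOC_PAIRS,
) -> SampleMeasurements:
    """Assemble one sample's full long-format measurement table.

    Emits, per tissue region: one positive-area-fraction row per marker
    mask, one co-localization-ratio row per marker pair, plus the ICL
    intimal cell density and the vessel density of every region.  Missing
    values (e.g. a ratio with an empty parent) are flagged, never silently
    zero.  ``cell_labels`` is accepted for interface completeness; the
    area- and density-type outputs here do not require it (see
    :func:`per_cell_marker_positivity` for the cell-level view).
    """
    for name, m in masks.items():
        if m.shape != image.shape:
            raise ValueError(f"mask {name!r} shape {m.shape} != image {image.shape}")
    if labels.shape != image.shape:
        raise ValueError("label map shape differs from image shape")
    if abs(labels.pixel_size_um - image.pixel_size_um) > 1e-9:
        raise ValueError("label map and image disagree on pixel size")

    sm = SampleMeasurements(sample_id=image.sample_id, group=group)
    for region in TISSUE_REGIONS:
        for marker, mask in masks.items():
            frac = positive_area_fraction(mask, labels, region)
            sm.rows.append(
                MeasurementRow(region.name, f"{marker}_area_fraction", frac, "%")
            )
        for parent, other in coloc_pairs:
            if parent not in masks or other not in masks:
                continue
            both = colocalize(masks[parent], masks[other])
            ratio = coloc_ratio(masks[parent], both, labels, region)
            sm.rows.append(
                MeasurementRow(
                    region.name,
                    f"{parent}+{other}_ratio",
                    ratio,
                    "%",
                    flag="missing" if math.isnan(ratio) else "ok",
                )
            )
    density = count_seed_density(seeds, RegionClass.ICL, labels)
    sm.rows.append(
        MeasurementRow(RegionClass.ICL.name, "cell_density", density, "cells/mm^2")
    )
    vm = vessel_metrics(vessels, labels)
    for rec in vm.table.to_dict("records"):
        sm.rows.append(
            MeasurementRow(
                rec["region"],
                "vessel_density",
                rec["density_per_mm2"],
                "BV/mm^2",
                flag="missing" if math.isnan(rec["density_per_mm2"]) else "ok",
            )
        )
    return sm


def per_cell_marker_positivity(
    cell_labels: CellLabelMap, masks: Mapping[str, BinaryMask], min_fraction: float = 0.1
) -> pd.DataFrame:
    """Secondary, cell-count-based view: marker positivity per cell mask.

    A cell is counted positive for a marker when at least ``min_fraction``
    of its mask pixels are signal-positive.  Kept clearly separate from the
    area-based ratios, which are the primary outputs.
    """
    records = []
    for k in range(1, cell_labels.n_cells + 1):
        cm = cell_labels.cell_mask(k)
        npix = int(cm.sum())
        rec: dict = {"cell": k, "n_pixels": npix}
        for marker, mask in masks.items():
            frac = (int((_mask_array(mask) & cm).sum()) / npix) if npix else math.nan
            rec[f"{marker}_fraction"] = frac
            rec[f"{marker}_positive"] = bool(npix and frac >= min_fraction)
        records.append(rec)
    return pd.DataFrame(records)
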