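"""Core container types shared across the pipeline.

Conventions used everywhere in this package:

* images are row-major 2-D arrays, origin at the top-left;
* a point is an ``(x, y)`` pair with ``x`` = column and ``y`` = row,
  0-based, pixel centers at integer coordinates;
* physical calibration is an isotropic pixel edge length in micrometres,
  so one pixel covers ``(pixel_size_um / 1000)**2`` mm^2.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RegionClass",
    "TISSUE_REGIONS",
    "RASTER_PAINT_ORDER",
    "CalibratedImage",
    "RegionLabelMap",
    "BinaryMask",
    "CellLabelMap",
    "MeasurementRow",
    "SampleMeasurements",
]


class RegionClass(enum.IntEnum):
    """Tissue-region partition labels.

    ICL is the intimal cell layer (the apical two-to-three-cell lining of a
    synovial villus), SI_V the subintimal layer of the villous region, SI_N
    the subintimal layer not associated with a villus.  EXCLUDED marks
    damaged tissue / processing artefacts that must never enter any
    numerator or denominator.
    """

    BACKGROUND = 0
    ICL = 1
    SI_V = 2
    SI_N = 3
    EXCLUDED = 4


#: regions over which metrics are reported
TISSUE_REGIONS = (RegionClass.ICL, RegionClass.SI_V, RegionClass.SI_N)

#: rasterization paint order, lowest precedence first; later classes
#: overwrite earlier ones, implementing EXCLUDED > ICL > SI_V > SI_N
RASTER_PAINT_ORDER = (
    RegionClass.SI_N,
    RegionClass.SI_V,
    RegionClass.ICL,
    RegionClass.EXCLUDED,
)


def as_region(value: "RegionClass | str | int") -> RegionClass:
    """Coerce a region given as enum, name string or integer code."""
    if isinstance(value, RegionClass):
        return value
    if isinstance(value, str):
        try:
            return RegionClass[value.replace("-", "_").upper()]
        except KeyError:
            raise ValueError(
                f"unknown region class {value!r}; expected one of "
                f"{[r.name for r in RegionClass]}"
            ) from None
    return RegionClass(value)


@dataclass
class CalibratedImage:
    """Named grayscale fluorescence channels with physical pixel size."""

    channels: Mapping[str, np.ndarray]
    pixel_size_um: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {name: np.asarray(ch).shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        self.channels = {name: np.asarray(ch) for name, ch in self.channels.items()}
        for name, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def mm2_per_pixel(self) -> float:
        return (self.pixel_size_um / 1000.0) ** 2


@dataclass
class RegionLabelMap:
    """Rasterized tissue-region partition; exactly one label per pixel."""

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def mm2_per_pixel(self) -> float:
        return (self.pixel_size_um / 1000.0) ** 2

    def region_mask(self, region: RegionClass | str) -> np.ndarray:
        return self.labels == int(as_region(region))

    def pixel_count(self, region: RegionClass | str) -> int:
        return int(self.region_mask(region).sum())

    def area_mm2(self, region: RegionClass | str) -> float:
        """Region area in mm^2: pixel count times pixel area."""
        return self.pixel_count(region) * self.mm2_per_pixel


@dataclass
class BinaryMask:
    """Binary marker mask from locally adaptive thresholding."""

    mask: np.ndarray
    channel_name: str = ""
    window_px: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class CellLabelMap:
    """Per-cell pixel masks from radius-constrained nearest-seed watershed.

    ``labels[r, c] == k`` assigns the pixel to seed ``k`` (1-based); 0 means
    no cell.  Every labelled pixel lies within ``radius_px`` of its own seed
    and cells are pairwise disjoint by construction.
    """

    labels: np.ndarray
    seeds: np.ndarray
    radius_px: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.seeds = np.asarray(self.seeds, dtype=float).reshape(-1, 2)
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")

    @property
    def n_cells(self) -> int:
        return len(self.seeds)

    def cell_mask(self, k: int) -> np.ndarray:
        """Boolean mask of cell ``k`` (1-based seed index)."""
        if not 1 <= k <= self.n_cells:
            raise IndexError(f"cell index {k} out of range 1..{self.n_cells}")
        return self.labels == k


@dataclass
class MeasurementRow:
    region: str
    variable: str
    value: float
    units: str
    flag: str = "ok"  # "ok" or "missing"


@dataclass
class SampleMeasurements:
    """Long-format per-sample metrics table (region x variable)."""

    sample_id: str
    group: str
    rows: list[MeasurementRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": self.sample_id,
                    "group": self.group,
                    "region": r.region,
                    "variable": r.variable,
                    "value": r.value,
                    "units": r.units,
                    "flag": r.flag,
                }
                for r in self.rows
            ]
        )

    def value(self, region: str, variable: str) -> float:
        for r in self.rows:
            if r.region == region and r.variable == variable:
                return r.value
        raise KeyError((region, variable))
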