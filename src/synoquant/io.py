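"""Reading and writing the pipeline's on-disk formats.

* Images: multi-page TIFF, one 16-bit page per channel, the channel name
  and calibration in each page's JSON description.
* Region and vessel annotations: GeoJSON FeatureCollections in pixel
  coordinates (x = column, y = row), region features carrying a
  ``region_class`` property, vessels ``kind: "vessel"``.
* Cell seeds: CSV ``sample_id,x,y``.
* Analytes: CSV ``sample_id,group,analyte,value,lod``.
* Measurements / statistics: CSV with a leading ``# config_hash=...``
  comment line so outputs from different configurations cannot be mixed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon, mapping, shape as shapely_shape

from .types import CalibratedImage, RegionClass, RegionLabelMap, as_region

__all__ = [
    "write_image_tiff",
    "read_image_tiff",
    "write_label_map_tiff",
    "regions_to_geojson",
    "geojson_to_regions",
    "vessels_to_geojson",
    "geojson_to_vessels",
    "write_seeds_csv",
    "read_seeds_csv",
    "write_table_csv",
    "read_table_csv",
]


def _to_uint16(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint16:
        return arr
    a = np.asarray(arr, dtype=float)
    if a.size and a.max() > 1.0:
        raise ValueError("float channels must be in [0, 1] for 16-bit export")
    return np.round(np.clip(a, 0.0, 1.0) * 65535.0).astype(np.uint16)


def write_image_tiff(image: CalibratedImage, path) -> None:
    """One 16-bit page per channel; JSON page descriptions carry the
    channel name, pixel size and sample id."""
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for name, ch in image.channels.items():
            desc = json.dumps(
                {
                    "channel": name,
                    "pixel_size_um": image.pixel_size_um,
                    "sample_id": image.sample_id,
                }
            )
            tif.write(_to_uint16(ch), description=desc, contiguous=False)


def read_image_tiff(path) -> CalibratedImage:
    channels: dict[str, np.ndarray] = {}
    pixel_size = None
    sample_id = ""
    with tifffile.TiffFile(path) as tif:
        for i, page in enumerate(tif.pages):
            meta = json.loads(page.description)
            channels[meta["channel"]] = page.asarray()
            pixel_size = float(meta["pixel_size_um"])
            sample_id = meta.get("sample_id", "")
    if pixel_size is None:
        raise ValueError(f"{path}: no channel pages found")
    return CalibratedImage(channels=channels, pixel_size_um=pixel_size, sample_id=sample_id)


def write_label_map_tiff(labels: RegionLabelMap, path) -> None:
    """Label map as a single-page 8-bit TIFF (enum codes 0-4) with a JSON
    area summary in the description."""
    areas = {r.name: labels.area_mm2(r) for r in RegionClass}
    desc = json.dumps({"pixel_size_um": labels.pixel_size_um, "area_mm2": areas})
    tifffile.imwrite(path, labels.labels.astype(np.uint8), description=desc)


# -------------------------------------------------------------------- GeoJSON


def _polygon_feature(poly: Polygon, properties: dict) -> dict:
    return {"type": "Feature", "geometry": mapping(poly), "properties": properties}


def regions_to_geojson(
    region_polygons: Iterable[tuple[RegionClass, Polygon]]
) -> dict:
    """FeatureCollection with one Feature per region polygon, property
    ``region_class`` in {ICL, SI_V, SI_N, EXCLUDED}; pixel coordinates."""
    return {
        "type": "FeatureCollection",
        "features": [
            _polygon_feature(poly, {"region_class": as_region(cls).name})
            for cls, poly in region_polygons
        ],
    }


def geojson_to_regions(doc: dict) -> list[tuple[RegionClass, Polygon]]:
    out = []
    for feat in doc.get("features", []):
        cls = as_region(feat["properties"]["region_class"])
        out.append((cls, shapely_shape(feat["geometry"])))
    return out


def vessels_to_geojson(vessels: Iterable[tuple[RegionClass, Polygon]]) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            _polygon_feature(
                poly, {"kind": "vessel", "region_class": as_region(cls).name}
            )
            for cls, poly in vessels
        ],
    }


def geojson_to_vessels(doc: dict) -> list[Polygon]:
    return [
        shapely_shape(feat["geometry"])
        for feat in doc.get("features", [])
        if feat.get("properties", {}).get("kind") == "vessel"
    ]


def dump_geojson(doc: dict, path) -> None:
    Path(path).write_text(json.dumps(doc, sort_keys=True) + "\n")


def load_geojson(path) -> dict:
    return json.loads(Path(path).read_text())


# ------------------------------------------------------------------------ CSV


def write_seeds_csv(seeds, sample_id: str, path) -> None:
    pts = np.asarray(seeds, dtype=float).reshape(-1, 2)
    df = pd.DataFrame({"sample_id": sample_id, "x": pts[:, 0], "y": pts[:, 1]})
    df.to_csv(path, index=False)


def read_seeds_csv(path, sample_id: "str | None" = None) -> np.ndarray:
    df = pd.read_csv(path)
    if sample_id is not None:
        df = df[df["sample_id"] == sample_id]
    return df[["x", "y"]].to_numpy(dtype=float)


def write_table_csv(df: pd.DataFrame, path, config_hash: "str | None" = None) -> None:
    """CSV with an optional leading ``# config_hash=`` line binding the
    file to the configuration that produced it."""
    path = Path(path)
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def read_table_csv(path, expect_hash: "str | None" = None) -> pd.DataFrame:
    path = Path(path)
    file_hash = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# config_hash="):
        file_hash = first.strip().split("=", 1)[1]
    if expect_hash is not None and file_hash is not None and file_hash != expect_hash:
        raise ValueError(
            f"{path}: config hash {file_hash} does not match expected {expect_hash}; "
            "refusing to mix outputs from different runs"
        )
    return pd.read_csv(path, comment="#")
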