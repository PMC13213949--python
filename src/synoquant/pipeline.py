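"""Configured, logged, reproducible runs: simulate -> quantify -> stats.

A :class:`RunConfig` collects every tunable of the analysis with the
published defaults (adaptive-threshold half-width 50 px, cell radius 15 px,
alpha = 0.050).  Its hash is written into the header of every tabular
output; downstream stages refuse to consume tables whose hash differs from
the configuration they were launched with.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .quantify import measure_sample
from .roi import assign_points, rasterize_regions
from .segmentation import cell_masks_from_seeds, local_adaptive_binarize
from .stats import compare_analytes, compare_groups, censor_below_lod
from .synthetic import (
    DEFAULT_GROUP_SIZES,
    TissueScenario,
    make_cohort,
    scenario_presets,
)
from .types import CalibratedImage, RegionClass

__all__ = ["RunConfig", "run_simulate", "run_quantify", "run_stats", "run_full"]

log = logging.getLogger("synoquant")

DEFAULT_MARKERS = ("CD14", "CD16", "CD206")


@dataclass
class RunConfig:
    """Analysis configuration; defaults are the published parameters."""

    pixel_size_um: float = 0.5
    window_px: int = 50
    cell_radius_px: int = 15
    alpha: float = 0.050
    rng_seed: int = 0
    scenario: str = "default"
    scenario_file: "str | None" = None
    n_per_group: "int | None" = None  # None = emulated cohort (10/11/9)
    noise_level: float = 0.05
    illumination_gradient_amplitude: float = 0.2
    channel_to_marker: Mapping[str, str] = field(
        default_factory=lambda: {m: m for m in DEFAULT_MARKERS}
    )
    # paths are bookkeeping, not analysis parameters: excluded from the hash
    input_dir: "str | None" = None
    out_dir: "str | None" = None

    _NON_HASHED = ("input_dir", "out_dir")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_to_marker"] = dict(self.channel_to_marker)
        return d

    @property
    def config_hash(self) -> str:
        d = {k: v for k, v in self.to_dict().items() if k not in self._NON_HASHED}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def scenarios(self) -> dict[str, TissueScenario]:
        """Resolve the scenario preset name or custom scenario file."""
        if self.scenario_file:
            raw = yaml.safe_load(Path(self.scenario_file).read_text())
            return {
                group: TissueScenario(group_label=group, **params)
                for group, params in raw.items()
            }
        if self.scenario != "default":
            raise ValueError(
                f"unknown scenario {self.scenario!r}; available: ['default']"
            )
        return scenario_presets(
            pixel_size_um=self.pixel_size_um,
            noise_level=self.noise_level,
            illumination_gradient_amplitude=self.illumination_gradient_amplitude,
        )


def _prepare_out_dir(out_dir, force: bool) -> Path:
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out} is not empty (use force=True / --force)"
        )
    out.mkdir(parents=True, exist_ok=True)
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_simulate(config: RunConfig, out_dir, force: bool = False) -> Path:
    """Generate a synthetic cohort on disk and return the manifest path.

    Writes per-sample multi-page TIFFs, region/vessel GeoJSON, intimal seed
    CSVs, the cohort analyte table, and a manifest recording the seed, the
    config hash and annotation checksums.
    """
    t0 = time.perf_counter()
    out = _prepare_out_dir(out_dir, force)
    (out / "images").mkdir(exist_ok=True)
    (out / "annotations").mkdir(exist_ok=True)
    (out / "seeds").mkdir(exist_ok=True)

    cohort = make_cohort(
        config.scenarios(), n_per_group=config.n_per_group, rng_seed=config.rng_seed
    )
    samples_meta = []
    for s in cohort.samples:
        img_path = out / "images" / f"{s.sample_id}.tif"
        sio.write_image_tiff(s.image, img_path)
        reg_path = out / "annotations" / f"{s.sample_id}.regions.geojson"
        sio.dump_geojson(sio.regions_to_geojson(s.section.region_polygons), reg_path)
        ves_path = out / "annotations" / f"{s.sample_id}.vessels.geojson"
        sio.dump_geojson(sio.vessels_to_geojson(s.section.vessels), ves_path)
        seed_path = out / "seeds" / f"{s.sample_id}.seeds.csv"
        sio.write_seeds_csv(s.section.icl_seeds(), s.sample_id, seed_path)
        samples_meta.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "image": img_path.name,
                "regions": reg_path.name,
                "vessels": ves_path.name,
                "seeds": seed_path.name,
                "checksums": {
                    "regions": _sha256(reg_path),
                    "vessels": _sha256(ves_path),
                    "seeds": _sha256(seed_path),
                },
            }
        )
    sio.write_table_csv(cohort.analytes, out / "analytes.csv", config.config_hash)

    groups = sorted({s.group for s in cohort.samples})
    manifest = {
        "config_hash": config.config_hash,
        "rng_seed": config.rng_seed,
        "config": config.to_dict(),
        "groups": groups,
        "n_per_group": {
            g: sum(1 for s in cohort.samples if s.group == g) for g in groups
        },
        "samples": samples_meta,
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    log.info("simulate: %d samples in %.1fs", len(samples_meta), manifest["elapsed_s"])
    return manifest_path


def _quantify_one(
    config: RunConfig, cohort_dir: Path, meta: dict
) -> tuple[pd.DataFrame, dict]:
    sid = meta["sample_id"]
    image = sio.read_image_tiff(cohort_dir / "images" / meta["image"])
    regions = sio.geojson_to_regions(
        sio.load_geojson(cohort_dir / "annotations" / meta["regions"])
    )
    vessels = sio.geojson_to_vessels(
        sio.load_geojson(cohort_dir / "annotations" / meta["vessels"])
    )
    seeds = sio.read_seeds_csv(cohort_dir / "seeds" / meta["seeds"], sample_id=sid)
    labels = rasterize_regions(regions, image.shape, image.pixel_size_um)
    masks = {
        marker: local_adaptive_binarize(
            image.channels[channel], window_px=config.window_px, channel_name=marker
        )
        for channel, marker in config.channel_to_marker.items()
        if channel in image.channels
    }
    cell_labels = cell_masks_from_seeds(
        seeds, image.shape, radius_px=config.cell_radius_px
    )
    sm = measure_sample(
        image, masks, seeds, labels, vessels, group=meta["group"],
        cell_labels=cell_labels,
    )
    assignment = assign_points(seeds, labels)
    qc = {
        "sample_id": sid,
        "n_seeds": int(len(seeds)),
        "n_unassigned_seeds": int(np.sum(~assignment.assigned)),
        "n_out_of_bounds_seeds": assignment.n_out_of_bounds,
        "mask_window_px": {m: masks[m].window_px for m in masks},
    }
    if "ISO" in image.channels:  # isotype control: QC positive fraction only
        iso = local_adaptive_binarize(
            image.channels["ISO"], window_px=config.window_px, channel_name="ISO"
        )
        tissue = labels.labels != int(RegionClass.BACKGROUND)
        qc["isotype_positive_fraction"] = float(
            (iso.mask & tissue).sum() / max(tissue.sum(), 1)
        )
    return sm.to_frame(), qc


def run_quantify(config: RunConfig, cohort_dir, out_dir) -> Path:
    """Measure every sample listed in the cohort manifest.

    Writes ``measurements.csv`` (long format, config-hash header) and a
    per-sample QC JSON.  Any per-sample failure aborts, naming the stage
    and the sample.
    """
    t0 = time.perf_counter()
    cohort_dir = Path(cohort_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    frames, qcs = [], []
    for meta in manifest["samples"]:
        try:
            frame, qc = _quantify_one(config, cohort_dir, meta)
        except Exception as e:
            raise RuntimeError(
                f"stage 'quantify' failed for sample {meta['sample_id']}: {e}"
            ) from e
        frames.append(frame)
        qcs.append(qc)
    measurements = pd.concat(frames, ignore_index=True)
    meas_path = out / "measurements.csv"
    sio.write_table_csv(measurements, meas_path, config.config_hash)
    (out / "qc.json").write_text(json.dumps(qcs, indent=1, sort_keys=True) + "\n")
    log.info(
        "quantify: %d samples, %d rows in %.1fs",
        len(qcs), len(measurements), time.perf_counter() - t0,
    )
    return meas_path


def _boxplot_data(measurements: pd.DataFrame) -> list[dict]:
    """Quartiles and 1.5*IQR whiskers per group x region x variable."""
    rows = []
    ok = measurements[measurements["flag"] != "missing"]
    for (variable, region, group), sub in ok.groupby(
        ["variable", "region", "group"], sort=False
    ):
        v = sub["value"].dropna().to_numpy()
        if len(v) == 0:
            continue
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo = float(v[v >= q1 - 1.5 * iqr].min())
        hi = float(v[v <= q3 + 1.5 * iqr].max())
        rows.append(
            {
                "variable": variable, "region": region, "group": group,
                "n": int(len(v)), "q1": float(q1), "median": float(med),
                "q3": float(q3), "whisker_low": lo, "whisker_high": hi,
            }
        )
    return rows


def run_stats(
    config: RunConfig, measurements_path, analytes_path, out_dir
) -> Path:
    """Group statistics for every measured variable and testable analyte.

    Consumes ``measurements.csv`` (+ analyte CSV), verifying config hashes;
    emits ``stats_report.csv`` (one row per variable x region x pair) and a
    JSON summary including the below-LOD block and boxplot data.
    """
    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    measurements = sio.read_table_csv(measurements_path, expect_hash=config.config_hash)
    analytes = sio.read_table_csv(analytes_path, expect_hash=config.config_hash)

    results, skipped = [], {}
    for (variable, region), _ in measurements.groupby(["variable", "region"], sort=False):
        try:
            res = compare_groups(
                measurements, variable, region=region, alpha=config.alpha
            )
        except ValueError as e:
            skipped[f"{variable}[{region}]"] = str(e)
            continue
        results.append(res)

    censored = censor_below_lod(analytes)
    analyte_results, analyte_report = compare_analytes(censored, alpha=config.alpha)
    results.extend(analyte_results)

    report = pd.concat(
        [r.to_frame() for r in results], ignore_index=True
    ) if results else pd.DataFrame()
    report_path = out / "stats_report.csv"
    sio.write_table_csv(report, report_path, config.config_hash)
    summary = {
        "config_hash": config.config_hash,
        "alpha": config.alpha,
        "omnibus": [
            {
                "variable": r.variable,
                "region": r.region,
                "test": r.omnibus_test,
                "p": r.omnibus_p,
                "descriptive_form": r.descriptives.form,
                "significant": bool(r.significant),
            }
            for r in results
        ],
        "below_lod": analyte_report,
        "skipped": skipped,
        "boxplot_data": _boxplot_data(measurements),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    (out / "stats_summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n"
    )
    log.info("stats: %d comparisons in %.1fs", len(results), summary["elapsed_s"])
    return report_path


def run_full(config: RunConfig, out_dir, force: bool = False) -> dict[str, Path]:
    """simulate -> quantify -> stats in one configured, logged run."""
    out = Path(out_dir)
    cohort_dir = out / "cohort"
    stages: dict[str, Path] = {}
    if config.input_dir:
        cohort_dir = Path(config.input_dir)
    else:
        stages["manifest"] = run_simulate(config, cohort_dir, force=force)
    stages["measurements"] = run_quantify(config, cohort_dir, out)
    stages["stats_report"] = run_stats(
        config, stages["measurements"], cohort_dir / "analytes.csv", out
    )
    return stages
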