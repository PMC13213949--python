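"""Ground-truth generator: determinism, calibration, self-consistency,
rendering contracts, cohort assembly."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from synoquant import RegionClass, assign_points, generate_section, render_channels
from synoquant.io import regions_to_geojson
from synoquant.roi import villus_shape_check
from synoquant.synthetic import (
    DEFAULT_GROUP_SIZES,
    TissueScenario,
    default_analyte_panel,
    make_analyte_table,
    make_cohort,
    scenario_presets,
    true_marker_area_fractions,
)


def test_generation_is_deterministic(ctrl_scenario):
    a = generate_section(ctrl_scenario, rng_seed=42)
    b = generate_section(ctrl_scenario, rng_seed=42)
    assert a == b
    # annotation output is bitwise identical
    sa = json.dumps(regions_to_geojson(a.region_polygons), sort_keys=True)
    sb = json.dumps(regions_to_geojson(b.region_polygons), sort_keys=True)
    assert sa == sb
    c = generate_section(ctrl_scenario, rng_seed=43)
    assert not (a == c)


def test_zero_marker_probs_give_all_negative_cells(ctrl_scenario):
    scenario = TissueScenario(
        group_label="CTRL",
        marker_probs={r: {m: 0.0 for m in ctrl_scenario.markers} for r in ("ICL", "SI_V", "SI_N")},
        coloc_probs={},
        cell_density_per_mm2=ctrl_scenario.cell_density_per_mm2,
        vessel_density_per_mm2={},
    )
    sec = generate_section(scenario, rng_seed=1)
    assert sec.n_cells > 0
    for flags in sec.marker_flags.values():
        assert not flags.any()


def test_cell_centers_reproduce_their_region(ctrl_scenario):
    for seed in (0, 1, 2):
        sec = generate_section(ctrl_scenario, seed)
        res = assign_points(sec.cells_xy, sec.label_map())
        assert np.array_equal(res.region_codes, sec.cell_regions.astype(np.int64))
        assert res.assigned.all()


def test_villus_taller_than_wide(ctrl_scenario):
    from shapely.ops import unary_union

    for seed in range(5):
        sec = generate_section(ctrl_scenario, seed)
        villus = unary_union(
            [p for c, p in sec.region_polygons if c in (RegionClass.ICL, RegionClass.SI_V)]
        )
        minx, miny, maxx, maxy = villus.bounds
        assert (maxy - miny) > (maxx - minx)
        assert villus_shape_check(villus.convex_hull.exterior.coords)


def test_poisson_counts_and_marker_calibration(ctrl_scenario):
    """Over 100 seeds, ICL cell counts follow density x area (Poisson), and
    the empirical marker-positive fraction per region sits within 3 SE of
    the configured marginal probability."""
    n_seeds = 100
    total_count = {r: 0 for r in ("ICL", "SI_V", "SI_N")}
    total_lambda = {r: 0.0 for r in ("ICL", "SI_V", "SI_N")}
    positives = {r: {m: 0 for m in ctrl_scenario.markers} for r in ("ICL", "SI_V", "SI_N")}
    for seed in range(n_seeds):
        sec = generate_section(ctrl_scenario, seed)
        lm = sec.label_map()
        for region in (RegionClass.ICL, RegionClass.SI_V, RegionClass.SI_N):
            name = region.name
            in_region = sec.cell_regions == int(region)
            total_count[name] += int(in_region.sum())
            total_lambda[name] += (
                ctrl_scenario.cell_density_per_mm2[name] * lm.area_mm2(region)
            )
            for m in ctrl_scenario.markers:
                positives[name][m] += int(sec.marker_flags[m][in_region].sum())
    for name in total_count:
        lam = total_lambda[name]
        assert abs(total_count[name] - lam) < 4 * np.sqrt(lam)
        for m in ctrl_scenario.markers:
            p = ctrl_scenario.marker_probs[name][m]
            n = total_count[name]
            se = np.sqrt(p * (1 - p) / n)
            assert abs(positives[name][m] / n - p) < 3 * se + 1e-12


def test_scenario_validation():
    base = scenario_presets()["F"]
    with pytest.raises(ValueError, match="pixel_size_um"):
        TissueScenario("F", base.marker_probs, base.coloc_probs,
                       base.cell_density_per_mm2, {}, pixel_size_um=0.0)
    with pytest.raises(ValueError, match="ICL cell density"):
        TissueScenario("F", base.marker_probs, base.coloc_probs,
                       {"ICL": 0.0}, {})
    with pytest.raises(ValueError, match="inconsistent"):
        TissueScenario(
            "F",
            {"ICL": {"CD14": 0.9, "CD16": 0.1}},
            {"ICL": {"CD16|CD14": 0.9}},  # implies P(CD16) >= 0.81 > 0.1
            base.cell_density_per_mm2,
            {},
        )
    small = TissueScenario("F", base.marker_probs, base.coloc_probs,
                           base.cell_density_per_mm2, {}, image_shape=(256, 256))
    with pytest.raises(ValueError, match="512"):
        generate_section(small, 0)


def test_render_zero_cells_is_blank(ctrl_scenario, ctrl_section):
    from dataclasses import replace

    empty = replace(
        ctrl_section,
        cells_xy=np.empty((0, 2)),
        cell_regions=np.empty(0, dtype=np.uint8),
        marker_flags={m: np.empty(0, dtype=bool) for m in ctrl_scenario.markers},
    )
    img = render_channels(empty, ctrl_scenario, rng_seed=0)
    for ch in img.channels.values():
        assert not ch.any()


def test_render_single_positive_cell_peak_location(ctrl_scenario, ctrl_section):
    from dataclasses import replace

    center = np.array([[250.3, 150.7]])
    one = replace(
        ctrl_section,
        cells_xy=center,
        cell_regions=np.array([int(RegionClass.SI_V)], dtype=np.uint8),
        marker_flags={
            "CD14": np.array([True]),
            "CD16": np.array([False]),
            "CD206": np.array([False]),
        },
    )
    quiet = replace(
        ctrl_scenario, noise_level=0.0, illumination_gradient_amplitude=0.0
    )
    img = render_channels(one, quiet, rng_seed=3)
    ch = img.channels["CD14"]
    r, c = np.unravel_index(np.argmax(ch), ch.shape)
    assert np.hypot(c - 250.3, r - 150.7) <= 2.0
    assert not img.channels["CD16"].any()
    assert not img.channels["CD206"].any()


def test_dapi_blob_count_matches_cells_on_sparse_layout(ctrl_scenario, ctrl_section):
    """Noise-free render of well-separated nuclei: connected components
    above half-max equal the number of cells."""
    from dataclasses import replace

    xs, ys = np.meshgrid(np.arange(60, 460, 50), np.arange(60, 400, 50))
    centers = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    n = len(centers)  # spacing 50 px >> 4 * sigma (12 px)
    quiet = replace(
        ctrl_scenario, noise_level=0.0, illumination_gradient_amplitude=0.0
    )
    sec = replace(
        ctrl_section,
        cells_xy=centers,
        cell_regions=np.full(n, int(RegionClass.SI_V), dtype=np.uint8),
        marker_flags={m: np.zeros(n, dtype=bool) for m in ctrl_scenario.markers},
    )
    img = render_channels(sec, quiet, rng_seed=5, quantize=False)
    dapi = img.channels["DAPI"]
    _, count = ndimage.label(dapi > 0.5 * dapi.max())
    assert count == n


def test_make_cohort_counts_ids_and_determinism():
    presets = scenario_presets()
    cohort = make_cohort(presets, n_per_group=3, rng_seed=11, render=False)
    assert len(cohort.samples) == 9
    ids = [s.sample_id for s in cohort.samples]
    assert len(set(ids)) == 9
    again = make_cohort(presets, n_per_group=3, rng_seed=11, render=False)
    pd.testing.assert_frame_equal(cohort.analytes, again.analytes)
    assert cohort.samples[0].section == again.samples[0].section
    default = make_cohort(presets, rng_seed=1, render=False)
    sizes = pd.Series([s.group for s in default.samples]).value_counts().to_dict()
    assert sizes == DEFAULT_GROUP_SIZES


def test_forced_below_lod_analytes_fully_censored(rng):
    panel = default_analyte_panel()
    table = make_analyte_table(panel, {f"s{i}": "CTRL" for i in range(40)}, rng)
    below = {a.name for a in panel if a.below_lod}
    for name in below:
        sub = table[table["analyte"] == name]
        assert (sub["value"] < sub["lod"]).all()
    # and a non-censored analyte stays quantifiable in most samples
    tnf = table[table["analyte"] == "TNF-a"]
    assert (tnf["value"] >= tnf["lod"]).mean() > 0.9


def test_true_fraction_table_schema(ctrl_section):
    truth = true_marker_area_fractions(ctrl_section)
    assert set(truth["region"]) == {"ICL", "SI_V", "SI_N"}
    icl = truth[truth["region"] == "ICL"].set_index("variable")["value"]
    assert 0 <= icl["CD14_area_fraction"] <= 100
    assert icl["cell_density"] > 0
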