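# synoquant

Region-stratified quantification of immunofluorescence-stained synovial
tissue, with a synthetic ground-truth tissue generator and normality-gated
group statistics.

Synovitis — inflammation of the soft-tissue lining of joint capsules — is a
driver of osteoarthritis, and macrophage surface markers (CD14, CD16,
CD206) on the synovial membrane are candidate readouts of joint state.
`synoquant` implements the measurement chain such studies use, for anyone
who needs reproducible, testable histomorphometry of multi-channel slide
scans: researchers quantifying marker expression across manually delineated
tissue regions, and method developers who want every stage validated
against exact synthetic ground truth.

## What it computes

Per sample, stratified over three manually delineated regions of interest —
the intimal cell layer (**ICL**, the apical 2–3-cell lining of a synovial
villus), the villous subintima (**SI-V**) and the non-villous subintima
(**SI-N**), with **EXCLUDED** artefact zones removed from every numerator
and denominator:

* **Marker-positive area fraction** per region R and binary mask M from
  locally adaptive thresholding (pixel positive iff it strictly exceeds the
  local mean over a 101×101 window):
  `100 · |M ∩ R| / |R|`  (%)
* **Co-localization ratio** for a marker pair, with the double-positive
  mask the product of the two binary masks:
  `100 · |M_A ∩ M_B ∩ R| / |M_A ∩ R|`  (%) —
  e.g. CD14⁺ area 10, CD14⁺CD16⁺ area 8 → 80 %.
* **Intimal cell density**: manually punctuated cell centers assigned to
  regions, `n_ICL / area_mm²(ICL)` (cells/mm²), with per-cell masks from a
  radius-constrained (15 px) nearest-seed watershed.
* **Vessel density and perimeter**: outline polygons assigned by centroid,
  count/mm² and mean arc length in µm.

Cohort statistics follow a Shapiro-Wilk gate per group (α = 0.05): all
groups normal → mean ± SD, Welch t-test / ANOVA + Tukey HSD; otherwise
median [Q1–Q3], rank-sum / Kruskal-Wallis + Dunn (Bonferroni).  Analytes
below their limit of detection are censored; fully censored analytes are
reported in a below-LOD block instead of being tested.

Because real slides for this kind of study are not publicly deposited, the
package ships a synthetic generator (`synoquant.synthetic`) producing
villus-shaped sections with known per-cell marker truth, rendered
multi-channel 16-bit images, matching annotation files and analyte tables —
every pipeline stage is tested against it.  See `docs/methods.md` for the
model and its limits.

## Worked example

```python
from synoquant import (scenario_presets, generate_section, render_channels,
                       rasterize_regions, local_adaptive_binarize, measure_sample)

scenario = scenario_presets()["CTRL"]
section = generate_section(scenario, rng_seed=7)
image = render_channels(section, scenario, rng_seed=8, sample_id="CTRL-01")
labels = rasterize_regions(section.region_polygons, image.shape, image.pixel_size_um)
masks = {m: local_adaptive_binarize(image.channels[m], window_px=50, channel_name=m)
         for m in ("CD14", "CD16", "CD206")}
sm = measure_sample(image, masks, section.icl_seeds(), labels,
                    [poly for _, poly in section.vessels], group="CTRL")
print(sm.to_frame().head(5).to_string(index=False))
```

```
sample_id group region            variable     value units flag
  CTRL-01  CTRL    ICL  CD14_area_fraction  5.359925     %   ok
  CTRL-01  CTRL    ICL  CD16_area_fraction  4.356497     %   ok
  CTRL-01  CTRL    ICL CD206_area_fraction  2.455594     %   ok
  CTRL-01  CTRL    ICL     CD14+CD16_ratio 26.976744     %   ok
  CTRL-01  CTRL    ICL    CD14+CD206_ratio 45.813953     %   ok
```

CD14 signal covers 5.36 % of this section's intimal layer, and 26.98 % of
that CD14⁺ area is also CD16⁺.  Measuring a full default cohort
(F 10 / CTRL 11 / OA 9 samples) and comparing groups:

```python
from synoquant import compare_groups
res = compare_groups(measurements, "CD14_area_fraction", region="ICL")
print(res.summary())
```

```
CD14_area_fraction [ICL]  (alpha = 0.050)
----------------------------------------------------------------
       F  n=10  mean ± SD: 3.504 ± 1.144
    CTRL  n=11  mean ± SD: 4.924 ± 1.134
      OA  n=9   mean ± SD: 1.86 ± 0.759
  omnibus: one-way ANOVA + Tukey HSD  stat=21.45  p=2.647e-06
    F vs CTRL: p=0.004243 (adj 0.01144) *
    F vs OA: p=0.00192 (adj 0.005281) *
    CTRL vs OA: p=5.046e-07 (adj 1.482e-06) *
```

All three groups pass the normality gate, so the parametric path is taken;
the control group's CD14⁺ intimal area exceeds the OA group's
(Tukey-adjusted p ≈ 1.5·10⁻⁶), the ordering the presets are calibrated to.

The same pipeline runs from a shell:

```bash
synoquant run --seed 0 --out results/           # simulate → quantify → stats
synoquant simulate --n-per-group 3 --out cohort/
synoquant quantify --cohort cohort/ --window-px 50 --out results/
synoquant stats --measurements results/measurements.csv \
                --analytes cohort/analytes.csv --out results/
```

All published analysis parameters are flags with their published defaults
(`--window-px 50`, `--cell-radius-px 15`, `--alpha 0.050`); outputs carry a
configuration hash and stages refuse to mix outputs from different
configurations.

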