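"""Synthetic synovial tissue sections with known ground truth.

Generates villus-shaped tissue geometry (a finger-like projection, taller
than wide, rising from a basal subintimal band), an apical intimal-cell-layer
band, per-cell marker positivity drawn from region-specific probabilities,
vessel outlines, rendered multi-channel fluorescence images, and cohort-level
analyte tables with configurable detection limits.  Everything is a pure
function of (scenario, seed), so every downstream stage of the pipeline can
be tested against exact ground truth without real slides.

The renderer's optics model: DAPI nuclei are isotropic Gaussian blobs
(sigma 3 px at the default 0.5 um/px); marker stains are compact flat-top
blobs ``a * (1 - (d/R)^8)`` with support radius R = 6 px.  The flat-top
profile makes the thresholded marker area nearly identical to the true
union-of-disks footprint regardless of the local mean, which is what lets
ground-truth area fractions be recovered to within a fraction of a
percentage point (a Gaussian's recovered radius drifts logarithmically with
local signal density).  Intensities live in [0, 1] before optional 16-bit
quantization; a multiplicative smooth illumination gradient and Poisson
shot noise (variance set by ``noise_level``) are applied on top.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .roi import rasterize_regions
from .types import (
    TISSUE_REGIONS,
    CalibratedImage,
    RegionClass,
    RegionLabelMap,
)

__all__ = [
    "TissueScenario",
    "GroundTruthSection",
    "generate_section",
    "render_channels",
    "true_marker_area_fractions",
    "AnalyteSpec",
    "default_analyte_panel",
    "make_analyte_table",
    "CohortSample",
    "CohortBundle",
    "make_cohort",
    "scenario_presets",
    "DEFAULT_GROUP_SIZES",
    "DAPI_SIGMA_PX",
    "MARKER_BLOB_RADIUS_PX",
]

DAPI_SIGMA_PX = 3.0
MARKER_BLOB_RADIUS_PX = 6.0
#: cohort sizes of the emulated study (foals / control adults / OA adults)
DEFAULT_GROUP_SIZES = {"F": 10, "CTRL": 11, "OA": 9}

_REGION_KEYS = ("ICL", "SI_V", "SI_N")


@dataclass(frozen=True)
class TissueScenario:
    """Study conditions for one group's synthetic sections.

    ``marker_probs[region][marker]`` is the *marginal* probability that a
    cell of that region is positive for the marker.
    ``coloc_probs[region]["B|A"]`` is the conditional probability that a
    cell already positive for A is also positive for B; the negative branch
    is chosen so the configured marginal of B is preserved exactly, which
    requires ``P(A)*P(B|A) <= P(B) <= P(A)*P(B|A) + (1 - P(A))``.
    Densities are per mm^2; ``noise_level`` is the relative shot-noise SD at
    unit intensity; the illumination gradient amplitude is the fractional
    drop of the multiplicative shading field across the image.
    """

    group_label: str
    marker_probs: Mapping[str, Mapping[str, float]]
    coloc_probs: Mapping[str, Mapping[str, float]]
    cell_density_per_mm2: Mapping[str, float]
    vessel_density_per_mm2: Mapping[str, float]
    pixel_size_um: float = 0.5
    noise_level: float = 0.05
    illumination_gradient_amplitude: float = 0.2
    image_shape: tuple[int, int] = (512, 512)
    markers: tuple[str, ...] = ("CD14", "CD16", "CD206")
    icl_thickness_px: float = 30.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")
        if not 0 <= self.illumination_gradient_amplitude < 1:
            raise ValueError("illumination_gradient_amplitude must be in [0, 1)")
        for region in _REGION_KEYS:
            probs = self.marker_probs.get(region, {})
            for marker, p in probs.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"marker_probs[{region}][{marker}] not in [0,1]")
            for pair, c in self.coloc_probs.get(region, {}).items():
                if not 0 <= c <= 1:
                    raise ValueError(f"coloc_probs[{region}][{pair}] not in [0,1]")
                b, a = _parse_pair(pair)
                pa, pb = probs.get(a, 0.0), probs.get(b, 0.0)
                if pa < 1:
                    q = (pb - pa * c) / (1 - pa)
                    if not -1e-12 <= q <= 1 + 1e-12:
                        raise ValueError(
                            f"coloc_probs[{region}][{pair}]={c} is inconsistent "
                            f"with marginals P({a})={pa}, P({b})={pb}"
                        )
        icl_density = self.cell_density_per_mm2.get("ICL", 0.0)
        if icl_density <= 0:
            raise ValueError("ICL cell density must be strictly positive")
        for region, d in self.vessel_density_per_mm2.items():
            if d < 0:
                raise ValueError(f"vessel density for {region} must be >= 0")


def _parse_pair(pair: str) -> tuple[str, str]:
    """``"CD16|CD14" -> ("CD16", "CD14")`` (B given A)."""
    b, _, a = pair.partition("|")
    if not a or not b:
        raise ValueError(f"co-expression pair {pair!r} must look like 'B|A'")
    return b, a


@dataclass
class GroundTruthSection:
    """One synthetic section's exact ground truth.

    ``cells_xy`` are cell centers (x = column, y = row); every center lies
    in a pixel carrying its recorded region class, so rasterizing
    ``region_polygons`` and querying the centers reproduces
    ``cell_regions`` exactly.
    """

    region_polygons: list[tuple[RegionClass, Polygon]]
    cells_xy: np.ndarray
    cell_regions: np.ndarray
    marker_flags: dict[str, np.ndarray]
    vessels: list[tuple[RegionClass, Polygon]]
    image_shape: tuple[int, int]
    pixel_size_um: float
    # generation-time raster, cached to avoid re-rasterizing; excluded
    # from equality comparisons
    labels: "RegionLabelMap | None" = field(default=None, compare=False, repr=False)

    @property
    def n_cells(self) -> int:
        return len(self.cells_xy)

    def cells_in(self, region: RegionClass) -> np.ndarray:
        return self.cells_xy[self.cell_regions == int(region)]

    def icl_seeds(self) -> np.ndarray:
        """Centers of intimal-lining cells — the manually punctuated seed
        set of the real workflow."""
        return self.cells_in(RegionClass.ICL)

    def label_map(self) -> RegionLabelMap:
        if self.labels is None:
            self.labels = rasterize_regions(
                self.region_polygons, self.image_shape, self.pixel_size_um
            )
        return self.labels

    def __eq__(self, other) -> bool:  # array-valued fields need np comparison
        if not isinstance(other, GroundTruthSection):
            return NotImplemented
        return (
            self.image_shape == other.image_shape
            and self.pixel_size_um == other.pixel_size_um
            and len(self.region_polygons) == len(other.region_polygons)
            and all(
                c1 == c2 and p1.equals_exact(p2, 0.0)
                for (c1, p1), (c2, p2) in zip(self.region_polygons, other.region_polygons)
            )
            and np.array_equal(self.cells_xy, other.cells_xy)
            and np.array_equal(self.cell_regions, other.cell_regions)
            and set(self.marker_flags) == set(other.marker_flags)
            and all(
                np.array_equal(v, other.marker_flags[k])
                for k, v in self.marker_flags.items()
            )
            and len(self.vessels) == len(other.vessels)
            and all(
                c1 == c2 and p1.equals_exact(p2, 0.0)
                for (c1, p1), (c2, p2) in zip(self.vessels, other.vessels)
            )
        )


# ------------------------------------------------------------------- geometry


def _halfwidth(u: np.ndarray, half_w: float, m: float = 2.5) -> np.ndarray:
    """Superellipse-like villus half-width profile: 0 at the tip (u = 0),
    ``half_w`` at the base (u = 1)."""
    return half_w * (1.0 - (1.0 - u) ** m) ** (1.0 / m)


def _villus_region_polygons(
    shape: tuple[int, int], rng: np.random.Generator, icl_thickness_px: float
) -> list[tuple[RegionClass, Polygon]]:
    """Layout emulating a scanned section: a basal subintimal band (SI_N),
    one villus (SI_V) with an apical intimal band (ICL), and one small
    EXCLUDED artefact patch in the basal band."""
    nrows, ncols = shape
    band_h = 0.22 * nrows
    ybase = nrows - band_h

    ytip = 0.06 * nrows + rng.uniform(0.0, 0.04 * nrows)
    height = ybase - ytip
    aspect = rng.uniform(1.2, 2.5)  # bounding-box height / width
    width = height / aspect
    half_w = width / 2.0
    cx = ncols / 2.0 + rng.uniform(-0.05, 0.05) * ncols
    cx = float(np.clip(cx, half_w + 5.0, ncols - half_w - 5.0))
    if half_w + 5.0 > ncols - half_w - 5.0 or half_w - icl_thickness_px < 12.0:
        raise ValueError(
            f"villus (width {width:.0f} px, intimal band {icl_thickness_px} px) "
            f"cannot fit an image of shape {shape}"
        )

    ybase_in = ybase + 2.0  # sink the base slightly into the band: no gap
    b = icl_thickness_px
    ytip_in = ytip + b
    half_w_in = half_w - b
    apical_frac = 0.8
    y_cut = ytip + apical_frac * height

    n_arc = 48
    u_outer = np.linspace(0.0, 1.0, n_arc)

    def outer_xy(u):
        return _halfwidth(u, half_w), ytip + u * (ybase_in - ytip)

    def inner_xy(u):
        return _halfwidth(u, half_w_in), ytip_in + u * (ybase_in - ytip_in)

    u_cut = (y_cut - ytip) / (ybase_in - ytip)
    u_cut_in = (y_cut - ytip_in) / (ybase_in - ytip_in)

    def arc(xy_fn, u_hi, descending=True):
        """Vertices along one side arc from u_hi down to the tip."""
        us = np.linspace(u_hi, 0.0, n_arc) if descending else np.linspace(0.0, u_hi, n_arc)
        hw, yy = xy_fn(us)
        return us, hw, yy

    # ICL: annular band between outer and inner outlines, apical part only
    _, hw_o, yy_o = arc(outer_xy, u_cut, descending=True)
    _, hw_i, yy_i = arc(inner_xy, u_cut_in, descending=False)
    icl = [(cx - w, y) for w, y in zip(hw_o, yy_o)]           # outer left, up to tip
    icl += [(cx + w, y) for w, y in zip(hw_o[::-1][1:], yy_o[::-1][1:])]  # outer right, down
    icl += [(cx + w, y) for w, y in zip(hw_i[::-1], yy_i[::-1])]  # inner right, up
    icl += [(cx - w, y) for w, y in zip(hw_i[1:], yy_i[1:])]      # inner left, down

    # SI_V: inner apical cap + outer flanks below the cut + base
    si_v = [(cx - w, y) for w, y in zip(hw_i[::-1], yy_i[::-1])]  # inner left, up
    si_v += [(cx + w, y) for w, y in zip(hw_i[1:], yy_i[1:])]     # inner right, down
    us_low = np.linspace(u_cut, 1.0, n_arc)
    hw_l, yy_l = outer_xy(us_low)
    si_v += [(cx + w, y) for w, y in zip(hw_l, yy_l)]             # outer right, to base
    si_v += [(cx - w, y) for w, y in zip(hw_l[::-1], yy_l[::-1])]  # base + outer left, up

    si_n = [
        (-0.5, ybase),
        (ncols - 0.5, ybase),
        (ncols - 0.5, nrows - 0.5),
        (-0.5, nrows - 0.5),
    ]

    ex_r = rng.uniform(12.0, 20.0)
    ex_x = rng.uniform(ex_r + 5.0, ncols - ex_r - 5.0)
    ex_y = rng.uniform(ybase + ex_r + 2.0, nrows - ex_r - 2.0)
    theta = np.linspace(0.0, 2.0 * np.pi, 33)[:-1]
    excluded = [(ex_x + ex_r * np.cos(t), ex_y + ex_r * np.sin(t)) for t in theta]

    polys = [
        (RegionClass.SI_N, Polygon(si_n)),
        (RegionClass.SI_V, Polygon(si_v)),
        (RegionClass.ICL, Polygon(icl)),
        (RegionClass.EXCLUDED, Polygon(excluded)),
    ]
    for cls, poly in polys:
        if not poly.is_valid:
            raise RuntimeError(f"generated {cls.name} polygon is invalid")
    return polys


# ------------------------------------------------------------------ generation


def generate_section(scenario: TissueScenario, rng_seed: int) -> GroundTruthSection:
    """Generate one section's geometry, cells, marker flags and vessels.

    Deterministic for a fixed seed.  Cell counts per region are Poisson
    with mean ``density * region_area``; positions are drawn uniformly over
    the region's pixels (jittered within the generating pixel, so the
    recorded region class is reproduced exactly by rasterization + floor
    assignment).  Marker flags follow the region's marginal probabilities,
    with co-expression pairs drawn via their conditional probabilities.
    """
    nrows, ncols = scenario.image_shape
    if nrows < 512 or ncols < 512:
        raise ValueError("image must be at least 512x512 px to contain a villus")
    rng = np.random.default_rng(rng_seed)
    polys = _villus_region_polygons(
        scenario.image_shape, rng, scenario.icl_thickness_px
    )
    labels = rasterize_regions(polys, scenario.image_shape, scenario.pixel_size_um)

    centers: list[np.ndarray] = []
    regions: list[np.ndarray] = []
    flags: dict[str, list[np.ndarray]] = {m: [] for m in scenario.markers}
    for region in TISSUE_REGIONS:
        area = labels.area_mm2(region)
        density = float(scenario.cell_density_per_mm2.get(region.name, 0.0))
        rr, cc = np.nonzero(labels.region_mask(region))
        n = int(rng.poisson(density * area))
        n = min(n, len(rr))
        if n == 0:
            continue
        idx = rng.choice(len(rr), size=n, replace=False)
        jx = rng.uniform(0.0, 0.9, size=n)
        jy = rng.uniform(0.0, 0.9, size=n)
        centers.append(np.column_stack([cc[idx] + jx, rr[idx] + jy]))
        regions.append(np.full(n, int(region), dtype=np.uint8))

        probs = scenario.marker_probs.get(region.name, {})
        coloc = scenario.coloc_probs.get(region.name, {})
        conditioned = {_parse_pair(pair)[0]: pair for pair in coloc}
        region_flags: dict[str, np.ndarray] = {}
        # fixed draw order (unconditioned markers first) = determinism
        for marker in scenario.markers:
            if marker in conditioned:
                continue
            region_flags[marker] = rng.random(n) < float(probs.get(marker, 0.0))
        for marker in scenario.markers:
            if marker not in conditioned:
                continue
            pair = conditioned[marker]
            _, a = _parse_pair(pair)
            if a not in region_flags:
                raise ValueError(
                    f"co-expression parent {a!r} of pair {pair!r} must be an "
                    "unconditioned marker"
                )
            p = float(probs.get(marker, 0.0))
            c = float(coloc[pair])
            pa = float(probs.get(a, 0.0))
            q = c if pa >= 1 else (p - pa * c) / (1.0 - pa)
            q = min(1.0, max(0.0, q))
            u = rng.random(n)
            region_flags[marker] = np.where(region_flags[a], u < c, u < q)
        for marker in scenario.markers:
            flags[marker].append(region_flags[marker])

    vessels: list[tuple[RegionClass, Polygon]] = []
    theta = np.linspace(0.0, 2.0 * np.pi, 33)[:-1]
    for region in TISSUE_REGIONS:
        density = float(scenario.vessel_density_per_mm2.get(region.name, 0.0))
        if density <= 0:
            continue
        area = labels.area_mm2(region)
        rr, cc = np.nonzero(labels.region_mask(region))
        n = min(int(rng.poisson(density * area)), len(rr))
        if n == 0:
            continue
        idx = rng.choice(len(rr), size=n, replace=False)
        radii = rng.uniform(6.0, 12.0, size=n)
        for k in range(n):
            vx, vy = cc[idx[k]] + 0.5, rr[idx[k]] + 0.5
            ring = [
                (vx + radii[k] * np.cos(t), vy + radii[k] * np.sin(t)) for t in theta
            ]
            vessels.append((region, Polygon(ring)))

    cells_xy = np.concatenate(centers) if centers else np.empty((0, 2))
    cell_regions = (
        np.concatenate(regions) if regions else np.empty(0, dtype=np.uint8)
    )
    marker_flags = {
        m: (np.concatenate(f) if f else np.empty(0, dtype=bool))
        for m, f in flags.items()
    }
    return GroundTruthSection(
        region_polygons=polys,
        cells_xy=cells_xy,
        cell_regions=cell_regions,
        marker_flags=marker_flags,
        vessels=vessels,
        image_shape=scenario.image_shape,
        pixel_size_um=scenario.pixel_size_um,
        labels=labels,
    )


# ------------------------------------------------------------------- rendering


def _stamp_max(img: np.ndarray, xy: np.ndarray, amps: np.ndarray, radius: float, profile) -> None:
    """Stamp radially symmetric blobs, combining overlaps with max
    (saturating-fluorophore model keeps intensities <= blob amplitude)."""
    nrows, ncols = img.shape
    r = int(math.ceil(radius))
    for (x, y), a in zip(xy, amps):
        r0, r1 = max(0, int(math.floor(y)) - r), min(nrows - 1, int(math.ceil(y)) + r)
        c0, c1 = max(0, int(math.floor(x)) - r), min(ncols - 1, int(math.ceil(x)) + r)
        if r0 > r1 or c0 > c1:
            continue
        yy = np.arange(r0, r1 + 1, dtype=float)[:, None] - y
        xx = np.arange(c0, c1 + 1, dtype=float)[None, :] - x
        patch = img[r0 : r1 + 1, c0 : c1 + 1]
        np.maximum(patch, a * profile(yy * yy + xx * xx), out=patch)


def _gauss_profile(d2: np.ndarray) -> np.ndarray:
    v = np.exp(-d2 / (2.0 * DAPI_SIGMA_PX**2))
    v[d2 > (3.5 * DAPI_SIGMA_PX) ** 2] = 0.0
    return v


def _flattop_profile(d2: np.ndarray) -> np.ndarray:
    rel = d2 / MARKER_BLOB_RADIUS_PX**2
    return np.where(rel < 1.0, 1.0 - rel**4, 0.0)  # (d/R)^8 in squared distance


def render_channels(
    gt: GroundTruthSection,
    scenario: TissueScenario,
    rng_seed: int,
    sample_id: str = "",
    quantize: bool = True,
) -> CalibratedImage:
    """Render the DAPI channel plus one channel per marker.

    DAPI gets a Gaussian nuclear blob for every cell; each marker channel
    gets a flat-top blob only at marker-positive cells.  A multiplicative
    smooth illumination gradient (random orientation, stated amplitude) and
    Poisson shot noise scaled by ``noise_level`` are applied; intensities
    are clipped to [0, 1] and, by default, quantized to unsigned 16-bit.
    """
    if gt.image_shape != scenario.image_shape or not math.isclose(
        gt.pixel_size_um, scenario.pixel_size_um
    ):
        raise ValueError("section and scenario disagree on image geometry")
    rng = np.random.default_rng(rng_seed)
    shape = gt.image_shape
    n = gt.n_cells

    channels: dict[str, np.ndarray] = {}
    dapi = np.zeros(shape, dtype=float)
    amps = rng.uniform(0.55, 0.9, size=n)
    _stamp_max(dapi, gt.cells_xy, amps, 3.5 * DAPI_SIGMA_PX, _gauss_profile)
    channels["DAPI"] = dapi
    for marker in scenario.markers:
        ch = np.zeros(shape, dtype=float)
        amps = rng.uniform(0.6, 0.95, size=n)
        pos = gt.marker_flags[marker]
        _stamp_max(ch, gt.cells_xy[pos], amps[pos], MARKER_BLOB_RADIUS_PX, _flattop_profile)
        channels[marker] = ch

    amp = scenario.illumination_gradient_amplitude
    if amp > 0:
        theta = rng.uniform(0.0, 2.0 * np.pi)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        proj = np.cos(theta) * xx + np.sin(theta) * yy
        ramp = (proj - proj.min()) / max(np.ptp(proj), 1.0)
        shading = 1.0 - amp * ramp
        for name in channels:
            channels[name] = channels[name] * shading

    if scenario.noise_level > 0:
        photons = 1.0 / scenario.noise_level**2
        for name in list(channels):
            ch = channels[name]
            nz = ch > 0  # Poisson(0) is identically 0: sample signal pixels only
            noisy = np.zeros_like(ch)
            noisy[nz] = rng.poisson(ch[nz] * photons) / photons
            channels[name] = noisy

    for name in list(channels):
        ch = np.clip(channels[name], 0.0, 1.0)
        channels[name] = (
            np.round(ch * 65535.0).astype(np.uint16) if quantize else ch
        )
    return CalibratedImage(
        channels=channels, pixel_size_um=scenario.pixel_size_um, sample_id=sample_id
    )


def true_marker_area_fractions(
    gt: GroundTruthSection,
    markers: "Sequence[str] | None" = None,
    coloc_pairs: Sequence[tuple[str, str]] = (("CD14", "CD16"), ("CD14", "CD206")),
) -> pd.DataFrame:
    """Ground-truth per-region area fractions and co-localization ratios.

    The true footprint of a marker is the union of the support disks
    (radius ``MARKER_BLOB_RADIUS_PX``) of its positive cells, evaluated at
    pixel centers exactly as the renderer does; true double-positive area
    is the intersection of two marker footprints.  Returned in the same
    long format (region, variable, value) as the measured tables.
    """
    markers = list(markers or gt.marker_flags)
    labels = gt.label_map()
    shape = gt.image_shape
    truth_masks = {}
    for marker in markers:
        mask = np.zeros(shape, dtype=bool)
        pos = gt.cells_xy[gt.marker_flags[marker]]
        _stamp_bool_disks(mask, pos, MARKER_BLOB_RADIUS_PX)
        truth_masks[marker] = mask
    rows = []
    for region in TISSUE_REGIONS:
        region_mask = labels.region_mask(region)
        denom = int(region_mask.sum())
        for marker in markers:
            frac = 100.0 * int((truth_masks[marker] & region_mask).sum()) / denom
            rows.append(
                {"region": region.name, "variable": f"{marker}_area_fraction", "value": frac}
            )
        for parent, other in coloc_pairs:
            if parent not in truth_masks or other not in truth_masks:
                continue
            n_parent = int((truth_masks[parent] & region_mask).sum())
            n_both = int(
                (truth_masks[parent] & truth_masks[other] & region_mask).sum()
            )
            rows.append(
                {
                    "region": region.name,
                    "variable": f"{parent}+{other}_ratio",
                    "value": (100.0 * n_both / n_parent) if n_parent else math.nan,
                }
            )
        n_cells = int(np.sum(gt.cell_regions == int(region)))
        area = labels.area_mm2(region)
        rows.append(
            {
                "region": region.name,
                "variable": "cell_density",
                "value": n_cells / area if area > 0 else math.nan,
            }
        )
        n_vessels = sum(1 for cls, _ in gt.vessels if cls == region)
        rows.append(
            {
                "region": region.name,
                "variable": "vessel_density",
                "value": n_vessels / area if area > 0 else math.nan,
            }
        )
    return pd.DataFrame(rows)


def _stamp_bool_disks(mask: np.ndarray, xy: np.ndarray, radius: float) -> None:
    """Union of open disks (pixel center strictly within ``radius``),
    matching the renderer's support exactly."""
    nrows, ncols = mask.shape
    r = int(math.ceil(radius))
    r2 = radius * radius
    for x, y in xy:
        r0, r1 = max(0, int(math.floor(y)) - r), min(nrows - 1, int(math.ceil(y)) + r)
        c0, c1 = max(0, int(math.floor(x)) - r), min(ncols - 1, int(math.ceil(x)) + r)
        if r0 > r1 or c0 > c1:
            continue
        yy = np.arange(r0, r1 + 1, dtype=float)[:, None] - y
        xx = np.arange(c0, c1 + 1, dtype=float)[None, :] - x
        mask[r0 : r1 + 1, c0 : c1 + 1] |= (yy * yy + xx * xx) < r2


# --------------------------------------------------------------------- cohort


@dataclass(frozen=True)
class AnalyteSpec:
    """Log-normal synovial-fluid analyte model for one analyte.

    ``group_median`` maps group label to the log-normal median; values are
    ``median * exp(sigma_log * Z)``.  With ``below_lod=True`` the analyte
    emulates an assay reading entirely under its detection limit: draws are
    capped just below ``lod``.
    """

    name: str
    units: str
    lod: float
    group_median: Mapping[str, float]
    sigma_log: float = 0.9
    below_lod: bool = False


def default_analyte_panel() -> list[AnalyteSpec]:
    """Synthetic cytokine/chemokine panel.

    Group medians echo the magnitudes and orderings of the emulated study's
    synovial-fluid table (no significant group differences; four analytes
    entirely below their detection limits: IL-1beta at 61, IFN-alpha at 12,
    IL-4 at 40 and CCL3 at 5 pg/ml), plus total protein, higher in foals.
    """
    m = lambda f, c, o: {"F": f, "CTRL": c, "OA": o}  # noqa: E731
    return [
        AnalyteSpec("TNF-a", "pg/ml", 10.0, m(2510, 6104, 13979), 1.2),
        AnalyteSpec("IFN-g", "U/ml", 1.0, m(11, 5, 4), 0.9),
        AnalyteSpec("IL-17A", "U/ml", 1.0, m(6.5, 4, 4), 0.7),
        AnalyteSpec("IL-10", "pg/ml", 5.0, m(103.5, 58, 40), 0.9),
        AnalyteSpec("CCL2", "pg/ml", 20.0, m(734.6, 1282, 992), 0.9),
        AnalyteSpec("CCL5", "pg/ml", 5.0, m(236, 90, 111), 0.9),
        AnalyteSpec("CCL11", "pg/ml", 20.0, m(1636, 2586, 3840), 0.9),
        AnalyteSpec("TP", "g/dl", 0.1, m(1.3, 0.75, 0.6), 0.4),
        AnalyteSpec("IL-1b", "pg/ml", 61.0, m(8, 8, 8), 0.5, below_lod=True),
        AnalyteSpec("IFN-a", "pg/ml", 12.0, m(2, 2, 2), 0.5, below_lod=True),
        AnalyteSpec("IL-4", "pg/ml", 40.0, m(6, 6, 6), 0.5, below_lod=True),
        AnalyteSpec("CCL3", "pg/ml", 5.0, m(0.8, 0.8, 0.8), 0.5, below_lod=True),
    ]


def make_analyte_table(
    panel: Sequence[AnalyteSpec],
    sample_groups: Mapping[str, str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Long table ``sample_id, group, analyte, value, lod`` drawn
    log-normally per group."""
    rows = []
    for spec in panel:
        for sample_id, group in sample_groups.items():
            median = float(spec.group_median.get(group, next(iter(spec.group_median.values()))))
            value = median * math.exp(spec.sigma_log * rng.standard_normal())
            if spec.below_lod:
                value = min(value, np.nextafter(spec.lod, 0.0))
            rows.append(
                {
                    "sample_id": sample_id,
                    "group": group,
                    "analyte": spec.name,
                    "value": value,
                    "lod": spec.lod,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CohortSample:
    sample_id: str
    group: str
    scenario: TissueScenario
    section: GroundTruthSection
    image: "CalibratedImage | None"  # None when the cohort skips rendering


@dataclass
class CohortBundle:
    samples: list[CohortSample]
    analytes: pd.DataFrame

    def sample_groups(self) -> dict[str, str]:
        return {s.sample_id: s.group for s in self.samples}


def make_cohort(
    scenarios: Mapping[str, TissueScenario],
    n_per_group: "int | Mapping[str, int] | None" = None,
    rng_seed: int = 0,
    analyte_panel: "Sequence[AnalyteSpec] | None" = None,
    render: bool = True,
) -> CohortBundle:
    """Generate a full cohort: per-sample sections (+ rendered images) and
    one analyte table.

    ``n_per_group`` may be a single integer, a per-group mapping, or None
    for the emulated study's cohort sizes (F 10 / CTRL 11 / OA 9, default
    10 for other labels).  All randomness descends from ``rng_seed``
    through a SeedSequence, so a fixed seed reproduces the cohort exactly.
    """
    sizes: dict[str, int] = {}
    for group in scenarios:
        if n_per_group is None:
            sizes[group] = DEFAULT_GROUP_SIZES.get(group, 10)
        elif isinstance(n_per_group, int):
            sizes[group] = n_per_group
        else:
            sizes[group] = int(n_per_group[group])
    if any(n < 1 for n in sizes.values()):
        raise ValueError("n_per_group must be >= 1")

    ids: list[tuple[str, str]] = []
    for group in scenarios:
        for i in range(sizes[group]):
            ids.append((f"{group}-{i + 1:02d}", group))
    id_list = [s for s, _ in ids]
    if len(set(id_list)) != len(id_list):
        raise ValueError("duplicate sample identifiers in cohort")

    state = np.random.SeedSequence(rng_seed).generate_state(2 * len(ids) + 1)
    samples: list[CohortSample] = []
    for k, (sample_id, group) in enumerate(ids):
        scenario = scenarios[group]
        sec_seed = int(state[2 * k]) & 0x7FFFFFFF
        render_seed = int(state[2 * k + 1]) & 0x7FFFFFFF
        section = generate_section(scenario, sec_seed)
        image = (
            render_channels(section, scenario, render_seed, sample_id=sample_id)
            if render
            else None
        )
        samples.append(CohortSample(sample_id, group, scenario, section, image))

    panel = list(analyte_panel) if analyte_panel is not None else default_analyte_panel()
    analyte_rng = np.random.default_rng(int(state[-1]) & 0x7FFFFFFF)
    analytes = make_analyte_table(panel, dict(ids), analyte_rng)
    return CohortBundle(samples=samples, analytes=analytes)


# -------------------------------------------------------------------- presets


def scenario_presets(
    pixel_size_um: float = 0.5,
    image_shape: tuple[int, int] = (512, 512),
    noise_level: float = 0.05,
    illumination_gradient_amplitude: float = 0.2,
) -> dict[str, TissueScenario]:
    """Scenario presets for the three study groups (F / CTRL / OA).

    The presets encode the emulated study's qualitative contrasts as
    package defaults (they are calibration choices, not claims about real
    tissue): the control adults carry the largest CD14+ areas in ICL and
    SI-V, foals the largest CD206+ areas, CD16+ areas are flat across
    groups (ICL probabilities are scaled inversely with the group's ICL
    cell density so the *area* stays flat while densities differ), intimal
    cell density is elevated in foals and OA adults, and subintimal
    vascularization is highest in SI-V with an OA excess in SI-N only.
    Effect sizes are deliberately large (standardized differences around 3
    at the default cohort sizes) so cohort-level orderings are detected
    reliably.
    """
    icl_density = {"F": 5532.0, "CTRL": 4300.0, "OA": 5641.0}
    cd16_icl = {g: 0.40 * icl_density["CTRL"] / icl_density[g] for g in icl_density}
    cd14 = {"F": 0.20, "CTRL": 0.50, "OA": 0.15}
    cd206 = {"F": 0.65, "CTRL": 0.30, "OA": 0.25}
    c16 = {"F": 0.40, "CTRL": 0.55, "OA": 0.75}  # P(CD16+ | CD14+)
    c206 = {"F": 0.80, "CTRL": 0.60, "OA": 0.30}  # P(CD206+ | CD14+)
    # a 512x512 px section at 0.5 um/px covers ~0.065 mm^2, so vessel
    # densities are set high enough that each region holds a countable
    # handful of vessels while preserving the orderings (SI_V > SI_N
    # everywhere; OA > CTRL in SI_N only)
    vessel_si_n = {"F": 40.0, "CTRL": 30.0, "OA": 80.0}

    presets = {}
    for g in ("F", "CTRL", "OA"):
        presets[g] = TissueScenario(
            group_label=g,
            marker_probs={
                "ICL": {"CD14": cd14[g], "CD16": cd16_icl[g], "CD206": cd206[g]},
                "SI_V": {"CD14": cd14[g], "CD16": 0.35, "CD206": cd206[g]},
                "SI_N": {"CD14": 0.05, "CD16": 0.10, "CD206": 0.10},
            },
            coloc_probs={
                region: {"CD16|CD14": c16[g], "CD206|CD14": c206[g]}
                if region != "SI_N"
                else {"CD16|CD14": 0.30, "CD206|CD14": 0.30}
                for region in _REGION_KEYS
            },
            cell_density_per_mm2={
                "ICL": icl_density[g],
                "SI_V": 2500.0,
                "SI_N": 1500.0,
            },
            vessel_density_per_mm2={"SI_V": 150.0, "SI_N": vessel_si_n[g]},
            pixel_size_um=pixel_size_um,
            noise_level=noise_level,
            illumination_gradient_amplitude=illumination_gradient_amplitude,
            image_shape=image_shape,
        )
    return presets
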