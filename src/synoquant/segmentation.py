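"""Binary marker masks, co-localization masks, and per-cell masks.

The three segmentation primitives of the quantification workflow:

* :func:`local_adaptive_binarize` — a pixel is signal iff it strictly
  exceeds the mean of its square neighbourhood (half-width ``window_px``,
  edge-inclusive symmetric padding);
* :func:`colocalize` — double-positive masks by elementwise AND
  ("multiplication of binary masks");
* :func:`cell_masks_from_seeds` — radius-constrained nearest-seed
  partition around manually punctuated cell centers, equivalent to a
  seeded watershed of the seed distance transform restricted to the union
  of radius-limited disks.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .roi import assign_points
from .types import BinaryMask, CellLabelMap, RegionClass, RegionLabelMap, as_region

__all__ = [
    "local_adaptive_binarize",
    "colocalize",
    "cell_masks_from_seeds",
    "count_seed_density",
]

# Relative guard absorbing float summation round-off so that a constant
# image is all-negative under the strict comparison.  Integer inputs use
# exact int64 arithmetic and need no guard.
_FLOAT_REL_GUARD = 2.0 ** -36


def _local_sum_int(channel: np.ndarray, w: int) -> np.ndarray:
    """Exact windowed sum of an integer image (window side 2w+1).

    Uses an integral image over a symmetric-padded array; int64 throughout,
    exact for any 16-bit input at any practical window size.
    """
    padded = np.pad(channel.astype(np.int64), w, mode="symmetric")
    c = padded.cumsum(axis=0).cumsum(axis=1)
    c = np.pad(c, ((1, 0), (1, 0)))
    side = 2 * w + 1
    return c[side:, side:] - c[:-side, side:] - c[side:, :-side] + c[:-side, :-side]


def local_adaptive_binarize(
    channel: np.ndarray, window_px: int = 50, channel_name: str = ""
) -> BinaryMask:
    """Locally adaptive mean thresholding of one fluorescence channel.

    A pixel is positive iff its intensity strictly exceeds the unweighted
    mean over the square neighbourhood of half-width ``window_px`` (side
    ``2*window_px + 1``), with symmetric padding at borders.  Deterministic;
    a constant image yields an all-false mask.

    Integer-typed channels are thresholded in exact integer arithmetic
    (``value * n_window > window_sum``).  Float channels use a box filter
    with a tiny relative guard (2^-36) so accumulated rounding can never
    turn a mathematically-equal pixel positive.

    A window larger than the image degenerates to a global-mean threshold
    (with a warning).
    """
    channel = np.asarray(channel)
    if channel.ndim != 2:
        raise ValueError("channel must be 2-D")
    if not np.issubdtype(channel.dtype, np.integer):
        if not np.all(np.isfinite(channel)):
            raise ValueError("channel contains non-finite pixels")
    if np.any(channel < 0):
        raise ValueError("channel intensities must be non-negative")
    window_px = int(window_px)
    if window_px < 1:
        raise ValueError("window_px must be >= 1")

    nrows, ncols = channel.shape
    side = 2 * window_px + 1
    if side > nrows or side > ncols:
        warnings.warn(
            f"window side {side} exceeds image shape {channel.shape}; "
            "degenerating to a global-mean threshold",
            stacklevel=2,
        )
        if np.issubdtype(channel.dtype, np.integer):
            total = int(channel.astype(np.int64).sum())
            mask = channel.astype(np.int64) * channel.size > total
        else:
            mean = float(channel.mean())
            mask = channel > mean * (1.0 + _FLOAT_REL_GUARD)
        return BinaryMask(mask=mask, channel_name=channel_name, window_px=window_px)

    if np.issubdtype(channel.dtype, np.integer):
        local_sum = _local_sum_int(channel, window_px)
        n = side * side
        mask = channel.astype(np.int64) * n > local_sum
    else:
        local_mean = ndimage.uniform_filter(
            channel.astype(np.float64), size=side, mode="reflect"
        )
        mask = channel > local_mean * (1.0 + _FLOAT_REL_GUARD)
    return BinaryMask(mask=mask, channel_name=channel_name, window_px=window_px)


def colocalize(mask_a: BinaryMask, mask_b: BinaryMask) -> BinaryMask:
    """Double-positive mask: elementwise AND of two binary masks.

    Commutative; the result is contained in both inputs.
    """
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"shape mismatch: {mask_a.shape} vs {mask_b.shape}")
    name_a = mask_a.channel_name or "a"
    name_b = mask_b.channel_name or "b"
    return BinaryMask(
        mask=mask_a.mask & mask_b.mask,
        channel_name=f"{name_a}+{name_b}",
        window_px=mask_a.window_px,
    )


def cell_masks_from_seeds(
    seeds, image_shape: tuple[int, int], radius_px: int = 15
) -> CellLabelMap:
    """Per-cell masks around manually marked centers.

    Every pixel within ``radius_px`` (Euclidean, inclusive) of at least one
    seed is assigned to its nearest seed; ties go to the lower seed index;
    pixels farther than ``radius_px`` from every seed stay unlabelled.
    This is the watershed of the seed distance field restricted to the
    union of radius-limited disks, realized directly as the constrained
    nearest-seed partition.  Seeds outside the image yield empty cells.

    Duplicate seeds are rejected with their indices.
    """
    pts = np.asarray(seeds, dtype=float).reshape(-1, 2)
    radius_px = int(radius_px)
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    _, first_idx, counts = np.unique(
        pts, axis=0, return_index=True, return_counts=True
    )
    if np.any(counts > 1):
        dup_coords = {tuple(pts[i]) for i in first_idx[counts > 1]}
        dup_idx = [i for i, p in enumerate(map(tuple, pts)) if p in dup_coords]
        raise ValueError(f"duplicate seeds at indices {dup_idx}")

    nrows, ncols = image_shape
    labels = np.zeros(image_shape, dtype=np.int32)
    best_d2 = np.full(image_shape, np.inf)
    r2 = float(radius_px) ** 2
    for k, (x, y) in enumerate(pts, start=1):
        r0 = max(0, int(np.ceil(y - radius_px)))
        r1 = min(nrows - 1, int(np.floor(y + radius_px)))
        c0 = max(0, int(np.ceil(x - radius_px)))
        c1 = min(ncols - 1, int(np.floor(x + radius_px)))
        if r0 > r1 or c0 > c1:
            continue
        yy = np.arange(r0, r1 + 1, dtype=float)[:, None] - y
        xx = np.arange(c0, c1 + 1, dtype=float)[None, :] - x
        d2 = yy * yy + xx * xx
        patch = (slice(r0, r1 + 1), slice(c0, c1 + 1))
        # strict improvement only: on exact ties the earlier (lower) seed wins
        take = (d2 <= r2) & (d2 < best_d2[patch])
        labels[patch][take] = k
        best_d2[patch][take] = d2[take]
    return CellLabelMap(labels=labels, seeds=pts, radius_px=radius_px)


def count_seed_density(
    seeds, region: "RegionClass | str", labels: RegionLabelMap
) -> float:
    """Cell density: seeds assigned to ``region`` per mm^2 of region area.

    Raises on a zero-area region rather than returning NaN.
    """
    region = as_region(region)
    area = labels.area_mm2(region)
    if area <= 0:
        raise ValueError(f"region {region.name} has zero area")
    assignment = assign_points(seeds, labels)
    n = int(np.sum(assignment.region_codes == int(region)))
    return n / area
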