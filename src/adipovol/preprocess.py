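"""Background-noise estimation and body-mask extraction.

Background noise is estimated from the image margins: the border band is
partitioned into 8 fields (4 corner squares plus 4 edge strips), voxels are
sampled from the non-excluded fields, and the noise level is summarised as
BG = mean + sd of the sampled intensities. Fields containing high-signal
objects (e.g. arms reaching into the border) can be excluded, either
explicitly or by a robust outlier rule.

The body mask is obtained from the anatomy-reference image (base image for
mice, in-phase image for humans) by Otsu thresholding, keeping the largest
connected object, and filling interior holes; the body contour is the line of
mask voxels facing the background. Everything outside the mask is zeroed in
the fat image so background noise cannot be segmented as fat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "MarginFieldSet",
    "BackgroundEstimate",
    "BodyMask",
    "partition_margin_fields",
    "estimate_background",
    "auto_exclude_fields",
    "otsu_threshold",
    "compute_body_mask",
    "apply_background_mask",
]

_STRUCT_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass
class MarginFieldSet:
    """The 8 disjoint margin fields of one image.

    Each field is a ``(rows, cols)`` pair of flat index arrays. Field order is
    fixed: 4 corners (top-left, top-right, bottom-left, bottom-right) then 4
    edge strips (top, bottom, left, right).
    """

    fields: list[tuple[np.ndarray, np.ndarray]]
    excluded: np.ndarray  # bool, shape (8,)
    band_width: int

    def __post_init__(self) -> None:
        if len(self.fields) != 8:
            raise ValueError("exactly 8 margin fields required")
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.excluded.shape != (8,):
            raise ValueError("excluded must have 8 entries")

    @property
    def active(self) -> list[int]:
        return [i for i in range(8) if not self.excluded[i]]


@dataclass(frozen=True)
class BackgroundEstimate:
    """Noise summary of sampled margin voxels: BG = mean + sd."""

    mean: float
    sd: float
    bg: float
    n_sampled: int
    seed: int


@dataclass
class BodyMask:
    """Hole-free binary body mask and its boundary voxels.

    ``contour`` is an ``(n, 2)`` array of (row, col) coordinates, in raster
    order, of mask voxels that touch background via 4-adjacency or lie on the
    image edge.
    """

    mask: np.ndarray
    contour: np.ndarray


def _block(r0: int, r1: int, c0: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    return rows.ravel(), cols.ravel()


def partition_margin_fields(width: int, height: int, band_width: int) -> MarginFieldSet:
    """Partition the border band of a ``height x width`` image into 8 fields.

    Four ``band_width``-square corners plus four edge strips; together they
    tile the whole margin band and are pairwise disjoint.
    """
    b = band_width
    if b < 1 or b >= min(width, height) / 2:
        raise ValueError("band exceeds image")
    h, w = height, width
    fields = [
        _block(0, b, 0, b),            # top-left corner
        _block(0, b, w - b, w),        # top-right corner
        _block(h - b, h, 0, b),        # bottom-left corner
        _block(h - b, h, w - b, w),    # bottom-right corner
        _block(0, b, b, w - b),        # top strip
        _block(h - b, h, b, w - b),    # bottom strip
        _block(b, h - b, 0, b),        # left strip
        _block(b, h - b, w - b, w),    # right strip
    ]
    return MarginFieldSet(fields, np.zeros(8, dtype=bool), b)


def estimate_background(
    image: np.ndarray,
    fields: MarginFieldSet,
    n_per_field: int = 100,
    seed: int = 0,
) -> BackgroundEstimate:
    """Estimate background noise from randomly sampled margin voxels.

    From each non-excluded field, ``min(n_per_field, field size)`` voxels are
    drawn uniformly without replacement with a seeded generator; the estimate
    is the mean, sample (n−1) standard deviation, and their sum BG over the
    pooled sample. Deterministic for a fixed seed.
    """
    active = fields.active
    if not active:
        raise ValueError("no background fields")
    rng = np.random.default_rng(seed)
    samples = []
    for i in active:
        rows, cols = fields.fields[i]
        size = rows.size
        k = min(n_per_field, size)
        pick = rng.choice(size, size=k, replace=False)
        samples.append(np.asarray(image)[rows[pick], cols[pick]])
    values = np.concatenate(samples)
    if values.size < 2:
        raise ValueError("need at least 2 sampled voxels")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return BackgroundEstimate(mean, sd, mean + sd, int(values.size), seed)


def auto_exclude_fields(image: np.ndarray, fields: MarginFieldSet, k: float = 3.0) -> MarginFieldSet:
    """Flag margin fields contaminated by high-signal objects.

    A field is excluded when its mean intensity exceeds
    ``median(field means) + k * MAD(field means)``. If the rule would exclude
    every field, none are excluded and a warning is issued. Existing
    exclusions are kept.
    """
    image = np.asarray(image)
    means = np.array([image[r, c].mean() for r, c in fields.fields])
    med = np.median(means)
    mad = np.median(np.abs(means - med))
    flag = means > med + k * mad
    combined = fields.excluded | flag
    if combined.all():
        warnings.warn("exclusion rule would drop all margin fields; keeping all", stacklevel=2)
        return replace(fields, excluded=fields.excluded.copy())
    return replace(fields, excluded=combined)


def otsu_threshold(image: np.ndarray, n_bins: int = 256) -> float:
    """Histogram threshold maximising between-class variance.

    Intensities are binned into ``n_bins`` equal-width bins on [min, max];
    candidate cuts are the interior bin edges, splitting voxels into
    ``v < edge`` and ``v >= edge``. Class means use exact per-bin intensity
    sums, so the result agrees with a brute-force search over the same cuts.
    Ties are broken toward the lower edge. Foreground is ``v >= threshold``.
    """
    values = np.asarray(image, dtype=np.float64).ravel()
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise ValueError("degenerate histogram")
    counts, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    sums, _ = np.histogram(values, bins=n_bins, range=(vmin, vmax), weights=values)

    c0 = np.cumsum(counts)[:-1].astype(np.float64)   # voxels below each interior edge
    s0 = np.cumsum(sums)[:-1]
    n = values.size
    total = sums.sum()
    c1 = n - c0
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = s0 / c0
        mu1 = (total - s0) / c1
        var_between = c0 * c1 * (mu0 - mu1) ** 2
    var_between = np.where((c0 == 0) | (c1 == 0), 0.0, var_between)
    k = int(np.argmax(var_between))  # first maximum = lower edge on ties
    return float(edges[k + 1])


def compute_body_mask(anatomy: np.ndarray) -> BodyMask:
    """Extract the body mask and its contour from an anatomy-reference slice.

    Otsu-threshold the slice, keep the largest 8-connected foreground object,
    fill its interior holes, and take as contour every mask voxel 4-adjacent
    to background (voxels on the image edge included).
    """
    anatomy = np.asarray(anatomy)
    thr = otsu_threshold(anatomy)
    fg = anatomy >= thr
    if not fg.any():
        raise ValueError("no body detected")
    labels, n = ndimage.label(fg, structure=_STRUCT_8)
    if n == 0:
        raise ValueError("no body detected")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == int(np.argmax(sizes))
    mask = ndimage.binary_fill_holes(mask)
    # erosion with border treated as background: edge voxels become contour
    interior = ndimage.binary_erosion(mask, structure=_STRUCT_4, border_value=0)
    contour = np.argwhere(mask & ~interior)
    return BodyMask(mask, contour)


def apply_background_mask(fat: np.ndarray, body: BodyMask) -> np.ndarray:
    """Zero every fat-image voxel outside the body mask."""
    fat = np.asarray(fat)
    if fat.shape != body.mask.shape:
        raise ValueError("shape mismatch")
    return np.where(body.mask, fat, 0.0)
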