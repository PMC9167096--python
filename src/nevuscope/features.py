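"""Shape, color and texture features of a segmented lesion.

Shape is summarized by binary geometric moments: s_pq = Σ i^p j^q over
foreground pixels, the centroid (r0, c0) = (s10/s00, s01/s00), central moments
ψ_pq = Σ (i−r0)^p (j−c0)^q, the equivalent-ellipse axis lengths

    L1,2 = sqrt( 8 (ψ02 + ψ20 ± sqrt((ψ02 − ψ20)² + 4 ψ11²)) / ψ00 )

(the full major/minor axis lengths of the ellipse whose second-order central
moments match the shape's), and the aspect ratio AR = L1/L2 ≥ 1. Color and
texture descriptors are simple masked statistics; the two groups form the two
"views" of the co-training regimes and can be fused into a single vector.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .segmentation import _luminance, color_distance

logger = logging.getLogger("nevuscope")


@dataclass(frozen=True)
class GeometricMoments:
    s00: float
    r0: float
    c0: float
    psi20: float
    psi02: float
    psi11: float


@dataclass(frozen=True)
class ShapeFeatures:
    area: float
    L1: float
    L2: float
    AR: float


@dataclass(frozen=True)
class FeatureVector:
    """An ordered real vector with a parallel schema of unique feature names."""

    values: np.ndarray
    schema: tuple[str, ...]
    view_tag: str = "fused"

    def __post_init__(self) -> None:
        if len(self.values) != len(self.schema):
            raise ValueError("values length must equal schema length")
        if len(set(self.schema)) != len(self.schema):
            raise ValueError("schema names must be unique")


def _foreground(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = np.nonzero(np.asarray(mask) != 0)
    if rows.size == 0:
        raise ValueError("empty lesion mask")
    return rows.astype(np.float64), cols.astype(np.float64)


def geometric_moment(mask: np.ndarray, p: int, q: int) -> float:
    """s_pq = Σ over foreground pixels of i^p j^q (0-based row i, col j)."""
    if p < 0 or q < 0:
        raise ValueError("moment orders must be non-negative")
    rows, cols = _foreground(mask)
    return float(np.sum(rows ** p * cols ** q))


def centroid(mask: np.ndarray) -> tuple[float, float]:
    """(r0, c0) = (s10/s00, s01/s00)."""
    rows, cols = _foreground(mask)
    n = rows.size
    return float(rows.sum() / n), float(cols.sum() / n)


def central_moment(mask: np.ndarray, p: int, q: int) -> float:
    """ψ_pq = Σ over foreground pixels of (i − r0)^p (j − c0)^q."""
    rows, cols = _foreground(mask)
    r0, c0 = rows.mean(), cols.mean()
    return float(np.sum((rows - r0) ** p * (cols - c0) ** q))


def compute_moments(mask: np.ndarray) -> GeometricMoments:
    rows, cols = _foreground(mask)
    r0, c0 = rows.mean(), cols.mean()
    dr, dc = rows - r0, cols - c0
    return GeometricMoments(
        s00=float(rows.size), r0=float(r0), c0=float(c0),
        psi20=float(np.sum(dr * dr)), psi02=float(np.sum(dc * dc)),
        psi11=float(np.sum(dr * dc)),
    )


def ellipse_axes(moments: GeometricMoments) -> tuple[float, float]:
    """Full axis lengths (L1 >= L2) of the moment-equivalent ellipse."""
    if moments.s00 <= 0:
        raise ValueError("ψ00 must be positive")
    disc = math.sqrt((moments.psi02 - moments.psi20) ** 2 + 4 * moments.psi11 ** 2)
    tr = moments.psi02 + moments.psi20
    L1 = math.sqrt(8.0 * (tr + disc) / moments.s00)
    inner = 8.0 * (tr - disc) / moments.s00
    L2 = math.sqrt(max(inner, 0.0))
    if L2 == 0.0:
        logger.warning("degenerate mask (collinear pixels): minor axis is 0")
    return L1, L2


def aspect_ratio(axes: tuple[float, float]) -> float:
    """AR = L1/L2 >= 1."""
    L1, L2 = axes
    if L2 <= 0:
        raise ValueError("degenerate lesion: minor axis is zero")
    return L1 / L2


def extract_shape_features(mask: np.ndarray) -> FeatureVector:
    m = compute_moments(mask)
    L1, L2 = ellipse_axes(m)
    ar = aspect_ratio((L1, L2)) if L2 > 0 else float("inf")
    return FeatureVector(
        values=np.array([m.s00, L1, L2, ar], dtype=np.float64),
        schema=("area", "axis_major", "axis_minor", "aspect_ratio"),
        view_tag="shape",
    )


def extract_color_features(image: np.ndarray, mask: np.ndarray) -> FeatureVector:
    """Per-channel mean and sd inside the lesion plus the lesion/background
    mean-color Euclidean distance (7 values)."""
    fg = np.asarray(mask) != 0
    if not fg.any():
        raise ValueError("empty lesion mask")
    if fg.all():
        raise ValueError("mask covers the entire image; background statistics unavailable")
    img = image.astype(np.float64)
    inside = img[fg].reshape(-1, 3)
    outside = img[~fg].reshape(-1, 3)
    means = inside.mean(axis=0)
    sds = inside.std(axis=0)
    contrast = color_distance(means, outside.mean(axis=0))
    return FeatureVector(
        values=np.array([*means, *sds, contrast], dtype=np.float64),
        schema=("mean_r", "mean_g", "mean_b", "sd_r", "sd_g", "sd_b",
                "lesion_background_contrast"),
        view_tag="color_texture",
    )


def extract_texture_features(image: np.ndarray, mask: np.ndarray,
                             n_bins: int = 32) -> FeatureVector:
    """Luminance statistics inside the lesion: variance, entropy of an
    ``n_bins``-bin histogram (bits), and mean absolute horizontal/vertical
    gradients (4 values). Gradients are taken over within-lesion pixel pairs
    only, so the lesion boundary does not contribute."""
    fg = np.asarray(mask) != 0
    if not fg.any():
        raise ValueError("empty lesion mask")
    lum = _luminance(image)
    vals = lum[fg]
    if vals.size < 2:
        logger.warning("single-pixel lesion: texture features are zero")
        return FeatureVector(values=np.zeros(4), view_tag="color_texture",
                             schema=("lum_variance", "lum_entropy",
                                     "grad_horizontal", "grad_vertical"))
    variance = float(vals.var())
    hist, _ = np.histogram(vals, bins=n_bins, range=(0.0, 255.0))
    p = hist[hist > 0] / hist.sum()
    entropy = float(-(p * np.log2(p)).sum())

    pair_h = fg[:, 1:] & fg[:, :-1]
    pair_v = fg[1:, :] & fg[:-1, :]
    dh = np.abs(np.diff(lum, axis=1))[pair_h]
    dv = np.abs(np.diff(lum, axis=0))[pair_v]
    grad_h = float(dh.mean()) if dh.size else 0.0
    grad_v = float(dv.mean()) if dv.size else 0.0
    return FeatureVector(
        values=np.array([variance, entropy, grad_h, grad_v], dtype=np.float64),
        schema=("lum_variance", "lum_entropy", "grad_horizontal", "grad_vertical"),
        view_tag="color_texture",
    )


def extract_color_texture_features(image: np.ndarray, mask: np.ndarray) -> FeatureVector:
    """The color+texture view: color (7) and texture (4) features, 11 values."""
    fused = fuse_features(extract_color_features(image, mask),
                          extract_texture_features(image, mask))
    return FeatureVector(values=fused.values, schema=fused.schema,
                         view_tag="color_texture")


def fuse_features(a: FeatureVector, b: FeatureVector) -> FeatureVector:
    """Concatenate two feature vectors (schemas must be disjoint)."""
    dup = set(a.schema) & set(b.schema)
    if dup:
        raise ValueError(f"duplicate feature names in fusion: {sorted(dup)}")
    return FeatureVector(values=np.concatenate([a.values, b.values]),
                         schema=a.schema + b.schema, view_tag="fused")
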