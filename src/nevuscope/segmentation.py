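"""Lesion segmentation by color-distance region merging.

The segmentation flow: removal of hair strokes and immersion-fluid bubbles,
median-filter denoising, over-segmentation into color-homogeneous connected
subregions, computation of each region's mean-color vector
H_i = (R̄_i, Ḡ_i, B̄_i), selection of the pair of regions with the largest
Euclidean color distance as foreground/background seeds, assignment of every
remaining region to its nearest seed in color space, and morphological
smoothing of the resulting binary lesion boundary. The lesion is taken to be
the darker of the two merged groups (pigmented nevi are darker than the
surrounding skin).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage
from skimage import morphology, restoration, segmentation as sk_seg

logger = logging.getLogger("nevuscope")


@dataclass
class RegionPartition:
    """A labeling of the image into N non-empty regions with region ids 1..N
    and per-region mean-color vectors."""

    label_map: np.ndarray            # (H, W) int, values in 1..N
    color_vectors: np.ndarray        # (N, 3) float, mean RGB per region

    @property
    def n_regions(self) -> int:
        return self.color_vectors.shape[0]

    def validate(self, image: np.ndarray | None = None, tol: float = 1e-9) -> None:
        ids = np.unique(self.label_map)
        if ids.min() < 1 or ids.max() > self.n_regions or len(ids) != self.n_regions:
            raise ValueError("label_map must use exactly the ids 1..N")
        if image is not None:
            for i in range(1, self.n_regions + 1):
                mean = image[self.label_map == i].reshape(-1, 3).mean(axis=0)
                if np.max(np.abs(mean - self.color_vectors[i - 1])) > tol:
                    raise ValueError(f"stored color vector of region {i} is stale")


@dataclass
class SegmentationResult:
    mask: np.ndarray                 # (H, W) uint8 in {0, 1}; 1 = lesion
    seed_pair: tuple[int, int]
    provenance: list[str] = field(default_factory=list)


def _luminance(image: np.ndarray) -> np.ndarray:
    """Rec. 601 luma of an RGB image, float64."""
    img = image.astype(np.float64)
    return 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def denoise(image: np.ndarray, kernel_radius: int = 2) -> np.ndarray:
    """Per-channel median filter with a square window of the given radius."""
    if kernel_radius < 1:
        raise ValueError("kernel_radius must be >= 1")
    h, w = image.shape[:2]
    if kernel_radius > min(h, w) / 2:
        raise ValueError(f"kernel_radius {kernel_radius} too large for a {h}x{w} image")
    size = 2 * kernel_radius + 1
    out = np.empty_like(image)
    for ch in range(image.shape[2]):
        out[..., ch] = ndimage.median_filter(image[..., ch], size=size)
    return out


def remove_artifacts(image: np.ndarray,
                     hair_length_min: int = 15,
                     bubble_brightness_min: float = 230.0,
                     max_inpaint_fraction: float = 0.30) -> np.ndarray:
    """Detect hair strokes and bright bubbles and fill them by inpainting.

    Hairs are found as the dark residue of a morphological closing of the
    luminance channel (bottom-hat); candidate components are kept only if
    their skeleton is at least ``hair_length_min`` pixels long, which rejects
    compact dark structure belonging to the lesion itself. Bubbles are bright
    (luminance >= ``bubble_brightness_min``) compact blobs of sufficient
    circularity. Detected pixels are replaced by biharmonic inpainting from
    their surroundings. If the combined artifact mask would cover more than
    ``max_inpaint_fraction`` of the image the input is returned unchanged with
    a warning (the "image" is then essentially all artifact and inpainting
    would fabricate content).
    """
    if hair_length_min <= 0 or bubble_brightness_min <= 0:
        raise ValueError("thresholds must be positive")
    lum = _luminance(image)

    # hairs: dark elongated residue of a grayscale closing
    closed = morphology.closing(lum, morphology.disk(3))
    residue = closed - lum
    hair_cand = residue > 20.0
    hair_mask = np.zeros_like(hair_cand)
    lab, n_comp = ndimage.label(hair_cand)
    for comp in range(1, n_comp + 1):
        comp_mask = lab == comp
        skel = morphology.skeletonize(comp_mask)
        if skel.sum() >= hair_length_min:
            hair_mask |= comp_mask

    # bubbles: bright compact blobs
    bright = lum >= bubble_brightness_min
    bubble_mask = np.zeros_like(bright)
    lab, n_comp = ndimage.label(bright)
    for comp in range(1, n_comp + 1):
        comp_mask = lab == comp
        area = comp_mask.sum()
        if area < 4:
            continue
        perim = _perimeter(comp_mask)
        circularity = 4 * np.pi * area / max(perim, 1.0) ** 2
        if circularity > 0.35:
            bubble_mask |= comp_mask

    artifact = morphology.dilation(hair_mask | bubble_mask, morphology.disk(1))
    frac = artifact.mean()
    if frac == 0:
        return image.copy()
    if frac > max_inpaint_fraction:
        logger.warning("artifact mask covers %.0f%% of the image; refusing to inpaint",
                       100 * frac)
        return image.copy()
    filled = restoration.inpaint_biharmonic(image, artifact, channel_axis=-1)
    return np.clip(np.rint(filled * 255.0), 0, 255).astype(np.uint8)


def _perimeter(mask: np.ndarray) -> float:
    eroded = ndimage.binary_erosion(mask)
    return float((mask & ~eroded).sum())


# ---------------------------------------------------------------------------
# over-segmentation and region statistics
# ---------------------------------------------------------------------------

def region_color_vectors(image: np.ndarray, label_map: np.ndarray) -> np.ndarray:
    """Mean RGB per region id 1..N (the H_i descriptors)."""
    n = int(label_map.max())
    img = image.reshape(-1, 3).astype(np.float64)
    flat = label_map.ravel()
    counts = np.bincount(flat, minlength=n + 1)[1:]
    sums = np.stack([np.bincount(flat, weights=img[:, ch], minlength=n + 1)[1:]
                     for ch in range(3)], axis=1)
    return sums / counts[:, None]


def oversegment(image: np.ndarray, target_regions: int = 64) -> RegionPartition:
    """Partition the image into roughly ``target_regions`` connected,
    color-homogeneous subregions (SLIC superpixels: k-means in color+position
    space), then compute per-region mean-color vectors."""
    h, w = image.shape[:2]
    if not 2 <= target_regions <= h * w:
        raise ValueError("target_regions must be between 2 and the pixel count")

    if image.std() == 0:
        logger.warning("constant image; falling back to a grid partition")
        label_map = _grid_partition(h, w, target_regions)
    else:
        if target_regions >= 16:
            labels = sk_seg.slic(image, n_segments=target_regions, compactness=10.0,
                                 start_label=1, enforce_connectivity=True,
                                 channel_axis=-1)
            label_map = _compress_labels(labels)
        else:
            # SLIC's grid seeding is unreliable for a handful of regions;
            # cluster directly in color+position space instead
            label_map = _kmeans_partition(image, target_regions)
        if label_map.max() < 2:
            logger.warning("over-segmentation collapsed to one region; using grid")
            label_map = _grid_partition(h, w, target_regions)
        elif label_map.max() > 2 * target_regions:
            label_map = _merge_smallest(image, label_map, 2 * target_regions)
    return RegionPartition(label_map=label_map,
                           color_vectors=region_color_vectors(image, label_map))


def _compress_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel to consecutive ids 1..N preserving order of first appearance
    by original id."""
    ids = np.unique(labels)
    lut = np.zeros(ids.max() + 1, dtype=np.int64)
    lut[ids] = np.arange(1, len(ids) + 1)
    return lut[labels]


def _kmeans_partition(image: np.ndarray, k: int,
                      position_weight: float = 0.2) -> np.ndarray:
    """Seeded k-means over (R, G, B, weighted row, weighted col) features,
    with each color cluster split into its spatially connected components."""
    from scipy.cluster.vq import kmeans2

    h, w = image.shape[:2]
    rr, cc = np.mgrid[0:h, 0:w].astype(np.float64)
    scale = 255.0 / max(h, w)
    feats = np.column_stack([
        image.reshape(-1, 3).astype(np.float64),
        position_weight * scale * rr.ravel(),
        position_weight * scale * cc.ravel(),
    ])
    _, assign = kmeans2(feats, k, minit="++", seed=0)
    label_map = np.zeros((h, w), dtype=np.int64)
    next_id = 1
    for cluster in np.unique(assign):
        comp, n_comp = ndimage.label((assign == cluster).reshape(h, w))
        for c in range(1, n_comp + 1):
            label_map[comp == c] = next_id
            next_id += 1
    return label_map


def _merge_smallest(image: np.ndarray, label_map: np.ndarray, max_regions: int) -> np.ndarray:
    """Absorb the smallest regions into their most color-similar spatial
    neighbor until at most ``max_regions`` remain."""
    label_map = label_map.copy()
    while True:
        ids, counts = np.unique(label_map, return_counts=True)
        if len(ids) <= max_regions:
            break
        vecs = region_color_vectors(image, _compress_labels(label_map))
        label_map = _compress_labels(label_map)
        ids, counts = np.unique(label_map, return_counts=True)
        smallest = ids[np.argmin(counts)]
        region = label_map == smallest
        ring = morphology.dilation(region, morphology.disk(1)) & ~region
        neighbors = np.unique(label_map[ring])
        neighbors = neighbors[neighbors != smallest]
        if neighbors.size == 0:
            break
        dists = [np.linalg.norm(vecs[n - 1] - vecs[smallest - 1]) for n in neighbors]
        label_map[region] = neighbors[int(np.argmin(dists))]
    return _compress_labels(label_map)


def _grid_partition(h: int, w: int, target: int) -> np.ndarray:
    side = max(int(round(np.sqrt(target))), 2)
    rows = np.minimum((np.arange(h) * side) // h, side - 1)
    cols = np.minimum((np.arange(w) * side) // w, side - 1)
    return (rows[:, None] * side + cols[None, :] + 1).astype(np.int64)


# ---------------------------------------------------------------------------
# color-distance merge
# ---------------------------------------------------------------------------

def color_distance(v1, v2) -> float:
    """Euclidean distance between two 3-component mean-color vectors."""
    v1 = np.asarray(v1, dtype=np.float64)
    v2 = np.asarray(v2, dtype=np.float64)
    if v1.shape != (3,) or v2.shape != (3,):
        raise ValueError("color vectors must have 3 components")
    return float(np.sqrt(np.sum((v1 - v2) ** 2)))


def select_seed_regions(partition: RegionPartition) -> tuple[int, int]:
    """The unordered region pair maximizing the mean-color Euclidean distance;
    ties broken toward the lexicographically smallest id pair."""
    n = partition.n_regions
    if n < 2:
        raise ValueError("need at least 2 regions to select a seed pair")
    best, best_d = (1, 2), -1.0
    for i, j in combinations(range(1, n + 1), 2):
        d = color_distance(partition.color_vectors[i - 1], partition.color_vectors[j - 1])
        if d > best_d:  # strict: ties keep the earlier (lexicographic) pair
            best, best_d = (i, j), d
    return best


def merge_regions(partition: RegionPartition,
                  seeds: tuple[int, int] | None = None) -> SegmentationResult:
    """Merge every region to its color-nearest seed and binarize.

    Each region joins the seed whose mean color is closer in Euclidean
    distance (ties go to the first seed C1). Of the two merged groups, the
    one with the lower mean luminance is labeled foreground (value 1).
    """
    if seeds is None:
        seeds = select_seed_regions(partition)
    c1, c2 = seeds
    n = partition.n_regions
    if not (1 <= c1 <= n and 1 <= c2 <= n) or c1 == c2:
        raise ValueError(f"invalid seed pair {seeds} for a {n}-region partition")

    vecs = partition.color_vectors
    d1 = np.sqrt(np.sum((vecs - vecs[c1 - 1]) ** 2, axis=1))
    d2 = np.sqrt(np.sum((vecs - vecs[c2 - 1]) ** 2, axis=1))
    joins_c1 = d1 <= d2  # ties -> C1

    # darker group = lesion foreground
    lum = 0.299 * vecs[:, 0] + 0.587 * vecs[:, 1] + 0.114 * vecs[:, 2]
    counts = np.bincount(partition.label_map.ravel(), minlength=n + 1)[1:].astype(float)
    lum_c1 = np.average(lum[joins_c1], weights=counts[joins_c1])
    lum_c2 = np.average(lum[~joins_c1], weights=counts[~joins_c1])
    fg_is_c1 = lum_c1 <= lum_c2

    region_fg = joins_c1 if fg_is_c1 else ~joins_c1
    lut = np.zeros(n + 1, dtype=np.uint8)
    lut[1:] = region_fg.astype(np.uint8)
    mask = lut[partition.label_map]
    return SegmentationResult(mask=mask, seed_pair=(c1, c2),
                              provenance=["merge_regions"])


def smooth_boundary(mask: np.ndarray, radius: int = 3) -> np.ndarray:
    """Morphological closing then opening with a disc, plus removal of
    foreground components smaller than radius**2 pixels."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if not mask.any():
        logger.warning("all-zero mask passed to smooth_boundary; returned unchanged")
        return mask.copy()
    selem = morphology.disk(radius)
    out = morphology.closing(mask.astype(bool), selem)
    out = morphology.opening(out, selem)
    # drop foreground components with area < radius**2
    out = morphology.remove_small_objects(out, max_size=radius * radius - 1)
    return out.astype(np.uint8)


# ---------------------------------------------------------------------------
# full flow
# ---------------------------------------------------------------------------

def segment_lesion(image: np.ndarray,
                   denoise_radius: int = 2,
                   target_regions: int = 64,
                   smooth_radius: int = 3,
                   artifact_removal: bool = True,
                   hair_length_min: int = 15,
                   bubble_brightness_min: float = 230.0) -> SegmentationResult:
    """Run the full segmentation flow on one RGB image."""
    steps = []
    img = image
    # artifacts first: the median filter blurs hair strokes and weakens the
    # bottom-hat detector, so removal must see the sharp image
    if artifact_removal:
        img = remove_artifacts(img, hair_length_min, bubble_brightness_min)
        steps.append("remove_artifacts")
    img = denoise(img, denoise_radius)
    steps.append(f"denoise(radius={denoise_radius})")
    partition = oversegment(img, target_regions)
    steps.append(f"oversegment(n={partition.n_regions})")
    seeds = select_seed_regions(partition)
    result = merge_regions(partition, seeds)
    steps.append(f"merge_regions(seeds={seeds})")
    result.mask = smooth_boundary(result.mask, smooth_radius)
    steps.append(f"smooth_boundary(radius={smooth_radius})")
    result.provenance = steps
    return result


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two binary masks."""
    a = mask_a.astype(bool)
    b = mask_b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * (a & b).sum() / denom
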