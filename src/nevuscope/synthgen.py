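"""Seeded generators of synthetic dermoscopy-like data.

Everything downstream — segmentation, shape/color/texture features, the SVM,
the co-training regimes and the case tabulations — is exercised on data made
here, so the generators are first-class, deterministic code:

* :func:`generate_lesion_image` rasterizes an elliptical pigmented lesion on a
  skin-tone background and overlays the artifacts a dermoscope picture
  typically carries (dark curved hairs, bright immersion-fluid bubbles,
  sensor noise), together with the exact ground-truth lesion mask.
* :func:`generate_two_view_dataset` draws a two-view Gaussian-blob
  classification problem (labeled + unlabeled rows) for the semi-supervised
  training regimes.
* :func:`generate_case_table` draws clinical case records (nevus type, lesion
  site, age, sex, study group), with an exact-counts mode that reproduces a
  fixed published-style contingency layout deterministically.

Conventions used throughout the package: images are 8-bit RGB arrays of shape
``(height, width, 3)``; coordinates are row-major and 0-based with pixel
centers at integer coordinates; all randomness flows through
``numpy.random.default_rng(seed)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("nevuscope")

NEVUS_TYPES = ("mixed", "junctional", "intradermal", "acral")

#: Per-type lesion-site counts of the built-in 268-case reference table
#: (rows: mixed, junctional, intradermal, acral).
REFERENCE_CASE_COUNTS = {
    "mixed": {"face": 34, "back": 51},
    "junctional": {"face": 19, "lips": 33, "right ear": 31},
    "intradermal": {"back": 16, "shoulders": 27},
    "acral": {"left middle finger": 32, "foot": 25},
}

SITES = ("face", "back", "lips", "shoulders", "left middle finger", "foot", "right ear")

# Default rendering palette: light skin tone vs dark-brown pigment.
DEFAULT_BACKGROUND = (224, 172, 138)
DEFAULT_LESION = (92, 54, 38)
HAIR_COLOR = (48, 30, 18)


# ---------------------------------------------------------------------------
# lesion images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticLesionSpec:
    """Parameters of one synthetic lesion image.

    ``semi_axes`` are the ellipse semi-axis lengths in pixels, ``rotation`` is
    the ellipse rotation in radians, ``noise_sd`` is the per-channel additive
    Gaussian noise standard deviation in 8-bit intensity units.
    """

    image_height: int = 128
    image_width: int = 128
    background_color: tuple[int, int, int] = DEFAULT_BACKGROUND
    lesion_color: tuple[int, int, int] = DEFAULT_LESION
    center: tuple[float, float] | None = None
    semi_axes: tuple[float, float] = (30.0, 20.0)
    rotation: float = 0.0
    noise_sd: float = 0.0
    n_hairs: int = 0
    n_bubbles: int = 0
    acral_grooves: bool = False
    seed: int = 0

    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return ((self.image_height - 1) / 2.0, (self.image_width - 1) / 2.0)

    def validate(self) -> None:
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError(f"semi_axes must be positive, got {self.semi_axes}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.image_height < 16 or self.image_width < 16:
            raise ValueError("image must be at least 16x16 pixels")
        r0, c0 = self.resolved_center()
        reach = max(a, b)
        if (r0 - reach < 0 or c0 - reach < 0
                or r0 + reach > self.image_height - 1
                or c0 + reach > self.image_width - 1):
            raise ValueError(
                "lesion exceeds image bounds: center "
                f"({r0:.1f}, {c0:.1f}) with semi-axes {self.semi_axes} does not "
                f"fit in a {self.image_height}x{self.image_width} image"
            )


@dataclass
class LabeledImage:
    """An RGB image with its ground-truth lesion mask and clinical tags."""

    image: np.ndarray           # (H, W, 3) uint8
    truth_mask: np.ndarray      # (H, W) uint8 in {0, 1}
    nevus_type: str = "mixed"
    site: str = "face"

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.truth_mask.shape:
            raise ValueError("mask dimensions must equal image dimensions")
        vals = np.unique(self.truth_mask)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("truth_mask must be {0,1}-valued")


def ellipse_mask(height: int, width: int, center: tuple[float, float],
                 semi_axes: tuple[float, float], rotation: float = 0.0) -> np.ndarray:
    """Boolean interior mask of a rotated ellipse (point-in-ellipse test on
    pixel centers)."""
    rr, cc = np.mgrid[0:height, 0:width]
    dr = rr - center[0]
    dc = cc - center[1]
    cos_t, sin_t = math.cos(rotation), math.sin(rotation)
    # rotate into the ellipse frame: u along semi-axis a (row direction at rot=0)
    u = cos_t * dr + sin_t * dc
    v = -sin_t * dr + cos_t * dc
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _draw_hair(img: np.ndarray, rng: np.random.Generator) -> None:
    """One dark quadratic Bezier stroke of width 1-3 px, drawn in place."""
    h, w = img.shape[:2]
    p0 = rng.uniform([0, 0], [h - 1, w - 1])
    p2 = rng.uniform([0, 0], [h - 1, w - 1])
    mid = (p0 + p2) / 2.0
    p1 = mid + rng.normal(0.0, 0.25 * max(h, w), size=2)
    width = rng.integers(1, 4)  # stroke width 1-3 px
    n = 4 * int(np.hypot(*(p2 - p0)) + 1)
    t = np.linspace(0.0, 1.0, max(n, 8))[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2
    radius = (width - 1) / 2.0
    color = np.array(HAIR_COLOR, dtype=np.float64)
    for pr, pc in pts:
        r_lo = max(int(math.floor(pr - radius)), 0)
        r_hi = min(int(math.ceil(pr + radius)), h - 1)
        c_lo = max(int(math.floor(pc - radius)), 0)
        c_hi = min(int(math.ceil(pc + radius)), w - 1)
        if r_lo > r_hi or c_lo > c_hi:
            continue
        img[r_lo:r_hi + 1, c_lo:c_hi + 1] = color


def _draw_bubble(img: np.ndarray, rng: np.random.Generator) -> None:
    """One bright disc with a soft (linear falloff) edge, drawn in place."""
    h, w = img.shape[:2]
    center = rng.uniform([4, 4], [h - 5, w - 5])
    radius = rng.uniform(2.0, 0.06 * max(h, w) + 3.0)
    rr, cc = np.mgrid[0:h, 0:w]
    d = np.hypot(rr - center[0], cc - center[1])
    # full brightness inside, linear fade over one pixel of rim
    alpha = np.clip(radius + 1.0 - d, 0.0, 1.0)
    bright = np.array([252.0, 250.0, 246.0])
    img[:] = (1 - alpha[..., None]) * img + alpha[..., None] * bright


def generate_lesion_image(spec: SyntheticLesionSpec,
                          nevus_type: str = "mixed",
                          site: str = "face") -> LabeledImage:
    """Render a synthetic dermoscopy-style lesion image with ground truth.

    The lesion is a rotated filled ellipse of ``lesion_color`` on
    ``background_color``; hairs and bubbles are overlaid on top of it, then
    i.i.d. Gaussian channel noise (sd ``noise_sd``) is added and clipped to
    [0, 255]. The truth mask marks exactly the ellipse-interior pixels and is
    independent of artifacts and noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(spec.background_color, dtype=np.float64)
    mask = ellipse_mask(h, w, spec.resolved_center(), spec.semi_axes, spec.rotation)
    img[mask] = np.asarray(spec.lesion_color, dtype=np.float64)

    if spec.acral_grooves or nevus_type == "acral":
        # parallel grooves: additive sinusoidal stripes inside the lesion
        rr, cc = np.mgrid[0:h, 0:w]
        phase = 2 * math.pi * (cc * math.cos(spec.rotation) - rr * math.sin(spec.rotation)) / 6.0
        stripes = 22.0 * np.sin(phase)
        img[mask] += stripes[..., None][mask]

    for _ in range(spec.n_hairs):
        _draw_hair(img, rng)
    for _ in range(spec.n_bubbles):
        _draw_bubble(img, rng)

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return LabeledImage(image=img, truth_mask=mask.astype(np.uint8),
                        nevus_type=nevus_type, site=site)


# ---------------------------------------------------------------------------
# two-view feature datasets
# ---------------------------------------------------------------------------

@dataclass
class TwoViewDataset:
    """Row-aligned two-view classification data for co-training experiments.

    ``labels`` holds -1/+1 for labeled rows and 0 for unlabeled rows;
    ``true_labels`` carries the hidden ground truth for every row (used only
    for scoring, never for training). The generation parameters are retained
    so regime comparisons can redraw equivalent datasets under fresh seeds.
    """

    view1: np.ndarray           # (n, d1)
    view2: np.ndarray           # (n, d2)
    labels: np.ndarray          # (n,) in {-1, 0, +1}
    true_labels: np.ndarray     # (n,) in {-1, +1}
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.view1.shape[0]
        if not (self.view2.shape[0] == n == self.labels.shape[0] == self.true_labels.shape[0]):
            raise ValueError("row counts must agree across views and labels")

    @property
    def labeled_idx(self) -> np.ndarray:
        return np.flatnonzero(self.labels != 0)

    @property
    def unlabeled_idx(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 0)


def generate_two_view_dataset(n_labeled: int, n_unlabeled: int,
                              class_separation: float = 2.0,
                              view_correlation: float = 0.5,
                              n_features: tuple[int, int] = (4, 4),
                              seed: int = 0) -> TwoViewDataset:
    """Draw a two-view Gaussian two-class problem.

    Each class is a unit-variance Gaussian blob per view, class means
    separated by ``class_separation`` standard deviations along a random
    direction. The two views share the class signal; their noise is a mix of
    a common component (weight ``view_correlation``) and an independent one,
    so views are informative but not redundant. Labeled counts are split
    evenly between the classes (exact counts, +1 class gets the remainder).
    """
    if n_labeled < 0 or n_unlabeled < 0:
        raise ValueError("counts must be non-negative")
    if not 0.0 <= view_correlation <= 1.0:
        raise ValueError("view_correlation must be in [0, 1]")
    if 0 < n_labeled < 4:
        logger.warning("fewer than 4 labeled examples; supervised training downstream "
                       "may be degenerate")
    rng = np.random.default_rng(seed)
    n = n_labeled + n_unlabeled
    d1, d2 = n_features

    # hidden truth: exact class balance on the labeled block, random on the rest
    lab_truth = np.ones(n_labeled, dtype=int)
    lab_truth[: n_labeled // 2] = -1
    unl_truth = rng.choice([-1, 1], size=n_unlabeled)
    truth = np.concatenate([lab_truth, unl_truth]).astype(int)

    def make_view(d: int, view_index: int) -> np.ndarray:
        # The discriminative direction is a property of the distribution, not
        # of the draw: derive it from a fixed per-view generator so datasets
        # sampled under different seeds share the same class geometry.
        dir_rng = np.random.default_rng(90001 + view_index)
        direction = dir_rng.normal(size=d)
        direction /= np.linalg.norm(direction)
        shared = rng.normal(size=(n, d))
        indep = rng.normal(size=(n, d))
        noise = math.sqrt(view_correlation) * shared + math.sqrt(1 - view_correlation) * indep
        return (truth[:, None] * (class_separation / 2.0) * direction[None, :]) + noise

    view1 = make_view(d1, 1)
    view2 = make_view(d2, 2)

    labels = truth.copy()
    labels[n_labeled:] = 0
    return TwoViewDataset(
        view1=view1, view2=view2, labels=labels, true_labels=truth, seed=seed,
        params=dict(n_labeled=n_labeled, n_unlabeled=n_unlabeled,
                    class_separation=class_separation,
                    view_correlation=view_correlation, n_features=n_features),
    )


# ---------------------------------------------------------------------------
# clinical case tables
# ---------------------------------------------------------------------------

def reference_case_table() -> pd.DataFrame:
    """The built-in deterministic 268-case table with the reference per-type
    lesion-site cell counts (exact-counts mode).

    Cases are numbered in a fixed order; groups alternate observation/control
    so each group holds 134 patients; sexes are assigned so the table holds
    126 males and 142 females; ages cycle deterministically over the study's
    four brackets with the control-group 18-38 bracket fixed at 56 of 134.
    """
    rows: list[dict] = []
    for ntype in NEVUS_TYPES:
        for site, count in REFERENCE_CASE_COUNTS[ntype].items():
            for _ in range(count):
                rows.append({"nevus_type": ntype, "site": site})
    df = pd.DataFrame(rows)
    n = len(df)
    df.insert(0, "patient_id", [f"P{i + 1:04d}" for i in range(n)])
    df.insert(1, "group", ["observation" if i % 2 == 0 else "control" for i in range(n)])
    # 126 males / 142 females, deterministic assignment
    sex = np.array(["female"] * n, dtype=object)
    sex[:126] = "male"
    df.insert(2, "sex", sex)
    df.insert(3, "age", _reference_ages(df["group"].to_numpy()))
    return df[["patient_id", "group", "age", "sex", "nevus_type", "site"]]


def _reference_ages(groups: np.ndarray) -> np.ndarray:
    """Deterministic ages reproducing the study's per-group bracket counts.

    Bracket counts (6-17, 18-38, 39-58, 59-74): control (19, 56, 37, 22),
    observation (9, 61, 38, 26). A representative age inside each bracket is
    assigned in order within each group.
    """
    bracket_reps = {(6, 17): 12, (18, 38): 28, (39, 58): 48, (59, 74): 66}
    counts = {
        "control": [19, 56, 37, 22],
        "observation": [9, 61, 38, 26],
    }
    ages = np.zeros(len(groups), dtype=int)
    for grp, cnts in counts.items():
        idx = np.flatnonzero(groups == grp)
        reps = []
        for (lo_hi, rep), c in zip(bracket_reps.items(), cnts):
            reps.extend([rep] * c)
        ages[idx] = np.asarray(reps[: len(idx)])
    return ages


def generate_case_table(n_cases: int,
                        type_probs=(0.32, 0.31, 0.16, 0.21),
                        site_probs_by_type: dict | None = None,
                        age_range: tuple[int, int] = (6, 74),
                        sex_prob_male: float = 0.47,
                        seed: int = 0,
                        exact: bool = False) -> pd.DataFrame:
    """Draw ``n_cases`` clinical case records.

    With ``exact=True`` the built-in 268-case reference table is returned
    (``n_cases`` must then be 268). Otherwise types, sites, sexes, groups and
    ages are sampled independently per case; empirical type frequencies
    converge to ``type_probs`` as ``n_cases`` grows.
    """
    if exact:
        if n_cases != sum(sum(v.values()) for v in REFERENCE_CASE_COUNTS.values()):
            raise ValueError("exact-counts mode defines a fixed 268-case table")
        return reference_case_table()

    type_probs = np.asarray(type_probs, dtype=float)
    if type_probs.shape != (4,) or abs(type_probs.sum() - 1.0) > 1e-9 or (type_probs < 0).any():
        raise ValueError(f"type_probs must be a 4-vector summing to 1, got {type_probs}")
    if site_probs_by_type is None:
        site_probs_by_type = {
            t: {s: c / sum(d.values()) for s, c in d.items()}
            for t, d in REFERENCE_CASE_COUNTS.items()
        }
    for t, d in site_probs_by_type.items():
        if abs(sum(d.values()) - 1.0) > 1e-9:
            raise ValueError(f"site probabilities for type {t!r} must sum to 1")

    rng = np.random.default_rng(seed)
    types = rng.choice(NEVUS_TYPES, size=n_cases, p=type_probs)
    sites = [
        rng.choice(list(site_probs_by_type[t].keys()),
                   p=list(site_probs_by_type[t].values()))
        for t in types
    ]
    return pd.DataFrame({
        "patient_id": [f"P{i + 1:04d}" for i in range(n_cases)],
        "group": rng.choice(["observation", "control"], size=n_cases),
        "age": rng.integers(age_range[0], age_range[1] + 1, size=n_cases),
        "sex": rng.choice(["male", "female"], size=n_cases,
                          p=[sex_prob_male, 1 - sex_prob_male]),
        "nevus_type": types,
        "site": sites,
    })
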