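"""End-to-end orchestration: image → segmentation → features → classifier →
metrics.

Each input image is segmented, the shape view and the color+texture view are
extracted from its predicted mask, and a classifier is trained and evaluated
under the configured regime (single-view feature training, fused-feature
training, or two-view co-training). Nevus-type labels with more than two
classes are handled one-vs-rest over the two-class SVM, predicting the class
with the largest decision value. A run writes per-stage artifacts (masks,
feature tables, model files, metrics) plus a manifest with the config hash,
the master seed and a checksum per artifact; identical config and seed give
an identical manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluation, features, segmentation
from .semisupervised import CoTrainConfig, co_train, fusion_train
from .svm import KernelSpec, decision_value, train_svm
from .synthgen import LabeledImage

logger = logging.getLogger("nevuscope")

REGIMES = ("feature", "fusion", "cotrain")

# fixed per-stage offsets from the master seed
_STAGE_SEED_OFFSETS = {"split": 11, "train": 23, "cotrain": 37}


@dataclass
class PipelineConfig:
    denoise_radius: int = 2
    target_regions: int = 64
    smooth_radius: int = 3
    artifact_removal: bool = True
    kernel: str = "linear"
    gamma: float | None = None
    degree: int = 3
    penalty: float = 10.0
    regime: str = "fusion"
    test_fraction: float = 0.0
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")

    def kernel_spec(self) -> KernelSpec:
        return KernelSpec(self.kernel, gamma=self.gamma, degree=self.degree)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _checksum(arr_or_bytes) -> str:
    if isinstance(arr_or_bytes, np.ndarray):
        data = np.ascontiguousarray(arr_or_bytes).tobytes()
    elif isinstance(arr_or_bytes, bytes):
        data = arr_or_bytes
    else:
        data = json.dumps(arr_or_bytes, sort_keys=True, default=float).encode()
    return hashlib.sha256(data).hexdigest()[:16]


# ---------------------------------------------------------------------------
# one-vs-rest bridge for >2 classes
# ---------------------------------------------------------------------------

@dataclass
class OneVsRestModel:
    classes: list[str]
    models: dict = field(default_factory=dict)

    def decision_matrix(self, x: np.ndarray) -> np.ndarray:
        return np.stack([np.atleast_1d(decision_value(self.models[c], x))
                         for c in self.classes], axis=1)

    def predict(self, x: np.ndarray) -> np.ndarray:
        g = self.decision_matrix(x)
        return np.asarray(self.classes, dtype=object)[np.argmax(g, axis=1)]


def train_one_vs_rest(x: np.ndarray, labels: np.ndarray, penalty: float,
                      kernel: KernelSpec) -> OneVsRestModel:
    classes = sorted(set(labels))
    ovr = OneVsRestModel(classes=classes)
    for c in classes:
        y = np.where(np.asarray(labels) == c, 1.0, -1.0)
        ovr.models[c] = train_svm(x, y, penalty=penalty, kernel=kernel)
    return ovr


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, images: list[LabeledImage]) -> dict:
    """Execute every stage in order; return the run manifest (metrics inside).

    With two label values the task is two-class (labels sorted; the second is
    the positive class); with more it is one-vs-rest. ``test_fraction > 0``
    holds out a stratified fraction for evaluation, otherwise metrics are
    training (resubstitution) metrics.
    """
    if len(images) < 4:
        raise ValueError("need at least 4 images")
    stage = "segmentation"
    try:
        masks = []
        for k, li in enumerate(images):
            res = segmentation.segment_lesion(
                li.image, denoise_radius=config.denoise_radius,
                target_regions=config.target_regions,
                smooth_radius=config.smooth_radius,
                artifact_removal=config.artifact_removal)
            if not res.mask.any():
                raise RuntimeError(f"image {k}: empty segmentation mask")
            masks.append(res.mask)

        stage = "features"
        shape_rows, ct_rows = [], []
        for k, (li, mask) in enumerate(zip(images, masks)):
            sf = features.extract_shape_features(mask)
            cf = features.extract_color_texture_features(li.image, mask)
            shape_rows.append(sf.values)
            ct_rows.append(cf.values)
        shape_schema = features.extract_shape_features(masks[0]).schema
        ct_schema = features.extract_color_texture_features(images[0].image, masks[0]).schema
        view1 = np.vstack(shape_rows)
        view2 = np.vstack(ct_rows)
        labels = np.asarray([li.nevus_type for li in images], dtype=object)

        stage = "classification"
        classes = sorted(set(labels))
        if len(classes) < 2:
            raise RuntimeError("need at least two classes among the images")

        rng = np.random.default_rng((config.seed + _STAGE_SEED_OFFSETS["split"]) % 2**31)
        idx = np.arange(len(images))
        if config.test_fraction > 0:
            test_idx = []
            for c in classes:
                cls_idx = idx[labels == c]
                rng.shuffle(cls_idx)
                n_test = max(1, int(round(config.test_fraction * len(cls_idx))))
                test_idx.extend(cls_idx[:n_test].tolist())
            test_idx = np.asarray(sorted(test_idx))
            train_idx = np.setdiff1d(idx, test_idx)
        else:
            train_idx = test_idx = idx

        kernel = config.kernel_spec()
        metrics: dict = {"n_train": int(len(train_idx)), "n_test": int(len(test_idx)),
                         "classes": classes, "regime": config.regime}
        if len(classes) == 2:
            y = np.where(labels == classes[1], 1, -1).astype(float)
            y_tr, y_te = y[train_idx], y[test_idx]
            if config.regime == "feature":
                model = train_svm(view1[train_idx], y_tr, config.penalty, kernel)
                scores = np.atleast_1d(decision_value(model, view1[test_idx]))
            elif config.regime == "fusion":
                model = fusion_train(view1[train_idx], view2[train_idx], y_tr,
                                     kernel, config.penalty)
                scores = np.atleast_1d(decision_value(
                    model, np.hstack([view1[test_idx], view2[test_idx]])))
            else:  # cotrain with no unlabeled images reduces to two supervised views
                ct = co_train(view1[train_idx], view2[train_idx], y_tr,
                              np.empty((0, view1.shape[1])), np.empty((0, view2.shape[1])),
                              kernel, config.penalty,
                              CoTrainConfig(seed=(config.seed + _STAGE_SEED_OFFSETS["cotrain"]) % 2**31))
                scores = ct.decision(view1[test_idx], view2[test_idx])
            pred = np.where(scores >= 0, 1, -1)
            metrics.update(evaluation.metrics_report(y_te, pred, scores))
        else:
            feat = view1 if config.regime == "feature" else np.hstack([view1, view2])
            ovr = train_one_vs_rest(feat[train_idx], labels[train_idx],
                                    config.penalty, kernel)
            pred = ovr.predict(feat[test_idx])
            metrics["accuracy"] = round(
                100.0 * float(np.mean(pred == labels[test_idx])), 2)
            metrics["per_class"] = {
                c: evaluation.metrics_report(
                    np.where(labels[test_idx] == c, 1, -1),
                    np.where(pred == c, 1, -1))
                for c in classes
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_images": len(images),
        "stages": {
            "segmentation": {"checksum": _checksum(np.stack(masks))},
            "features": {
                "checksum": _checksum(np.hstack([view1, view2])),
                "view1_schema": list(shape_schema),
                "view2_schema": list(ct_schema),
            },
            "classification": {"checksum": _checksum(metrics)},
        },
        "metrics": metrics,
    }

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        from PIL import Image
        for k, mask in enumerate(masks):
            Image.fromarray((mask * 255).astype(np.uint8)).save(out / f"mask_{k:03d}.png")
        pd.DataFrame(view1, columns=shape_schema).to_csv(out / "features_shape.csv", index=False)
        pd.DataFrame(view2, columns=ct_schema).to_csv(out / "features_color_texture.csv", index=False)
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2, default=float))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest


def make_report(manifest: dict) -> str:
    """Human-readable markdown summary of one pipeline run."""
    lines = ["# nevuscope run report", ""]
    lines.append(f"- config hash: `{manifest.get('config_hash', 'absent')}`")
    lines.append(f"- seed: {manifest.get('seed', 'absent')}")
    lines.append(f"- images: {manifest.get('n_images', 'absent')}")
    lines.append("")
    metrics = manifest.get("metrics") or {}
    if not metrics:
        lines.append("## Metrics\n\n*not run*")
        return "\n".join(lines) + "\n"
    lines.append("## Metrics")
    lines.append("")
    lines.append("| metric | value |")
    lines.append("|---|---|")
    for key in ("regime", "accuracy", "sensitivity_TPR", "specificity_std",
                "paper_FPR", "auc"):
        lines.append(f"| {key} | {metrics.get(key, 'not run')} |")
    per_class = metrics.get("per_class")
    if per_class:
        lines.append("")
        lines.append("## Per-class (one-vs-rest)")
        lines.append("")
        lines.append("| class | sensitivity | specificity | accuracy |")
        lines.append("|---|---|---|---|")
        for c, m in per_class.items():
            lines.append(f"| {c} | {m['sensitivity_TPR']} | {m['specificity_std']} "
                         f"| {m['accuracy']} |")
    return "\n".join(lines) + "\n"
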