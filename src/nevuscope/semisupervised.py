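"""Supervised, fused and semi-supervised (self-/co-) training regimes.

Three ways of using two feature views of the same examples are compared:

* **feature training** — a supervised SVM on one view alone;
* **fusion training** — a supervised SVM on the concatenated views;
* **collaborative (co-)training** — one SVM per view; each round every view
  pseudo-labels its most confident unlabeled examples (largest |decision
  value|) and donates them to the *other* view's labeled pool, and the final
  predictor is the sign of the summed decision values of the two views.

Self-training is the single-view analogue: the classifier augments its own
pool with its own most confident pseudo-labels. Both schemes reduce exactly
to supervised training when there are no unlabeled examples (or the
confidence threshold is unreachable), and no example is ever pseudo-labeled
twice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evaluation
from .svm import KernelSpec, SVMModel, decision_value, predict, train_svm
from .synthgen import TwoViewDataset, generate_two_view_dataset

logger = logging.getLogger("nevuscope")


@dataclass(frozen=True)
class CoTrainConfig:
    """Schedule of the pseudo-labeling loop.

    ``confidence_min`` is the minimum |decision value| an unlabeled example
    needs to be pseudo-labeled; ``k_per_round`` caps additions per class per
    view per round; ``max_rounds`` bounds the loop.
    """

    confidence_min: float = 0.0
    k_per_round: int = 2
    max_rounds: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_per_round < 1:
            raise ValueError("k_per_round must be >= 1")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


def _confident_picks(g: np.ndarray, pool: np.ndarray, config: CoTrainConfig) -> list[int]:
    """Indices (into the pool) of the top-k most confident examples per
    predicted class, subject to the confidence floor; ties by row index."""
    picks: list[int] = []
    for sign in (1, -1):
        cand = np.flatnonzero((np.sign(g) == sign) | ((g == 0) & (sign == 1)))
        cand = cand[np.abs(g[cand]) >= config.confidence_min]
        if cand.size == 0:
            continue
        # stable sort on -|g| keeps row-index order among ties
        order = np.argsort(-np.abs(g[cand]), kind="stable")
        picks.extend(cand[order[: config.k_per_round]].tolist())
    return picks


def self_train(labeled_x: np.ndarray, labeled_y: np.ndarray,
               unlabeled_x: np.ndarray, kernel: KernelSpec, penalty: float,
               config: CoTrainConfig | None = None,
               tol: float = 1e-3) -> SVMModel:
    """Iterative self-labeling: train, pseudo-label the most confident
    unlabeled points, retrain; stop when nothing is added or ``max_rounds``
    is reached."""
    config = config or CoTrainConfig()
    x = np.asarray(labeled_x, dtype=np.float64)
    y = np.asarray(labeled_y, dtype=np.float64).ravel()
    u = np.asarray(unlabeled_x, dtype=np.float64)
    model = train_svm(x, y, penalty=penalty, kernel=kernel, tol=tol)
    pool = np.arange(u.shape[0])
    for _ in range(config.max_rounds):
        if pool.size == 0:
            break
        g = decision_value(model, u[pool])
        picks = _confident_picks(np.atleast_1d(g), pool, config)
        if not picks:
            break
        chosen = pool[picks]
        pseudo = np.where(np.atleast_1d(g)[picks] >= 0, 1.0, -1.0)
        x = np.vstack([x, u[chosen]])
        y = np.concatenate([y, pseudo])
        pool = np.setdiff1d(pool, chosen)
        model = train_svm(x, y, penalty=penalty, kernel=kernel, tol=tol)
    return model


@dataclass
class CoTrainResult:
    model1: SVMModel
    model2: SVMModel
    rounds: int
    n_pseudo_labeled: tuple[int, int] = (0, 0)   # rows donated to view 1, view 2

    def decision(self, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        return np.atleast_1d(decision_value(self.model1, x1)) + \
            np.atleast_1d(decision_value(self.model2, x2))

    def predict(self, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        return np.where(self.decision(x1, x2) >= 0, 1, -1)


def co_train(view1_x: np.ndarray, view2_x: np.ndarray, labeled_y: np.ndarray,
             unlabeled1: np.ndarray, unlabeled2: np.ndarray,
             kernel: KernelSpec, penalty: float,
             config: CoTrainConfig | None = None, tol: float = 1e-3) -> CoTrainResult:
    """Two-view collaborative training with cross-view donation.

    The labeled rows of the two views must be row-aligned (same examples,
    same labels), as must the unlabeled rows. Each round each view's
    classifier picks its most confident unlabeled examples (top
    ``k_per_round`` per class) and donates them, with its pseudo-labels, to
    the other view's labeled pool; an example leaves the shared unlabeled
    pool the first time either view claims it.
    """
    config = config or CoTrainConfig()
    if view1_x.shape[0] != view2_x.shape[0] or unlabeled1.shape[0] != unlabeled2.shape[0]:
        raise ValueError("views must have identical row counts")
    y = np.asarray(labeled_y, dtype=np.float64).ravel()

    pools = {1: (np.asarray(view1_x, float).copy(), y.copy()),
             2: (np.asarray(view2_x, float).copy(), y.copy())}
    u = {1: np.asarray(unlabeled1, float), 2: np.asarray(unlabeled2, float)}
    models = {v: train_svm(*pools[v], penalty=penalty, kernel=kernel, tol=tol)
              for v in (1, 2)}
    shared_pool = np.arange(u[1].shape[0])

    rounds = 0
    n_donated = {1: 0, 2: 0}
    for _ in range(config.max_rounds):
        if shared_pool.size == 0:
            break
        # both views pick concurrently from the same pool, so the scheme is
        # symmetric under swapping the view order
        picks_of = {}
        labels_of = {}
        for v in (1, 2):
            g = np.atleast_1d(decision_value(models[v], u[v][shared_pool]))
            picks = _confident_picks(g, shared_pool, config)
            picks_of[v] = shared_pool[picks] if picks else np.empty(0, dtype=int)
            labels_of[v] = dict(zip(picks_of[v].tolist(),
                                    np.where(g[picks] >= 0, 1.0, -1.0))) if picks else {}
        if picks_of[1].size == 0 and picks_of[2].size == 0:
            break
        # an example picked by both views with conflicting labels is dropped
        # from the pool without being donated
        conflicts = {i for i in set(picks_of[1]) & set(picks_of[2])
                     if labels_of[1][i] != labels_of[2][i]}
        claimed = set(picks_of[1].tolist()) | set(picks_of[2].tolist())
        donations = {1: ([], []), 2: ([], [])}  # receiver -> (rows, labels)
        for v, other in ((1, 2), (2, 1)):
            for i in picks_of[v].tolist():
                if i in conflicts:
                    continue
                donations[other][0].append(i)
                donations[other][1].append(labels_of[v][i])
        for v in (1, 2):
            rows, labs = donations[v]
            if rows:
                xv, yv = pools[v]
                pools[v] = (np.vstack([xv, u[v][rows]]),
                            np.concatenate([yv, labs]))
                n_donated[v] += len(rows)
        shared_pool = np.setdiff1d(shared_pool, np.array(sorted(claimed), dtype=int))
        for v in (1, 2):
            models[v] = train_svm(*pools[v], penalty=penalty, kernel=kernel, tol=tol)
        rounds += 1
    return CoTrainResult(model1=models[1], model2=models[2], rounds=rounds,
                         n_pseudo_labeled=(n_donated[1], n_donated[2]))


def fusion_train(view1_x: np.ndarray, view2_x: np.ndarray, labeled_y: np.ndarray,
                 kernel: KernelSpec, penalty: float, tol: float = 1e-3) -> SVMModel:
    """A single supervised SVM on the concatenated (fused) views."""
    if view1_x.shape[0] != view2_x.shape[0]:
        raise ValueError("views must have identical row counts")
    fused = np.hstack([np.atleast_2d(view1_x), np.atleast_2d(view2_x)])
    return train_svm(fused, labeled_y, penalty=penalty, kernel=kernel, tol=tol)


REGIMES = ("feature_view1", "feature_view2", "fusion", "cotrain")


def compare_regimes(dataset: TwoViewDataset, kernel: KernelSpec, penalty: float,
                    config: CoTrainConfig | None = None, n_seeds: int = 20,
                    n_test: int = 200) -> pd.DataFrame:
    """Mean ± sd of sensitivity/specificity/accuracy per training regime.

    For each of ``n_seeds`` replicates the dataset's stored generation
    parameters are redrawn under a derived seed, each regime is trained on
    the labeled (+ unlabeled, where the regime uses them) rows, and evaluated
    on a freshly drawn held-out labeled sample of ``n_test`` rows from the
    same distribution.
    """
    config = config or CoTrainConfig()
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if not dataset.params:
        raise ValueError("dataset must carry its generation parameters")

    per_regime: dict[str, list[dict]] = {r: [] for r in REGIMES}
    for s in range(n_seeds):
        train_seed = (dataset.seed + 7919 * s) % (2 ** 31)
        test_seed = (dataset.seed + 7919 * s + 104729) % (2 ** 31)
        ds = generate_two_view_dataset(seed=train_seed, **dataset.params)
        test_params = dict(dataset.params, n_labeled=n_test, n_unlabeled=0)
        held = generate_two_view_dataset(seed=test_seed, **test_params)

        li, ui = ds.labeled_idx, ds.unlabeled_idx
        x1, x2, y = ds.view1[li], ds.view2[li], ds.labels[li].astype(float)
        u1, u2 = ds.view1[ui], ds.view2[ui]
        t1, t2, ty = held.view1, held.view2, held.true_labels

        m1 = train_svm(x1, y, penalty=penalty, kernel=kernel)
        m2 = train_svm(x2, y, penalty=penalty, kernel=kernel)
        mf = fusion_train(x1, x2, y, kernel, penalty)
        ct = co_train(x1, x2, y, u1, u2, kernel, penalty, config)

        preds = {
            "feature_view1": predict(m1, t1),
            "feature_view2": predict(m2, t2),
            "fusion": predict(mf, np.hstack([t1, t2])),
            "cotrain": ct.predict(t1, t2),
        }
        for regime, p in preds.items():
            cm = evaluation.confusion_matrix(ty, p)
            per_regime[regime].append({
                "sensitivity": evaluation.sensitivity(cm),
                "specificity": evaluation.specificity_std(cm),
                "accuracy": evaluation.accuracy(cm),
            })

    rows = []
    for regime in REGIMES:
        recs = pd.DataFrame(per_regime[regime])
        row = {"regime": regime, "n_seeds": n_seeds}
        for metric in ("sensitivity", "specificity", "accuracy"):
            row[f"{metric}_mean"] = float(recs[metric].mean())
            row[f"{metric}_sd"] = float(recs[metric].std(ddof=0))
        rows.append(row)
    return pd.DataFrame(rows)
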