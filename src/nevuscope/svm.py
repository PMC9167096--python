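"""From-scratch two-class soft-margin SVM.

The classifier solves the Lagrangian dual of the max-margin problem

    max  Σ a_i − ½ Σ_ij a_i a_j y_i y_j K(x_i, x_j)
    s.t. Σ a_i y_i = 0,  0 ≤ a_i ≤ P,

by pairwise coordinate ascent (SMO) with maximal-KKT-violating-pair working
set selection; the offset b* is recovered from the non-bound support vectors.
The decision function is G(x) = Σ_{i ∈ sv} a_i* y_i K(x_i, x) + b* and the
predicted label is sign(G(x)), with sign(0) → +1.

Kernels: linear x·y, polynomial (γ x·y + c0)^d, sigmoid tanh(γ x·y + c0), and
Gaussian/RBF exp(−||x−y||²/δ²) with the width δ related to the usual shape
parameter by γ = 1/δ². Features are standardized (train-set mean/variance)
before kernel evaluation by default, since the nonlinear kernels are
scale-sensitive; the constants are stored on the model.

The logistic sigmoid activation f(x) = 1/(1+e^(−x)) and its derivative
f(1−f) are provided as standalone utilities.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("nevuscope")

KERNEL_KINDS = ("linear", "polynomial", "sigmoid", "rbf")


# ---------------------------------------------------------------------------
# activation utilities
# ---------------------------------------------------------------------------

def sigmoid_activation(x):
    """Logistic sigmoid 1/(1 + e^(−x)), numerically stable at both tails."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return float(out) if out.ndim == 0 else out


def sigmoid_derivative(x):
    """f'(x) = f(x)·(1 − f(x)) of the logistic sigmoid."""
    f = sigmoid_activation(x)
    return f * (1.0 - f)


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and its parameters. For the RBF kernel either ``gamma``
    or the width ``delta`` may be given (γ = 1/δ²)."""

    kind: str = "linear"
    gamma: float | None = None
    delta: float | None = None
    degree: int = 3
    coef0: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.kind == "rbf":
            if self.gamma is None and self.delta is None:
                object.__setattr__(self, "gamma", 1.0)
            elif self.gamma is None:
                if self.delta <= 0:
                    raise ValueError("delta must be positive")
                object.__setattr__(self, "gamma", 1.0 / self.delta ** 2)
            if self.gamma <= 0:
                raise ValueError("gamma must be positive")
            object.__setattr__(self, "delta", 1.0 / np.sqrt(self.gamma))
        elif self.gamma is None:
            object.__setattr__(self, "gamma", 1.0)


def kernel_eval(spec: KernelSpec, x, y) -> float:
    """K(x, y) for one pair of equal-dimension vectors."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(kernel_matrix(spec, x[None, :], y[None, :])[0, 0])


def kernel_matrix(spec: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Gram matrix K[i, j] = K(A_i, B_j)."""
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    if spec.kind == "linear":
        return A @ B.T
    if spec.kind == "polynomial":
        return (spec.gamma * (A @ B.T) + spec.coef0) ** spec.degree
    if spec.kind == "sigmoid":
        return np.tanh(spec.gamma * (A @ B.T) + spec.coef0)
    # rbf
    sq = (np.sum(A * A, axis=1)[:, None] + np.sum(B * B, axis=1)[None, :]
          - 2.0 * (A @ B.T))
    return np.exp(-spec.gamma * np.maximum(sq, 0.0))


# ---------------------------------------------------------------------------
# model and training
# ---------------------------------------------------------------------------

@dataclass
class SVMModel:
    support_vectors: np.ndarray     # (m, d), in standardized space
    sv_labels: np.ndarray           # (m,) in {-1, +1}
    multipliers: np.ndarray         # (m,) a_i* in (0, P]
    offset: float                   # b*
    kernel: KernelSpec
    penalty: float
    mean_: np.ndarray               # standardization constants (d,)
    scale_: np.ndarray
    converged: bool = True
    n_features: int = 0
    dual_objective: float = 0.0

    def check_kkt(self, tol: float = 1e-6) -> None:
        """Raise if the stored multipliers violate the dual constraints."""
        bal = abs(float(np.sum(self.multipliers * self.sv_labels)))
        if bal > tol:
            raise ValueError(f"Σ a_i y_i = {bal:g} exceeds tolerance")
        if (self.multipliers < -tol).any() or (self.multipliers > self.penalty + tol).any():
            raise ValueError("multipliers outside [0, P]")


def _validate_training_set(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("x must be (n, d) with one label per row")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training points")
    if not np.isfinite(x).all() or not np.isfinite(y).all():
        raise ValueError("training data must be finite")
    if not np.all(np.isin(y, [-1.0, 1.0])):
        raise ValueError("labels must be in {-1, +1}")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return x, y


def train_svm(x: np.ndarray, y: np.ndarray, penalty: float = 1.0,
              kernel: KernelSpec | None = None, tol: float = 1e-3,
              max_iter: int = 10_000, standardize: bool = True) -> SVMModel:
    """Fit the soft-margin dual by SMO.

    ``tol`` is the maximal allowed KKT violation (the gap between the most
    violating up/down pair); ``max_iter`` bounds the number of pairwise
    updates per training point (n·max_iter updates total). On non-convergence
    the best iterate is returned with ``converged=False`` and a warning.
    """
    x, y = _validate_training_set(x, y)
    if penalty <= 0:
        raise ValueError("penalty P must be positive")
    kernel = kernel or KernelSpec("linear")
    n, d = x.shape

    if standardize:
        mean = x.mean(axis=0)
        scale = x.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        mean = np.zeros(d)
        scale = np.ones(d)
    xs = (x - mean) / scale

    K = kernel_matrix(kernel, xs, xs)
    Q = (y[:, None] * y[None, :]) * K
    a = np.zeros(n)
    grad = -np.ones(n)          # gradient of ½aᵀQa − Σa at a = 0
    C = float(penalty)
    tau = 1e-12

    converged = False
    max_updates = max_iter * n
    for _ in range(max_updates):
        # maximal violating pair
        up = ((y > 0) & (a < C - 1e-12)) | ((y < 0) & (a > 1e-12))
        low = ((y < 0) & (a < C - 1e-12)) | ((y > 0) & (a > 1e-12))
        neg_yg = -y * grad
        if not up.any() or not low.any():
            converged = True
            break
        i = int(np.flatnonzero(up)[np.argmax(neg_yg[up])])
        j = int(np.flatnonzero(low)[np.argmin(neg_yg[low])])
        if neg_yg[i] - neg_yg[j] <= tol:
            converged = True
            break

        old_ai, old_aj = a[i], a[j]
        if y[i] != y[j]:
            quad = max(Q[i, i] + Q[j, j] + 2.0 * Q[i, j], tau)
            delta = (-grad[i] - grad[j]) / quad
            diff = old_ai - old_aj
            ai, aj = old_ai + delta, old_aj + delta
            if diff > 0:
                if aj < 0:
                    aj, ai = 0.0, diff
            else:
                if ai < 0:
                    ai, aj = 0.0, -diff
            if diff > 0:
                if ai > C:
                    ai, aj = C, C - diff
            else:
                if aj > C:
                    aj, ai = C, C + diff
        else:
            quad = max(Q[i, i] + Q[j, j] - 2.0 * Q[i, j], tau)
            delta = (grad[i] - grad[j]) / quad
            s = old_ai + old_aj
            ai, aj = old_ai - delta, old_aj + delta
            if s > C:
                if ai > C:
                    ai, aj = C, s - C
            else:
                if aj < 0:
                    aj, ai = 0.0, s
            if s > C:
                if aj > C:
                    aj, ai = C, s - C
            else:
                if ai < 0:
                    ai, aj = 0.0, s
        a[i], a[j] = ai, aj
        grad += Q[:, i] * (ai - old_ai) + Q[:, j] * (aj - old_aj)

    if not converged:
        logger.warning("SMO did not reach tol=%g within %d updates", tol, max_updates)

    # offset b*: average over non-bound support vectors of y_i − Σ_j a_j y_j K_ij
    free = (a > 1e-8) & (a < C - 1e-8)
    if free.any():
        b = float(np.mean(-y[free] * grad[free]))
    else:
        up = ((y > 0) & (a < C - 1e-12)) | ((y < 0) & (a > 1e-12))
        low = ((y < 0) & (a < C - 1e-12)) | ((y > 0) & (a > 1e-12))
        neg_yg = -y * grad
        hi = neg_yg[up].max() if up.any() else 0.0
        lo = neg_yg[low].min() if low.any() else 0.0
        b = float((hi + lo) / 2.0)

    sv = a > 1e-8
    dual_obj = float(np.sum(a) - 0.5 * a @ Q @ a)
    return SVMModel(
        support_vectors=xs[sv].copy(), sv_labels=y[sv].copy(),
        multipliers=a[sv].copy(), offset=b, kernel=kernel, penalty=C,
        mean_=mean, scale_=scale, converged=converged, n_features=d,
        dual_objective=dual_obj,
    )


def decision_value(model: SVMModel, x: np.ndarray):
    """Signed pre-threshold value G(x) = Σ a_i* y_i K(x_i, x) + b*.

    Accepts one vector (returns float) or an (n, d) matrix (returns array).
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, got {X.shape[1]}")
    Xs = (X - model.mean_) / model.scale_
    if model.support_vectors.shape[0] == 0:
        g = np.full(X.shape[0], model.offset)
    else:
        K = kernel_matrix(model.kernel, Xs, model.support_vectors)
        g = K @ (model.multipliers * model.sv_labels) + model.offset
    return float(g[0]) if single else g


def predict(model: SVMModel, x: np.ndarray):
    """sign(G(x)) with the tie sign(0) → +1."""
    g = decision_value(model, x)
    if np.isscalar(g):
        return 1 if g >= 0 else -1
    return np.where(np.asarray(g) >= 0, 1, -1)


# ---------------------------------------------------------------------------
# cross-validated grid search
# ---------------------------------------------------------------------------

def stratified_folds(y: np.ndarray, folds: int, seed: int = 0) -> list[np.ndarray]:
    """Index arrays of a stratified k-fold split (shuffled within class)."""
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < folds:
            raise ValueError(f"class {cls} has {len(idx)} members, fewer than {folds} folds")
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return [np.flatnonzero(assignment == f) for f in range(folds)]


def grid_search(x: np.ndarray, y: np.ndarray, kernel_kinds=("linear", "rbf"),
                P_grid=(0.1, 1.0, 10.0), gamma_grid=(0.1, 1.0),
                folds: int = 5, seed: int = 0,
                degree: int = 3, coef0: float = 0.0):
    """Stratified k-fold CV accuracy over a (kernel, P, γ) grid.

    Returns ``(best_kernel_spec, best_P, table)`` where the table holds one
    row per setting with its mean CV accuracy. Ties are broken toward smaller
    P, then smaller γ, then kernel order as listed.
    """
    x, y = _validate_training_set(x, y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    fold_idx = stratified_folds(y, folds, seed)
    all_idx = np.arange(len(y))

    rows = []
    best = None  # (accuracy, record index)
    for kind in kernel_kinds:
        gammas = [None] if kind == "linear" else sorted(gamma_grid)
        for P in sorted(P_grid):
            for g in gammas:
                spec = KernelSpec(kind, gamma=g, degree=degree, coef0=coef0)
                correct = 0
                for test in fold_idx:
                    train = np.setdiff1d(all_idx, test)
                    model = train_svm(x[train], y[train], penalty=P, kernel=spec)
                    correct += int(np.sum(predict(model, x[test]) == y[test]))
                acc = correct / len(y)
                rows.append({"kernel": kind, "P": P,
                             "gamma": np.nan if g is None else g,
                             "cv_accuracy": acc, "n": len(y)})
                if best is None or acc > best[0]:
                    best = (acc, len(rows) - 1)
    table = pd.DataFrame(rows)
    rec = rows[best[1]]
    g = None if np.isnan(rec["gamma"]) else rec["gamma"]
    return KernelSpec(rec["kernel"], gamma=g, degree=degree, coef0=coef0), rec["P"], table


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model: SVMModel, path) -> None:
    payload = {
        "format_version": _FORMAT_VERSION,
        "support_vectors": model.support_vectors.tolist(),
        "sv_labels": model.sv_labels.tolist(),
        "multipliers": model.multipliers.tolist(),
        "offset": model.offset,
        "kernel": {"kind": model.kernel.kind, "gamma": model.kernel.gamma,
                   "degree": model.kernel.degree, "coef0": model.kernel.coef0},
        "penalty": model.penalty,
        "mean": model.mean_.tolist(),
        "scale": model.scale_.tolist(),
        "converged": model.converged,
        "n_features": model.n_features,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> SVMModel:
    p = json.loads(Path(path).read_text())
    if p.get("format_version") != _FORMAT_VERSION:
        raise ValueError("unsupported model format version")
    k = p["kernel"]
    return SVMModel(
        support_vectors=np.asarray(p["support_vectors"], dtype=np.float64).reshape(-1, p["n_features"]),
        sv_labels=np.asarray(p["sv_labels"], dtype=np.float64),
        multipliers=np.asarray(p["multipliers"], dtype=np.float64),
        offset=float(p["offset"]),
        kernel=KernelSpec(k["kind"], gamma=k["gamma"], degree=k["degree"], coef0=k["coef0"]),
        penalty=float(p["penalty"]),
        mean_=np.asarray(p["mean"], dtype=np.float64),
        scale_=np.asarray(p["scale"], dtype=np.float64),
        converged=bool(p["converged"]),
        n_features=int(p["n_features"]),
    )
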