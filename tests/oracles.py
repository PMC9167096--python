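"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: the dual QP is solved by
a generic constrained optimizer, moments by explicit double loops, AUC by
exhaustive pair counting, and ellipse areas by a dense point-in-ellipse scan.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize

from nevuscope.svm import KernelSpec, kernel_matrix


def solve_dual_qp(x: np.ndarray, y: np.ndarray, C: float, spec: KernelSpec):
    """Dense SLSQP solve of the soft-margin dual; returns (a, b)."""
    K = kernel_matrix(spec, x, x)
    Q = (y[:, None] * y[None, :]) * K
    n = len(y)

    def f(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - 1.0

    cons = [{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}]
    res = minimize(f, np.zeros(n), jac=grad, bounds=[(0.0, C)] * n,
                   constraints=cons, method="SLSQP",
                   options={"ftol": 1e-14, "maxiter": 2000})
    a = res.x
    g = Q @ a - 1.0
    free = (a > 1e-7) & (a < C - 1e-7)
    if free.any():
        b = float(np.mean(-y[free] * g[free]))
    else:
        up = ((y > 0) & (a < C - 1e-12)) | ((y < 0) & (a > 1e-12))
        low = ((y < 0) & (a < C - 1e-12)) | ((y > 0) & (a > 1e-12))
        ng = -y * g
        b = float((ng[up].max() + ng[low].min()) / 2.0)
    return a, b


def qp_decision_values(x, y, a, b, spec: KernelSpec, x_test) -> np.ndarray:
    K = kernel_matrix(spec, np.atleast_2d(x_test), x)
    return K @ (a * y) + b


def brute_force_moment(mask: np.ndarray, p: int, q: int) -> float:
    total = 0.0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j]:
                total += i ** p * j ** q
    return total


def brute_force_central_moment(mask: np.ndarray, p: int, q: int) -> float:
    s00 = brute_force_moment(mask, 0, 0)
    r0 = brute_force_moment(mask, 1, 0) / s00
    c0 = brute_force_moment(mask, 0, 1) / s00
    total = 0.0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j]:
                total += (i - r0) ** p * (j - c0) ** q
    return total


def pair_count_auc(scores, truth) -> float:
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    pos = scores[truth == 1]
    neg = scores[truth == -1]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def ellipse_pixel_area(center, semi_axes, rotation, height, width) -> int:
    """Count pixels whose integer center lies inside the rotated ellipse."""
    count = 0
    a, b = semi_axes
    ct, st = math.cos(rotation), math.sin(rotation)
    for i in range(height):
        for j in range(width):
            dr, dc = i - center[0], j - center[1]
            u = ct * dr + st * dc
            v = -st * dr + ct * dc
            if (u / a) ** 2 + (v / b) ** 2 <= 1.0:
                count += 1
    return count
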