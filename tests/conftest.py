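"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize

from svmt import LabeledExpressionData


def dual_qp_oracle(X, y, C):
    """Independent linear-SVM solver: maximise the soft-margin dual with SLSQP.

    maximise  sum_i a_i - 0.5 * a' Q a   with Q_ij = y_i y_j x_i.x_j
    subject to 0 <= a_i <= C,  sum_i a_i y_i = 0.

    Returns (weights, intercept, multipliers).  Only meant for tiny
    problems; it shares no code with the package's fitting path.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    G = (y[:, None] * X) @ (y[:, None] * X).T

    def fun(a):
        return 0.5 * a @ G @ a - a.sum()

    def jac(a):
        return G @ a - 1.0

    res = minimize(
        fun,
        np.full(n, min(C, 1.0) / 2),
        jac=jac,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    assert res.success, res.message
    a = res.x
    w = (a * y) @ X
    margin = (a > 1e-6 * C) & (a < C * (1 - 1e-6))
    if margin.any():
        b = float(np.mean(y[margin] - X[margin] @ w))
    else:  # all SVs at the box bound; midpoint rule
        sv = a > 1e-6 * C
        b = float(np.mean(y[sv] - X[sv] @ w))
    return w, b, a


def make_data(values, labels, prefix="g"):
    values = np.asarray(values, dtype=float)
    return LabeledExpressionData(
        values=values,
        labels=labels,
        gene_ids=tuple(f"{prefix}{j + 1}" for j in range(values.shape[1])),
        sample_ids=tuple(f"s{i + 1}" for i in range(values.shape[0])),
    )


@pytest.fixture
def two_point_data():
    """1-D symmetric pair: x = +1/-1 with matching labels."""
    return make_data([[1.0], [-1.0]], [1, -1])


@pytest.fixture
def separable_2d_data():
    """4-point 2-D linearly separable toy set."""
    values = [[2.0, 2.0], [2.5, 1.0], [-1.0, -1.5], [-2.0, -0.5]]
    return make_data(values, [1, 1, -1, -1])


@pytest.fixture
def random_toy_data():
    """10-sample, 5-gene linearly separable random set (fixed seed)."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(10, 5))
    X[:5, 0] += 3.0  # gene 1 separates
    return make_data(X, [1] * 5 + [-1] * 5)


@pytest.fixture
def one_informative_gene_data():
    """8 samples, 6 genes; gene 1 alone perfectly separates the classes."""
    rng = np.random.default_rng(7)
    X = rng.normal(scale=0.5, size=(8, 6))
    X[:4, 0] = [3.0, 3.2, 2.8, 3.1]
    X[4:, 0] = [-3.0, -2.9, -3.3, -3.1]
    return make_data(X, [1] * 4 + [-1] * 4)
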