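"""Linear soft-margin SVM fit and support-vector extraction.

The decision function is ``sgn(w.x + b)`` with ``w = sum_i alpha_i y_i x_i``;
only samples with nonzero dual multiplier (the support vectors) contribute.
All three ranking criteria in :mod:`svmt.criteria` consume the model
produced here, so the solver configuration is fixed and deterministic:
results must not depend on run-to-run solver state.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.svm import SVC

from .data import LabeledExpressionData
from .errors import FitError, NoSupportVectorError

__all__ = ["LinearSVMModel", "fit_linear_svm", "support_vector_split", "DEFAULT_COST"]

#: Default soft-margin penalty C.  The criteria and the number of support
#: vectors depend on it, so it is surfaced on every public entry point.
DEFAULT_COST: float = 1.0

# Solver convergence tolerance; fixed so repeated fits are byte-identical.
# Tight enough that symmetry properties (label negation, sample permutation)
# hold to ~1e-12 on the weight vector; costs nothing at these problem sizes.
_SOLVER_TOL = 1e-12


def _sv_tolerance(cost: float) -> float:
    # Scale-free: multipliers live in [0, cost].
    return 1e-8 * cost


@dataclasses.dataclass(frozen=True)
class LinearSVMModel:
    """A fitted linear soft-margin SVM.

    ``weights`` is reconstructible as ``sum_i multipliers[i]*labels[i]*x_i``;
    multipliers satisfy the box constraint ``0 <= alpha_i <= cost`` and the
    equality constraint ``sum_i alpha_i y_i = 0``.
    """

    weights: np.ndarray
    intercept: float
    multipliers: np.ndarray
    labels: np.ndarray
    cost: float
    sv_indices: np.ndarray
    sv_indices_pos: np.ndarray
    sv_indices_neg: np.ndarray

    @property
    def n_sv(self) -> int:
        return self.sv_indices.size

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted class labels in {+1, -1}; ties on the hyperplane go to +1."""
        return np.where(self.decision_function(X) >= 0, 1, -1)

    def error_rate(self, data: LabeledExpressionData) -> float:
        """Misclassification fraction of ``data`` under this model."""
        return float(np.mean(self.predict(data.values) != data.labels))


def fit_linear_svm(
    data: LabeledExpressionData, cost: float = DEFAULT_COST
) -> LinearSVMModel:
    """Fit a linear soft-margin SVM.

    Parameters
    ----------
    data
        Two-class expression data (both classes present by construction).
    cost
        Soft-margin penalty C > 0 bounding the dual multipliers.

    Raises
    ------
    FitError
        If ``cost <= 0`` or the data degenerate (single class, no genes;
        normally prevented by the container invariants).
    NoSupportVectorError
        If either class ends with no support vector above tolerance.
    """
    if cost <= 0:
        raise FitError(f"cost must be > 0, got {cost}")
    labels = np.asarray(data.labels)
    if np.unique(labels).size < 2:
        raise FitError("single-class input: SVM requires both classes")
    if data.n_genes == 0:
        raise FitError("zero-gene matrix")

    clf = SVC(kernel="linear", C=cost, tol=_SOLVER_TOL, shrinking=True)
    clf.fit(data.values, labels)

    multipliers = np.zeros(data.n_samples)
    # dual_coef_ holds alpha_i * y_i for the support rows.
    multipliers[clf.support_] = np.abs(clf.dual_coef_[0])
    weights = np.asarray(clf.coef_[0], dtype=float)
    intercept = float(clf.intercept_[0])

    tol = _sv_tolerance(cost)
    sv = np.flatnonzero(multipliers > tol)
    sv_pos = sv[labels[sv] == 1]
    sv_neg = sv[labels[sv] == -1]
    if sv_pos.size == 0 or sv_neg.size == 0:
        raise NoSupportVectorError(
            "a class has no support vectors above tolerance "
            f"(n_pos={sv_pos.size}, n_neg={sv_neg.size})"
        )
    return LinearSVMModel(
        weights=weights,
        intercept=intercept,
        multipliers=multipliers,
        labels=labels,
        cost=cost,
        sv_indices=sv,
        sv_indices_pos=sv_pos,
        sv_indices_neg=sv_neg,
    )


def support_vector_split(
    model: LinearSVMModel,
    data: LabeledExpressionData,
    tol: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split support-vector sample indices by class.

    ``tol`` defaults to the scale-free fitting tolerance ``1e-8 * cost``.
    Raises :class:`NoSupportVectorError` if the threshold empties a class,
    in which case the SV-restricted t criterion is undefined.
    """
    if tol is None:
        tol = _sv_tolerance(model.cost)
    if tol < 0:
        raise NoSupportVectorError(f"tolerance must be >= 0, got {tol}")
    sv = np.flatnonzero(model.multipliers > tol)
    pos = sv[data.labels[sv] == 1]
    neg = sv[data.labels[sv] == -1]
    if pos.size == 0 or neg.size == 0:
        raise NoSupportVectorError(
            f"tolerance {tol} leaves a class without support vectors "
            f"(n_pos={pos.size}, n_neg={neg.size})"
        )
    return pos, neg
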