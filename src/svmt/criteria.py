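"""Per-gene ranking criteria: SVMRFE, RSVM and the SV-restricted t (SVM-t).

SVMRFE ranks genes by the squared weight ``w_j**2`` of the linear SVM.
RSVM ranks by the signed product ``w_j * (m_j+ - m_j-)`` of the weight and
the full-sample class-mean difference.  SVM-t ranks by the absolute
Welch-form t-statistic of each gene computed over support-vector samples
only: the SVM acts as a sampling device that trims non-informative samples
before a univariate test.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .data import LabeledExpressionData
from .errors import NoSupportVectorError, SVMTError
from .svm import LinearSVMModel

__all__ = [
    "RankingScores",
    "SVTComponents",
    "score_svmrfe",
    "score_rsvm",
    "score_svmt",
    "svt_components",
    "rank_and_keep",
    "METHODS",
]

#: Criterion tags accepted throughout the package.
METHODS = ("svmt", "svmrfe", "rsvm")


@dataclasses.dataclass(frozen=True)
class RankingScores:
    """Per-gene criterion values for one method.

    ``scores`` entries are finite or ``+inf`` (the zero-within-SV-variance
    rule for SVM-t); higher means more important.  For RSVM the scores are
    signed and ranking is by the signed value, exactly as the criterion is
    defined.
    """

    method: str
    scores: np.ndarray
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise SVMTError(f"unknown method tag {self.method!r}")
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (len(self.gene_ids),):
            raise SVMTError("scores length does not match gene_ids")
        if np.isnan(scores).any():
            raise SVMTError("NaN ranking score")
        object.__setattr__(self, "scores", scores)


@dataclasses.dataclass(frozen=True)
class SVTComponents:
    """Support-vector-restricted per-gene summary statistics.

    Means are defined for any SV count >= 1; sample standard deviations
    (n-1 convention) only when the corresponding class has >= 2 support
    vectors, else NaN placeholders that the criterion never touches.
    """

    mean_pos: np.ndarray
    mean_neg: np.ndarray
    sd_pos: np.ndarray
    sd_neg: np.ndarray
    n_pos: int
    n_neg: int


def score_svmrfe(
    model: LinearSVMModel, gene_ids: Sequence[str] | None = None
) -> RankingScores:
    """Squared weight-vector entries ``w_j**2``."""
    if gene_ids is None:
        gene_ids = tuple(str(j) for j in range(model.weights.size))
    return RankingScores(
        method="svmrfe", scores=model.weights**2, gene_ids=tuple(gene_ids)
    )


def score_rsvm(model: LinearSVMModel, data: LabeledExpressionData) -> RankingScores:
    """Signed ``w_j * (m_j+ - m_j-)`` with class means over ALL samples."""
    m_pos = data.values[data.class_mask(1)].mean(axis=0)
    m_neg = data.values[data.class_mask(-1)].mean(axis=0)
    return RankingScores(
        method="rsvm",
        scores=model.weights * (m_pos - m_neg),
        gene_ids=data.gene_ids,
    )


def svt_components(
    data: LabeledExpressionData,
    sv_pos: np.ndarray,
    sv_neg: np.ndarray,
) -> SVTComponents:
    """Per-gene SV-restricted means/sds and the SV counts per class."""
    sv_pos = np.asarray(sv_pos, dtype=int)
    sv_neg = np.asarray(sv_neg, dtype=int)
    if sv_pos.size == 0 or sv_neg.size == 0:
        raise NoSupportVectorError("empty support-vector set on one side")
    Xp = data.values[sv_pos]
    Xn = data.values[sv_neg]
    sd_pos = Xp.std(axis=0, ddof=1) if sv_pos.size >= 2 else np.full(data.n_genes, np.nan)
    sd_neg = Xn.std(axis=0, ddof=1) if sv_neg.size >= 2 else np.full(data.n_genes, np.nan)
    return SVTComponents(
        mean_pos=Xp.mean(axis=0),
        mean_neg=Xn.mean(axis=0),
        sd_pos=sd_pos,
        sd_neg=sd_neg,
        n_pos=int(sv_pos.size),
        n_neg=int(sv_neg.size),
    )


def score_svmt(
    data: LabeledExpressionData,
    sv_pos: np.ndarray,
    sv_neg: np.ndarray,
) -> RankingScores:
    """Absolute Welch-form t computed over support-vector samples only.

    Four regimes, by the SV count on each side:

    a. one SV per class: the plain absolute difference ``|u+ - u-|``;
    b. single SV in class -1: one-sample form ``|u+ - u-| / sqrt(s+^2/n+)``;
    c. single SV in class +1: one-sample form with the class -1 variance;
    d. >= 2 SVs per class: the full Welch denominator
       ``sqrt(s+^2/n+ + s-^2/n-)``.

    Zero denominator (zero within-SV variance): the gene scores ``+inf``
    when the SV means differ (a perfectly separated constant gene is
    maximally informative among SVs) and 0 when they are equal too.
    """
    comp = svt_components(data, sv_pos, sv_neg)
    diff = np.abs(comp.mean_pos - comp.mean_neg)
    if comp.n_pos == 1 and comp.n_neg == 1:
        return RankingScores(method="svmt", scores=diff, gene_ids=data.gene_ids)
    if comp.n_neg == 1:
        denom_sq = comp.sd_pos**2 / comp.n_pos
    elif comp.n_pos == 1:
        denom_sq = comp.sd_neg**2 / comp.n_neg
    else:
        denom_sq = comp.sd_pos**2 / comp.n_pos + comp.sd_neg**2 / comp.n_neg
    denom = np.sqrt(denom_sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(
            denom > 0, diff / np.where(denom > 0, denom, 1.0),
            np.where(diff > 0, np.inf, 0.0),
        )
    return RankingScores(method="svmt", scores=scores, gene_ids=data.gene_ids)


def rank_and_keep(scores: RankingScores, d: int) -> list[str]:
    """The ``d`` gene ids with the highest scores.

    Sorted by score descending; ties broken by ascending original gene
    index (stable), so results are reproducible bit-for-bit.
    """
    if d <= 0:
        raise SVMTError(f"number of genes to keep must be positive, got {d}")
    n = len(scores.gene_ids)
    if d > n:
        raise SVMTError(f"cannot keep {d} genes out of {n}")
    order = np.argsort(-scores.scores, kind="stable")
    return [scores.gene_ids[i] for i in order[:d]]


def scores_for(
    method: str,
    model: LinearSVMModel,
    data: LabeledExpressionData,
) -> RankingScores:
    """Dispatch a criterion tag to its scoring routine."""
    if method == "svmrfe":
        return score_svmrfe(model, gene_ids=data.gene_ids)
    if method == "rsvm":
        return score_rsvm(model, data)
    if method == "svmt":
        return score_svmt(data, model.sv_indices_pos, model.sv_indices_neg)
    raise SVMTError(f"unknown method tag {method!r}")
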