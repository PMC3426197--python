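"""Backward elimination down a geometric level ladder, with CV2 evaluation.

The procedure fixes a monotone decreasing sequence of retained-gene counts
(the *ladder*), refits the SVM at every level, scores the surviving genes
with one of the three criteria and keeps the top of the ranking for the
next level.  Cross-validated evaluation ("CV2") reruns the whole selection
inside every training fold, which is the unbiased way to estimate the error
of a selected gene set.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .criteria import METHODS, rank_and_keep, scores_for
from .data import LabeledExpressionData
from .errors import EliminationError, FoldError, LadderError, SVMTError
from .svm import DEFAULT_COST, LinearSVMModel, fit_linear_svm

__all__ = [
    "EliminationLadder",
    "LevelRecord",
    "EliminationPath",
    "CVReport",
    "make_ladder",
    "run_elimination",
    "cv2_evaluate",
    "select_best",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class EliminationLadder:
    """Strictly decreasing retained-gene counts ``{d_k, ..., d_0}``."""

    levels: tuple[int, ...]
    ratio: float | None = None
    d_min: int | None = None

    def __post_init__(self) -> None:
        levels = tuple(int(d) for d in self.levels)
        if not levels:
            raise LadderError("empty ladder")
        if any(d <= 0 for d in levels):
            raise LadderError("ladder levels must be positive")
        if any(a <= b for a, b in zip(levels, levels[1:])):
            raise LadderError(f"ladder must be strictly decreasing: {levels}")
        object.__setattr__(self, "levels", levels)

    def __len__(self) -> int:
        return len(self.levels)

    def __iter__(self) -> Iterator[int]:
        return iter(self.levels)


def make_ladder(p_start: int, ratio: float, d_min: int) -> EliminationLadder:
    """Geometric ladder from ``p_start`` down to ``d_min``.

    Each level is the previous one times ``ratio``, rounded half to even;
    if rounding stalls the level is decremented by one so the sequence
    stays strictly decreasing.  The first level at or below ``d_min`` is
    clamped to ``d_min`` and ends the ladder.
    """
    if not 0 < ratio < 1:
        raise LadderError(f"ratio must be in (0, 1), got {ratio}")
    if d_min <= 0:
        raise LadderError(f"d_min must be positive, got {d_min}")
    if d_min > p_start:
        raise LadderError(f"d_min={d_min} exceeds starting gene count {p_start}")
    levels = [int(p_start)]
    while levels[-1] > d_min:
        nxt = int(round(ratio * levels[-1]))  # round half to even
        if nxt >= levels[-1]:
            nxt = levels[-1] - 1
        if nxt <= d_min:
            nxt = d_min
        levels.append(nxt)
    return EliminationLadder(levels=tuple(levels), ratio=ratio, d_min=d_min)


@dataclasses.dataclass(frozen=True)
class LevelRecord:
    """One ladder level of an elimination path."""

    level: int
    gene_ids: tuple[str, ...]
    n_sv: int
    holdout_error: float | None = None
    model: LinearSVMModel | None = None


@dataclasses.dataclass(frozen=True)
class EliminationPath:
    """Nested gene subsets down the ladder with per-level fit summaries."""

    method: str
    cost: float
    records: tuple[LevelRecord, ...]

    @property
    def levels(self) -> tuple[int, ...]:
        return tuple(r.level for r in self.records)

    def record_at(self, level: int) -> LevelRecord:
        for r in self.records:
            if r.level == level:
                return r
        raise SVMTError(f"level {level} not in path (levels {self.levels})")

    def genes_at(self, level: int) -> tuple[str, ...]:
        return self.record_at(level).gene_ids

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": [r.level for r in self.records],
                "n_sv": [r.n_sv for r in self.records],
                "holdout_error": [r.holdout_error for r in self.records],
            }
        )


def run_elimination(
    data: LabeledExpressionData,
    ladder: EliminationLadder,
    method: str,
    cost: float = DEFAULT_COST,
    test_data: LabeledExpressionData | None = None,
    keep_models: bool = False,
) -> EliminationPath:
    """Backward elimination of ``data``'s genes down ``ladder``.

    At every level the SVM is refit on the surviving genes, its SV count
    (and, when ``test_data`` is given, its hold-out error) recorded, the
    criterion evaluated and the top ``d_next`` genes kept.  Gene sets are
    strictly nested across consecutive levels.
    """
    if method not in METHODS:
        raise SVMTError(f"unknown method tag {method!r}")
    if ladder.levels[0] != data.n_genes:
        raise LadderError(
            f"ladder starts at {ladder.levels[0]} but data has {data.n_genes} genes"
        )
    current = data
    records: list[LevelRecord] = []
    for i, d in enumerate(ladder.levels):
        try:
            model = fit_linear_svm(current, cost=cost)
        except SVMTError as exc:
            raise EliminationError(f"level {d}: {exc}") from exc
        holdout = None
        if test_data is not None:
            holdout = model.error_rate(test_data.subset_genes(current.gene_ids))
        records.append(
            LevelRecord(
                level=d,
                gene_ids=current.gene_ids,
                n_sv=model.n_sv,
                holdout_error=holdout,
                model=model if keep_models else None,
            )
        )
        if i + 1 < len(ladder.levels):
            try:
                scores = scores_for(method, model, current)
                keep = rank_and_keep(scores, ladder.levels[i + 1])
            except SVMTError as exc:
                raise EliminationError(f"level {d}: {exc}") from exc
            current = current.subset_genes(keep)
    return EliminationPath(method=method, cost=cost, records=tuple(records))


@dataclasses.dataclass(frozen=True)
class CVReport:
    """Per-level pooled CV error and mean SV count."""

    levels: tuple[int, ...]
    cv_error: tuple[float, ...]
    mean_sv: tuple[float, ...]
    scheme: str
    n_folds: int
    failed_folds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (len(self.levels) == len(self.cv_error) == len(self.mean_sv)):
            raise SVMTError("CVReport columns must have one row per level")
        if any(not 0 <= e <= 1 for e in self.cv_error):
            raise SVMTError("cv_error entries must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": self.levels,
                "cv_error": self.cv_error,
                "mean_sv": self.mean_sv,
            }
        )


def _loo_folds(n: int) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    idx = np.arange(n)
    for i in range(n):
        yield idx[idx != i], idx[i : i + 1]


def cv2_evaluate(
    data: LabeledExpressionData,
    ladder: EliminationLadder,
    method: str,
    cost: float = DEFAULT_COST,
    scheme: str = "loo",
    n_folds: int = 5,
    seed: int = 0,
    selection_in_folds: bool = True,
) -> CVReport:
    """Cross-validated error of the selection procedure at every level.

    With ``selection_in_folds`` (CV2, the default and the honest estimate),
    the full elimination is rerun on each fold's training part and the held
    out samples are predicted at every ladder level with that fold's level
    model.  With ``selection_in_folds=False`` the gene sets are fixed once
    on all data and only the per-level SVMs are refit inside folds; this is
    optimistically biased and kept only for comparison.

    ``cv_error`` pools misclassifications over folds; ``mean_sv`` averages
    the per-fold SV counts per level.
    """
    if scheme == "loo":
        folds = list(_loo_folds(data.n_samples))
    elif scheme == "kfold":
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        folds = list(splitter.split(data.values, data.labels))
    else:
        raise SVMTError(f"unknown CV scheme {scheme!r}")

    logger.info(
        "CV2: method=%s cost=%g scheme=%s folds=%d levels=%s selection_in_folds=%s",
        method, cost, scheme, len(folds), ladder.levels, selection_in_folds,
    )

    fixed_sets: dict[int, tuple[str, ...]] | None = None
    if not selection_in_folds:
        full_path = run_elimination(data, ladder, method, cost=cost)
        fixed_sets = {r.level: r.gene_ids for r in full_path.records}

    n_levels = len(ladder.levels)
    errors = np.zeros(n_levels)
    counted = np.zeros(n_levels)
    sv_counts: list[list[int]] = [[] for _ in range(n_levels)]
    failed: list[int] = []

    for k, (train_idx, test_idx) in enumerate(folds):
        train_labels = data.labels[train_idx]
        if np.unique(train_labels).size < 2:
            raise FoldError(f"fold {k}: training part contains a single class")
        train = data.subset_samples(train_idx)
        test_values = data.values[test_idx]
        test_labels = data.labels[test_idx]
        try:
            if selection_in_folds:
                path = run_elimination(train, ladder, method, cost=cost, keep_models=True)
                level_iter = [(r.level, r.gene_ids, r.model) for r in path.records]
            else:
                assert fixed_sets is not None
                level_iter = []
                for level in ladder.levels:
                    genes = fixed_sets[level]
                    sub = train.subset_genes(genes)
                    level_iter.append((level, genes, fit_linear_svm(sub, cost=cost)))
        except SVMTError as exc:
            logger.warning("fold %d aborted: %s", k, exc)
            failed.append(k)
            continue
        for li, (level, genes, model) in enumerate(level_iter):
            cols = data.gene_indices(genes)
            pred = model.predict(test_values[:, cols])
            errors[li] += np.sum(pred != test_labels)
            counted[li] += test_labels.size
            sv_counts[li].append(model.n_sv)

    if not np.all(counted > 0):
        raise FoldError("no successful folds; cannot pool CV error")
    return CVReport(
        levels=ladder.levels,
        cv_error=tuple(float(e / c) for e, c in zip(errors, counted)),
        mean_sv=tuple(float(np.mean(c)) for c in sv_counts),
        scheme=scheme,
        n_folds=len(folds),
        failed_folds=tuple(failed),
    )


def select_best(report: CVReport) -> int:
    """The ladder level minimising CV error; ties go to the fewest genes."""
    if not report.levels:
        raise SVMTError("empty CV report")
    best = min(zip(report.cv_error, report.levels), key=lambda t: (t[0], t[1]))
    return best[1]
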