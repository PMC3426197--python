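"""Labelled two-class expression data container.

The container is deliberately strict: both classes present, no missing
values, unique gene identifiers.  Every downstream routine (SVM fits,
ranking criteria, elimination, cross-validation) assumes these invariants
and never re-checks them.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .errors import DataError

__all__ = ["LabeledExpressionData", "zscore_genes"]


@dataclasses.dataclass(frozen=True)
class LabeledExpressionData:
    """A samples x genes expression matrix with binary class labels.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_samples, n_genes)``; log-scale intensities
        or simulated reals.  No NaN/Inf allowed.
    labels
        Per-sample class label in ``{+1, -1}``; both classes must occur.
    gene_ids
        Unique identifier per gene (column).
    sample_ids
        Identifier per sample (row).
    """

    values: np.ndarray
    labels: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        gene_ids = tuple(str(g) for g in self.gene_ids)
        sample_ids = tuple(str(s) for s in self.sample_ids)
        if values.ndim != 2:
            raise DataError(f"expression matrix must be 2-D, got shape {values.shape}")
        if values.shape[1] == 0:
            raise DataError("expression matrix has zero genes")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                f"missing/non-finite value at sample {bad[0]}, gene {bad[1]}"
            )
        if labels.shape != (values.shape[0],):
            raise DataError(
                f"label count {labels.shape} does not match {values.shape[0]} samples"
            )
        present = set(np.unique(labels).tolist())
        if not present <= {-1, 1}:
            raise DataError(f"labels must be +1/-1, found {sorted(present)}")
        if present != {-1, 1}:
            raise DataError("both classes (+1 and -1) must be present")
        if len(gene_ids) != values.shape[1]:
            raise DataError("gene_ids length does not match gene count")
        if len(set(gene_ids)) != len(gene_ids):
            seen: set[str] = set()
            dup = next(g for g in gene_ids if g in seen or seen.add(g))
            raise DataError(f"duplicate gene id: {dup!r}")
        if len(sample_ids) != values.shape[0]:
            raise DataError("sample_ids length does not match sample count")
        values.setflags(write=False)
        labels.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "sample_ids", sample_ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_indices(self, gene_ids: Iterable[str]) -> np.ndarray:
        """Column indices of ``gene_ids``, in the order given."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise DataError(f"unknown gene id {exc.args[0]!r}") from None

    def subset_genes(self, gene_ids: Sequence[str]) -> "LabeledExpressionData":
        """Restrict to ``gene_ids`` (columns reordered to the given order)."""
        idx = self.gene_indices(gene_ids)
        return LabeledExpressionData(
            values=self.values[:, idx],
            labels=self.labels,
            gene_ids=tuple(gene_ids),
            sample_ids=self.sample_ids,
        )

    def subset_samples(self, indices: Sequence[int]) -> "LabeledExpressionData":
        idx = np.asarray(indices, dtype=int)
        return LabeledExpressionData(
            values=self.values[idx],
            labels=self.labels[idx],
            gene_ids=self.gene_ids,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
        )

    def with_flipped_labels(self) -> "LabeledExpressionData":
        """Same data with every class label negated."""
        return LabeledExpressionData(
            values=self.values,
            labels=-self.labels,
            gene_ids=self.gene_ids,
            sample_ids=self.sample_ids,
        )

    def class_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def zscore_genes(data: LabeledExpressionData) -> LabeledExpressionData:
    """Per-gene standardisation (mean 0, sd 1) across all samples.

    Off by default everywhere: simulated data are generated on a common
    scale and real log2 intensities are usually analysed unscaled.  A gene
    with zero variance is left centred at 0.
    """
    mu = data.values.mean(axis=0)
    sd = data.values.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return LabeledExpressionData(
        values=(data.values - mu) / sd,
        labels=data.labels,
        gene_ids=data.gene_ids,
        sample_ids=data.sample_ids,
    )
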