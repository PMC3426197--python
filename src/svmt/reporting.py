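"""Delimited-text I/O: expression readers, level reports, ranked gene tables.

Gene reports use the full-sample two-sided Welch t-test (unequal variances,
Welch-Satterthwaite degrees of freedom); the rank of a gene is its 1-based
position in the p-value ordering of ALL genes in the dataset, reported for
whatever subset was selected — so ranks in a subset report may skip
integers.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import LabeledExpressionData
from .errors import DataError
from .rfe import CVReport

__all__ = [
    "GeneReportRow",
    "read_expression",
    "welch_report",
    "write_level_report",
    "read_level_report",
    "write_gene_report",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class GeneReportRow:
    """One row of a ranked-gene table."""

    gene_id: str
    rank: int
    t_statistic: float
    p_value: float
    q_value: float | None = None


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_matrix(path: Path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except Exception as exc:
        raise DataError(f"cannot parse {path}: {exc}") from exc
    return frame


def read_expression(
    matrix_path: str | Path,
    label_spec: str | Path,
    orientation: str = "genes-in-columns",
    positive_label: str | None = None,
) -> LabeledExpressionData:
    """Read a delimited expression matrix and two-class labels.

    Parameters
    ----------
    matrix_path
        TSV/CSV with a header row and an index column.  With
        ``orientation="genes-in-columns"`` rows are samples; with
        ``"genes-in-rows"`` the matrix is transposed after reading.
    label_spec
        Either the name of a column of the matrix file holding the labels,
        or a path to a delimited file whose first column is the sample id
        and second column the label (header optional via a single column of
        labels in sample order).
    positive_label
        Which of the two label values maps to class +1.  Defaults to the
        lexicographically first value; the mapping is always logged because
        it matters for sign-dependent criteria (RSVM).
    """
    matrix_path = Path(matrix_path)
    frame = _read_matrix(matrix_path)

    labels_series: pd.Series | None = None
    if isinstance(label_spec, (str, Path)) and Path(str(label_spec)).is_file():
        lab_path = Path(str(label_spec))
        lab = pd.read_csv(lab_path, sep=_sep_for(lab_path), header=None, dtype=str)
        if lab.shape[1] >= 2:
            labels_series = pd.Series(
                lab.iloc[:, 1].values, index=lab.iloc[:, 0].values
            )
        else:
            labels_series = pd.Series(lab.iloc[:, 0].values)
    elif str(label_spec) in frame.columns and orientation == "genes-in-columns":
        labels_series = frame[str(label_spec)].astype(str)
        frame = frame.drop(columns=[str(label_spec)])
    else:
        raise DataError(
            f"label spec {label_spec!r} is neither an existing file nor a column "
            f"of {matrix_path.name}"
        )

    if orientation == "genes-in-rows":
        frame = frame.T
    elif orientation != "genes-in-columns":
        raise DataError(f"unknown orientation {orientation!r}")

    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise DataError(
                f"non-numeric cell at sample {row!r}, gene {col!r}: "
                f"{frame.loc[row, col]!r}"
            )
        frame[col] = coerced
    if frame.isna().any().any():
        col = frame.columns[frame.isna().any().values][0]
        row = frame.index[frame[col].isna()][0]
        raise DataError(f"missing value at sample {row!r}, gene {col!r}")

    sample_ids = [str(s) for s in frame.index]
    if labels_series.index.dtype == object and set(sample_ids) <= set(
        str(i) for i in labels_series.index
    ):
        labels_series = labels_series.reindex(sample_ids)
    if len(labels_series) != len(sample_ids):
        raise DataError(
            f"{len(labels_series)} labels for {len(sample_ids)} samples"
        )
    raw_labels = [str(v) for v in labels_series.values]
    classes = sorted(set(raw_labels))
    if len(classes) != 2:
        raise DataError(f"exactly two classes required, found {classes}")
    if positive_label is None:
        positive_label = classes[0]
    elif positive_label not in classes:
        raise DataError(f"positive label {positive_label!r} not among {classes}")
    negative_label = next(c for c in classes if c != positive_label)
    logger.info(
        "label mapping: %r -> +1, %r -> -1", positive_label, negative_label
    )
    labels = np.array([1 if v == positive_label else -1 for v in raw_labels])
    return LabeledExpressionData(
        values=frame.values.astype(float),
        labels=labels,
        gene_ids=tuple(str(g) for g in frame.columns),
        sample_ids=tuple(sample_ids),
    )


def welch_report(
    data: LabeledExpressionData,
    gene_subset: Sequence[str] | None = None,
    adjust: bool = False,
) -> list[GeneReportRow]:
    """Ranked gene table with full-sample Welch t and two-sided p-values.

    Ranks are assigned within the p-value ordering of all genes in ``data``
    and then restricted to ``gene_subset`` (rows sorted by p ascending).
    With ``adjust=True`` a Benjamini-Hochberg q-value column is added; raw
    p-values stay untouched either way.
    """
    pos = data.values[data.class_mask(1)]
    neg = data.values[data.class_mask(-1)]
    if pos.shape[0] < 2 or neg.shape[0] < 2:
        raise DataError("each class needs >= 2 samples for the Welch test")
    t, p = stats.ttest_ind(pos, neg, axis=0, equal_var=False)
    t = np.asarray(t)
    p = np.asarray(p)
    order = np.argsort(p, kind="stable")
    rank = np.empty(data.n_genes, dtype=int)
    rank[order] = np.arange(1, data.n_genes + 1)
    q = None
    if adjust:
        # Benjamini-Hochberg step-up over all genes
        q_sorted = p[order] * data.n_genes / np.arange(1, data.n_genes + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        q = np.empty_like(p)
        q[order] = np.minimum(q_sorted, 1.0)
    if gene_subset is None:
        subset_idx = np.arange(data.n_genes)
    else:
        subset_idx = data.gene_indices(gene_subset)
    subset_idx = subset_idx[np.argsort(rank[subset_idx], kind="stable")]
    return [
        GeneReportRow(
            gene_id=data.gene_ids[j],
            rank=int(rank[j]),
            t_statistic=float(t[j]),
            p_value=float(p[j]),
            q_value=None if q is None else float(q[j]),
        )
        for j in subset_idx
    ]


def write_level_report(report: CVReport, out: str | Path) -> None:
    """TSV with columns level, cv_error_pct (2 decimals), mean_sv (2 decimals)."""
    out = Path(out)
    with out.open("w") as fh:
        fh.write("level\tcv_error_pct\tmean_sv\n")
        for level, err, sv in zip(report.levels, report.cv_error, report.mean_sv):
            fh.write(f"{level}\t{100.0 * err:.2f}\t{sv:.2f}\n")


def read_level_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_report(rows: Sequence[GeneReportRow], out: str | Path) -> None:
    """TSV with columns gene_id, rank, t_statistic, p_value (and q_value if set)."""
    out = Path(out)
    with_q = any(r.q_value is not None for r in rows)
    with out.open("w") as fh:
        header = "gene_id\trank\tt_statistic\tp_value"
        fh.write(header + ("\tq_value\n" if with_q else "\n"))
        for r in rows:
            line = f"{r.gene_id}\t{r.rank}\t{r.t_statistic:.3f}\t{r.p_value:.2e}"
            if with_q:
                line += f"\t{r.q_value:.2e}"
            fh.write(line + "\n")
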