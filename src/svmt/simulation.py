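"""Gaussian two-class simulation study and the label-switch stability experiment.

The generator draws balanced two-class samples over ``p_total`` genes.  The
first half of the informative genes is up-shifted by ``+mu`` in class +1
and ``-mu`` in class -1; the second half has the signs reversed; the
remaining genes are zero-mean noise in both classes, possibly with a larger
standard deviation than the informative block.  Six canonical scenarios
cross the mean shift (0.15 / 0.25) with the informative and noise standard
deviations; training sets have 50 samples per class and evaluation sets
500 per class.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .data import LabeledExpressionData
from .errors import SVMTError
from .rfe import EliminationLadder, run_elimination
from .svm import DEFAULT_COST

__all__ = [
    "SimulationConfig",
    "SCENARIOS",
    "SIMULATION_LADDER",
    "scenario_config",
    "generate_dataset",
    "recovery_fraction",
    "StudyMetrics",
    "run_study",
    "StabilityResult",
    "jaccard",
    "label_switch_experiment",
]

logger = logging.getLogger(__name__)

#: (mu, sigma_informative, sigma_noise) per scenario number.
SCENARIOS: dict[int, tuple[float, float, float]] = {
    1: (0.15, 0.5, 1.0),
    2: (0.15, 1.0, 1.0),
    3: (0.15, 1.0, 2.0),
    4: (0.25, 0.5, 1.0),
    5: (0.25, 1.0, 1.0),
    6: (0.25, 1.0, 2.0),
}

#: The fixed level sequence used by the study result tables.
SIMULATION_LADDER = EliminationLadder(
    levels=(1000, 800, 600, 500, 400, 300, 200, 150, 100, 90, 80, 70, 60, 50)
)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated scenario.

    Defaults are the canonical study conditions: 100 training samples
    (50 per class), 1000 evaluation samples, 1000 genes of which 300 are
    informative.
    """

    mu: float = 0.15
    sigma_informative: float = 0.5
    sigma_noise: float = 1.0
    n_train_per_class: int = 50
    n_test_per_class: int = 500
    p_total: int = 1000
    p_informative: int = 300
    n_runs: int = 100
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.p_informative % 2 != 0 or not 0 < self.p_informative <= self.p_total:
            raise SVMTError("p_informative must be even and in (0, p_total]")
        if self.sigma_informative <= 0 or self.sigma_noise <= 0:
            raise SVMTError("standard deviations must be positive")
        if self.n_runs < 1:
            raise SVMTError("n_runs must be >= 1")
        if self.n_train_per_class < 1 or self.n_test_per_class < 1:
            raise SVMTError("sample counts out of range")


def scenario_config(scenario: int, **overrides) -> SimulationConfig:
    """A :class:`SimulationConfig` for one of the six canonical scenarios."""
    try:
        mu, s_inf, s_noise = SCENARIOS[scenario]
    except KeyError:
        raise SVMTError(f"scenario must be 1..6, got {scenario}") from None
    return SimulationConfig(
        mu=mu, sigma_informative=s_inf, sigma_noise=s_noise, **overrides
    )


def _draw(
    rng: np.random.Generator, config: SimulationConfig, n_per_class: int, tag: str
) -> LabeledExpressionData:
    half = config.p_informative // 2
    n = 2 * n_per_class
    X = rng.normal(0.0, config.sigma_noise, size=(n, config.p_total))
    X[:, : config.p_informative] = rng.normal(
        0.0, config.sigma_informative, size=(n, config.p_informative)
    )
    labels = np.repeat([1, -1], n_per_class)
    # block 1: +mu in class +1, -mu in class -1; block 2: signs reversed
    shift = np.zeros((n, config.p_total))
    shift[labels == 1, :half] = config.mu
    shift[labels == 1, half : config.p_informative] = -config.mu
    shift[labels == -1, :half] = -config.mu
    shift[labels == -1, half : config.p_informative] = config.mu
    gene_ids = tuple(f"g{j + 1:04d}" for j in range(config.p_total))
    sample_ids = tuple(f"{tag}{i + 1:04d}" for i in range(n))
    return LabeledExpressionData(
        values=X + shift, labels=labels, gene_ids=gene_ids, sample_ids=sample_ids
    )


def generate_dataset(
    config: SimulationConfig, run_seed: int
) -> tuple[LabeledExpressionData, LabeledExpressionData, frozenset[str]]:
    """One training set, one independent evaluation set, and the informative ids.

    Deterministic in ``run_seed``: the same seed reproduces the same
    matrices bit-for-bit.
    """
    rng = np.random.default_rng(run_seed)
    train = _draw(rng, config, config.n_train_per_class, tag="tr")
    test = _draw(rng, config, config.n_test_per_class, tag="te")
    informative = frozenset(train.gene_ids[: config.p_informative])
    return train, test, informative


def recovery_fraction(
    selected: Sequence[str], informative: frozenset[str] | set[str], d: int
) -> float:
    """Fraction of retained genes that are truly informative.

    The denominator is ``min(d, n_informative)``: above the informative
    count the ceiling is set by the 300 informative genes, below it by the
    level size itself, so a perfect selection always scores 1.0.
    """
    selected_set = set(selected)
    if not selected_set:
        raise SVMTError("empty selection")
    if len(selected_set) != d:
        raise SVMTError(f"|selected|={len(selected_set)} does not match d={d}")
    return len(selected_set & set(informative)) / min(d, len(informative))


@dataclasses.dataclass(frozen=True)
class StudyMetrics:
    """Per (method, level) aggregates over simulation runs.

    ``table`` columns: method, level, test_mean, test_sd (percent),
    rec_mean, rec_sd (percent), nsv_mean, nsv_sd.  ``degenerate`` flags a
    single-run aggregation whose sds are reported as 0.
    """

    table: pd.DataFrame
    n_runs: int
    failures: dict[str, int]
    degenerate: bool
    runs: pd.DataFrame | None = None

    def cell(self, method: str, level: int) -> pd.Series:
        rows = self.table[(self.table.method == method) & (self.table.level == level)]
        if rows.empty:
            raise SVMTError(f"no aggregate for method={method}, level={level}")
        return rows.iloc[0]


def run_study(
    config: SimulationConfig,
    methods: Sequence[str] = ("svmt", "svmrfe", "rsvm"),
    ladder: EliminationLadder = SIMULATION_LADDER,
    cost: float = DEFAULT_COST,
    keep_runs: bool = False,
) -> StudyMetrics:
    """Replicate the scenario ``config.n_runs`` times and aggregate.

    Each run draws a fresh train/test pair (seed ``base_seed + run``, shared
    by all methods so between-method comparisons use common random numbers)
    and runs every method down the ladder with hold-out evaluation on the
    refit full-training-set model.  Per-run failures are counted per method
    and excluded from the aggregates with a warning, never silently.
    """
    if ladder.levels[0] != config.p_total:
        raise SVMTError(
            f"ladder starts at {ladder.levels[0]} but scenario has {config.p_total} genes"
        )
    logger.info(
        "study: mu=%g s_inf=%g s_noise=%g runs=%d cost=%g methods=%s",
        config.mu, config.sigma_informative, config.sigma_noise,
        config.n_runs, cost, list(methods),
    )
    rows: list[dict] = []
    failures = {m: 0 for m in methods}
    for run in range(config.n_runs):
        run_seed = config.base_seed + run
        train, test, informative = generate_dataset(config, run_seed)
        for method in methods:
            try:
                path = run_elimination(
                    train, ladder, method, cost=cost, test_data=test
                )
            except SVMTError as exc:
                failures[method] += 1
                logger.warning("run %d method %s failed: %s", run, method, exc)
                continue
            for rec in path.records:
                rows.append(
                    {
                        "run": run,
                        "method": method,
                        "level": rec.level,
                        "test_pct": 100.0 * (rec.holdout_error or 0.0),
                        "rec_pct": 100.0
                        * recovery_fraction(rec.gene_ids, informative, rec.level),
                        "n_sv": rec.n_sv,
                    }
                )
    if not rows:
        raise SVMTError("every run failed; nothing to aggregate")
    raw = pd.DataFrame(rows)
    degenerate = config.n_runs == 1

    def _sd(x: pd.Series) -> float:
        return 0.0 if len(x) < 2 else float(x.std(ddof=1))

    agg = (
        raw.groupby(["method", "level"], sort=False)
        .agg(
            test_mean=("test_pct", "mean"),
            test_sd=("test_pct", _sd),
            rec_mean=("rec_pct", "mean"),
            rec_sd=("rec_pct", _sd),
            nsv_mean=("n_sv", "mean"),
            nsv_sd=("n_sv", _sd),
        )
        .reset_index()
    )
    return StudyMetrics(
        table=agg,
        n_runs=config.n_runs,
        failures=failures,
        degenerate=degenerate,
        runs=raw if keep_runs else None,
    )


def jaccard(a: Sequence[str], b: Sequence[str]) -> float:
    """|A n B| / |A u B| between two gene sets."""
    sa, sb = set(a), set(b)
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


@dataclasses.dataclass(frozen=True)
class StabilityResult:
    """Selection frequencies and per-run Jaccard under label switching."""

    gene_ids: tuple[str, ...]
    freq_original: np.ndarray
    freq_switched: np.ndarray
    jaccard_per_run: np.ndarray
    n_runs: int
    level: int

    def frequency_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "freq_original": self.freq_original,
                "freq_switched": self.freq_switched,
            }
        )


def label_switch_experiment(
    config: SimulationConfig,
    method: str,
    ladder: EliminationLadder = SIMULATION_LADDER,
    cost: float = DEFAULT_COST,
    final_level: int = 50,
) -> StabilityResult:
    """Selection stability under negating every class label.

    Each run draws ONE dataset (both orientations share the seed), runs the
    elimination once with the original labels and once with all labels
    negated, and compares the two gene sets selected at ``final_level`` by
    their Jaccard coefficient and per-gene selection counts.
    """
    if final_level not in ladder.levels:
        raise SVMTError(f"final_level {final_level} not on the ladder {ladder.levels}")
    gene_ids: tuple[str, ...] | None = None
    freq_a = freq_b = None
    jac: list[float] = []
    for run in range(config.n_runs):
        train, _, _ = generate_dataset(config, config.base_seed + run)
        if gene_ids is None:
            gene_ids = train.gene_ids
            freq_a = np.zeros(len(gene_ids), dtype=int)
            freq_b = np.zeros(len(gene_ids), dtype=int)
        try:
            path_a = run_elimination(train, ladder, method, cost=cost)
            path_b = run_elimination(
                train.with_flipped_labels(), ladder, method, cost=cost
            )
        except SVMTError as exc:
            raise SVMTError(f"stability run {run}: {exc}") from exc
        sel_a = path_a.genes_at(final_level)
        sel_b = path_b.genes_at(final_level)
        idx = {g: i for i, g in enumerate(gene_ids)}
        freq_a[[idx[g] for g in sel_a]] += 1
        freq_b[[idx[g] for g in sel_b]] += 1
        jac.append(jaccard(sel_a, sel_b))
    assert gene_ids is not None and freq_a is not None and freq_b is not None
    return StabilityResult(
        gene_ids=gene_ids,
        freq_original=freq_a,
        freq_switched=freq_b,
        jaccard_per_run=np.asarray(jac),
        n_runs=config.n_runs,
        level=final_level,
    )
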