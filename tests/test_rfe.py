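"""Elimination ladder construction, backward elimination, CV2 and level choice."""
import numpy as np
import pytest
from sklearn.svm import SVC

from svmt import (
    CVReport,
    EliminationLadder,
    FoldError,
    LadderError,
    cv2_evaluate,
    fit_linear_svm,
    make_ladder,
    run_elimination,
    select_best,
)

from conftest import make_data

# Published 45-level sequence from 7129 at ratio 0.85 down to 5.
LADDER_7129 = (
    7129, 6060, 5151, 4378, 3721, 3163, 2689, 2286, 1943, 1652, 1404, 1193,
    1014, 862, 733, 623, 530, 450, 382, 325, 276, 235, 200, 170, 144, 122,
    104, 88, 75, 64, 54, 46, 39, 33, 28, 24, 20, 17, 14, 12, 10, 8, 7, 6, 5,
)


class TestMakeLadder:
    def test_full_reference_sequence(self):
        lad = make_ladder(7129, 0.85, 5)
        assert lad.levels == LADDER_7129
        assert len(lad.levels) == 45

    def test_half_rounding_is_to_even(self):
        # 10 * 0.85 = 8.5 -> 8 and 450 * 0.85 = 382.5 -> 382
        assert make_ladder(10, 0.85, 5).levels[:2] == (10, 8)
        assert make_ladder(450, 0.85, 5).levels[:2] == (450, 382)

    def test_single_level_when_start_equals_min(self):
        assert make_ladder(5, 0.85, 5).levels == (5,)

    def test_rounding_stall_decrements(self):
        # with ratio 0.99, round(0.99 * d) == d for small d; must still decrease
        lad = make_ladder(20, 0.99, 5)
        assert all(a > b for a, b in zip(lad.levels, lad.levels[1:]))
        assert lad.levels[-1] == 5

    @pytest.mark.parametrize(
        "p_start, ratio, d_min",
        [(100, 0.85, 200), (100, 1.5, 5), (100, 0.85, 0)],
    )
    def test_invalid_parameters_rejected(self, p_start, ratio, d_min):
        with pytest.raises(LadderError):
            make_ladder(p_start, ratio, d_min)

    def test_nonmonotone_ladder_rejected(self):
        with pytest.raises(LadderError, match="decreasing"):
            EliminationLadder(levels=(10, 10, 5))


def _bruteforce_elimination(data, levels, method, cost):
    """Independent fit-score-truncate loop built directly on sklearn/numpy."""
    X = data.values.copy()
    y = np.asarray(data.labels, dtype=float)
    ids = list(data.gene_ids)
    sets = []
    for i, d in enumerate(levels):
        clf = SVC(kernel="linear", C=cost, tol=1e-12).fit(X, y)
        sets.append(tuple(ids))
        if i + 1 == len(levels):
            break
        w = clf.coef_[0]
        if method == "svmrfe":
            crit = w**2
        elif method == "rsvm":
            crit = w * (X[y == 1].mean(axis=0) - X[y == -1].mean(axis=0))
        else:  # svmt
            alpha = np.zeros(len(y))
            alpha[clf.support_] = np.abs(clf.dual_coef_[0])
            sv = alpha > 1e-8 * cost
            P, N = X[sv & (y == 1)], X[sv & (y == -1)]
            diff = np.abs(P.mean(axis=0) - N.mean(axis=0))
            if len(P) == 1 and len(N) == 1:
                crit = diff
            else:
                var_sum = np.zeros(X.shape[1])
                if len(P) > 1:
                    var_sum += P.var(ddof=1, axis=0) / len(P)
                if len(N) > 1:
                    var_sum += N.var(ddof=1, axis=0) / len(N)
                denom = np.sqrt(var_sum)
                crit = np.where(
                    denom > 0,
                    diff / np.where(denom > 0, denom, 1),
                    np.where(diff > 0, np.inf, 0),
                )
        keep = np.argsort(-crit, kind="stable")[: levels[i + 1]]
        X = X[:, keep]
        ids = [ids[j] for j in keep]
    return sets


@pytest.mark.parametrize("method", ["svmt", "svmrfe", "rsvm"])
def test_elimination_matches_bruteforce_oracle(method):
    rng = np.random.default_rng(11)
    X = rng.normal(size=(8, 6))
    X[:4, :2] += 1.5
    data = make_data(X, [1] * 4 + [-1] * 4)
    ladder = EliminationLadder(levels=(6, 4, 2))
    path = run_elimination(data, ladder, method, cost=1.0)
    oracle_sets = _bruteforce_elimination(data, (6, 4, 2), method, cost=1.0)
    for rec, oracle in zip(path.records, oracle_sets):
        assert set(rec.gene_ids) == set(oracle)


def test_single_level_ladder_is_one_fit(random_toy_data):
    ladder = EliminationLadder(levels=(5,))
    path = run_elimination(random_toy_data, ladder, "svmt", cost=1.0)
    assert len(path.records) == 1
    assert set(path.records[0].gene_ids) == set(random_toy_data.gene_ids)


def test_nesting_and_sizes(random_toy_data):
    ladder = EliminationLadder(levels=(5, 3, 2, 1))
    path = run_elimination(random_toy_data, ladder, "svmrfe", cost=1.0)
    sets = [set(r.gene_ids) for r in path.records]
    for rec, level in zip(path.records, ladder.levels):
        assert len(rec.gene_ids) == level
    for big, small in zip(sets, sets[1:]):
        assert small < big


def test_mismatched_start_level_rejected(random_toy_data):
    with pytest.raises(LadderError, match="starts at"):
        run_elimination(random_toy_data, EliminationLadder(levels=(9, 3)), "svmt")


def test_holdout_error_recorded(one_informative_gene_data):
    train = one_informative_gene_data
    ladder = EliminationLadder(levels=(6, 2, 1))
    path = run_elimination(train, ladder, "svmt", cost=1.0, test_data=train)
    # training data itself as hold-out: the separating gene gives zero error
    assert path.record_at(1).holdout_error == 0.0


@pytest.mark.parametrize("method", ["svmt", "svmrfe", "rsvm"])
def test_perfectly_separating_gene_survives_to_last_level(
    one_informative_gene_data, method
):
    ladder = EliminationLadder(levels=(6, 4, 2, 1))
    path = run_elimination(one_informative_gene_data, ladder, method, cost=1.0)
    assert path.genes_at(1) == ("g1",)


class TestCV2:
    def test_separable_data_zero_error_at_full_level(self, one_informative_gene_data):
        ladder = EliminationLadder(levels=(6,))
        rep = cv2_evaluate(one_informative_gene_data, ladder, "svmt", scheme="loo")
        assert rep.cv_error[0] == 0.0
        assert rep.n_folds == 8

    def test_loo_matches_explicit_fold_enumeration(self, one_informative_gene_data):
        data = one_informative_gene_data
        ladder = EliminationLadder(levels=(6, 3))
        rep = cv2_evaluate(data, ladder, "svmrfe", cost=1.0, scheme="loo")
        # oracle: enumerate folds by hand, pool misclassifications per level
        miss = np.zeros(2)
        svs = np.zeros((2, data.n_samples))
        for i in range(data.n_samples):
            keep = [j for j in range(data.n_samples) if j != i]
            train = data.subset_samples(keep)
            path = run_elimination(train, ladder, "svmrfe", cost=1.0, keep_models=True)
            for li, rec in enumerate(path.records):
                cols = data.gene_indices(rec.gene_ids)
                pred = rec.model.predict(data.values[i : i + 1, cols])
                miss[li] += pred[0] != data.labels[i]
                svs[li, i] = rec.model.n_sv
        np.testing.assert_allclose(rep.cv_error, miss / data.n_samples)
        np.testing.assert_allclose(rep.mean_sv, svs.mean(axis=1))

    def test_report_shape_and_bounds(self, one_informative_gene_data):
        ladder = EliminationLadder(levels=(6, 3, 1))
        rep = cv2_evaluate(one_informative_gene_data, ladder, "rsvm", scheme="loo")
        assert rep.levels == (6, 3, 1)
        assert all(0 <= e <= 1 for e in rep.cv_error)

    def test_kfold_deterministic_for_fixed_seed(self, one_informative_gene_data):
        ladder = EliminationLadder(levels=(6, 2))
        r1 = cv2_evaluate(one_informative_gene_data, ladder, "svmt", scheme="kfold", n_folds=4, seed=3)
        r2 = cv2_evaluate(one_informative_gene_data, ladder, "svmt", scheme="kfold", n_folds=4, seed=3)
        assert r1 == r2

    def test_biased_variant_fixes_selection_on_all_data(self, one_informative_gene_data):
        ladder = EliminationLadder(levels=(6, 1))
        rep = cv2_evaluate(
            one_informative_gene_data, ladder, "svmt", scheme="loo",
            selection_in_folds=False,
        )
        assert rep.cv_error[-1] == 0.0  # the separating gene was picked on all data

    def test_single_class_fold_raises_named_error(self):
        # only one negative sample: its LOO fold has a single-class training part
        data = make_data([[1.0], [2.0], [-1.0]], [1, 1, -1])
        with pytest.raises(FoldError, match="fold 2"):
            cv2_evaluate(data, EliminationLadder(levels=(1,)), "svmt", scheme="loo")

    def test_unknown_scheme_rejected(self, one_informative_gene_data):
        with pytest.raises(Exception, match="scheme"):
            cv2_evaluate(one_informative_gene_data, EliminationLadder(levels=(6,)), "svmt", scheme="bootstrap")


class TestSelectBest:
    def test_tie_goes_to_fewest_genes(self):
        rep = CVReport(levels=(100, 50, 20), cv_error=(0.05, 0.05, 0.08),
                       mean_sv=(10.0, 9.0, 8.0), scheme="loo", n_folds=10)
        assert select_best(rep) == 50

    def test_single_level(self):
        rep = CVReport(levels=(7,), cv_error=(0.3,), mean_sv=(4.0,), scheme="loo", n_folds=7)
        assert select_best(rep) == 7

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        levels = tuple(range(100, 0, -10))
        errors = tuple(rng.choice([0.1, 0.2, 0.3], size=10).tolist())
        rep = CVReport(levels=levels, cv_error=errors, mean_sv=(0.0,) * 10,
                       scheme="loo", n_folds=10)
        best = min(((e, l) for l, e in zip(levels, errors)))[1]
        assert select_best(rep) == best


def test_elimination_determinism(random_toy_data):
    ladder = EliminationLadder(levels=(5, 3, 1))
    p1 = run_elimination(random_toy_data, ladder, "svmt", cost=1.0)
    p2 = run_elimination(random_toy_data, ladder, "svmt", cost=1.0)
    assert [r.gene_ids for r in p1.records] == [r.gene_ids for r in p2.records]
    assert [r.n_sv for r in p1.records] == [r.n_sv for r in p2.records]
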