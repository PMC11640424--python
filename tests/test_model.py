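import json

import numpy as np
import pytest

from tlbkit import Cohort, FittedModel, PairFeature, Thermogram, classify, fit, score
from tlbkit.errors import FitError, GridMismatchError, SplitError
from tlbkit.model import (
    default_lambda_grid,
    fit_path,
    lambda_max,
    solve_lasso_logistic,
    train_validate_split,
)
from tlbkit.preprocess import FeatureVector
from tlbkit.tsp import PairMatrix

from oracles import lasso_logistic_grid_search


def _pm(indicators, pair_temps=None):
    indicators = np.asarray(indicators)
    n, k = indicators.shape
    temps = pair_temps or [(55.0 + 2 * i, 56.0 + 2 * i) for i in range(k)]
    pairs = [PairFeature(a, b, 0.5, 0.0) for a, b in temps]
    return PairMatrix([f"S{i}" for i in range(n)], pairs, indicators)


class TestSolver:
    def test_matches_grid_search_oracle(self):
        X = np.array([[0, 1], [0, 0], [0, 1], [1, 0], [1, 1], [1, 1]], float)
        y = np.array([0, 0, 0, 1, 1, 1])
        _, beta = solve_lasso_logistic(X, y, lam=0.1, fit_intercept=False)
        oracle = lasso_logistic_grid_search(X, y, lam=0.1)
        assert np.abs(beta - oracle).max() < 5e-3

    def test_lambda_max_kills_all_coefficients(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, (20, 5)).astype(float)
        y = rng.integers(0, 2, 20)
        lmax = lambda_max(X, y)
        _, beta = solve_lasso_logistic(X, y, lam=lmax * 1.0001)
        assert np.all(beta == 0.0)
        _, beta2 = solve_lasso_logistic(X, y, lam=lmax * 0.5)
        assert np.any(beta2 != 0.0)

    def test_nonzero_count_non_increasing_along_path(self):
        rng = np.random.default_rng(42)
        y = rng.integers(0, 2, 30)
        X = (rng.random((30, 6)) < 0.3 + 0.4 * y[:, None]).astype(float)
        lambdas = default_lambda_grid(X, y)
        sols = fit_path(X, y, lambdas)
        nnz = [int(np.sum(b != 0)) for _, b in sols]
        assert all(a <= b for a, b in zip(nnz, nnz[1:]))
        assert nnz[0] == 0  # at lambda_max everything is shrunk away


class TestFit:
    def test_separable_indicator_retained_and_classifies_training(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        ind = np.column_stack([y, np.array([0, 1, 0, 1, 0, 1, 0, 1])])
        model = fit(_pm(ind), y, cv_folds=4, seed=0)
        cols = {(55.0, 56.0): 0, (57.0, 58.0): 1}
        kept_idx = [cols[(p.ti, p.tj)] for p in model.pairs]
        assert 0 in kept_idx  # the separating pair survives
        assert model.coefficients[kept_idx.index(0)] > 0
        scores = model.intercept + ind[:, kept_idx] @ model.coefficients
        assert np.array_equal((scores > 0).astype(int), y)

    def test_full_shrinkage_gives_intercept_only_prevalence_model(self):
        y = np.array([0, 0, 0, 0, 1, 1])
        ind = np.array([[0, 1], [1, 0], [0, 0], [1, 1], [1, 0], [0, 1]])
        model = fit(_pm(ind), y, lambda_grid=np.array([10.0]), cv_folds=2, seed=0)
        assert len(model.pairs) == 0
        prevalence = y.mean()
        assert model.intercept == pytest.approx(np.log(prevalence / (1 - prevalence)), abs=1e-6)

    def test_single_class_is_fit_error(self):
        ind = np.array([[0, 1], [1, 0], [1, 1]])
        with pytest.raises(FitError, match="both classes"):
            fit(_pm(ind), [1, 1, 1])

    def test_constant_columns_dropped_with_warning(self, caplog):
        y = np.array([0, 0, 1, 1, 0, 1])
        ind = np.column_stack([np.ones(6, int), y])
        with caplog.at_level("WARNING", logger="tlbkit.model"):
            model = fit(_pm(ind), y, cv_folds=2, seed=0)
        assert "constant" in caplog.text
        assert all(p.ti != 55.0 for p in model.pairs)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 16)
        ind = (rng.random((16, 4)) < 0.2 + 0.6 * y[:, None]).astype(int)
        a = fit(_pm(ind), y, cv_folds=4, seed=7)
        b = fit(_pm(ind), y, cv_folds=4, seed=7)
        assert a.intercept == b.intercept
        assert np.array_equal(a.coefficients, b.coefficients)
        assert a.penalty == b.penalty

    def test_json_round_trip(self, tmp_path):
        y = np.array([0, 0, 1, 1, 0, 1])
        ind = np.column_stack([y, 1 - y])
        model = fit(_pm(ind), y, cv_folds=2, seed=0)
        path = tmp_path / "m.json"
        model.to_json(path)
        back = FittedModel.from_json(path)
        assert back.intercept == model.intercept
        assert np.array_equal(back.coefficients, model.coefficients)
        assert [(p.ti, p.tj) for p in back.pairs] == [(p.ti, p.tj) for p in model.pairs]


class TestScoreAndClassify:
    def _fv(self, values, temps=(55.0, 70.0)):
        return FeatureVector("S", np.asarray(temps, float), np.asarray(values, float))

    def _model(self, intercept, coefs, pairs):
        return FittedModel(
            pairs=[PairFeature(a, b, 0.5, 0.0) for a, b in pairs],
            intercept=intercept,
            coefficients=np.asarray(coefs, float),
            penalty=0.1,
        )

    def test_score_arithmetic(self):
        m = self._model(0.0, [2.0], [(55.0, 70.0)])
        assert score(m, self._fv([3.0, 1.0])) == 2.0  # indicator 1
        assert score(m, self._fv([1.0, 3.0])) == 0.0  # indicator 0

    def test_all_indicators_zero_scores_intercept(self):
        m = self._model(-1.7, [2.0, 3.0], [(55.0, 70.0), (70.0, 55.0)])
        assert score(m, self._fv([1.0, 1.0])) == -1.7  # ties: both indicators 0

    def test_two_accumulation_routes_agree(self):
        rng = np.random.default_rng(3)
        temps = 55.0 + np.arange(10.0)
        pairs = [(temps[i], temps[j]) for i, j in [(0, 5), (2, 7), (9, 1)]]
        coefs = rng.normal(size=3)
        m = self._model(0.37, coefs, pairs)
        fv = FeatureVector("S", temps, rng.normal(size=10))
        s_loop = m.intercept
        for (a, b), c in zip(pairs, coefs):
            ia = np.flatnonzero(temps == a)[0]
            ib = np.flatnonzero(temps == b)[0]
            s_loop += c * (1.0 if fv.values[ia] > fv.values[ib] else 0.0)
        assert score(m, fv) == pytest.approx(s_loop, abs=1e-12)

    def test_sign_rule_negative_and_positive_scores(self):
        m_neg = self._model(-1.31, [], [])
        m_pos = self._model(1.54, [], [])
        fv = self._fv([1.0, 2.0])
        assert classify(m_neg, fv) == "negative"
        assert classify(m_pos, fv) == "positive"

    def test_zero_score_maps_to_negative_class(self):
        m = self._model(0.0, [], [])
        assert classify(m, self._fv([1.0, 2.0])) == "negative"

    def test_missing_grid_temperature_is_error(self):
        m = self._model(0.0, [1.0], [(55.0, 91.0)])
        with pytest.raises(GridMismatchError):
            score(m, self._fv([1.0, 2.0]))


class TestTrainValidateSplit:
    def _cohort(self, n_confirmed, n_unconfirmed):
        thermos, confirmed = [], {}
        for i in range(n_confirmed + n_unconfirmed):
            sid = f"S{i:02d}"
            thermos.append(Thermogram(sid, [40.0, 95.0], [1.0, 1.0]))
            confirmed[sid] = i < n_confirmed
        return Cohort(thermos, {}, confirmed)

    def test_study_sized_split(self):
        train, val = train_validate_split(self._cohort(22, 13))
        assert (len(train), len(val)) == (22, 13)
        assert set(train.sample_ids).isdisjoint(val.sample_ids)
        assert len(train) + len(val) == 35

    def test_all_confirmed_gives_empty_validation_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="tlbkit.model"):
            train, val = train_validate_split(self._cohort(5, 0))
        assert len(val) == 0
        assert "validation set is empty" in caplog.text

    def test_missing_flags_is_split_error(self):
        c = self._cohort(2, 1)
        del c.confirmed["S02"]
        with pytest.raises(SplitError, match="without confirmed flag"):
            train_validate_split(c)

    def test_no_confirmed_samples_is_split_error(self):
        with pytest.raises(SplitError, match="no confirmed"):
            train_validate_split(self._cohort(0, 3))
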