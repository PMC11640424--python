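import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tlbkit import indicator_matrix, ktsp_select, pair_score
from tlbkit.errors import DomainError, SelectionError

from conftest import feature_vectors_from_matrix
from oracles import tsp_scores_bruteforce


def _random_features(n_samples, n_temps, seed):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_samples, n_temps))
    y = np.r_[np.zeros(n_samples // 2, int), np.ones(n_samples - n_samples // 2, int)]
    return X, y, feature_vectors_from_matrix(X)


class TestPairScore:
    def test_perfect_separation_scores_one(self):
        # class 0: X_55 < X_70, class 1: X_55 > X_70
        X = np.array([[1.0, 2.0], [1.5, 2.5], [3.0, 2.0], [2.5, 1.0]])
        fvs = feature_vectors_from_matrix(X, [55.0, 70.0])
        primary, _ = pair_score(fvs, [0, 0, 1, 1], 55.0, 70.0)
        assert primary == 1.0

    def test_equal_frequencies_score_zero(self):
        # within each class exactly half the samples have X_55 > X_70
        X = np.array([[2.0, 1.0], [1.0, 2.0], [2.0, 1.0], [1.0, 2.0]])
        fvs = feature_vectors_from_matrix(X, [55.0, 70.0])
        primary, _ = pair_score(fvs, [0, 0, 1, 1], 55.0, 70.0)
        assert primary == 0.0

    def test_matches_exhaustive_counting_oracle(self):
        X, y, fvs = _random_features(8, 31, seed=7)
        temps = fvs[0].grid
        for i, j in [(0, 30), (3, 17), (12, 13), (28, 2), (17, 3)]:
            prim, sec = pair_score(fvs, y, temps[i], temps[j])
            o_prim, o_sec = tsp_scores_bruteforce(X, y, i, j)
            assert prim == pytest.approx(o_prim, abs=1e-12)
            assert sec == pytest.approx(o_sec, abs=1e-12)

    def test_same_temperature_rejected(self):
        _, y, fvs = _random_features(4, 5, seed=0)
        with pytest.raises(DomainError):
            pair_score(fvs, y, 55.0, 55.0)

    def test_empty_class_rejected(self):
        _, _, fvs = _random_features(4, 5, seed=0)
        with pytest.raises(DomainError, match="non-empty"):
            pair_score(fvs, [0, 0, 0, 0], 55.0, 56.0)

    def test_label_swap_symmetry(self):
        X, y, fvs = _random_features(10, 8, seed=3)
        temps = fvs[0].grid
        a = pair_score(fvs, y, temps[2], temps[6])
        b = pair_score(fvs, 1 - y, temps[2], temps[6])
        assert a == b

    def test_reversal_symmetry_on_continuous_data(self):
        X, y, fvs = _random_features(10, 8, seed=4)
        temps = fvs[0].grid
        a, _ = pair_score(fvs, y, temps[1], temps[5])
        b, _ = pair_score(fvs, y, temps[5], temps[1])
        assert a == pytest.approx(b, abs=1e-15)


class TestKtspSelect:
    def test_all_465_pair_scores_match_bruteforce(self):
        X, y, fvs = _random_features(10, 31, seed=11)
        pairs = ktsp_select(fvs, y, k_max=465, disjoint=False)
        assert len(pairs) == 465
        temps = fvs[0].grid.tolist()
        for p in pairs:
            i, j = temps.index(p.ti), temps.index(p.tj)
            o_prim, o_sec = tsp_scores_bruteforce(X, y, i, j)
            assert p.score_primary == pytest.approx(o_prim, abs=1e-12)
            assert p.score_secondary == pytest.approx(o_sec, abs=1e-12)

    def test_selection_order_matches_independent_sort(self):
        X, y, fvs = _random_features(10, 12, seed=5)
        pairs = ktsp_select(fvs, y, k_max=66, disjoint=False)
        keys = [(-p.score_primary, -p.score_secondary, p.ti, p.tj) for p in pairs]
        assert keys == sorted(keys)

    def test_dominant_pair_ranked_first(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 6)) * 0.01
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        # plant a perfectly separating ordering between temps 0 and 3
        X[:5, 0], X[:5, 3] = 0.0, 1.0
        X[5:, 0], X[5:, 3] = 1.0, 0.0
        fvs = feature_vectors_from_matrix(X)
        top = ktsp_select(fvs, y, k_max=1)[0]
        assert {top.ti, top.tj} == {55.0, 58.0}
        assert top.score_primary == 1.0

    def test_disjoint_selection_equals_greedy_filter_of_full_ranking(self):
        _, y, fvs = _random_features(10, 10, seed=9)
        full = ktsp_select(fvs, y, k_max=45, disjoint=False)
        expected, used = [], set()
        for p in full:
            if p.ti in used or p.tj in used:
                continue
            expected.append(p)
            used.update((p.ti, p.tj))
            if len(expected) == 3:
                break
        assert ktsp_select(fvs, y, k_max=3, disjoint=True) == expected

    def test_disjoint_skips_pair_sharing_a_temperature(self):
        # temps 0,1,2: pair (0,1) perfect; (0,2) near-perfect; (1,2) weak
        X = np.array(
            [
                [0.0, 1.0, 0.9],
                [0.0, 1.0, 0.8],
                [0.1, 1.0, 0.7],
                [1.0, 0.0, 0.1],
                [1.0, 0.0, 0.2],
                [1.0, 0.5, 0.3],
            ]
        )
        y = np.array([0, 0, 0, 1, 1, 1])
        fvs = feature_vectors_from_matrix(X, [55.0, 56.0, 57.0])
        selected = ktsp_select(fvs, y, k_max=2, disjoint=True)
        assert len(selected) == 1  # second and third pairs share temperatures
        both = ktsp_select(fvs, y, k_max=2, disjoint=False)
        assert len(both) == 2

    def test_too_few_temperatures_rejected(self):
        fvs = feature_vectors_from_matrix(np.ones((4, 1)), [55.0])
        with pytest.raises(SelectionError):
            ktsp_select(fvs, [0, 0, 1, 1], k_max=1)


class TestIndicatorMatrix:
    def test_definition_and_tie_rule(self):
        X = np.array([[3.0, 1.0], [2.0, 2.0]])
        fvs = feature_vectors_from_matrix(X, [55.0, 56.0])
        from tlbkit import PairFeature

        pm = indicator_matrix(fvs, [PairFeature(55.0, 56.0, 0.0, 0.0)])
        assert pm.indicators[0, 0] == 1  # 3 > 1
        assert pm.indicators[1, 0] == 0  # tie -> 0

    def test_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(5, 4))
        fvs = feature_vectors_from_matrix(X)
        from tlbkit import PairFeature

        temps = fvs[0].grid
        pairs = [PairFeature(temps[0], temps[2], 0.0, 0.0), PairFeature(temps[3], temps[1], 0.0, 0.0)]
        pm = indicator_matrix(fvs, pairs)
        for s in range(5):
            assert pm.indicators[s, 0] == (1 if X[s, 0] > X[s, 2] else 0)
            assert pm.indicators[s, 1] == (1 if X[s, 3] > X[s, 1] else 0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 1000),
        c=st.floats(min_value=1e-3, max_value=1e3),
        s_idx=st.integers(0, 7),
    )
    def test_monotone_amplitude_invariance(self, seed, c, s_idx):
        """Scaling one sample's curve by c > 0 flips no ordering indicator."""
        X, y, fvs = _random_features(8, 6, seed=seed)
        pairs = ktsp_select(fvs, y, k_max=3)
        base = indicator_matrix(fvs, pairs)
        X2 = X.copy()
        X2[s_idx] *= c
        scaled = indicator_matrix(feature_vectors_from_matrix(X2), pairs)
        assert np.array_equal(base.indicators, scaled.indicators)
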