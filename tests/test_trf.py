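"""Lagged ridge encoding model: design, split, fit, score, permutation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seegenc.core import EnvelopeSeries
from seegenc.synth import simulate_envelope
from seegenc.trf import (
    RidgeWorkspace,
    _shuffle_training_response,
    make_lagged_design,
    permutation_test,
    ridge_fit,
    score,
    split_train_test,
)


def random_envelope(n=1000, fs=100.0, seed=0):
    rng = np.random.default_rng(seed)
    return EnvelopeSeries(values=np.abs(rng.standard_normal(n)), fs=fs)


class TestLaggedDesign:
    def test_shape_and_delay_grid(self):
        design = make_lagged_design(random_envelope(1000))
        assert design.matrix.shape == (1000, 60)
        np.testing.assert_allclose(design.delays, np.arange(60) * 0.01)

    def test_single_zero_delay_is_identity(self):
        env = random_envelope(200)
        design = make_lagged_design(env, 0.0, 0.6, n_delays=1)
        np.testing.assert_array_equal(design.matrix[:, 0], env.values)

    def test_impulse_shifts_to_correct_row(self):
        values = np.zeros(200)
        values[50] = 1.0
        design = make_lagged_design(EnvelopeSeries(values=values, fs=100.0))
        col = design.matrix[:, 10]  # tau = 0.10 s -> 10 frames
        assert col[60] == 1.0
        assert col.sum() == 1.0

    def test_causal_zero_padding(self):
        design = make_lagged_design(random_envelope(100))
        assert np.all(design.matrix[0, 1:] == 0)

    def test_too_many_delays_rejected(self):
        with pytest.raises(ValueError):
            make_lagged_design(random_envelope(30), n_delays=60)

    @given(lag=st.integers(min_value=0, max_value=59),
           t=st.integers(min_value=0, max_value=499))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_column_is_delayed_envelope(self, lag, t):
        env = random_envelope(500, seed=42)
        design = make_lagged_design(env)
        expected = env.values[t - lag] if t >= lag else 0.0
        assert design.matrix[t, lag] == expected


class TestSplit:
    def test_partition_is_disjoint_and_exhaustive(self):
        train, test = split_train_test(6000, seed=1)
        assert np.intersect1d(train, test).size == 0
        assert np.union1d(train, test).size == 6000

    def test_train_fraction_within_one_chunk(self):
        train, _ = split_train_test(6000, train_frac=0.8, chunk_sec=5, fs=100)
        assert abs(train.size - 4800) <= 500

    def test_deterministic_under_seed(self):
        a = split_train_test(6000, seed=3)
        b = split_train_test(6000, seed=3)
        np.testing.assert_array_equal(a[0], b[0])

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(6000, train_frac=1.5)

    def test_too_few_chunks_rejected(self):
        with pytest.raises(ValueError, match="chunks"):
            split_train_test(300, chunk_sec=5, fs=100)


class TestRidgeFit:
    def test_matches_normal_equations_alpha_zero(self):
        rng = np.random.default_rng(0)
        design = make_lagged_design(random_envelope(200, seed=1), n_delays=20)
        y = rng.standard_normal(200)
        train = np.arange(150)
        model = ridge_fit(design, y, train, np.arange(150, 200), alpha=0.0)
        xc = design.matrix[train] - design.matrix[train].mean(axis=0)
        yc = y[train] - y[train].mean()
        w_direct = np.linalg.solve(xc.T @ xc, xc.T @ yc)
        np.testing.assert_allclose(model.weights.ravel(), w_direct, atol=1e-8)

    def test_matches_normal_equations_with_penalty(self):
        rng = np.random.default_rng(2)
        design = make_lagged_design(random_envelope(200, seed=3), n_delays=30)
        y = rng.standard_normal(200)
        train = np.arange(160)
        alpha = 7.5
        model = ridge_fit(design, y, train, np.arange(160, 200), alpha=alpha)
        xc = design.matrix[train] - design.matrix[train].mean(axis=0)
        yc = y[train] - y[train].mean()
        w_direct = np.linalg.solve(xc.T @ xc + alpha * np.eye(30), xc.T @ yc)
        rel = np.linalg.norm(model.weights.ravel() - w_direct) / np.linalg.norm(w_direct)
        assert rel < 1e-8

    def test_agrees_with_sklearn_ridge(self):
        """Cross-check against an independent ridge implementation."""
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(40)
        design = make_lagged_design(random_envelope(300, seed=41))
        y = rng.standard_normal(300)
        train = np.arange(240)
        alpha = 12.5
        model = ridge_fit(design, y, train, np.arange(240, 300), alpha=alpha)
        ref = Ridge(alpha=alpha, fit_intercept=True, solver="svd")
        ref.fit(design.matrix[train], y[train])
        np.testing.assert_allclose(model.weights.ravel(), ref.coef_, atol=1e-8)

    def test_noiseless_identifiability(self):
        rng = np.random.default_rng(4)
        env = random_envelope(2000, seed=5)
        design = make_lagged_design(env)
        w_true = rng.standard_normal(60)
        y = design.matrix @ w_true
        train, test = split_train_test(2000, seed=6)
        model = ridge_fit(design, y, train, test, alpha=1e-10)
        np.testing.assert_allclose(model.weights.ravel(), w_true, atol=1e-6)
        assert score(model, design, y) > 0.999

    def test_huge_alpha_shrinks_weights_to_zero(self):
        design = make_lagged_design(random_envelope(500, seed=7))
        y = np.random.default_rng(8).standard_normal(500)
        train, test = split_train_test(500, chunk_sec=1, seed=9)
        ws = RidgeWorkspace(design, train)
        alpha = 1e12 * ws.s[0] ** 2
        model = ridge_fit(design, y, train, test, alpha=alpha)
        assert np.linalg.norm(model.weights) < 1e-6

    def test_monotonicity_in_alpha(self):
        """Training RSS is non-decreasing and ||w|| non-increasing in alpha."""
        design = make_lagged_design(random_envelope(800, seed=10))
        y = np.random.default_rng(11).standard_normal(800)
        train, test = split_train_test(800, chunk_sec=1, seed=12)
        rss_prev, norm_prev = -np.inf, np.inf
        for alpha in [0.0, 1.0, 100.0, 1e4, 1e6]:
            model = ridge_fit(design, y, train, test, alpha=alpha)
            resid = y[train] - model.predict(design, train)
            rss = float(resid @ resid)
            norm = float(np.linalg.norm(model.weights))
            assert rss >= rss_prev - 1e-9
            assert norm <= norm_prev + 1e-12
            rss_prev, norm_prev = rss, norm

    def test_singular_design_alpha_zero_raises(self):
        values = np.ones(300)  # constant envelope -> rank-deficient design
        design = make_lagged_design(EnvelopeSeries(values=values, fs=100.0),
                                    n_delays=10)
        with pytest.raises(np.linalg.LinAlgError, match="alpha"):
            ridge_fit(design, np.random.default_rng(0).standard_normal(300),
                      np.arange(250), np.arange(250, 300), alpha=0.0)

    def test_length_mismatch_rejected(self):
        design = make_lagged_design(random_envelope(100))
        with pytest.raises(ValueError, match="length"):
            ridge_fit(design, np.zeros(99), np.arange(80), np.arange(80, 99))


class TestScore:
    def test_perfect_and_anticorrelated_predictions(self):
        env = random_envelope(500, seed=13)
        design = make_lagged_design(env, n_delays=1)
        train, test = split_train_test(500, chunk_sec=1, seed=14)
        y = env.values.copy()
        model = ridge_fit(design, y, train, test, alpha=1e-12)
        assert score(model, design, y) == pytest.approx(1.0, abs=1e-9)
        assert score(model, design, -y + 2 * y.mean()) == pytest.approx(-1.0, abs=1e-6)

    def test_independent_noise_scores_near_zero(self):
        """Monte-Carlo under independence: a prediction that carries no
        information about the response scores |r| < 0.05 in >= 95% of
        100 seeded runs at 6000 frames."""
        from seegenc.trf import TRFModel

        env = random_envelope(6000, seed=15)
        design = make_lagged_design(env)
        rng = np.random.default_rng(17)
        small = 0
        for _ in range(100):
            model = TRFModel(weights=rng.standard_normal((1, 60)), alpha=1.0,
                             train_idx=np.arange(0), test_idx=np.arange(6000),
                             alpha_grid=np.array([1.0]),
                             col_mean=np.zeros(60), y_mean=0.0)
            y = rng.standard_normal(6000)
            small += abs(score(model, design, y)) < 0.05
        assert small >= 95

    def test_zero_variance_prediction_warns_and_returns_zero(self):
        from seegenc.trf import TRFModel

        env = random_envelope(500, seed=18)
        design = make_lagged_design(env)
        model = TRFModel(weights=np.zeros((1, 60)), alpha=1.0,
                         train_idx=np.arange(400), test_idx=np.arange(400, 500),
                         alpha_grid=np.array([1.0]),
                         col_mean=np.zeros(60), y_mean=0.0)
        with pytest.warns(RuntimeWarning):
            assert score(model, design, np.arange(500.0)) == 0.0


class TestPermutation:
    def test_shuffle_preserves_training_multiset(self):
        rng = np.random.default_rng(21)
        y = rng.standard_normal(1000)
        train, _ = split_train_test(1000, chunk_sec=1, seed=22)
        y_null = _shuffle_training_response(y, train, chunk_len=100, rng=rng)
        np.testing.assert_array_equal(np.sort(y_null[train]), np.sort(y[train]))
        # test frames untouched
        mask = np.ones(1000, dtype=bool)
        mask[train] = False
        np.testing.assert_array_equal(y_null[mask], y[mask])

    def test_floor_when_true_model_wins(self):
        env = random_envelope(6000, seed=23)
        design = make_lagged_design(env)
        y = design.matrix @ np.linspace(1, 0, 60)  # strong true relation
        train, test = split_train_test(6000, seed=24)
        es = permutation_test(design, y, train, test, n_perm=100, seed=25)
        assert es.p == pytest.approx(0.01)
        assert np.all(es.null_r < es.r)
        assert es.null_r.size == 100

    def test_p_is_one_when_true_model_always_loses(self):
        env = random_envelope(1000, seed=26)
        design = make_lagged_design(env)
        train, test = split_train_test(1000, seed=27)
        y = -(design.matrix @ np.linspace(1, 0, 60))
        # force a sign-flipped model: fit on the negated response so every
        # null beats the (anti-predictive) true correlation
        model = ridge_fit(design, -y, train, test, alpha=1.0)
        es = permutation_test(design, y, train, test, n_perm=50, seed=28,
                              true_model=model)
        assert es.p == 1.0

    def test_invalid_nperm_rejected(self):
        env = random_envelope(1000, seed=29)
        design = make_lagged_design(env)
        train, test = split_train_test(1000, seed=30)
        with pytest.raises(ValueError):
            permutation_test(design, np.zeros(1000), train, test, n_perm=0)
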