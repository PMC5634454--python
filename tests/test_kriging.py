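"""Kriging core: kernel, weights, concentrated likelihood, swarm training,
prediction and analytic gradients — each against an independent oracle."""

import numpy as np
import pytest

from krigforce.kriging import (
    Hyperparameters,
    KrigingModel,
    PSOConfig,
    concentrated_log_likelihood,
    correlation_matrix,
    fit_weights,
    load_model,
    save_model,
    train,
)


def _brute_kernel(xi, xj, theta, p):
    return np.exp(-sum(t * abs(a - b) ** q for t, q, a, b in zip(theta, p, xi, xj)))


def _gp_draw(rng, n, theta, p, d=3):
    """Sample y from the kriging kernel itself: the data-generating process."""
    x = rng.uniform(0, 1, (n, d))
    r = correlation_matrix(x, Hyperparameters(theta, p), 1e-10)
    y = np.linalg.cholesky(r) @ rng.normal(size=n)
    return x, y


class TestCorrelationMatrix:
    def test_zero_theta_limit_gives_all_ones(self):
        x = np.random.default_rng(0).uniform(0, 1, (6, 3))
        hyp = Hyperparameters(np.zeros(3), np.full(3, 2.0))
        r = correlation_matrix(x, hyp, 1e-8)
        np.testing.assert_allclose(r, np.ones((6, 6)) + 1e-8 * np.eye(6), atol=0)

    def test_identical_rows_fully_correlated(self):
        x = np.array([[0.3, 0.7], [0.3, 0.7], [0.9, 0.1]])
        hyp = Hyperparameters(np.array([2.0, 3.0]), np.array([1.5, 2.0]))
        r = correlation_matrix(x, hyp, 0.0)
        assert r[0, 1] == 1.0

    def test_matches_term_by_term_brute_force(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-1, 1, (5, 3))
        theta = np.array([0.5, 2.0, 7.0])
        p = np.array([1.0, 1.5, 2.0])
        r = correlation_matrix(x, Hyperparameters(theta, p), 0.0)
        for i in range(5):
            for j in range(5):
                assert r[i, j] == pytest.approx(
                    _brute_kernel(x[i], x[j], theta, p), abs=1e-12
                )

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            Hyperparameters(np.array([-1.0]), np.array([2.0]))
        with pytest.raises(ValueError):
            Hyperparameters(np.array([1.0]), np.array([2.5]))


class TestFitWeights:
    def test_single_point_forced_solution(self):
        mu, a = fit_weights(np.array([[0.5]]), np.array([3.7]),
                            Hyperparameters(np.array([1.0]), np.array([2.0])))
        assert mu == pytest.approx(3.7)
        np.testing.assert_allclose(a, [0.0], atol=1e-12)

    def test_constant_response(self):
        x = np.random.default_rng(2).uniform(0, 1, (8, 2))
        mu, a = fit_weights(x, np.full(8, 4.2),
                            Hyperparameters(np.array([1.0, 1.0]),
                                            np.array([2.0, 2.0])))
        assert mu == pytest.approx(4.2)
        np.testing.assert_allclose(a, 0.0, atol=1e-9)

    def test_defining_identity_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n, d = rng.integers(4, 20), rng.integers(1, 4)
            x = rng.uniform(0, 1, (n, d))
            y = rng.normal(size=n)
            hyp = Hyperparameters(rng.uniform(0.5, 5, d), rng.uniform(1, 2, d))
            mu, a = fit_weights(x, y, hyp)
            r = correlation_matrix(x, hyp)
            assert np.max(np.abs(r @ a - (y - mu))) <= 1e-8


class TestConcentratedLogLikelihood:
    def test_output_scaling_shifts_by_n_log_c(self):
        rng = np.random.default_rng(4)
        x, y = _gp_draw(rng, 12, np.array([3.0, 1.0, 2.0]), np.full(3, 2.0))
        hyp = Hyperparameters(np.array([2.0, 2.0, 2.0]), np.full(3, 2.0))
        base = concentrated_log_likelihood(x, y, hyp)
        for c in (2.0, -3.5, 0.1):
            shifted = concentrated_log_likelihood(x, c * y, hyp)
            assert shifted == pytest.approx(base - 12 * np.log(abs(c)), abs=1e-8)

    def test_matches_explicit_determinant_formula(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, (6, 2))
        y = rng.normal(size=6)
        hyp = Hyperparameters(np.array([1.5, 4.0]), np.array([2.0, 1.3]))
        lam = 1e-10
        r = correlation_matrix(x, hyp, lam)
        r_inv = np.linalg.inv(r)
        ones = np.ones(6)
        mu = (ones @ r_inv @ y) / (ones @ r_inv @ ones)
        sigma2 = (y - mu) @ r_inv @ (y - mu) / 6
        expected = -3 * np.log(sigma2) - 0.5 * np.log(np.linalg.det(r))
        assert concentrated_log_likelihood(x, y, hyp, lam) == pytest.approx(
            expected, abs=1e-10
        )

    def test_prefers_generating_theta_over_shrunk_theta(self):
        """On data simulated from the kernel, the likelihood at the true θ
        beats the likelihood at θ/100 in a majority of replicates."""
        theta_true = np.array([8.0, 8.0, 8.0])
        p = np.full(3, 2.0)
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            x, y = _gp_draw(rng, 50, theta_true, p)
            at_true = concentrated_log_likelihood(
                x, y, Hyperparameters(theta_true, p)
            )
            at_shrunk = concentrated_log_likelihood(
                x, y, Hyperparameters(theta_true / 100, p)
            )
            wins += at_true > at_shrunk
        assert wins > 10

    def test_constant_response_sentinel(self):
        x = np.random.default_rng(6).uniform(0, 1, (5, 1))
        hyp = Hyperparameters(np.array([1.0]), np.array([2.0]))
        with pytest.warns(UserWarning, match="constant"):
            assert concentrated_log_likelihood(x, np.full(5, 2.0), hyp) == np.inf


class TestTrain:
    def test_recovers_generating_theta_within_order_of_magnitude(self):
        rng = np.random.default_rng(7)
        theta_true = np.array([30.0, 5.0, 60.0])
        x, y = _gp_draw(rng, 100, theta_true, np.full(3, 2.0))
        model = train(
            x, y, PSOConfig(swarm_size=25, iterations=60, seed=1,
                            p_bounds=(2.0, 2.0))
        )
        ratio = model.hyper.theta / theta_true
        assert np.all(ratio > 0.1) and np.all(ratio < 10.0)

    def test_same_seed_reproduces_model_exactly(self, tmp_path):
        rng = np.random.default_rng(8)
        x, y = _gp_draw(rng, 30, np.array([4.0, 4.0, 4.0]), np.full(3, 2.0))
        cfg = PSOConfig(swarm_size=8, iterations=10, seed=3)
        m1, m2 = train(x, y, cfg), train(x, y, cfg)
        save_model(m1, tmp_path / "a.json")
        save_model(m2, tmp_path / "b.json")
        assert (tmp_path / "a.json").read_text() == (tmp_path / "b.json").read_text()

    def test_more_iterations_never_worse(self):
        rng = np.random.default_rng(9)
        x, y = _gp_draw(rng, 40, np.array([6.0, 2.0, 9.0]), np.full(3, 2.0))
        short = train(x, y, PSOConfig(swarm_size=10, iterations=0, seed=5))
        long = train(x, y, PSOConfig(swarm_size=10, iterations=40, seed=5))
        assert long.metadata["log_likelihood"] >= short.metadata["log_likelihood"]

    def test_non_finite_data_rejected(self):
        with pytest.raises(ValueError):
            train(np.array([[0.0], [np.nan]]), np.array([1.0, 2.0]))


@pytest.fixture(scope="module")
def predict_model():
    rng = np.random.default_rng(10)
    x, y = _gp_draw(rng, 40, np.array([5.0, 5.0, 5.0]), np.full(3, 2.0))
    hyp = Hyperparameters(np.full(3, 5.0), np.full(3, 2.0))
    mu, a = fit_weights(x, y, hyp)
    return KrigingModel(mu, a, x, y, hyp, 1e-10)


@pytest.fixture(scope="module")
def gradient_model():
    rng = np.random.default_rng(13)
    x, y = _gp_draw(rng, 35, np.array([4.0, 4.0, 4.0]), np.full(3, 2.0))
    hyp = Hyperparameters(np.array([4.0, 4.0, 4.0]), np.full(3, 2.0))
    mu, a = fit_weights(x, y, hyp)
    return KrigingModel(mu, a, x, y, hyp, 1e-10)


class TestPredict:
    @pytest.fixture()
    def model(self, predict_model):
        return predict_model

    def test_interpolates_training_points(self, model):
        for i in range(model.n_train):
            assert model.predict(model.X[i]) == pytest.approx(
                model.y[i], abs=1e-6
            )

    def test_mean_reversion_far_from_data(self, model):
        far = model.X[0] + 1e6
        assert model.predict(far) == pytest.approx(model.mu, abs=1e-9)

    def test_matches_term_by_term_brute_force(self, model):
        rng = np.random.default_rng(11)
        theta, p = model.hyper.theta, model.hyper.p
        for _ in range(50):
            x = rng.uniform(-0.5, 1.5, 3)
            brute = model.mu + sum(
                aj * _brute_kernel(xj, x, theta, p)
                for aj, xj in zip(model.a, model.X)
            )
            assert model.predict(x) == pytest.approx(brute, abs=1e-12)

    def test_dimension_mismatch_rejected(self, model):
        with pytest.raises(ValueError, match="features"):
            model.predict(np.zeros(4))

    def test_permutation_invariance(self, model):
        perm = np.random.default_rng(12).permutation(model.n_train)
        hyp = model.hyper
        mu, a = fit_weights(model.X[perm], model.y[perm], hyp)
        shuffled = KrigingModel(mu, a, model.X[perm], model.y[perm], hyp, 1e-10)
        x = np.array([0.21, 0.43, 0.65])
        assert shuffled.predict(x) == pytest.approx(model.predict(x), abs=1e-8)


class TestPredictGradient:
    @pytest.fixture()
    def model(self, gradient_model):
        return gradient_model

    def test_matches_finite_differences_at_p2(self, model):
        rng = np.random.default_rng(14)
        h = 1e-6
        for _ in range(50):
            x = rng.uniform(0.05, 0.95, 3)
            grad = model.predict_gradient(x)
            fd = np.array(
                [
                    (model.predict(x + h * e) - model.predict(x - h * e)) / (2 * h)
                    for e in np.eye(3)
                ]
            )
            scale = max(np.max(np.abs(fd)), 1e-8)
            assert np.max(np.abs(grad - fd)) / scale <= 1e-5

    def test_tie_uses_plus_one_sign(self):
        """At x_k^j = x_k the cusp factor is +1: for p = 1 the one-sided
        derivative equals +θ·a_j exactly (hand-computed single-point case)."""
        x_train = np.array([[0.5]])
        hyp = Hyperparameters(np.array([2.0]), np.array([1.0]))
        model = KrigingModel(0.0, np.array([3.0]), x_train, np.array([3.0]),
                             hyp, 0.0)
        # Eq. |x^j - x| = 0: gradient term = a·δ·(−θ·p·|0|^0) = 3·1·(−2) = −6
        assert model.predict_gradient(np.array([0.5]))[0] == pytest.approx(-6.0)

    def test_constant_model_zero_gradient(self):
        x = np.random.default_rng(15).uniform(0, 1, (10, 2))
        hyp = Hyperparameters(np.array([1.0, 1.0]), np.full(2, 2.0))
        model = KrigingModel(5.0, np.zeros(10), x, np.full(10, 5.0), hyp, 1e-10)
        np.testing.assert_array_equal(model.predict_gradient(np.array([0.3, 0.4])),
                                      0.0)

    def test_continuous_through_training_point_at_p2(self, model):
        x0 = model.X[7]
        eps = 1e-9
        for k in range(3):
            e = np.eye(3)[k]
            left = model.predict_gradient(x0 - eps * e)
            right = model.predict_gradient(x0 + eps * e)
            np.testing.assert_allclose(left, right, atol=1e-6)


def test_model_file_round_trips_bit_exactly(tmp_path):
    rng = np.random.default_rng(16)
    x, y = _gp_draw(rng, 25, np.array([3.0, 7.0, 1.0]), np.full(3, 2.0))
    model = train(x, y, PSOConfig(swarm_size=8, iterations=10, seed=2),
                  metadata={"output": "E_intra", "atom": 1})
    path = tmp_path / "model.json"
    save_model(model, path)
    back = load_model(path)
    assert back.mu == model.mu
    np.testing.assert_array_equal(back.a, model.a)
    np.testing.assert_array_equal(back.X, model.X)
    np.testing.assert_array_equal(back.hyper.theta, model.hyper.theta)
    np.testing.assert_array_equal(back.hyper.p, model.hyper.p)
    assert back.metadata["output"] == "E_intra"
    x_query = rng.uniform(0, 1, 3)
    assert back.predict(x_query) == model.predict(x_query)


def test_wrong_format_file_rejected(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text('{"format": "something-else"}')
    with pytest.raises(ValueError, match="not a krigforce model"):
        load_model(path)
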