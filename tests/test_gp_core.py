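"""GP regression: kernel, standardization, posterior algebra, MAP fitting."""

import numpy as np
import pytest

from barrierbo import (
    GPConfig,
    GPState,
    StandardTransform,
    fit_hyperparameters,
    posterior,
    posterior_batch,
    rbf_kernel,
    standardize,
)
from barrierbo.gp_core import (
    DegenerateStandardizationError,
    GPError,
    kernel_matrix,
    map_objective,
)


def naive_posterior(X, y, theta1, theta2, noise_var, x_star):
    """Independent oracle: explicit matrix inversion, python-loop kernels."""
    n = len(y)
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = theta1 * np.exp(
                -np.sum((X[i] - X[j]) ** 2) / (2.0 * theta2**2)
            )
    Kinv = np.linalg.inv(K + noise_var * np.eye(n))
    kstar = np.array(
        [
            theta1 * np.exp(-np.sum((x_star - X[i]) ** 2) / (2.0 * theta2**2))
            for i in range(n)
        ]
    )
    mean = kstar @ Kinv @ y
    var = theta1 - kstar @ Kinv @ kstar
    return mean, var


class TestRBFKernel:
    def test_zero_distance_gives_theta1(self):
        assert rbf_kernel([1.0, 2.0], [1.0, 2.0], theta1=3.7, theta2=0.5) == 3.7

    def test_hand_evaluated_closed_form(self):
        # squared distance 2, unit hyperparameters -> e^-1
        x = np.zeros(2)
        y = np.array([1.0, 1.0])
        assert rbf_kernel(x, y, 1.0, 1.0) == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=4), rng.normal(size=4)
        assert rbf_kernel(a, b, 2.0, 1.5) == rbf_kernel(b, a, 2.0, 1.5)

    @pytest.mark.parametrize("t1,t2", [(0, 1), (1, 0), (-1, 1), (1, -2)])
    def test_nonpositive_hyperparameters_rejected(self, t1, t2):
        with pytest.raises(GPError):
            rbf_kernel([0.0], [1.0], t1, t2)

    def test_kernel_matrix_is_psd(self, rng):
        X = rng.normal(size=(40, 6))
        K = kernel_matrix(X, X, theta1=2.0, theta2=1.0)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestStandardize:
    def test_two_point_closed_form(self):
        std, t = standardize([100.0, 120.0])
        np.testing.assert_allclose(std, [-1.0, 1.0], atol=1e-12)
        assert t.mean == pytest.approx(110.0)
        assert t.sd == pytest.approx(10.0)  # population convention

    def test_mean_zero_sd_one(self, rng):
        raw = rng.normal(50, 7, size=100)
        std, _ = standardize(raw)
        assert abs(std.mean()) < 1e-10
        assert abs(std.std() - 1.0) < 1e-10

    def test_idempotent_and_invertible(self, rng):
        raw = rng.normal(size=50)
        std, t1 = standardize(raw)
        std2, t2 = standardize(std)
        np.testing.assert_allclose(std2, std, atol=1e-9)
        assert abs(t2.mean) < 1e-10 and abs(t2.sd - 1.0) < 1e-10
        np.testing.assert_allclose(t1.invert(std), raw, atol=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateStandardizationError):
            standardize([5.0, 5.0, 5.0])
        with pytest.raises(DegenerateStandardizationError):
            standardize([5.0])


class TestPosterior:
    def test_matches_naive_oracle_on_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 50))
            d = int(rng.integers(1, 8))
            X = rng.normal(size=(n, d))
            y = rng.normal(size=n)
            t1 = float(rng.uniform(0.5, 2.0))
            t2 = float(rng.uniform(0.8, 3.0))
            nv = float(rng.uniform(1e-3, 0.1))
            state = GPState(X=X, y=y, theta1=t1, theta2=t2, noise_var=nv)
            x_star = rng.normal(size=d)
            pred = posterior(state, x_star)
            m_ref, v_ref = naive_posterior(X, y, t1, t2, nv, x_star)
            assert pred.mean == pytest.approx(m_ref, abs=1e-8)
            assert pred.variance == pytest.approx(max(v_ref, 0.0), abs=1e-8)

    def test_noiseless_interpolation_at_training_point(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        state = GPState(X=X, y=y, theta1=1.0, theta2=1.5, noise_var=0.0)
        pred = posterior(state, X[4])
        assert pred.mean == pytest.approx(y[4], abs=1e-8)
        assert pred.variance == pytest.approx(0.0, abs=1e-8)

    def test_single_point_closed_form(self):
        # one training point: mean = (c/theta1) y1, var = theta1 - c^2/theta1
        theta1, theta2, y1 = 2.0, 1.0, 3.0
        state = GPState(X=[[0.0]], y=[y1], theta1=theta1, theta2=theta2, noise_var=0.0)
        x = np.array([1.2])
        c = rbf_kernel([0.0], x, theta1, theta2)
        pred = posterior(state, x)
        assert pred.mean == pytest.approx((c / theta1) * y1, abs=1e-10)
        assert pred.variance == pytest.approx(theta1 - c**2 / theta1, abs=1e-10)

    def test_prior_reversion_far_from_data(self, rng):
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        state = GPState(X=X, y=y, theta1=1.7, theta2=0.5, noise_var=0.01)
        pred = posterior(state, np.full(2, 100.0))
        assert abs(pred.mean) < 1e-10
        assert pred.variance == pytest.approx(1.7, abs=1e-10)

    def test_observing_a_point_never_raises_its_variance(self, rng):
        X = rng.normal(size=(8, 2))
        y = rng.normal(size=8)
        x_new = rng.normal(size=2)
        before = GPState(X=X, y=y, theta1=1.0, theta2=1.0, noise_var=1e-4)
        v_before = posterior(before, x_new).variance
        mu_new = posterior(before, x_new).mean
        after = GPState(
            X=np.vstack([X, x_new]),
            y=np.append(y, mu_new),
            theta1=1.0,
            theta2=1.0,
            noise_var=1e-4,
        )
        assert posterior(after, x_new).variance <= v_before + 1e-12

    def test_variance_clipping_is_tiny(self, rng):
        # near-duplicate rows stress the factorization; clipped mass stays small
        X = np.repeat(rng.normal(size=(5, 3)), 3, axis=0)
        X += rng.normal(scale=1e-9, size=X.shape)
        y = rng.normal(size=15)
        state = GPState(X=X, y=y, theta1=1.0, theta2=1.0, noise_var=0.0)
        _, _, clip = posterior_batch(state, X, return_clip=True)
        assert clip <= 1e-6


class TestFitHyperparameters:
    def test_recovers_length_scale_from_gp_draw(self, rng):
        theta2_true = 1.5
        X = rng.normal(size=(200, 2))
        K = kernel_matrix(X, X, theta1=1.0, theta2=theta2_true) + 1e-6 * np.eye(200)
        y = np.linalg.cholesky(K) @ rng.normal(size=200)
        y_std, t = standardize(y)
        state = fit_hyperparameters(X, y_std, GPConfig(n_restarts=3), seed=0, transform=t)
        assert theta2_true / 2 < state.theta2 < theta2_true * 2

    def test_scale_invariance_through_standardization(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.normal(10.0, 3.0, size=30)
        y1, _ = standardize(y)
        y2, _ = standardize(2.0 * y)
        np.testing.assert_allclose(y1, y2, atol=1e-12)
        s1 = fit_hyperparameters(X, y1, seed=1)
        s2 = fit_hyperparameters(X, y2, seed=1)
        assert (s1.theta1, s1.theta2, s1.noise_var) == (s2.theta1, s2.theta2, s2.noise_var)

    def test_objective_not_worse_than_warm_start(self, rng):
        X = rng.normal(size=(40, 3))
        y, t = standardize(rng.normal(size=40))
        cfg = GPConfig()
        for trial in range(3):
            start = (
                float(rng.uniform(0.3, 3.0)),
                float(rng.uniform(0.5, 5.0)),
                float(rng.uniform(1e-4, 0.5)),
            )
            init_state = GPState(
                X=X, y=y, theta1=start[0], theta2=start[1], noise_var=start[2]
            )
            fitted = fit_hyperparameters(
                X, y, cfg, seed=trial, warm_start=start, n_restarts=1
            )
            assert fitted.objective >= map_objective(init_state, cfg) - 1e-6

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(25, 2))
        y, _ = standardize(rng.normal(size=25))
        a = fit_hyperparameters(X, y, seed=5)
        b = fit_hyperparameters(X, y, seed=5)
        assert (a.theta1, a.theta2, a.noise_var) == (b.theta1, b.theta2, b.noise_var)


def test_state_json_roundtrip(tmp_path, rng):
    X = rng.normal(size=(6, 2))
    y = rng.normal(size=6)
    state = GPState(
        X=X, y=y, theta1=1.2, theta2=0.8, noise_var=0.01,
        transform=StandardTransform(110.0, 14.0), objective=-3.5,
    )
    path = tmp_path / "state.json"
    state.to_json(path)
    back = GPState.from_json(path)
    np.testing.assert_array_equal(back.X, state.X)
    np.testing.assert_array_equal(back.y, state.y)
    assert back.transform == state.transform
    assert (back.theta1, back.theta2, back.noise_var) == (1.2, 0.8, 0.01)
    p1, p2 = posterior(state, X[0]), posterior(back, X[0])
    assert p1.mean == p2.mean and p1.variance == p2.variance
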