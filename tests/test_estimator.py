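import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from stcorr import (
    ResponseVector,
    SpatialFilter,
    UndefinedCorrelationError,
    Window,
    build_augmented,
    default_lambda_grid,
    objective,
    solve_weights,
)
from tests.conftest import make_band_dataset, single_latency_design


def multiple_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """OLS oracle: the multiple correlation of y on the rows of x (channels)."""
    xc = (x - x.mean(axis=1, keepdims=True)).T
    yc = y - y.mean()
    beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fit = xc @ beta
    return float(np.linalg.norm(fit) / np.linalg.norm(yc))


class TestBuildAugmented:
    def test_augmented_response_has_n_delta_t_entries(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 5, 4))  # latencies at 0,10,..,40 ms
        data = make_band_dataset(x)
        y = np.array([1.0, 2.0, 3.0, 4.0])
        design = build_augmented(data, Window(0.0, 30.0), ResponseVector(y))
        assert design.delta_t == 3
        assert design.response.shape == (12,)
        # each y_n appears delta_t times (centered)
        yc = y - y.mean()
        assert np.allclose(design.response, np.tile(yc, 3))

    def test_delta_t_one_equals_single_latency_matrix(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((3, 4, 10))
        data = make_band_dataset(x)
        y = rng.standard_normal(10)
        design = build_augmented(data, Window(10.0, 20.0), ResponseVector(y))
        assert design.delta_t == 1
        expect = x[:, 1, :] - x[:, 1, :].mean(axis=1, keepdims=True)
        assert np.allclose(design.values, expect)

    def test_covariance_equals_average_of_per_sample_estimates(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((4, 6, 30))
        data = make_band_dataset(x)
        y = rng.standard_normal(30)
        design = build_augmented(data, Window(0.0, 60.0), ResponseVector(y))
        # brute force: average the per-sample outer-product estimates of the
        # jointly centered data
        mu = x.mean(axis=(1, 2), keepdims=True)
        per_sample = [
            (x[:, s, :] - mu[:, 0, :]) @ (x[:, s, :] - mu[:, 0, :]).T / 30 for s in range(6)
        ]
        assert np.allclose(design.covariance, np.mean(per_sample, axis=0), atol=1e-10)

    def test_window_outside_epoch_rejected(self):
        rng = np.random.default_rng(3)
        data = make_band_dataset(rng.standard_normal((2, 4, 6)))
        with pytest.raises(ValueError):
            build_augmented(data, Window(100.0, 200.0), ResponseVector(np.arange(6.0)))

    def test_response_length_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        data = make_band_dataset(rng.standard_normal((2, 4, 6)))
        with pytest.raises(ValueError):
            build_augmented(data, Window(0.0, 20.0), ResponseVector(np.arange(5.0)))


class TestSolveWeights:
    def test_single_channel_copy_of_response_is_perfectly_correlated(self):
        rng = np.random.default_rng(5)
        y = rng.standard_normal(20)
        data = make_band_dataset(y[None, None, :], latencies_ms=[0.0])
        design = build_augmented(data, Window(0.0, 10.0), ResponseVector(y))
        filt = solve_weights(design, 0.0)
        assert filt.achieved_r == pytest.approx(1.0, abs=1e-10)

    def test_closed_form_attains_multiple_correlation(self):
        rng = np.random.default_rng(6)
        data, resp, win = single_latency_design(rng, d=3, n=60)
        design = build_augmented(data, win, resp)
        filt = solve_weights(design, 0.0)
        oracle = multiple_correlation(data.values[:, 0, :], resp.values)
        assert filt.achieved_r == pytest.approx(oracle, abs=1e-8)

    def test_large_lambda_limit_is_cross_covariance_direction(self):
        rng = np.random.default_rng(7)
        data, resp, win = single_latency_design(rng, d=5, n=100)
        design = build_augmented(data, win, resp)
        lam = 1e6 * float(np.linalg.eigvalsh(design.covariance).max())
        filt = solve_weights(design, lam)
        direction = design.cross / np.linalg.norm(design.cross)
        cos = abs(filt.weights @ direction)
        assert cos > 0.999

    def test_singular_covariance_at_lambda_zero_falls_back_with_warning(self):
        rng = np.random.default_rng(8)
        base = rng.standard_normal(30)
        x = np.stack([base, base])[:, None, :]  # two identical channels
        data = make_band_dataset(x, latencies_ms=[0.0])
        design = build_augmented(data, Window(0.0, 10.0), ResponseVector(rng.standard_normal(30)))
        with pytest.warns(RuntimeWarning):
            filt = solve_weights(design, 0.0)
        assert np.all(np.isfinite(filt.weights))

    def test_negative_lambda_rejected(self):
        rng = np.random.default_rng(9)
        data, resp, win = single_latency_design(rng, d=3, n=20)
        design = build_augmented(data, win, resp)
        with pytest.raises(ValueError):
            solve_weights(design, -1.0)

    def test_json_round_trip(self):
        filt = SpatialFilter(
            np.array([0.6, 0.8]), 0.5, Window(10.0, 70.0), "alpha", 0.42, ["C3", "C4"]
        )
        back = SpatialFilter.from_json(filt.to_json())
        assert np.allclose(back.weights, filt.weights)
        assert back.lam == filt.lam
        assert back.tau == filt.tau
        assert back.band == filt.band
        assert back.achieved_r == filt.achieved_r
        # deterministic serialization
        assert filt.to_json() == back.to_json()


class TestObjective:
    def test_orthogonal_weights_raise_undefined_correlation(self):
        y = np.arange(10.0)
        x = np.zeros((2, 1, 10))
        x[0, 0] = np.arange(10.0)
        data = make_band_dataset(x, latencies_ms=[0.0])
        design = build_augmented(data, Window(0.0, 10.0), ResponseVector(y))
        with pytest.raises(UndefinedCorrelationError):
            objective(np.array([0.0, 1.0]), design)  # second channel is flat

    @settings(derandomize=True, max_examples=30)
    @given(scale=hst.floats(1e-3, 1e3), seed=hst.integers(0, 50))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        data, resp, win = single_latency_design(rng, d=4, n=25)
        design = build_augmented(data, win, resp)
        w = rng.standard_normal(4)
        assert objective(w, design) == pytest.approx(objective(scale * w, design), abs=1e-10)

    def test_closed_form_beats_random_directions(self):
        rng = np.random.default_rng(10)
        data, resp, win = single_latency_design(rng, d=4, n=50)
        design = build_augmented(data, win, resp)
        best = solve_weights(design, 0.0).achieved_r
        dirs = rng.standard_normal((1000, 4))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        rs = [objective(w, design) for w in dirs]
        assert best >= max(rs) - 1e-12

    def test_constant_response_raises(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((2, 1, 10))
        data = make_band_dataset(x, latencies_ms=[0.0])
        design = build_augmented(data, Window(0.0, 10.0), ResponseVector(np.full(10, 3.0)))
        with pytest.raises(UndefinedCorrelationError):
            objective(np.array([1.0, 0.0]), design)


class TestInvariants:
    def test_achieved_r_is_nonnegative_and_flip_invariant(self):
        rng = np.random.default_rng(12)
        for seed in range(5):
            data, resp, win = single_latency_design(np.random.default_rng(seed), d=4, n=40)
            design = build_augmented(data, win, resp)
            filt = solve_weights(design, 0.1)
            assert filt.achieved_r >= 0
            neg = build_augmented(data, win, ResponseVector(-resp.values))
            filt_neg = solve_weights(neg, 0.1)
            assert filt_neg.achieved_r == pytest.approx(filt.achieved_r, abs=1e-10)
            assert np.allclose(filt_neg.weights, -filt.weights, atol=1e-8)

    def test_equivariance_under_invertible_channel_transform(self):
        rng = np.random.default_rng(13)
        d, n = 4, 200
        x = rng.standard_normal((d, 1, n))
        y = rng.standard_normal(n)
        a_mat = rng.standard_normal((d, d)) + 2 * np.eye(d)
        data = make_band_dataset(x, latencies_ms=[0.0])
        data_t = make_band_dataset((a_mat @ x[:, 0, :])[:, None, :], latencies_ms=[0.0])
        f1 = solve_weights(build_augmented(data, Window(0.0, 10.0), ResponseVector(y)), 0.0)
        f2 = solve_weights(build_augmented(data_t, Window(0.0, 10.0), ResponseVector(y)), 0.0)
        assert f2.achieved_r == pytest.approx(f1.achieved_r, abs=1e-8)
        mapped = np.linalg.inv(a_mat).T @ f1.weights
        mapped /= np.linalg.norm(mapped)
        assert abs(mapped @ f2.weights) == pytest.approx(1.0, abs=1e-8)

    def test_training_objective_non_increasing_in_lambda(self):
        rng = np.random.default_rng(14)
        data, resp, win = single_latency_design(rng, d=6, n=80)
        design = build_augmented(data, win, resp)
        grid = np.concatenate([[0.0], default_lambda_grid(design, 6)])
        rs = [solve_weights(design, lam).achieved_r for lam in np.sort(grid)]
        assert all(r1 >= r2 - 1e-12 for r1, r2 in zip(rs, rs[1:]))

    def test_numerical_maximizer_never_beats_closed_form(self):
        from scipy.optimize import minimize

        for seed in range(3):
            rng = np.random.default_rng(seed)
            data, resp, win = single_latency_design(rng, d=3, n=50)
            design = build_augmented(data, win, resp)
            closed = solve_weights(design, 0.0).achieved_r
            best = -np.inf
            for start in range(4):
                w0 = np.random.default_rng(100 + start).standard_normal(3)
                res = minimize(lambda w: -objective(w, design), w0, method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
                best = max(best, -res.fun)
            assert best <= closed + 1e-6
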