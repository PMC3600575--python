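import numpy as np
import pytest

from stcorr import (
    ResponseVector,
    SpatialFilter,
    UndefinedCorrelationError,
    Window,
    build_augmented,
    cct,
    component_map,
    forward_model,
    scc,
    solve_weights,
)
from stcorr.components import plot_component_map
from tests.conftest import make_band_dataset


def unit_filter(d, j, tau=None, ch_names=None):
    w = np.zeros(d)
    w[j] = 1.0
    return SpatialFilter(w, 0.0, tau, "alpha", 0.0, ch_names or [f"ch{i:03d}" for i in range(d)])


class TestSCC:
    def test_selector_filter_returns_channel(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 5, 7))
        data = make_band_dataset(x)
        comp = scc(unit_filter(3, 1), data)
        assert np.allclose(comp.values, x[1].T)

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((3, 5, 7))
        data = make_band_dataset(x)
        w = rng.standard_normal(3)
        f1 = SpatialFilter(w, 0.0, None, "alpha", 0.0)
        f2 = SpatialFilter(2 * w, 0.0, None, "alpha", 0.0)
        assert np.allclose(scc(f2, data).values, 2 * scc(f1, data).values)

    def test_channel_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        data = make_band_dataset(rng.standard_normal((3, 5, 7)))
        with pytest.raises(ValueError):
            scc(unit_filter(4, 0), data)

    def test_fitted_component_tracks_source_at_least_as_well_as_any_channel(self, small_band_data):
        data, resp, truth = small_band_data
        win = truth.window
        design = build_augmented(data, win, resp)
        filt = solve_weights(design, 0.0)
        # every single-channel selector is a feasible filter, so the fitted
        # objective dominates each channel's correlation with the response
        from stcorr.estimator import objective

        for c in range(data.n_channels):
            e_c = np.zeros(data.n_channels)
            e_c[c] = 1.0
            assert filt.achieved_r >= objective(e_c, design) - 1e-9
        # and the extracted component tracks the planted source power closely
        comp = scc(filt, data)
        from stcorr.windows import window_samples

        idx = window_samples(win, data.latencies_ms)
        z = comp.values[:, idx].mean(axis=1)
        assert abs(np.corrcoef(z, truth.source_power)[0, 1]) > 0.9


class TestCCT:
    def test_values_within_unit_interval_and_peak_near_planted_window(self, small_band_data):
        data, resp, truth = small_band_data
        design = build_augmented(data, truth.window, resp)
        filt = solve_weights(design, 0.0)
        trace = cct(filt, data, resp)
        finite = trace.values[np.isfinite(trace.values)]
        assert np.all(finite <= 1.0) and np.all(finite >= -1.0)
        peak = data.latencies_ms[np.nanargmax(trace.values)]
        assert truth.window.start_ms - 100 <= peak <= truth.window.stop_ms + 100

    def test_trace_invariant_under_joint_sign_flip_after_refit(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((4, 6, 40))
        x[2] += 0.5 * np.linspace(-1, 1, 40)[None, :]
        data = make_band_dataset(x)
        y = rng.standard_normal(40) + np.linspace(-1, 1, 40)
        win = Window(10.0, 30.0)
        f_pos = solve_weights(build_augmented(data, win, ResponseVector(y)), 0.1)
        f_neg = solve_weights(build_augmented(data, win, ResponseVector(-y)), 0.1)
        t_pos = cct(f_pos, data, ResponseVector(y))
        t_neg = cct(f_neg, data, ResponseVector(-y))
        assert np.allclose(t_pos.values, t_neg.values, atol=1e-8)

    def test_cct_at_tau_matches_achieved_r_for_single_sample_window(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((3, 5, 30))
        data = make_band_dataset(x)
        y = rng.standard_normal(30)
        win = Window(20.0, 30.0)  # exactly one latency sample
        design = build_augmented(data, win, ResponseVector(y))
        assert design.delta_t == 1
        filt = solve_weights(design, 0.0)
        trace = cct(filt, data, ResponseVector(y))
        assert trace.values[2] == pytest.approx(filt.achieved_r, abs=1e-8)

    def test_constant_response_raises(self):
        rng = np.random.default_rng(5)
        data = make_band_dataset(rng.standard_normal((3, 5, 10)))
        with pytest.raises(UndefinedCorrelationError):
            cct(unit_filter(3, 0), data, ResponseVector(np.full(10, 2.0)))

    def test_zero_variance_latency_marked_nan_not_zero(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((2, 4, 10))
        x[:, 2, :] = 5.0  # flat latency across trials
        data = make_band_dataset(x)
        trace = cct(unit_filter(2, 0), data, ResponseVector(rng.standard_normal(10)))
        assert np.isnan(trace.values[2])
        assert np.all(np.isfinite(np.delete(trace.values, 2)))

    def test_tsv_output(self, tmp_path):
        rng = np.random.default_rng(7)
        data = make_band_dataset(rng.standard_normal((2, 4, 10)))
        trace = cct(unit_filter(2, 0), data, ResponseVector(rng.standard_normal(10)))
        path = tmp_path / "trace.tsv"
        trace.write_tsv(path)
        assert path.read_text().splitlines()[0] == "latency_ms\tr"


class TestForwardModel:
    def test_rank_one_data_recovers_coupling_exactly(self):
        rng = np.random.default_rng(8)
        a0 = rng.standard_normal(4)
        z0 = rng.standard_normal(12)
        x = a0[:, None, None] * z0[None, None, :]
        data = make_band_dataset(np.repeat(x, 3, axis=1))
        # filter with w'a0 = 1 recovers the component z0 itself, so the
        # forward model returns the mixing vector exactly
        filt = SpatialFilter(a0 / (a0 @ a0), 0.0, Window(0.0, 10.0), "alpha", 0.0)
        comp = scc(filt, data)
        assert np.allclose(comp.values[:, 0], z0)
        fm = forward_model(data, comp, latency_ms=0.0)
        assert np.allclose(fm.coupling, a0, atol=1e-10)

    def test_scaling_data_scales_coupling(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((3, 4, 15))
        d1 = make_band_dataset(x)
        d2 = make_band_dataset(4.0 * x)
        w = rng.standard_normal(3)
        filt = SpatialFilter(w, 0.0, Window(0.0, 20.0), "alpha", 0.0)
        c1 = scc(filt, d1)
        fm1 = forward_model(d1, c1)
        # same component against scaled data: a -> 4 a
        fm2 = forward_model(d2, c1)
        assert np.allclose(fm2.coupling, 4.0 * fm1.coupling)

    def test_coupling_times_component_invariant_under_filter_rescale(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((3, 4, 15))
        data = make_band_dataset(x)
        w = rng.standard_normal(3)
        f1 = SpatialFilter(w, 0.0, Window(0.0, 10.0), "alpha", 0.0)
        f2 = SpatialFilter(5 * w, 0.0, Window(0.0, 10.0), "alpha", 0.0)
        c1, c2 = scc(f1, data), scc(f2, data)
        a1 = forward_model(data, c1).coupling
        a2 = forward_model(data, c2).coupling
        assert np.allclose(np.outer(a1, c1.values[:, 0]), np.outer(a2, c2.values[:, 0]))

    def test_planted_topography_recovered_in_power_space(self, small_band_data):
        data, resp, truth = small_band_data
        design = build_augmented(data, truth.window, resp)
        filt = solve_weights(design, 1e-3 * float(np.trace(design.covariance)) / data.n_channels)
        comp = scc(filt, data)
        fm = forward_model(data, comp)
        cos = abs(fm.coupling @ truth.power_topography) / np.linalg.norm(fm.coupling)
        assert cos >= 0.95

    def test_zero_component_rejected(self):
        data = make_band_dataset(np.random.default_rng(11).standard_normal((2, 3, 8)))
        filt = SpatialFilter(np.zeros(2), 0.0, Window(0.0, 10.0), "alpha", 0.0)
        comp = scc(filt, data)
        with pytest.raises(ValueError):
            forward_model(data, comp, latency_ms=0.0)


class TestComponentMap:
    def test_sorted_response_gives_identity_order(self):
        rng = np.random.default_rng(12)
        data = make_band_dataset(rng.standard_normal((2, 3, 5)))
        comp = scc(unit_filter(2, 0), data)
        cm = component_map(comp, ResponseVector(np.array([1.0, 2.0, 3.0, 4.0, 5.0])))
        assert np.array_equal(cm.order, np.arange(5))
        assert np.allclose(cm.values, comp.values)

    def test_reversed_response_reverses_rows(self):
        rng = np.random.default_rng(13)
        data = make_band_dataset(rng.standard_normal((2, 3, 5)))
        comp = scc(unit_filter(2, 0), data)
        cm = component_map(comp, ResponseVector(np.array([5.0, 4.0, 3.0, 2.0, 1.0])))
        assert np.array_equal(cm.order, np.arange(5)[::-1])
        assert np.allclose(cm.values, comp.values[::-1])

    def test_inverse_permutation_restores_original(self):
        rng = np.random.default_rng(14)
        data = make_band_dataset(rng.standard_normal((2, 3, 20)))
        comp = scc(unit_filter(2, 0), data)
        y = rng.standard_normal(20)
        cm = component_map(comp, ResponseVector(y))
        restored = np.empty_like(cm.values)
        restored[cm.order] = cm.values
        assert np.allclose(restored, comp.values)
        assert np.all(np.diff(cm.response_sorted) >= 0)

    def test_ties_keep_original_trial_order(self):
        rng = np.random.default_rng(15)
        data = make_band_dataset(rng.standard_normal((2, 3, 4)))
        comp = scc(unit_filter(2, 0), data)
        cm = component_map(comp, ResponseVector(np.array([2.0, 1.0, 2.0, 1.0])))
        assert list(cm.order) == [1, 3, 0, 2]

    def test_length_mismatch_rejected(self):
        rng = np.random.default_rng(16)
        data = make_band_dataset(rng.standard_normal((2, 3, 5)))
        comp = scc(unit_filter(2, 0), data)
        with pytest.raises(ValueError):
            component_map(comp, ResponseVector(np.arange(4.0)))

    def test_png_heatmap_written(self, tmp_path):
        rng = np.random.default_rng(17)
        data = make_band_dataset(rng.standard_normal((2, 6, 10)))
        comp = scc(unit_filter(2, 0, tau=Window(10.0, 30.0)), data)
        cm = component_map(comp, ResponseVector(rng.standard_normal(10)))
        out = tmp_path / "map.png"
        plot_component_map(cm, out)
        assert out.exists() and out.stat().st_size > 0
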