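"""Autoencoder core: forward maps, LM training, restart selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emg2kin import (
    AENParams,
    FeatureSeries,
    TrainConfig,
    extract_activations,
    fit_autoencoder,
    forward_hidden,
    forward_output,
    reconstruction_sse,
    train_lm,
)
from emg2kin.autoencoder import ActivationSeries, selection_correlation


def _feats(values):
    return FeatureSeries(
        values=np.atleast_2d(values), frame_rate=10.0, window_seconds=0.1
    )


def _params(iw, lw=None, b=None):
    iw = np.atleast_2d(iw)
    r = iw.shape[1]
    return AENParams(
        iw=iw,
        lw=np.zeros((r, 2)) if lw is None else np.asarray(lw, float),
        b=np.zeros(r) if b is None else np.asarray(b, float),
    )


class TestForwardHidden:
    def test_identity_projection_of_nonnegative_input(self):
        p = _params(np.eye(2))
        act = forward_hidden(p, _feats([[3.0], [4.0]]))
        assert np.allclose([act.a1[0], act.a2[0]], [3.0, 4.0])

    def test_absolute_value_of_negative_projection(self):
        p = _params([[-1.0, 0.0], [0.0, 1.0]])
        act = forward_hidden(p, _feats([[3.0], [4.0]]))
        assert np.isclose(act.a1[0], 3.0)

    def test_hand_computed_projection(self):
        p = _params([[1.0, -2.0, 0.0], [0.0, 1.0, 1.0]])
        act = forward_hidden(p, _feats([[1.0], [1.0], [2.0]]))
        assert np.allclose([act.a1[0], act.a2[0]], [1.0, 3.0])

    def test_dimension_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="dimension mismatch"):
            forward_hidden(_params(np.eye(2)), _feats([[1.0], [1.0], [1.0]]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 2**16), r=st.integers(1, 8))
    def test_activations_nonnegative_for_arbitrary_weights(self, seed, r):
        rng = np.random.default_rng(seed)
        p = _params(rng.normal(size=(2, r)) * 10)
        feats = _feats(np.abs(rng.normal(size=(r, 20))))
        act = forward_hidden(p, feats)
        assert np.all(act.a1 >= 0) and np.all(act.a2 >= 0)


class TestForwardOutput:
    def test_zero_weights_give_bias_only(self):
        p = _params(np.eye(2), b=[1.5, -2.0])
        act = ActivationSeries(a1=np.ones(4), a2=np.ones(4), frame_rate=10.0)
        q = forward_output(p, act)
        assert np.allclose(q, np.array([[1.5], [-2.0]]) * np.ones((1, 4)))

    def test_unit_activation_selects_column(self):
        lw = np.array([[0.3, 9.0], [0.7, 9.0]])
        p = _params(np.eye(2), lw=lw)
        act = ActivationSeries(a1=np.ones(1), a2=np.zeros(1), frame_rate=10.0)
        assert np.allclose(forward_output(p, act).ravel(), lw[:, 0])

    def test_hand_computed_output(self):
        p = _params(np.eye(2), lw=[[1.0, 1.0], [2.0, 0.0]], b=[0.0, 1.0])
        act = ActivationSeries(a1=[2.0], a2=[3.0], frame_rate=10.0)
        assert np.allclose(forward_output(p, act).ravel(), [5.0, 5.0])


class TestReconstructionSse:
    def test_exact_reconstruction_gives_zero(self):
        # identity-ish network on a single positive channel pair
        p = AENParams(iw=np.eye(2), lw=np.eye(2), b=np.zeros(2))
        feats = _feats(np.abs(np.random.default_rng(0).normal(size=(2, 9))))
        assert reconstruction_sse(p, feats) == pytest.approx(0.0, abs=1e-20)

    def test_zero_params_on_unit_norm_windows_gives_n(self):
        rng = np.random.default_rng(1)
        v = np.abs(rng.normal(size=(3, 7)))
        v /= np.linalg.norm(v, axis=0, keepdims=True)
        p = _params(np.zeros((2, 3)))
        assert reconstruction_sse(p, _feats(v)) == pytest.approx(7.0)

    def test_matches_elementwise_loop_oracle(self, rng):
        r, n = 4, 6
        p = AENParams(
            iw=rng.normal(size=(2, r)),
            lw=rng.normal(size=(r, 2)),
            b=rng.normal(size=r),
        )
        feats = _feats(np.abs(rng.normal(size=(r, n))))
        total = 0.0
        for t in range(n):
            a = np.abs(p.iw @ feats.values[:, t])
            q = p.lw @ a + p.b
            for ch in range(r):
                total += (q[ch] - feats.values[ch, t]) ** 2
        assert reconstruction_sse(p, feats) == pytest.approx(total, rel=1e-12)


class TestExtractActivations:
    def test_equals_forward_hidden_bitwise(self, rng):
        p = AENParams(
            iw=rng.normal(size=(2, 16)),
            lw=rng.normal(size=(16, 2)),
            b=rng.normal(size=16),
        )
        feats = _feats(np.abs(rng.normal(size=(16, 25))))
        full = forward_hidden(p, feats)
        proj = extract_activations(p.iw, feats)
        assert np.array_equal(full.a1, proj.a1)
        assert np.array_equal(full.a2, proj.a2)

    def test_zero_features_give_zero_activations(self):
        act = extract_activations(np.ones((2, 3)), _feats(np.zeros((3, 5))))
        assert np.all(act.a1 == 0) and np.all(act.a2 == 0)

    def test_matches_dot_product_oracle(self, rng):
        iw = rng.normal(size=(2, 16))
        feats = _feats(np.abs(rng.normal(size=(16, 10))))
        act = extract_activations(iw, feats)
        for t in range(10):
            assert act.a1[t] == pytest.approx(
                abs(sum(iw[0, j] * feats.values[j, t] for j in range(16)))
            )


def _rank2_features(rng, r=6, n=120, noise=0.0):
    """Features generated by an abs-value rank-2 network (exactly realizable)."""
    h = np.abs(rng.normal(size=(r, 2)))
    g = np.abs(rng.normal(size=(2, n)))
    v = h @ g + noise * rng.normal(size=(r, n))
    return _feats(np.clip(v, 0, None)), h, g


class TestTrainLm:
    def test_zero_iterations_returns_initial_params(self, rng):
        feats, _, _ = _rank2_features(rng)
        init = AENParams(
            iw=rng.normal(size=(2, 6)), lw=rng.normal(size=(6, 2)),
            b=rng.normal(size=6),
        )
        cfg = TrainConfig(max_iterations=0, n_restarts=1)
        out, trace = train_lm(feats, cfg, init)
        assert np.array_equal(out.iw, init.iw)
        assert np.array_equal(out.lw, init.lw)
        assert len(trace) == 1

    def test_recovers_realizable_structure_from_near_truth_init(self, rng):
        feats, h, g = _rank2_features(rng)
        # true generating parameters, perturbed slightly
        true_iw = np.linalg.pinv(h)
        init = AENParams(
            iw=true_iw + 0.01 * rng.normal(size=true_iw.shape),
            lw=h + 0.01 * rng.normal(size=h.shape),
            b=0.01 * rng.normal(size=6),
        )
        cfg = TrainConfig(max_iterations=200, convergence_tol=1e-14)
        initial_sse = reconstruction_sse(init, feats)
        out, trace = train_lm(feats, cfg, init)
        assert trace[-1] < 1e-6 * initial_sse

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_accepted_step_sse_is_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        feats, _, _ = _rank2_features(rng, noise=0.05)
        init = AENParams(
            iw=rng.uniform(-0.5, 0.5, (2, 6)),
            lw=rng.uniform(-0.5, 0.5, (6, 2)),
            b=rng.uniform(-0.5, 0.5, 6),
        )
        _, trace = train_lm(feats, TrainConfig(max_iterations=60), init)
        assert all(b <= a + 1e-15 for a, b in zip(trace, trace[1:]))

    def test_sse_matches_scipy_least_squares_on_smooth_instance(self, rng):
        """Independent optimizer cross-check on a fixed-sign-pattern instance."""
        from scipy.optimize import least_squares

        from emg2kin.autoencoder import _pack, _residuals_and_jacobian

        feats, h, _ = _rank2_features(rng, r=4, n=60)
        init = AENParams(
            iw=np.linalg.pinv(h) + 0.05 * rng.normal(size=(2, 4)),
            lw=h + 0.05 * rng.normal(size=(4, 2)),
            b=0.05 * rng.normal(size=4),
        )
        ours, trace = train_lm(
            feats, TrainConfig(max_iterations=300, convergence_tol=1e-14), init
        )
        res = least_squares(
            lambda th: _residuals_and_jacobian(th, feats.values)[0],
            _pack(init),
            jac=lambda th: _residuals_and_jacobian(th, feats.values)[1],
            method="lm",
            max_nfev=2000,
        )
        scipy_sse = float(res.fun @ res.fun)
        assert trace[-1] <= scipy_sse * (1 + 1e-3) + 1e-10


class TestScaleIndeterminacy:
    def test_row_column_rescaling_leaves_reconstruction_unchanged(self, rng):
        p = AENParams(
            iw=rng.normal(size=(2, 5)), lw=rng.normal(size=(5, 2)),
            b=rng.normal(size=5),
        )
        feats = _feats(np.abs(rng.normal(size=(5, 12))))
        q0 = forward_output(p, forward_hidden(p, feats))
        c = 3.7
        scaled = AENParams(
            iw=p.iw * np.array([[c], [1.0]]),
            lw=p.lw / np.array([[c, 1.0]]),
            b=p.b,
        )
        q1 = forward_output(scaled, forward_hidden(scaled, feats))
        assert np.allclose(q0, q1, rtol=1e-12)


class TestSelectionCorrelation:
    def test_zero_variance_unit_treated_as_decoupled(self):
        act = ActivationSeries(
            a1=np.zeros(10), a2=np.arange(10.0), frame_rate=10.0
        )
        assert selection_correlation(act) == 0.0

    def test_perfectly_correlated_units(self):
        a = np.arange(10.0)
        act = ActivationSeries(a1=a, a2=2 * a, frame_rate=10.0)
        assert selection_correlation(act) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(3)
    # two directions active in disjoint epochs, as in calibration
    g = np.zeros((2, 200))
    g[0, :100] = np.abs(rng.normal(size=100))
    g[1, 100:] = np.abs(rng.normal(size=100))
    h = np.abs(rng.normal(size=(8, 2)))
    feats = _feats(h @ g + 0.01 * np.abs(rng.normal(size=(8, 200))))
    return fit_autoencoder(feats, TrainConfig(seed=11)), feats


class TestFitAutoencoder:

    def test_selected_network_has_minimum_absolute_correlation(self, fitted):
        fit, _ = fitted
        assert len(fit.restart_correlations) == 10
        assert abs(fit.selection_correlation) == pytest.approx(
            min(abs(r) for r in fit.restart_correlations)
        )

    def test_selected_correlation_not_above_restart_median(self, fitted):
        fit, _ = fitted
        med = np.median([abs(r) for r in fit.restart_correlations])
        assert abs(fit.selection_correlation) <= med

    def test_trained_sse_beats_zero_weight_model(self, fitted):
        fit, feats = fitted
        zero = AENParams(
            iw=np.zeros((2, 8)), lw=np.zeros((8, 2)), b=np.zeros(8)
        )
        assert fit.sse <= reconstruction_sse(zero, feats)

    def test_folded_params_apply_to_raw_features(self, fitted):
        # the stored SSE was computed on normalized features; the folded
        # network must reconstruct the raw features equally well
        fit, feats = fitted
        assert reconstruction_sse(fit.params, feats) <= reconstruction_sse(
            AENParams(np.zeros((2, 8)), np.zeros((8, 2)), np.zeros(8)), feats
        )

    def test_single_restart_returns_that_network(self, rng):
        feats, _, _ = _rank2_features(rng)
        fit = fit_autoencoder(feats, TrainConfig(n_restarts=1, seed=5))
        assert len(fit.restart_correlations) == 1

    def test_same_seed_reproduces_fit_exactly(self, rng):
        feats, _, _ = _rank2_features(rng)
        cfg = TrainConfig(seed=9, max_iterations=30)
        f1 = fit_autoencoder(feats, cfg)
        f2 = fit_autoencoder(feats, cfg)
        assert np.array_equal(f1.params.iw, f2.params.iw)
        assert f1.restart_correlations == f2.restart_correlations
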