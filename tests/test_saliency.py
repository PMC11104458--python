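"""Saliency pipeline: gradient correctness, composition, and planted truth."""

import numpy as np
import pytest

from cardiolens.model import ModelConfig, build_model, predict
from cardiolens.saliency import (Heatmap, align_heatmap, explain,
                                 explain_batch, feature_gradients,
                                 kernel_weights, lead_cam)


def fd_gradient(model, feats, label, eps=1e-3):
    """Central finite differences of the label logit w.r.t. the features."""
    g = np.zeros_like(feats[0])
    for c in range(feats.shape[1]):
        for t in range(feats.shape[2]):
            fp, fm = feats.copy(), feats.copy()
            fp[0, c, t] += eps
            fm[0, c, t] -= eps
            g[c, t] = (model.logits_from_features(fp)[0, label]
                       - model.logits_from_features(fm)[0, label]) / (2 * eps)
    return g


class TestFeatureGradients:
    def test_matches_finite_differences(self, toy_config):
        model = build_model(toy_config)
        x = np.random.default_rng(0).normal(size=(1, 2, 16))
        feats = model.encode(x)
        for label in range(2):
            g = model.feature_gradient_batch(feats, label)[0]
            np.testing.assert_allclose(g, fd_gradient(model, feats, label),
                                       atol=1e-4)

    def test_gradient_independent_of_other_heads(self, toy_config):
        model = build_model(toy_config)
        x = np.random.default_rng(1).normal(size=(1, 2, 16))
        g0 = feature_gradients(model, x, 0)
        # perturb the other head's weights only
        head = model.trunk.layers[-1]
        head.w[1] += 5.0
        assert np.array_equal(g0, feature_gradients(model, x, 0))

    def test_label_out_of_range_rejected(self, toy_config):
        model = build_model(toy_config)
        x = np.zeros((1, 2, 16))
        with pytest.raises(ValueError):
            feature_gradients(model, x, 5)


class TestKernelWeights:
    def test_constant_gradient_gives_its_value(self):
        g = np.full((3, 8), 2.5)
        np.testing.assert_allclose(kernel_weights(g).alpha, 2.5)

    def test_antisymmetric_gradient_cancels(self):
        g = np.concatenate([np.ones((2, 4)), -np.ones((2, 4))], axis=1)
        np.testing.assert_allclose(kernel_weights(g).alpha, 0.0)

    def test_matches_explicit_mean(self):
        g = np.random.default_rng(2).normal(size=(6, 20))
        expected = np.array([sum(row) / len(row) for row in g])
        np.testing.assert_allclose(kernel_weights(g).alpha, expected)

    def test_empty_time_axis_rejected(self):
        with pytest.raises(ValueError):
            kernel_weights(np.zeros((3, 0)))


class TestLeadCam:
    def test_negative_weights_positive_features_zero_map(self):
        feats = np.abs(np.random.default_rng(3).normal(size=(4, 10)))
        w = kernel_weights(-np.ones((4, 10)))
        block_map = [(0, 2), (2, 4)]
        assert lead_cam(feats, w, block_map).max() == 0.0

    def test_identity_case_single_channel_unit_weight(self):
        feats = np.random.default_rng(4).normal(size=(2, 10))
        w = kernel_weights(np.ones((2, 10)))
        out = lead_cam(feats, w, [(0, 1), (1, 2)])
        np.testing.assert_allclose(out, np.maximum(feats, 0.0))

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(5)
        feats = rng.normal(size=(6, 12))
        grad = rng.normal(size=(6, 12))
        w = kernel_weights(grad)
        block_map = [(0, 2), (2, 4), (4, 6)]
        out = lead_cam(feats, w, block_map)
        for l, (lo, hi) in enumerate(block_map):
            for t in range(12):
                acc = sum(w.alpha[c] * feats[c, t] for c in range(lo, hi))
                assert out[l, t] == pytest.approx(max(acc, 0.0))


class TestAlignHeatmap:
    def test_doubles_temporal_length(self):
        raw = np.random.default_rng(6).uniform(size=(12, 2048))
        assert align_heatmap(raw, 4096).shape == (12, 4096)

    def test_constant_map_stays_constant(self):
        out = align_heatmap(np.full((2, 16), 0.7), 32)
        np.testing.assert_allclose(out, 0.7)

    def test_linear_ramp_preserved(self):
        n = 64
        raw = np.tile(np.linspace(0, 1, n), (1, 1))
        out = align_heatmap(raw, 2 * n)
        np.testing.assert_allclose(out[0], np.linspace(0, 1, 2 * n), atol=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            align_heatmap(np.zeros((2, 10)), 21)


class TestExplain:
    def test_composition_equals_staged_pipeline(self, toy_config):
        model = build_model(toy_config)
        x = np.random.default_rng(7).normal(size=(1, 2, 16))
        hm = explain(model, x[0], label=1)
        feats = model.encode(x)
        g = model.feature_gradient_batch(feats, 1)[0]
        raw = lead_cam(feats[0], kernel_weights(g), model.block_map)
        full = align_heatmap(raw, 16)
        if full.max() > 0:
            full = full / full.max()
        np.testing.assert_array_equal(hm.values, full)

    def test_zero_gradient_zero_heatmap(self, toy_config):
        model = build_model(toy_config)
        head = model.trunk.layers[-1]
        head.w[...] = 0.0  # logit constant -> zero gradient
        hm = explain(model, np.random.default_rng(8).normal(size=(2, 16)),
                     label=0)
        assert np.all(hm.values == 0.0)

    def test_normalised_range_and_shape(self, toy_config):
        model = build_model(toy_config)
        hm = explain(model, np.random.default_rng(9).normal(size=(2, 16)),
                     label=0)
        assert hm.values.shape == (2, 16)
        assert hm.values.min() >= 0.0 and hm.values.max() in (0.0, 1.0)

    def test_scale_invariance_of_normalised_map(self, toy_config):
        """Scaling the input scales features and gradients consistently in the
        (piecewise-linear) network, leaving the normalised heatmap unchanged."""
        model = build_model(toy_config)
        for l in model._stacks():
            for layer in l.layers:
                if hasattr(layer, "b"):
                    layer.b[...] = 0.0  # make the network positively homogeneous
        x = np.random.default_rng(10).normal(size=(2, 16))
        h1 = explain(model, x, label=0)
        h2 = explain(model, 3.0 * x, label=0)
        np.testing.assert_allclose(h1.values, h2.values, atol=1e-9)

    def test_oracle_rederivation_on_toy_model(self, toy_config):
        """Full from-scratch re-derivation: finite-difference gradients plus
        explicit sums reproduce explain() within 1e-3."""
        model = build_model(toy_config)
        x = np.random.default_rng(11).normal(size=(1, 2, 16))
        label = 0
        feats = model.encode(x)
        g = fd_gradient(model, feats, label)
        alpha = g.mean(axis=1)
        raw = np.zeros((2, 8))
        for l, (lo, hi) in enumerate(model.block_map):
            for t in range(8):
                raw[l, t] = max(0.0, sum(alpha[c] * feats[0, c, t]
                                         for c in range(lo, hi)))
        expected = align_heatmap(raw, 16)
        if expected.max() > 0:
            expected = expected / expected.max()
        hm = explain(model, x[0], label=label)
        np.testing.assert_allclose(hm.values, expected, atol=1e-3)

    def test_planted_lead_dominates_confident_records(self, planted_model,
                                                      planted_small):
        _, _, xte, yte, plant = planted_small
        probs = np.array([p.probabilities[0]
                          for p in predict(planted_model, xte)])
        conf = np.where(probs > 0.8)[0]
        assert len(conf) > 20
        hms = explain_batch(planted_model, xte[conf], label=0)
        dom = [int(np.argmax(h.values.sum(axis=1))) for h in hms]
        assert np.mean(np.array(dom) == plant.lead_index) >= 0.9

    def test_planted_window_holds_most_lead_mass(self, planted_model,
                                                 planted_small):
        _, _, xte, _, plant = planted_small
        probs = np.array([p.probabilities[0]
                          for p in predict(planted_model, xte)])
        conf = np.where(probs > 0.8)[0]
        hms = explain_batch(planted_model, xte[conf], label=0)
        fs = 400.0
        i0 = int((plant.window[0] - 0.1) * fs)
        i1 = int((plant.window[1] + 0.1) * fs)
        for h in hms:
            row = h.values[plant.lead_index]
            assert row[i0:i1].sum() / max(row.sum(), 1e-12) >= 0.6
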