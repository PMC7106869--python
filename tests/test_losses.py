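"""Loss terms: closed forms, gradients, linearity and composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from echosketch import losses as L

RNG = np.random.default_rng(11)


class TestClassBalancedCrossEntropy:
    def test_perfect_prediction_vanishes(self):
        target = RNG.integers(0, 3, size=(1, 8, 8))
        logits = np.full((1, 3, 8, 8), -1e3)
        np.put_along_axis(logits, target[:, None], 1e3, axis=1)
        assert L.class_balanced_cross_entropy(logits, target) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_logits_balanced_target_closed_form(self):
        """Two balanced classes, uniform prediction: w_c = 0.5 for both, so
        the loss is 0.5 * ln 2."""
        target = np.array([[[0, 1], [1, 0]]])
        loss = L.class_balanced_cross_entropy(np.zeros((1, 2, 2, 2)), target)
        assert loss == pytest.approx(0.5 * np.log(2), abs=1e-12)

    def test_single_class_target_gets_zero_weight(self):
        target = np.zeros((1, 4, 4), dtype=int)
        logits = RNG.normal(size=(1, 2, 4, 4))
        assert L.class_balanced_cross_entropy(logits, target) == pytest.approx(0.0)

    def test_class_outside_channel_range_rejected(self):
        with pytest.raises(ValueError):
            L.class_balanced_cross_entropy(
                np.zeros((1, 2, 2, 2)), np.full((1, 2, 2), 5)
            )

    def test_gradient_matches_finite_differences(self):
        logits = RNG.normal(size=(1, 3, 4, 4))
        target = RNG.integers(0, 3, size=(1, 4, 4))
        _, grad = L.class_balanced_cross_entropy(logits, target, return_grad=True)
        eps = 1e-6
        for _ in range(5):
            idx = tuple(RNG.integers(0, s) for s in logits.shape)
            lp, lm = logits.copy(), logits.copy()
            lp[idx] += eps
            lm[idx] -= eps
            num = (
                L.class_balanced_cross_entropy(lp, target)
                - L.class_balanced_cross_entropy(lm, target)
            ) / (2 * eps)
            assert num == pytest.approx(grad[idx], abs=1e-6)


class TestAdversarialTerms:
    def test_uncertain_discriminator_closed_form(self):
        d, g = L.adversarial_terms(np.full(4, 0.5), np.full(4, 0.5))
        assert d == pytest.approx(2 * np.log(2), abs=1e-9)
        assert g == pytest.approx(np.log(2), abs=1e-9)

    def test_perfect_discriminator_limit(self):
        d, _ = L.adversarial_terms(np.ones(4), np.zeros(4))
        assert d == pytest.approx(0.0, abs=1e-5)

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            L.adversarial_terms(np.array([1.5]), np.array([0.5]))

    def test_finite_under_extreme_scores(self):
        d, g = L.adversarial_terms(np.zeros(3), np.ones(3))
        assert np.isfinite(d) and np.isfinite(g)


class TestPixelTerms:
    def test_l1_identity_and_constant_offset(self):
        a = RNG.normal(size=(8, 8))
        assert L.l1_image_loss(a, a) == 0.0
        assert L.l1_image_loss(np.full((4, 4), 0.2), np.full((4, 4), -0.3)) == pytest.approx(0.5)

    def test_l1_matches_elementwise_oracle(self):
        a, b = RNG.normal(size=(6, 6)), RNG.normal(size=(6, 6))
        assert L.l1_image_loss(a, b) == pytest.approx(np.abs(a - b).mean(), abs=1e-15)

    def test_tv_constant_image_is_zero(self):
        assert L.tv_loss(np.full((5, 5), 0.7)) == 0.0

    def test_tv_two_by_two_closed_form(self):
        assert L.tv_loss(np.array([[0.0, 1.0], [0.0, 1.0]])) == 0.5

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_tv_nonnegative_and_complement_symmetric(self, seed):
        a = np.random.default_rng(seed).uniform(-1, 1, size=(6, 6))
        tv = L.tv_loss(a)
        assert tv >= 0
        assert L.tv_loss(1 - a) == pytest.approx(tv, abs=1e-12)


class TestPerceptualLoss:
    def test_identical_inputs_give_zero(self):
        a = RNG.normal(size=(1, 1, 16, 16))
        assert L.perceptual_loss(a, a, L.FeatureExtractor(seed=2)) == 0.0

    def test_symmetric_in_arguments(self):
        ext = L.FeatureExtractor(seed=2)
        a, b = RNG.normal(size=(1, 1, 16, 16)), RNG.normal(size=(1, 1, 16, 16))
        assert L.perceptual_loss(a, b, ext) == pytest.approx(
            L.perceptual_loss(b, a, ext), abs=1e-12
        )

    def test_identity_extractor_reduces_to_mse(self):
        a, b = RNG.normal(size=(1, 1, 8, 8)), RNG.normal(size=(1, 1, 8, 8))
        loss = L.perceptual_loss(a, b, L.IdentityExtractor())
        assert loss == pytest.approx(np.mean((a - b) ** 2), abs=1e-15)

    def test_gradient_nonzero_and_matches_finite_differences(self):
        ext = L.FeatureExtractor(seed=3)
        a, b = RNG.normal(size=(1, 1, 16, 16)), RNG.normal(size=(1, 1, 16, 16))
        _, grad = L.perceptual_loss(a, b, ext, return_grad=True)
        assert np.abs(grad).max() > 0
        eps = 1e-6
        for _ in range(4):
            idx = tuple(RNG.integers(0, s) for s in a.shape)
            ap, am = a.copy(), a.copy()
            ap[idx] += eps
            am[idx] -= eps
            num = (L.perceptual_loss(ap, b, ext) - L.perceptual_loss(am, b, ext)) / (2 * eps)
            assert num == pytest.approx(grad[idx], abs=1e-5)


class TestComposites:
    def test_LS_toggle_and_sum(self):
        w_off = L.LossWeights(use_l1_in_LS=False)
        rep = L.compose_LS((1.0, 0.4), 0.3, w_off)
        assert rep.total == 0.4
        rep = L.compose_LS((1.0, np.log(2)), 0.1, L.LossWeights())
        assert rep.total == pytest.approx(np.log(2) + 0.1, abs=1e-12)
        rep.validate()

    def test_LU_default_weights(self):
        w = L.LossWeights()
        rep = L.compose_LU((0.0, 0.0), 1.0, 1.0, 1.0, w)
        assert rep.total == pytest.approx(6e-3 + 2e-8 + 1.0, abs=1e-15)
        rep.validate(w)

    @given(
        st.floats(0, 10),
        st.floats(0, 10),
        st.floats(0, 10),
    )
    @settings(max_examples=30, deadline=None)
    def test_LU_linear_in_weights(self, l1w, l2w, l3w):
        terms = (0.7, 0.3)
        base = L.compose_LU(terms, 2.0, 3.0, 5.0, L.LossWeights(l1w, l2w, l3w)).total
        doubled = L.compose_LU(
            terms, 2.0, 3.0, 5.0, L.LossWeights(2 * l1w, 2 * l2w, 2 * l3w)
        ).total
        g_adv = terms[1]
        assert doubled - g_adv == pytest.approx(2 * (base - g_adv), rel=1e-12, abs=1e-12)

    def test_total_loss_addition_and_contract(self):
        a = L.LossReport({"g_adv": 1.0}, 1.0)
        b = L.LossReport({"g_adv": 2.5}, 2.5)
        assert L.total_loss(a, b) == 3.5
        assert L.total_loss(a, b) == L.total_loss(b, a)
        with pytest.raises(ValueError):
            L.total_loss(a, L.LossReport({}, None))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            L.LossWeights(lambda1=-1.0)

    def test_report_recomputation_detects_corruption(self):
        rep = L.compose_LS((1.0, 0.5), 0.2, L.LossWeights())
        rep.total += 0.1
        with pytest.raises(AssertionError):
            rep.validate()
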