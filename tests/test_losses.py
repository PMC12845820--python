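"""Contrastive alignment, cross-attention, and the composite losses."""

import numpy as np
import pytest

from eegaug.autodiff import Tensor
from eegaug.losses import (EmbeddingPair, LossWeights, Temperature,
                           average_contrastive_loss, classification_total_loss,
                           combine_regression_loss, contrastive_logits,
                           contrastive_loss_pair, cross_attention_align,
                           cross_entropy_loss, negative_pearson_loss,
                           regression_total_loss)
from conftest import assert_grad_matches


class TestContrastiveLogits:
    def test_identity_embeddings_scaled_by_tau(self):
        eye = np.eye(2)
        logits = contrastive_logits(EmbeddingPair(eye, eye, tau=2.0))
        np.testing.assert_allclose(logits.data, [[2, 0], [0, 2]])

    def test_same_embeddings_give_symmetric_gram(self, rng):
        f = rng.standard_normal((4, 3))
        logits = contrastive_logits(EmbeddingPair(f, f, tau=1.0))
        np.testing.assert_allclose(logits.data, logits.data.T)

    def test_linear_in_tau(self, rng):
        f_a, f_i = rng.standard_normal((3, 4)), rng.standard_normal((3, 4))
        l1 = contrastive_logits(EmbeddingPair(f_a, f_i, tau=1.0))
        l2 = contrastive_logits(EmbeddingPair(f_a, f_i, tau=2.0))
        np.testing.assert_allclose(l2.data, 2 * l1.data)

    def test_nonpositive_tau_rejected(self, rng):
        f = rng.standard_normal((2, 2))
        with pytest.raises(ValueError, match="positive"):
            contrastive_logits(EmbeddingPair(f, f, tau=0.0))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            EmbeddingPair(rng.standard_normal((2, 3)), rng.standard_normal((2, 4)))


class TestContrastiveLossPair:
    def test_identity_logits_closed_form(self):
        # softmax row [1,0]: p(correct) = e/(e+1); loss = -log it = 0.31326...
        loss = contrastive_loss_pair(np.eye(2))
        assert float(loss) == pytest.approx(0.3132616875, abs=1e-9)

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_uniform_logits_give_log_k(self, k):
        assert float(contrastive_loss_pair(np.zeros((k, k)))) == pytest.approx(np.log(k))

    def test_margin_monotonicity(self):
        prev = np.inf
        for scale in (1.0, 2.0, 10.0):
            val = float(contrastive_loss_pair(np.eye(3) * scale))
            assert val < prev
            prev = val

    def test_nonnegative(self, rng):
        for _ in range(10):
            assert float(contrastive_loss_pair(rng.standard_normal((4, 4)))) >= 0

    def test_nonsquare_rejected(self, rng):
        with pytest.raises(ValueError, match="square"):
            contrastive_loss_pair(rng.standard_normal((2, 3)))

    def test_tau_to_zero_limit_is_log_batch(self, rng):
        f_a, f_i = rng.standard_normal((5, 6)), rng.standard_normal((5, 6))
        loss = contrastive_loss_pair(
            contrastive_logits(EmbeddingPair(f_a, f_i, tau=1e-9)))
        assert float(loss) == pytest.approx(np.log(5), abs=1e-6)


class TestAverageContrastiveLoss:
    def test_single_pair_reduces_to_pair_loss(self, rng):
        pair = EmbeddingPair(rng.standard_normal((3, 4)), rng.standard_normal((3, 4)))
        expected = float(contrastive_loss_pair(contrastive_logits(pair)))
        assert float(average_contrastive_loss([pair])) == pytest.approx(expected)

    def test_arithmetic_mean_and_order_invariance(self, rng):
        pairs = [EmbeddingPair(rng.standard_normal((3, 4)),
                               rng.standard_normal((3, 4))) for _ in range(3)]
        fwd = float(average_contrastive_loss(pairs))
        rev = float(average_contrastive_loss(pairs[::-1]))
        singles = [float(contrastive_loss_pair(contrastive_logits(p))) for p in pairs]
        assert fwd == pytest.approx(np.mean(singles))
        assert fwd == pytest.approx(rev)

    def test_empty_collection_is_zero(self):
        assert float(average_contrastive_loss([])) == 0.0


class TestCrossAttention:
    def test_weights_rows_sum_to_one(self, rng):
        f_a, f_i = rng.standard_normal((5, 8)), rng.standard_normal((5, 8))
        _, attn = cross_attention_align(f_a, f_i, return_weights=True)
        np.testing.assert_allclose(attn.data.sum(axis=1), 1.0, atol=1e-6)

    def test_dominant_match_recovers_matched_row(self):
        # hand-computed 2x2: query 0 nearly orthogonal to row 1, huge overlap
        # with row 0, so attention collapses onto row 0
        f_a = np.array([[20.0, 0.0], [0.0, 20.0]])
        f_i = np.array([[20.0, 0.0], [0.0, 20.0]])
        scores = (f_i @ f_a.T) / np.sqrt(2)
        expected = (np.exp(scores - scores.max(axis=1, keepdims=True))
                    / np.exp(scores - scores.max(axis=1, keepdims=True)).sum(
                        axis=1, keepdims=True)) @ f_a
        out = cross_attention_align(f_a, f_i)
        np.testing.assert_allclose(out.data, expected, atol=1e-9)
        np.testing.assert_allclose(out.data[0], f_a[0], atol=1e-6)

    def test_output_within_convex_hull_bounds(self, rng):
        f_a, f_i = rng.standard_normal((6, 4)), rng.standard_normal((6, 4))
        out = cross_attention_align(f_a, f_i)
        assert np.all(out.data <= f_a.max(axis=0) + 1e-12)
        assert np.all(out.data >= f_a.min(axis=0) - 1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="dimension"):
            cross_attention_align(rng.standard_normal((3, 4)),
                                  rng.standard_normal((3, 5)))


class TestNegativePearson:
    def test_perfect_correlation(self, rng):
        x = rng.standard_normal((3, 20))
        assert float(negative_pearson_loss(x, x)) == pytest.approx(-1.0)
        assert float(negative_pearson_loss(x, -x)) == pytest.approx(1.0)

    def test_vector_oracle(self):
        loss = float(negative_pearson_loss([1.0, 2, 3], [1.0, 2, 4]))
        assert loss == pytest.approx(-0.98198, abs=1e-5)

    def test_affine_invariance(self, rng):
        x, y = rng.standard_normal((4, 30)), rng.standard_normal((4, 30))
        base = float(negative_pearson_loss(x, y))
        assert float(negative_pearson_loss(3.0 * x + 7.0, y)) == pytest.approx(base)

    def test_bounded_by_one(self, rng):
        for _ in range(20):
            v = float(negative_pearson_loss(rng.standard_normal((2, 15)),
                                            rng.standard_normal((2, 15))))
            assert -1.0 - 1e-9 <= v <= 1.0 + 1e-9

    def test_zero_variance_bin_skipped_with_warning(self, rng):
        x = rng.standard_normal((3, 10))
        y = x.copy()
        x[1] = 5.0  # constant bin
        with pytest.warns(UserWarning, match="zero-variance"):
            loss = float(negative_pearson_loss(x, y))
        assert loss == pytest.approx(-1.0)


class TestComposites:
    def test_regression_arithmetic_oracle(self):
        val = combine_regression_loss(-0.5, 1.0, 2.0, LossWeights(0.01, 0.001))
        assert float(val) == pytest.approx(-0.488)

    def test_zero_weights_reduce_to_pearson_term(self, rng):
        x, y = rng.standard_normal((3, 12)), rng.standard_normal((3, 12))
        total = regression_total_loss(x, y, L_cont=5.0, weights=LossWeights(0, 0))
        assert float(total) == pytest.approx(float(negative_pearson_loss(x, y)))

    def test_default_weights(self):
        w = LossWeights()
        assert (w.alpha, w.beta) == (0.01, 0.001)

    def test_classification_arithmetic(self):
        assert float(classification_total_loss(0.7, 0.2, alpha=0.01)) == \
            pytest.approx(0.702)
        assert float(classification_total_loss(0.7, 0.2, alpha=0.0)) == \
            pytest.approx(0.7)
        # additivity in L_cont
        a = float(classification_total_loss(0.5, 1.0, 0.01))
        b = float(classification_total_loss(0.5, 2.0, 0.01))
        assert b - a == pytest.approx(0.01)


class TestCrossEntropy:
    def test_perfect_one_hot_zero(self):
        yhat = np.eye(3)
        assert float(cross_entropy_loss([0, 1, 2], yhat)) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_log_c(self):
        yhat = np.full((4, 5), 0.2)
        assert float(cross_entropy_loss([0, 1, 2, 3], yhat)) == pytest.approx(np.log(5))

    def test_two_sample_oracle(self):
        yhat = np.array([[0.8, 0.2], [0.5, 0.5]])
        assert float(cross_entropy_loss([0, 0], yhat)) == \
            pytest.approx(-(np.log(0.8) + np.log(0.5)) / 2)

    def test_zero_probability_clamped(self):
        yhat = np.array([[1.0, 0.0], [0.0, 1.0]])
        with pytest.warns(UserWarning, match="clamped"):
            loss = float(cross_entropy_loss([1, 1], yhat))
        assert np.isfinite(loss)


class TestGradients:
    """Finite-difference gradients of every differentiable loss, 4x8 inputs."""

    def test_contrastive_loss_gradient(self, rng):
        f_a = Tensor(rng.standard_normal((4, 8)), requires_grad=True)
        f_i = Tensor(rng.standard_normal((4, 8)), requires_grad=True)
        temp = Temperature(1.0)
        assert_grad_matches(
            lambda: contrastive_loss_pair(
                contrastive_logits(EmbeddingPair(f_a, f_i, temp.tau))),
            [f_a, f_i, temp.theta])

    def test_cross_attention_gradient(self, rng):
        f_a = Tensor(rng.standard_normal((4, 8)), requires_grad=True)
        f_i = Tensor(rng.standard_normal((4, 8)), requires_grad=True)
        assert_grad_matches(
            lambda: (cross_attention_align(f_a, f_i) ** 2.0).sum(), [f_a, f_i])

    def test_pearson_and_l1_gradient(self, rng):
        x = Tensor(rng.standard_normal((4, 8)), requires_grad=True)
        y = Tensor(rng.standard_normal((4, 8)), requires_grad=True)
        assert_grad_matches(lambda: negative_pearson_loss(x, y), [x, y])
        assert_grad_matches(lambda: regression_total_loss(x, y, L_cont=0.3), [x, y])

    def test_cross_entropy_gradient(self, rng):
        from eegaug.autodiff import softmax
        logits = Tensor(rng.standard_normal((4, 3)), requires_grad=True)
        y = np.array([0, 2, 1, 1])
        assert_grad_matches(
            lambda: cross_entropy_loss(y, softmax(logits, axis=1)), [logits])
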