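"""Loss-term unit tests against independent oracles.

Every non-trivial expected value here is produced by a brute-force oracle
(column-centering covariance, per-sample loops, log-sum-exp identities,
central finite differences) computed independently of the implementation.
"""

import numpy as np
import pytest
from scipy.special import logsumexp as scipy_lse

from trapnet.autograd import Tensor
from trapnet.losses import (
    LossBreakdown,
    coral_gradient,
    coral_loss,
    correlation_matrix,
    reverse_focal_adv_loss,
    reverse_focal_adv_loss_logits,
    source_ce_loss,
    total_loss,
    transformer_loss,
)


def centering_cov_oracle(B):
    """Brute-force sample covariance: subtract column means, divide by N-1."""
    B = np.asarray(B, dtype=float)
    centered = B - B.mean(axis=0)
    return centered.T @ centered / (B.shape[0] - 1)


class TestCorrelationMatrix:
    def test_hand_worked_two_by_two(self):
        C = correlation_matrix(np.array([[1.0, 0.0], [0.0, 1.0]]))
        np.testing.assert_allclose(C, [[0.5, -0.5], [-0.5, 0.5]], atol=1e-12)

    def test_identical_rows_give_zero_matrix(self):
        C = correlation_matrix(np.tile([2.0, -1.0, 3.0], (5, 1)))
        np.testing.assert_allclose(C, 0.0, atol=1e-12)

    @pytest.mark.parametrize("shape", [(2, 3), (7, 4), (32, 11)])
    def test_matches_centering_oracle(self, rng, shape):
        B = rng.normal(size=shape)
        np.testing.assert_allclose(correlation_matrix(B), centering_cov_oracle(B), atol=1e-10)

    def test_symmetric(self, rng):
        C = correlation_matrix(rng.normal(size=(9, 5)))
        np.testing.assert_allclose(C, C.T, atol=1e-12)

    def test_batch_too_small(self):
        with pytest.raises(ValueError, match="batch too small"):
            correlation_matrix(np.ones((1, 3)))


class TestCoralLoss:
    def test_identical_batches_zero(self, rng):
        B = rng.normal(size=(6, 4))
        assert coral_loss(B, B) == pytest.approx(0.0, abs=1e-15)

    def test_hand_worked_value(self):
        # C_S = [[.5,-.5],[-.5,.5]], C_T = [[.5,.5],[.5,.5]], ||dC||_F^2 = 1,
        # over 4 d^2 = 16 -> 1/16... recomputed: dC = [[0,-1],[-1,0]], so
        # ||dC||_F^2 = 2 and the loss is 2/16 = 0.125
        b_s = np.array([[1.0, 0.0], [0.0, 1.0]])
        b_t = np.array([[1.0, 1.0], [0.0, 0.0]])
        assert coral_loss(b_s, b_t) == pytest.approx(0.125, abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        b_s, b_t = rng.normal(size=(5, 3)), rng.normal(size=(8, 3))
        assert coral_loss(b_s, b_t) == pytest.approx(coral_loss(b_t, b_s), rel=1e-12)

    def test_nonnegative(self, rng):
        for _ in range(10):
            assert coral_loss(rng.normal(size=(4, 3)), rng.normal(size=(6, 3))) >= 0.0

    def test_quartic_scaling(self, rng):
        b_s, b_t = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        c = 2.0
        assert coral_loss(c * b_s, c * b_t) == pytest.approx(c**4 * coral_loss(b_s, b_t), rel=1e-10)

    def test_mismatched_feature_dim(self, rng):
        with pytest.raises(ValueError, match="share the feature dimension"):
            coral_loss(rng.normal(size=(4, 3)), rng.normal(size=(4, 2)))


class TestCoralGradient:
    @staticmethod
    def fd_gradient(f, x, step=1e-5):
        g = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = x[idx]
            x[idx] = orig + step
            hi = f()
            x[idx] = orig - step
            lo = f()
            x[idx] = orig
            g[idx] = (hi - lo) / (2 * step)
        return g

    def test_zero_at_minimum(self, rng):
        B = rng.normal(size=(5, 3))
        g_s, g_t = coral_gradient(B, B.copy())
        np.testing.assert_allclose(g_s, 0.0, atol=1e-12)
        np.testing.assert_allclose(g_t, 0.0, atol=1e-12)

    def test_matches_finite_differences_on_20_seeded_pairs(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            b_s = rng.normal(size=(4, 3))
            b_t = rng.normal(size=(6, 3))
            g_s, g_t = coral_gradient(b_s, b_t)
            fd_s = self.fd_gradient(lambda: coral_loss(b_s, b_t), b_s)
            fd_t = self.fd_gradient(lambda: coral_loss(b_s, b_t), b_t)
            np.testing.assert_allclose(g_s, fd_s, rtol=1e-4, atol=1e-9)
            np.testing.assert_allclose(g_t, fd_t, rtol=1e-4, atol=1e-9)

    def test_cubic_scaling(self, rng):
        b_s, b_t = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        g_s, _ = coral_gradient(b_s, b_t)
        g_s_scaled, _ = coral_gradient(2.0 * b_s, 2.0 * b_t)
        np.testing.assert_allclose(g_s_scaled, 2.0**3 * g_s, rtol=1e-10)

    def test_swap_identity_from_opposite_signs(self, rng):
        # the target gradient enters with opposite sign through (C_S - C_T),
        # so swapping the arguments swaps the roles exactly: the gradient of
        # batch b as "source" equals its gradient as "target" after the swap
        b = rng.normal(size=(5, 3))
        b_t = rng.normal(size=(5, 3))
        g_s, _ = coral_gradient(b, b_t)
        _, g_t_swapped = coral_gradient(b_t, b)
        np.testing.assert_allclose(g_s, g_t_swapped, rtol=1e-10)

    def test_autograd_node_uses_analytic_gradient(self, rng):
        b_s = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        b_t = Tensor(rng.normal(size=(5, 3)), requires_grad=True)
        loss = coral_loss(b_s, b_t)
        loss.backward()
        g_s, g_t = coral_gradient(b_s.data, b_t.data)
        np.testing.assert_allclose(b_s.grad, g_s, rtol=1e-12)
        np.testing.assert_allclose(b_t.grad, g_t, rtol=1e-12)


class TestReverseFocalAdvLoss:
    def test_closed_form_at_half(self):
        # both domains at the indifference point D = 0.5
        expected = 2.0 * np.exp(0.5) * np.log(2.0)
        assert reverse_focal_adv_loss([0.5], [0.5]) == pytest.approx(expected, rel=1e-12)

    def test_perfect_discrimination_limit(self):
        eps = 1e-9
        assert reverse_focal_adv_loss([1.0 - eps], [eps]) == pytest.approx(0.0, abs=1e-6)

    def test_matches_per_sample_loop_oracle(self, rng):
        d_src = rng.uniform(0.01, 0.99, size=7)
        d_tgt = rng.uniform(0.01, 0.99, size=5)
        src_terms = [np.exp(d) * (-np.log(d)) for d in d_src]
        tgt_terms = [np.exp(1 - d) * (-np.log(1 - d)) for d in d_tgt]
        expected = np.mean(src_terms) + np.mean(tgt_terms)
        assert reverse_focal_adv_loss(d_src, d_tgt) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_out_of_range_scores(self, bad):
        with pytest.raises(ValueError, match="strictly inside"):
            reverse_focal_adv_loss([0.5, bad], [0.5])

    def test_rejects_empty_batch(self):
        with pytest.raises(ValueError):
            reverse_focal_adv_loss(np.array([]), [0.5])

    def test_focal_weights_lie_in_one_to_e(self, rng):
        # weights exp(D), exp(1-D) for D in (0,1) are bounded by (1, e)
        d = rng.uniform(1e-6, 1 - 1e-6, size=100)
        assert np.all(np.exp(d) > 1.0) and np.all(np.exp(d) < np.e)
        assert np.all(np.exp(1 - d) > 1.0) and np.all(np.exp(1 - d) < np.e)

    def test_logit_form_agrees_with_probability_form(self, rng):
        z_s = rng.normal(scale=3.0, size=6)
        z_t = rng.normal(scale=3.0, size=4)
        d_s = 1.0 / (1.0 + np.exp(-z_s))
        d_t = 1.0 / (1.0 + np.exp(-z_t))
        assert reverse_focal_adv_loss_logits(z_s, z_t) == pytest.approx(
            reverse_focal_adv_loss(d_s, d_t), rel=1e-10
        )

    def test_detached_weights_change_gradient_not_value(self, rng):
        vals = rng.uniform(0.2, 0.8, size=5)
        a = Tensor(vals, requires_grad=True)
        b = Tensor(vals.copy(), requires_grad=True)
        tgt = rng.uniform(0.2, 0.8, size=5)
        l_det = reverse_focal_adv_loss(a, tgt, detach_weights=True)
        l_full = reverse_focal_adv_loss(b, tgt, detach_weights=False)
        assert l_det.item() == pytest.approx(l_full.item(), rel=1e-12)
        l_det.backward()
        l_full.backward()
        assert not np.allclose(a.grad, b.grad)


class TestCrossEntropyLosses:
    def test_uniform_logits_give_log_c(self):
        for n_cls in (4, 11):
            Z = np.zeros((5, n_cls))
            y = np.arange(5) % n_cls
            assert transformer_loss(Z, y) == pytest.approx(np.log(n_cls), rel=1e-12)
            assert source_ce_loss(Z, y) == pytest.approx(np.log(n_cls), rel=1e-12)

    def test_confident_correct_limit(self):
        Z = np.zeros((1, 3))
        Z[0, 1] = 200.0
        assert transformer_loss(Z, [1]) == pytest.approx(0.0, abs=1e-8)

    def test_matches_logsumexp_oracle(self, rng):
        Z = rng.normal(scale=4.0, size=(9, 6))
        y = rng.integers(0, 6, size=9)
        expected = np.mean(scipy_lse(Z, axis=1) - Z[np.arange(9), y])
        assert transformer_loss(Z, y) == pytest.approx(expected, abs=1e-8)
        assert source_ce_loss(Z, y) == pytest.approx(expected, abs=1e-8)

    def test_row_shift_invariance(self, rng):
        Z = rng.normal(size=(6, 5))
        y = rng.integers(0, 5, size=6)
        shifted = Z + rng.normal(size=(6, 1)) * 10.0
        assert transformer_loss(shifted, y) == pytest.approx(transformer_loss(Z, y), abs=1e-8)

    def test_label_out_of_range(self, rng):
        with pytest.raises(IndexError):
            source_ce_loss(rng.normal(size=(3, 4)), [0, 1, 4])

    def test_gradient_matches_softmax_identity(self, rng):
        # d CE / d logits = (softmax - onehot) / n
        Z = Tensor(rng.normal(size=(5, 4)), requires_grad=True)
        y = rng.integers(0, 4, size=5)
        source_ce_loss(Z, y).backward()
        p = np.exp(Z.data - scipy_lse(Z.data, axis=1, keepdims=True))
        onehot = np.eye(4)[y]
        np.testing.assert_allclose(Z.grad, (p - onehot) / 5, atol=1e-10)


class TestTotalLoss:
    def test_ablation_identity(self):
        parts = LossBreakdown(l_ce=1.7, l_adv=9.9, l_ca=3.3, l_t=4.4, alpha=0, beta=0, gamma=0)
        assert total_loss(parts) == pytest.approx(1.7)

    def test_published_operating_point(self):
        # alpha=1.0, beta=gamma=0.25, at full ramp
        parts = LossBreakdown(l_ce=1.0, l_adv=2.0, l_ca=4.0, l_t=8.0, alpha=1.0, beta=0.25, gamma=0.25, ramp=1.0)
        assert total_loss(parts) == pytest.approx(1.0 + 2.0 + 1.0 + 2.0)

    def test_ramp_scales_only_adversarial_term(self):
        parts = LossBreakdown(l_ce=1.0, l_adv=2.0, l_ca=4.0, l_t=8.0, alpha=1.0, beta=0.25, gamma=0.25, ramp=0.5)
        assert total_loss(parts) == pytest.approx(1.0 + 1.0 + 1.0 + 2.0)

    def test_linear_in_beta(self):
        lo = total_loss(LossBreakdown(0.0, 0.0, 3.0, 0.0, alpha=0, beta=0.25, gamma=0))
        hi = total_loss(LossBreakdown(0.0, 0.0, 3.0, 0.0, alpha=0, beta=0.5, gamma=0))
        assert hi == pytest.approx(2 * lo)

    def test_single_term_recovery(self):
        for term, weights in [
            ("l_adv", dict(alpha=1, beta=0, gamma=0)),
            ("l_ca", dict(alpha=0, beta=1, gamma=0)),
            ("l_t", dict(alpha=0, beta=0, gamma=1)),
        ]:
            kwargs = dict(l_ce=0.0, l_adv=0.0, l_ca=0.0, l_t=0.0)
            kwargs[term] = 5.0
            assert total_loss(LossBreakdown(**kwargs, **weights)) == pytest.approx(5.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            total_loss(LossBreakdown(1.0, 1.0, 1.0, 1.0, alpha=-0.1))
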