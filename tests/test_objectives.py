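import numpy as np
import pytest

from screcon._autodiff import Tensor
from screcon.objectives import (LossReport, LossWeights, corr_loss,
                                gene_pearson, mask_loss, recon_loss,
                                total_loss)

RNG = np.random.default_rng(1)


def pearson_oracle(x, y):
    """Textbook covariance / (sd * sd), coded independently."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = (sum((a - mx) ** 2 for a in x) / n) ** 0.5
    sy = (sum((b - my) ** 2 for b in y) / n) ** 0.5
    return cov / (sx * sy)


class TestReconLoss:
    def test_identity(self):
        x = RNG.normal(size=(3, 4))
        assert float(recon_loss(x, x)) == 0.0

    def test_unit_offset(self):
        x = RNG.normal(size=(3, 4))
        assert float(recon_loss(x + 1.0, x)) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        pred = np.array([[1.0, 2.0], [3.0, 4.0]])
        target = np.array([[0.0, 2.0], [3.0, 0.0]])
        assert float(recon_loss(pred, target)) == pytest.approx(4.25)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            recon_loss(np.ones((2, 2)), np.ones((2, 3)))


class TestMaskLoss:
    def test_all_ones_equals_recon(self):
        pred, target = RNG.normal(size=(4, 5)), RNG.normal(size=(4, 5))
        m = np.ones((4, 5))
        assert float(mask_loss(pred, target, m)) == pytest.approx(
            float(recon_loss(pred, target)))

    def test_all_zero_mask(self):
        pred, target = RNG.normal(size=(4, 5)), RNG.normal(size=(4, 5))
        assert float(mask_loss(pred, target, np.zeros((4, 5)))) == 0.0

    def test_hand_arithmetic(self):
        target = np.zeros((2, 2))
        pred = np.array([[1.0, 2.0], [3.0, 4.0]])
        m = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert float(mask_loss(pred, target, m)) == pytest.approx(8.5)

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            mask_loss(np.ones((2, 2)), np.ones((2, 2)), np.full((2, 2), 0.5))

    def test_bounded_by_recon_times_density(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pred, target = rng.normal(size=(6, 8)), rng.normal(size=(6, 8))
            m = (rng.random((6, 8)) < 0.5).astype(float)
            if m.sum() == 0:
                continue
            bound = float(recon_loss(pred, target)) * (48 / m.sum())
            assert float(mask_loss(pred, target, m)) <= bound + 1e-12


class TestGenePearson:
    def test_self_correlation(self):
        x = RNG.normal(size=10)
        assert gene_pearson(x, x) == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = RNG.normal(size=10)
        assert gene_pearson(x, -x) == pytest.approx(-1.0)

    def test_matches_textbook_oracle(self):
        pred = [1.0, 2.0, 3.0, 5.0]
        target = [2.0, 1.0, 4.0, 6.0]
        assert gene_pearson(pred, target) == pytest.approx(
            pearson_oracle(pred, target), abs=1e-10)

    def test_zero_variance_returns_zero(self):
        assert gene_pearson(np.ones(5), RNG.normal(size=5)) == 0.0

    def test_too_short(self):
        with pytest.raises(ValueError):
            gene_pearson([1.0], [2.0])


class TestCorrLoss:
    def test_identical_columns_zero(self):
        x = RNG.normal(size=(6, 4))
        assert float(corr_loss(x, x)) == pytest.approx(0.0, abs=1e-9)

    def test_negated_columns_two(self):
        x = RNG.normal(size=(6, 4))
        assert float(corr_loss(-x, x)) == pytest.approx(2.0, abs=1e-9)

    def test_half_negated_one(self):
        x = RNG.normal(size=(6, 4))
        pred = x.copy()
        pred[:, 2:] *= -1
        assert float(corr_loss(pred, x)) == pytest.approx(1.0, abs=1e-9)

    def test_affine_invariance_unlike_recon(self):
        """Rescaling a predicted column leaves the correlation loss alone
        but changes the reconstruction loss: the two terms constrain
        different things."""
        target = RNG.normal(size=(8, 3))
        pred = target + RNG.normal(size=(8, 3)) * 0.1
        scaled = pred * 3.0 + 2.0
        assert float(corr_loss(scaled, target)) == pytest.approx(
            float(corr_loss(pred, target)), abs=1e-9)
        assert float(recon_loss(scaled, target)) != pytest.approx(
            float(recon_loss(pred, target)))


class TestTotalLoss:
    def test_zero_weights_reduce_to_recon(self):
        pred, target = RNG.normal(size=(5, 4)), RNG.normal(size=(5, 4))
        m = (RNG.random((5, 4)) < 0.5).astype(float)
        rep = total_loss(pred, target, m, LossWeights(0.0, 0.0))
        assert rep.total == pytest.approx(rep.recon)

    def test_weighted_sum_identity(self):
        pred, target = RNG.normal(size=(5, 4)), RNG.normal(size=(5, 4))
        m = (RNG.random((5, 4)) < 0.5).astype(float)
        w = LossWeights(alpha1=0.1, alpha2=0.5)
        rep = total_loss(pred, target, m, w)
        assert rep.total == pytest.approx(
            rep.recon + 0.1 * rep.mask + 0.5 * rep.corr, abs=1e-8)

    def test_unit_terms_with_default_weights(self):
        # alpha1=0.1, alpha2=0.5 with recon=mask=corr=1 gives 1.6
        rep = LossReport(recon=1.0, mask=1.0, corr=1.0, total=0.0)
        w = LossWeights(0.1, 0.5)
        assert rep.recon + w.alpha1 * rep.mask + w.alpha2 * rep.corr \
            == pytest.approx(1.6)

    def test_doubling_weights_doubles_excess(self):
        pred, target = RNG.normal(size=(5, 4)), RNG.normal(size=(5, 4))
        m = np.ones((5, 4))
        r1 = total_loss(pred, target, m, LossWeights(0.1, 0.5))
        r2 = total_loss(pred, target, m, LossWeights(0.2, 1.0))
        assert (r2.total - r2.recon) == pytest.approx(2 * (r1.total - r1.recon))

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            LossWeights(alpha1=-0.1)
        with pytest.raises(ValueError):
            LossWeights(alpha2=float("nan"))


class TestDifferentiability:
    @pytest.mark.parametrize("loss_name", ["recon", "mask", "corr", "total"])
    def test_autodiff_matches_central_differences(self, loss_name):
        rng = np.random.default_rng(5)
        target = rng.normal(size=(5, 3))
        m = (rng.random((5, 3)) < 0.6).astype(float)
        x0 = rng.normal(size=(5, 3))

        def f(x):
            t = Tensor(x, requires_grad=isinstance(x, np.ndarray))
            if loss_name == "recon":
                return recon_loss(t, target), t
            if loss_name == "mask":
                return mask_loss(t, target, m), t
            if loss_name == "corr":
                return corr_loss(t, target), t
            return total_loss(t, target, m, LossWeights(0.1, 0.5)).node, t

        out, t = f(x0)
        out.backward()
        grad = t.grad
        eps = 1e-6
        num = np.zeros_like(x0)
        for i in range(5):
            for j in range(3):
                xp = x0.copy(); xp[i, j] += eps
                xm = x0.copy(); xm[i, j] -= eps
                num[i, j] = (float(f(xp)[0]) - float(f(xm)[0])) / (2 * eps)
        np.testing.assert_allclose(grad, num, rtol=1e-4, atol=1e-6)
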