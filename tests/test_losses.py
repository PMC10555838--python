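import math

import numpy as np
import pytest

from axocarto import losses
from axocarto.losses import (AffineTransform, DeformationField, SimilaritySpec,
                             affine_identity_penalty, affine_scaling_penalty,
                             approx_inverse_field, axon_bce, cycle_loss,
                             field_smoothness, gan_loss, inverse_consistency,
                             multiconstraint_objective, outline_bce,
                             sample_displaced, semi_multiview_loss, sim_lcc,
                             sim_mi, sim_mse)

LOG2 = math.log(2.0)


class TestAxonBCE:
    def test_background_voxel_logit_zero(self):
        assert axon_bce(np.zeros((1, 1, 1)), np.zeros((1, 1, 1))) == pytest.approx(LOG2)

    def test_axon_voxel_logit_zero_weighted(self):
        assert axon_bce(np.zeros((1, 1, 1)), np.ones((1, 1, 1))) == pytest.approx(3 * LOG2)

    def test_perfect_extreme_logits_vanish(self):
        logits = np.array([[[50.0, -50.0]]])
        target = np.array([[[1, 0]]])
        assert axon_bce(logits, target) < 1e-10

    def test_matches_brute_force_per_voxel(self):
        """Direct per-voxel evaluation of the weighted sigmoid BCE."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(0, 3, (5, 5, 5))
            y = rng.integers(0, 2, (5, 5, 5))
            sig = 1.0 / (1.0 + np.exp(-x))
            brute = 0.0
            for xi, yi, si in zip(x.ravel(), y.ravel(), sig.ravel()):
                w = 3.0 if yi == 1 else 1.0
                brute += -w * (yi * math.log(si) + (1 - yi) * math.log(1 - si))
            brute /= x.size
            assert axon_bce(x, y) == pytest.approx(brute, abs=1e-10)

    def test_non_binary_target_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            axon_bce(np.zeros((2, 2, 2)), np.full((2, 2, 2), 0.5))


class TestStyleTransferLosses:
    def test_gan_loss_uninformed_discriminator(self):
        half = np.full((4, 4), 0.5)
        assert gan_loss(half, half) == pytest.approx(2 * math.log(0.5))

    def test_gan_loss_score_bounds(self):
        with pytest.raises(ValueError):
            gan_loss(np.array([1.0]), np.array([0.5]))

    def test_cycle_loss_closed_forms(self):
        rng = np.random.default_rng(1)
        x = rng.random((3, 3, 3))
        y = rng.random((3, 3, 3))
        assert cycle_loss(x, x, y, y) == 0.0
        assert cycle_loss(x, x + 0.25, y, y) == pytest.approx(0.25)
        assert cycle_loss(x, x - 1, y, y + 2) >= 0

    def test_outline_bce_sum_form(self):
        pred = np.full((2, 2, 2), 0.5)
        gt = np.zeros((2, 2, 2))
        assert outline_bce(pred, gt) == pytest.approx(8 * LOG2)
        # summed form scales linearly with voxel count
        assert outline_bce(np.full((4, 2, 2), 0.5), np.zeros((4, 2, 2))) \
            == pytest.approx(16 * LOG2)

    def test_outline_bce_clamps_extremes(self):
        with pytest.warns(UserWarning, match="clamped"):
            v = outline_bce(np.array([[[0.0, 1.0]]]), np.array([[[0, 1]]]))
        assert v < 1e-4


class TestSemiMultiview:
    def test_identical_views_zero_consistency(self):
        rng = np.random.default_rng(2)
        pred = rng.uniform(0.1, 0.9, (4, 4))
        gt = rng.integers(0, 2, (4, 4))
        out = semi_multiview_loss(pred, gt, pred, pred, pred, pred)
        assert out["l_qua"] == 0.0
        assert out["l_3d"] == 0.0

    def test_single_voxel_difference_gives_unit_quadratic(self):
        up = np.zeros((3, 3))
        ur = up.copy()
        ur[1, 1] = 1.0
        out = semi_multiview_loss(np.full((2, 2), 0.5), np.zeros((2, 2)), up, ur,
                                  np.zeros((2, 2)), np.zeros((2, 2)))
        assert out["l_qua"] == pytest.approx(1.0)

    def test_total_additivity(self):
        rng = np.random.default_rng(3)
        args = (rng.uniform(0.2, 0.8, (3, 3)), rng.integers(0, 2, (3, 3)),
                rng.random((3, 3)), rng.random((3, 3)),
                rng.random((3, 3)), rng.random((3, 3)))
        out = semi_multiview_loss(*args)
        assert out["total"] == pytest.approx(out["l_cor"] + out["l_hor"] + out["l_3d"])


class TestSimilarities:
    def test_mi_binary_self_similarity(self):
        x = np.zeros((4, 4, 4))
        x[:2] = 1.0
        assert sim_mi(x, x, bins=2) == pytest.approx(-LOG2)

    def test_mi_constant_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert sim_mi(np.random.default_rng(0).random((3, 3, 3)),
                          np.ones((3, 3, 3))) == 0.0

    def test_mi_symmetry(self):
        rng = np.random.default_rng(4)
        x, y = rng.random((6, 6, 6)), rng.random((6, 6, 6))
        assert sim_mi(x, y) == pytest.approx(sim_mi(y, x))

    def test_lcc_affine_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.random((12, 12, 12))
        assert sim_lcc(x, 2 * x + 5, s=5) == pytest.approx(-1.0, abs=1e-9)

    def test_lcc_independent_noise_near_zero(self):
        rng = np.random.default_rng(6)
        x = rng.random((16, 16, 16))
        y = rng.random((16, 16, 16))
        assert abs(sim_lcc(x, y, s=7)) < 0.15

    def test_lcc_bounds(self):
        rng = np.random.default_rng(7)
        x, y = rng.random((10, 10, 10)), rng.random((10, 10, 10))
        assert -1.0 <= sim_lcc(x, y, s=5) <= 1.0
        with pytest.raises(ValueError):
            sim_lcc(x, y, s=11)

    def test_mse_closed_forms(self):
        x = np.random.default_rng(8).random((5, 5, 5))
        assert sim_mse(x, x) == 0.0
        assert sim_mse(x, x + 3.0) == pytest.approx(3.0)
        assert sim_mse(x, x - 3.0) == pytest.approx(3.0)


class TestAffinePenalties:
    def test_identity_penalty_closed_forms(self):
        assert affine_identity_penalty(AffineTransform.identity()) == 0.0
        assert affine_identity_penalty(
            AffineTransform(np.diag([2.0, 1.0, 1.0]), np.zeros(3))) == pytest.approx(1.0)
        assert affine_identity_penalty(
            AffineTransform(np.eye(3), np.array([1.0, 2.0, 2.0]))) == pytest.approx(9.0)

    def test_scaling_penalty_modes(self):
        ident = AffineTransform.identity()
        scaled = AffineTransform(np.diag([2.0, 1.0, 1.0]), np.zeros(3))
        assert affine_scaling_penalty(ident, "det") == 0.0
        assert affine_scaling_penalty(scaled, "det") == pytest.approx(1.0)
        # the literal printed form: |rank(A) - 1| = 2 for any invertible A
        assert affine_scaling_penalty(ident, "literal_rank") == 2.0


class TestFieldOperations:
    def test_smoothness_constant_and_ramp(self):
        assert field_smoothness(DeformationField(np.ones((3, 4, 4, 4)))) == 0.0
        phi = np.zeros((3, 4, 4, 4))
        phi[0] = np.arange(4, dtype=float)[:, None, None]  # Δz component = z
        # one of nine difference arrays is all ones: mean L1 = 1/9
        assert field_smoothness(DeformationField(phi)) == pytest.approx(1.0 / 9.0)

    def test_approx_inverse_zero_and_translation(self):
        zero = DeformationField.zeros((5, 5, 5))
        np.testing.assert_array_equal(approx_inverse_field(zero).phi, zero.phi)
        const = DeformationField(np.full((3, 8, 8, 8), 0.75))
        inv = approx_inverse_field(const)
        np.testing.assert_allclose(inv.phi, -0.75)

    def test_approx_inverse_composition_residual_small(self):
        from scipy import ndimage
        rng = np.random.default_rng(9)
        phi = np.stack([ndimage.gaussian_filter(rng.normal(0, 2.0, (16, 16, 16)), 4)
                        for _ in range(3)])
        scale = 2.0 / max(np.abs(phi).max(), 1e-9)
        f = DeformationField(phi * min(scale, 1.0))
        inv = approx_inverse_field(f)
        # composition Φ ∘ Φ⁻¹ on interior voxels is much smaller than Φ
        comp = np.stack([sample_displaced(f.phi[c], inv) for c in range(3)])
        resid = comp + inv.phi
        core = (slice(4, -4),) * 3
        assert np.abs(resid[(slice(None),) + core]).max() \
            < 0.1 * np.abs(f.phi).max() + 0.02

    def test_inverse_consistency_conventions(self):
        rng = np.random.default_rng(10)
        y = rng.random((8, 8, 8))
        assert inverse_consistency(y, DeformationField.zeros((8, 8, 8))) == 0.0
        const_y = np.full((8, 8, 8), 3.3)
        f = DeformationField(np.full((3, 8, 8, 8), 0.5))
        assert inverse_consistency(const_y, f) == pytest.approx(0.0, abs=1e-12)

    def test_inverse_consistency_shrinks_with_field(self):
        from scipy import ndimage
        rng = np.random.default_rng(11)
        y = ndimage.gaussian_filter(rng.random((12, 12, 12)), 2)
        phi = np.stack([ndimage.gaussian_filter(rng.normal(0, 1.0, (12, 12, 12)), 3)
                        for _ in range(3)])
        vals = [inverse_consistency(y, DeformationField(phi * a))
                for a in (1.0, 0.5, 0.1)]
        assert vals[0] > vals[1] > vals[2] >= 0


class TestMulticonstraintObjective:
    def _channels(self, rng, weights=(0.70, 0.15, 0.15)):
        x = rng.random((10, 10, 10))
        y = rng.random((10, 10, 10))
        m = rng.random((10, 10, 10))
        return [
            (x, x, SimilaritySpec("mi", weight=weights[0])),
            (y, y, SimilaritySpec("lcc", weight=weights[1], lcc_window=5)),
            (m, m, SimilaritySpec("mse", weight=weights[2])),
        ]

    def test_identical_channels_rigid_floor(self):
        ch = self._channels(np.random.default_rng(12))
        val = multiconstraint_objective(ch, "rigid")
        # MI and LCC of an image with itself are at their similarity floor
        assert val <= 0.70 * sim_mi(ch[0][0], ch[0][0]) + 1e-9

    def test_weight_linearity(self):
        rng = np.random.default_rng(13)
        x = rng.random((8, 8, 8))
        y = rng.random((8, 8, 8))
        m = rng.random((8, 8, 8))
        base = [(x, y, SimilaritySpec("mse", weight=0.5)),
                (m, m, SimilaritySpec("mse", weight=0.5))]
        shifted = [(x, y, SimilaritySpec("mse", weight=0.75)),
                   (m, m, SimilaritySpec("mse", weight=0.25))]
        delta = (multiconstraint_objective(shifted, "rigid")
                 - multiconstraint_objective(base, "rigid"))
        assert delta == pytest.approx(0.25 * (sim_mse(x, y) - sim_mse(m, m)))

    def test_bad_weights_rejected(self):
        rng = np.random.default_rng(14)
        x = rng.random((4, 4, 4))
        ch = [(x, x, SimilaritySpec("mse", weight=0.9))]
        with pytest.raises(ValueError, match="sum to 1"):
            multiconstraint_objective(ch, "rigid")

    def test_stage_penalties_added(self):
        rng = np.random.default_rng(15)
        x = rng.random((6, 6, 6))
        ch = [(x, x, SimilaritySpec("mse", weight=1.0))]
        t = AffineTransform(np.diag([1.2, 1.0, 1.0]), np.zeros(3))
        rigid = multiconstraint_objective(ch, "rigid")
        affine = multiconstraint_objective(ch, "affine", t=t)
        expected = affine_identity_penalty(t) + affine_scaling_penalty(t)
        assert affine - rigid == pytest.approx(expected)


class TestAxisPermutationInvariance:
    @pytest.mark.parametrize("perm", [(1, 0, 2), (2, 1, 0), (1, 2, 0)])
    def test_similarities_invariant(self, perm):
        rng = np.random.default_rng(16)
        x = rng.random((8, 8, 8))
        y = rng.random((8, 8, 8))
        for fn in (lambda a, b: sim_mi(a, b, 16),
                   lambda a, b: sim_lcc(a, b, 5),
                   sim_mse):
            assert fn(x, y) == pytest.approx(
                fn(np.transpose(x, perm), np.transpose(y, perm)))

    def test_bce_invariant(self):
        rng = np.random.default_rng(17)
        x = rng.normal(0, 2, (6, 6, 6))
        y = rng.integers(0, 2, (6, 6, 6))
        perm = (2, 0, 1)
        assert axon_bce(x, y) == pytest.approx(
            axon_bce(np.transpose(x, perm), np.transpose(y, perm)))
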