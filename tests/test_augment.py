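import numpy as np
import pytest
from scipy import stats

from axocarto import augment
from axocarto.augment import (AugmentRecipe, augment_pool, cutmix,
                              histogram_match_aug, local_contrast_aug,
                              replay_chain, standard_aug)


class TestCutmix:
    def test_zero_fraction_is_identity(self, axon_pool, artifact_pool):
        out = cutmix(axon_pool[0], artifact_pool[0], frac=0.0, seed=1)
        np.testing.assert_array_equal(out.intensity.data,
                                      axon_pool[0].intensity.data)
        np.testing.assert_array_equal(out.annotation.data,
                                      axon_pool[0].annotation.data)

    def test_every_voxel_from_exactly_one_source(self, axon_pool, artifact_pool):
        out = cutmix(axon_pool[0], artifact_pool[0], frac=0.4, seed=2)
        from_axon = out.intensity.data == axon_pool[0].intensity.data
        from_art = out.intensity.data == artifact_pool[0].intensity.data
        assert (from_axon | from_art).all()

    def test_annotation_cleared_inside_pasted_box(self, axon_pool, artifact_pool):
        out = cutmix(axon_pool[0], artifact_pool[0], frac=0.5, seed=3)
        pasted = out.intensity.data != axon_pool[0].intensity.data
        assert not (out.annotation.data.astype(bool) & pasted).any()
        assert out.provenance == "augmented"

    def test_shape_mismatch_rejected(self, axon_pool, artifact_pool):
        import axocarto.synthgen as sg
        small = sg.make_axon_cube(16, 1, 1.0, 10.0, seed=0)
        with pytest.raises(ValueError, match="congruent"):
            cutmix(small, artifact_pool[0], 0.3, 0)


class TestHistogramMatch:
    def test_axon_voxels_bit_identical(self, axon_pool, artifact_pool):
        out = histogram_match_aug(axon_pool[0], artifact_pool[0].intensity, seed=1)
        m = axon_pool[0].annotation.data.astype(bool)
        np.testing.assert_array_equal(out.intensity.data[m],
                                      axon_pool[0].intensity.data[m])
        np.testing.assert_array_equal(out.annotation.data,
                                      axon_pool[0].annotation.data)

    def test_self_match_close_to_identity(self, axon_pool):
        pair = axon_pool[0]
        out = histogram_match_aug(pair, pair.intensity, seed=2)
        bg = ~pair.annotation.data.astype(bool)
        diff = (out.intensity.data[bg].astype(float)
                - pair.intensity.data[bg].astype(float))
        assert np.median(np.abs(diff)) <= 2.0

    def test_ks_distance_does_not_increase(self, axon_pool, artifact_pool):
        src = axon_pool[1]
        ref = artifact_pool[1].intensity
        bg = ~src.annotation.data.astype(bool)
        out = histogram_match_aug(src, ref, seed=3)
        before = stats.ks_2samp(src.intensity.data[bg].ravel(),
                                ref.data.ravel()).statistic
        after = stats.ks_2samp(out.intensity.data[bg].ravel(),
                               ref.data.ravel()).statistic
        assert after <= before + 1e-9

    def test_degenerate_reference_rejected(self, axon_pool):
        from axocarto.volio import IntensityCube
        flat = IntensityCube(np.full((8, 8, 8), 7, np.uint16))
        with pytest.raises(ValueError, match="distinct"):
            histogram_match_aug(axon_pool[0], flat, seed=0)


class TestLocalContrast:
    def test_identity_factor_leaves_intensities(self, axon_pool):
        out = local_contrast_aug(axon_pool[0], (1.0, 1.0), seed=1)
        np.testing.assert_array_equal(out.intensity.data,
                                      axon_pool[0].intensity.data)

    def test_only_selected_components_change(self, axon_pool):
        src = axon_pool[2]
        out = local_contrast_aug(src, (1.5, 2.0), seed=2)
        outside = ~src.annotation.data.astype(bool)
        np.testing.assert_array_equal(out.intensity.data[outside],
                                      src.intensity.data[outside])
        np.testing.assert_array_equal(out.annotation.data, src.annotation.data)

    def test_empty_annotation_warns(self, artifact_pool):
        with pytest.warns(UserWarning, match="no-op"):
            out = local_contrast_aug(artifact_pool[0], (0.5, 1.5), seed=0)
        np.testing.assert_array_equal(out.intensity.data,
                                      artifact_pool[0].intensity.data)


class TestStandardOps:
    def test_zero_rotation_identity(self, axon_pool):
        out = standard_aug(axon_pool[0], "rotation", {"angle": 0.0}, seed=1)
        np.testing.assert_allclose(out.intensity.data,
                                   axon_pool[0].intensity.data, atol=1e-6)

    def test_four_quarter_turns_compose_to_identity(self, axon_pool):
        pair = axon_pool[0]
        for _ in range(4):
            pair = standard_aug(pair, "rotation", {"angle": 90.0, "axes": (1, 2)},
                                seed=0)
        np.testing.assert_array_equal(pair.intensity.data,
                                      axon_pool[0].intensity.data)
        np.testing.assert_array_equal(pair.annotation.data,
                                      axon_pool[0].annotation.data)

    @pytest.mark.parametrize("op", ["gaussian_noise", "blur", "brightness"])
    def test_photometric_ops_leave_annotation(self, axon_pool, op):
        out = standard_aug(axon_pool[1], op, seed=5)
        np.testing.assert_array_equal(out.annotation.data,
                                      axon_pool[1].annotation.data)

    def test_scaling_keeps_shape_and_binary_annotation(self, axon_pool):
        out = standard_aug(axon_pool[0], "scaling", {"factor": 1.2}, seed=2)
        assert out.intensity.shape == axon_pool[0].intensity.shape
        assert set(np.unique(out.annotation.data)) <= {0, 1}

    def test_unknown_op_rejected(self, axon_pool):
        with pytest.raises(ValueError, match="unknown op"):
            standard_aug(axon_pool[0], "shear", seed=0)


class TestAugmentPool:
    def test_default_recipe_yield(self, axon_pool, artifact_pool):
        out = augment_pool(axon_pool, artifact_pool, AugmentRecipe(master_seed=0))
        # sources + 10 derivatives per axon cube
        assert len(out) == len(axon_pool) * (1 + 10)

    def test_all_zero_recipe_empty(self, axon_pool, artifact_pool):
        rec = AugmentRecipe(cutmix=0, histogram_match=0, local_contrast=0, standard=0)
        assert augment_pool(axon_pool, artifact_pool, rec) == []

    def test_deterministic_given_master_seed(self, axon_pool, artifact_pool):
        rec = AugmentRecipe(master_seed=42)
        a = augment_pool(axon_pool, artifact_pool, rec)
        b = augment_pool(axon_pool, artifact_pool, rec)
        assert len(a) == len(b)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.intensity.data, pb.intensity.data)
            np.testing.assert_array_equal(pa.annotation.data, pb.annotation.data)
            assert pa.chain == pb.chain

    def test_cutmix_without_artifacts_rejected(self, axon_pool):
        with pytest.raises(ValueError, match="artifact pool"):
            augment_pool(axon_pool, [], AugmentRecipe())

    def test_invariants_across_many_seeded_cases(self, axon_pool, artifact_pool):
        """Augmentation never leaves the annotation domain {0,1}, never
        changes cube shape, and photometric ops never touch labels."""
        shape = axon_pool[0].intensity.shape
        for seed in range(25):
            rec = AugmentRecipe(master_seed=seed, cutmix=1, histogram_match=1,
                                local_contrast=1, standard=1)
            for pair in augment_pool(axon_pool[:1], artifact_pool[:1], rec):
                assert pair.intensity.shape == shape
                assert set(np.unique(pair.annotation.data)) <= {0, 1}

    def test_replay_chain_reproduces_outputs(self, axon_pool, artifact_pool):
        rec = AugmentRecipe(master_seed=7, cutmix=1, histogram_match=0,
                            local_contrast=1, standard=1)
        out = augment_pool(axon_pool[:1], artifact_pool, rec)
        for pair in out[1:]:
            sources = {"pair": axon_pool[0]}
            # cutmix partner identity is embedded in the seeded recipe; replay
            # needs the partner actually used, recoverable from the pool replay
            replayed = None
            for art in artifact_pool:
                try:
                    cand = replay_chain({"pair": axon_pool[0], "artifact": art,
                                         "reference": art.intensity}, pair.chain)
                except Exception:
                    continue
                if np.array_equal(cand.intensity.data, pair.intensity.data):
                    replayed = cand
                    break
            assert replayed is not None
            np.testing.assert_array_equal(replayed.annotation.data,
                                          pair.annotation.data)
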