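import math

import numpy as np
import pytest
from scipy import ndimage

from axocarto.losses import AffineTransform, DeformationField
from axocarto.register import (RegistrationBundle, RegistrationConfig,
                               RegistrationModel, apply_transform,
                               build_pyramid, fit_deformable, fit_rigid,
                               _center_decompose, _rescale_affine)
from axocarto.synthgen import deform_phantom, make_phantom_brain
from axocarto.volio import LabelVolume, Volume


def _rotation_z(deg):
    a = math.radians(deg)
    return np.array([[math.cos(a), -math.sin(a), 0],
                     [math.sin(a), math.cos(a), 0],
                     [0, 0, 1.0]])


def _center_affine(A, t, shape):
    c = (np.asarray(shape, float) - 1) / 2
    return AffineTransform(A, c - A @ c + np.asarray(t, float))


@pytest.fixture(scope="module")
def small_phantom():
    return make_phantom_brain((40, 57, 66), 6, seed=7)


@pytest.fixture(scope="module")
def small_bundles(small_phantom):
    ref = RegistrationBundle.from_phantom(small_phantom)
    return small_phantom, ref


class TestPyramid:
    def test_atlas_scale_extent_sequence(self):
        b = RegistrationBundle(Volume(np.zeros((320, 456, 528), np.uint8)))
        pyr = build_pyramid(b, levels=3, factor=2)
        assert [lvl.shape for lvl in pyr] == [(320, 456, 528), (160, 228, 264),
                                              (80, 114, 132)]

    def test_single_level_is_input(self, small_bundles):
        _, ref = small_bundles
        assert build_pyramid(ref, 1, 2) == [ref]

    def test_mask_pyramid_stays_binary(self, small_bundles):
        _, ref = small_bundles
        pyr = build_pyramid(ref, 3, 2)
        for lvl in pyr:
            for m in lvl.region_masks.values():
                assert m.dtype == bool

    def test_zero_extent_rejected(self):
        b = RegistrationBundle(Volume(np.zeros((1, 40, 40), np.float32)))
        with pytest.raises(ValueError, match="extent 0"):
            build_pyramid(b, 2, 2)


class TestRigidFit:
    def test_self_registration_near_identity(self, small_bundles):
        _, ref = small_bundles
        cfg = RegistrationConfig(pyramid_levels=2)
        pyr = build_pyramid(ref, 2, 2)
        t = fit_rigid(pyr[-1], pyr[-1], cfg)
        A, tb = _center_decompose(t, pyr[-1].shape)
        angle = math.degrees(math.acos(np.clip((np.trace(A) - 1) / 2, -1, 1)))
        assert angle <= 0.5
        assert np.abs(tb).max() <= 0.5

    def test_known_rotation_translation_recovered(self, small_phantom):
        T = _center_affine(_rotation_z(5.0), (1.5, -1.0, 0.5),
                           small_phantom.intensity.shape)
        src_ph = deform_phantom(small_phantom, T, noise_sd=3.0, seed=1)
        cfg = RegistrationConfig(pyramid_levels=2)
        sp = build_pyramid(RegistrationBundle.from_phantom(src_ph), 2, 2)
        rp = build_pyramid(RegistrationBundle.from_phantom(small_phantom), 2, 2)
        fitted = fit_rigid(sp[-1], rp[-1], cfg)
        f0 = _rescale_affine(fitted, sp[-1].shape, small_phantom.intensity.shape, 2)
        rel = f0.A @ np.linalg.inv(T.A)
        angle = math.degrees(math.acos(np.clip((np.trace(rel) - 1) / 2, -1, 1)))
        _, tb = _center_decompose(f0, small_phantom.intensity.shape)
        assert angle <= 1.0
        assert np.abs(tb - [1.5, -1.0, 0.5]).max() <= 1.0

    def test_objective_trace_non_increasing(self, small_bundles):
        _, ref = small_bundles
        pyr = build_pyramid(ref, 2, 2)
        t = fit_rigid(pyr[-1], pyr[-1], RegistrationConfig(pyramid_levels=2))
        tr = t.trace
        assert all(a >= b - 1e-8 for a, b in zip(tr, tr[1:]))


class TestApplyTransform:
    def test_identity_stages_leave_volume(self, small_phantom):
        out = apply_transform(small_phantom.intensity)
        np.testing.assert_allclose(out.data, small_phantom.intensity.data,
                                   atol=1e-5)

    def test_points_affine_round_trip(self):
        t = _center_affine(_rotation_z(12.0), (2.0, 1.0, -3.0), (40, 40, 40))
        pts = np.array([[10.0, 20.0, 30.0], [5.0, 5.0, 5.0]])
        fwd = apply_transform(pts, rigid=t)
        back = t.apply_points(fwd)
        np.testing.assert_allclose(back, pts, atol=1e-6)

    def test_label_value_set_never_grows(self, small_phantom):
        t = _center_affine(_rotation_z(8.0), (1.0, 0.0, 0.0),
                           small_phantom.labels.shape)
        out = apply_transform(small_phantom.labels, rigid=t, interp="nearest")
        assert set(np.unique(out.data)) <= set(np.unique(small_phantom.labels.data))

    def test_linear_interp_rejected_for_labels(self, small_phantom):
        with pytest.raises(ValueError, match="nearest"):
            apply_transform(small_phantom.labels, interp="linear")


class TestDeformable:
    def test_self_registration_field_stays_small(self, small_bundles):
        _, ref = small_bundles
        cfg = RegistrationConfig(pyramid_levels=2, deform_iters=(10, 0))
        pyr = build_pyramid(ref, 2, 2)
        field = fit_deformable(pyr, pyr, cfg)
        assert np.percentile(field.magnitude(), 99) <= 0.5

    def test_smoothness_weight_monotonically_damps_field(self, small_phantom):
        shape = small_phantom.intensity.shape
        rng = np.random.default_rng(2)
        phi = np.stack([ndimage.gaussian_filter(rng.normal(0, 5, shape), 8)
                        for _ in range(3)])
        phi *= 2.5 / np.abs(phi).max()
        src_ph = deform_phantom(small_phantom, DeformationField(phi),
                                noise_sd=2.0, seed=3)
        src = RegistrationBundle.from_phantom(src_ph)
        ref = RegistrationBundle.from_phantom(small_phantom)
        sp = build_pyramid(src, 2, 2)
        rp = build_pyramid(ref, 2, 2)
        tvs = []
        for w in (0.02, 0.2, 2.0):
            cfg = RegistrationConfig(pyramid_levels=2, deform_iters=(15, 0),
                                     smooth_weight=w)
            field = fit_deformable(sp, rp, cfg)
            tv = sum(np.abs(np.diff(field.phi[c], axis=a)).sum()
                     for c in range(3) for a in range(3))
            tvs.append(tv)
        assert tvs[0] >= tvs[1] >= tvs[2]

    def test_traces_non_increasing(self, small_bundles):
        _, ref = small_bundles
        cfg = RegistrationConfig(pyramid_levels=2, deform_iters=(8, 0))
        pyr = build_pyramid(ref, 2, 2)
        field = fit_deformable(pyr, pyr, cfg)
        for tr in field.traces:
            assert all(a >= b - 1e-10 for a, b in zip(tr, tr[1:]))


class TestEndToEnd:
    def test_model_fit_improves_alignment(self, small_phantom):
        T = _center_affine(_rotation_z(4.0), (1.0, -1.0, 1.0),
                           small_phantom.intensity.shape)
        src_ph = deform_phantom(small_phantom, T, noise_sd=2.0, seed=4)
        src = RegistrationBundle.from_phantom(src_ph)
        ref = RegistrationBundle.from_phantom(small_phantom)
        cfg = RegistrationConfig(pyramid_levels=2, deform_iters=(10, 0))
        res = RegistrationModel(src, ref, cfg).fit()

        def mean_dice(bundle):
            vals = []
            for rid, m in ref.region_masks.items():
                inter = (m & bundle.region_masks[rid]).sum()
                tot = m.sum() + bundle.region_masks[rid].sum()
                vals.append(2 * inter / tot if tot else 1.0)
            return float(np.mean(vals))

        assert mean_dice(res.warped) > mean_dice(src)
        before = np.linalg.norm(src.landmarks - ref.landmarks, axis=1).mean()
        after = np.linalg.norm(res.warped.landmarks - ref.landmarks, axis=1).mean()
        assert after <= before
        assert "objective" in res.summary()

    def test_self_registration_region_dice(self, small_bundles):
        _, ref = small_bundles
        cfg = RegistrationConfig(pyramid_levels=2, deform_iters=(5, 0))
        res = RegistrationModel(ref, ref, cfg).fit()
        for rid, m in ref.region_masks.items():
            w = res.warped.region_masks[rid]
            d = 2 * (m & w).sum() / (m.sum() + w.sum())
            assert d >= 0.99

    def test_incompatible_grids_rejected(self, small_bundles):
        _, ref = small_bundles
        other = RegistrationBundle(Volume(np.zeros((10, 10, 10), np.float32)))
        with pytest.raises(ValueError, match="grid"):
            RegistrationModel(other, ref)
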