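"""Traction cytometry tests: kernel closed form, inversion, PIV, drift."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellmech import (
    DisplacementField,
    IntensityImage,
    LabelMask,
    SubstrateModel,
    TractionField,
    average_traction_stress,
    boussinesq_forward,
    drift_correct,
    estimate_displacements,
    fttc_inverse,
    net_force_fraction,
)
from cellmech.synthetic import (
    NoiseParams,
    SceneConfig,
    TfmParams,
    TractionPatch,
    balanced_traction_truth,
    make_tfm_scene,
)

E_PA = 10_000.0
NU = 0.5


def _substrate(pixel_size=1.65):
    return SubstrateModel(E_PA, NU, pixel_size)


def _gaussian_dipole(shape=(64, 64), pixel_size=1.65, grid_spacing=1.0):
    patches = (
        TractionPatch((shape[0] * 0.375, shape[1] * 0.375), 8, 100.0, 0.0),
        TractionPatch((shape[0] * 0.625, shape[1] * 0.625), 8, 100.0, 180.0),
    )
    return balanced_traction_truth(shape, patches, pixel_size, grid_spacing)


class TestBoussinesqForward:
    def test_zero_traction_zero_displacement(self):
        t = TractionField(np.zeros((32, 32)), np.zeros((32, 32)), 0.0, 1.0, 1.65)
        d = boussinesq_forward(t, _substrate())
        assert np.abs(d.u).max() == 0 and np.abs(d.v).max() == 0

    def test_stiffness_scaling(self):
        t = _gaussian_dipole()
        d1 = boussinesq_forward(t, SubstrateModel(E_PA, NU, 1.65))
        d2 = boussinesq_forward(t, SubstrateModel(2 * E_PA, NU, 1.65))
        np.testing.assert_allclose(d2.u, d1.u / 2, atol=1e-15)
        np.testing.assert_allclose(d2.v, d1.v / 2, atol=1e-15)

    def test_single_harmonic_matches_closed_form(self):
        n, h = 64, 1.65
        x = np.arange(n) * h
        kx = 2 * np.pi * 3 / (n * h)
        tx = 100.0 * np.sin(kx * x)[None, :] * np.ones((n, 1))
        t = TractionField(tx, np.zeros((n, n)), 0.0, 1.0, h)
        d = boussinesq_forward(t, _substrate(h))
        # for k = (kx, 0) the xx kernel entry is 2(1+nu)(1-nu)/(E kx)
        expected = 100.0 * 2 * (1 + NU) * (1 - NU) / (E_PA * kx) * np.sin(kx * x)
        rel = np.abs(d.u - expected[None, :]).max() / np.abs(expected).max()
        assert rel < 1e-10
        assert np.abs(d.v).max() < 1e-12

    def test_nonfinite_rejected(self):
        tx = np.zeros((16, 16))
        tx[0, 0] = np.inf
        t = TractionField(tx, np.zeros((16, 16)), 0.0, 1.0, 1.65)
        with pytest.raises(ValueError):
            boussinesq_forward(t, _substrate())


class TestFttcInverse:
    def test_zero_displacement_zero_traction(self):
        d = DisplacementField(
            np.zeros((32, 32)), np.zeros((32, 32)), np.ones((32, 32), bool), 16, 0.103
        )
        t = fttc_inverse(d, _substrate())
        assert np.abs(t.magnitude).max() == 0

    def test_negative_lambda_rejected(self):
        d = DisplacementField(
            np.zeros((16, 16)), np.zeros((16, 16)), np.ones((16, 16), bool), 16, 0.103
        )
        with pytest.raises(ValueError):
            fttc_inverse(d, _substrate(), lam=-1.0)

    def test_noiseless_roundtrip_recovers_patches(self):
        truth = _gaussian_dipole()
        d = boussinesq_forward(truth, _substrate())
        rec = fttc_inverse(d, _substrate(), lam=1e-6)
        sel = truth.magnitude > 50.0
        t_mean, r_mean = truth.magnitude[sel].mean(), rec.magnitude[sel].mean()
        assert abs(r_mean - t_mean) / t_mean < 0.05
        bg = truth.magnitude < 1.0
        assert np.sqrt((rec.magnitude[bg] ** 2).mean()) < 2.0

    def test_linearity_in_displacement(self):
        truth = _gaussian_dipole()
        d = boussinesq_forward(truth, _substrate())
        rec1 = fttc_inverse(d, _substrate(), lam=1e-4)
        rec3 = fttc_inverse(replace(d, u=3 * d.u, v=3 * d.v), _substrate(), lam=1e-4)
        np.testing.assert_allclose(rec3.tx, 3 * rec1.tx, rtol=1e-10, atol=1e-9)
        np.testing.assert_allclose(rec3.ty, 3 * rec1.ty, rtol=1e-10, atol=1e-9)

    def test_norm_non_increasing_in_lambda(self):
        truth = _gaussian_dipole()
        d = boussinesq_forward(truth, _substrate())
        rng = np.random.default_rng(0)
        d = replace(d, u=d.u + rng.normal(0, 0.01, d.u.shape), v=d.v + rng.normal(0, 0.01, d.v.shape))
        norms = [
            np.linalg.norm(fttc_inverse(d, _substrate(), lam).magnitude)
            for lam in (0.0, 1e-6, 1e-4, 1e-3, 1e-2)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(norms, norms[1:]))

    def test_net_force_balance_preserved(self):
        truth = _gaussian_dipole()
        assert net_force_fraction(truth) < 1e-12
        d = boussinesq_forward(truth, _substrate())
        rec = fttc_inverse(d, _substrate(), lam=1e-4)
        assert net_force_fraction(rec) < 0.01

    def test_band_limited_roundtrip_l2(self):
        # smooth (band-limited) field: lam -> 0 roundtrip error < 2%
        truth = _gaussian_dipole()
        d = boussinesq_forward(truth, _substrate())
        rec = fttc_inverse(d, _substrate(), lam=0.0)
        err = np.linalg.norm(rec.magnitude - truth.magnitude) / np.linalg.norm(truth.magnitude)
        assert err < 0.02

    def test_invalid_vectors_interpolated(self):
        truth = _gaussian_dipole()
        d = boussinesq_forward(truth, _substrate())
        validity = np.ones_like(d.u, bool)
        validity[10, 10] = False
        broken = replace(d, u=d.u.copy(), validity=validity)
        broken.u[10, 10] = 1e6  # garbage must be ignored
        rec = fttc_inverse(broken, _substrate(), lam=1e-4)
        assert np.abs(rec.magnitude).max() < 500.0


class TestEstimateDisplacements:
    def test_identical_images_zero_field(self, rng):
        img = IntensityImage(np.clip(50 + rng.gamma(2, 200, (256, 256)), 0, None), 0.103)
        f = estimate_displacements(img, img, 32, 0.5)
        assert np.abs(f.u).max() < 1e-10 and np.abs(f.v).max() < 1e-10

    @pytest.mark.parametrize("roll", [(2, 0), (3, -2)])
    def test_integer_roll_exact(self, rng, roll):
        img = np.clip(50 + rng.gamma(2, 200, (256, 256)), 0, None)
        a = IntensityImage(img, 0.103)
        b = a.with_pixels(np.roll(img, roll, axis=(0, 1)))
        f = estimate_displacements(b, a, 32, 0.5)
        assert np.abs(f.v / 0.103 - roll[0]).max() <= 0.02
        assert np.abs(f.u / 0.103 - roll[1]).max() <= 0.02

    def test_bead_scene_rms_error(self):
        patches = (
            TractionPatch((200, 200), 40, 100.0, 0.0, "disk"),
            TractionPatch((320, 320), 40, 100.0, 180.0, "disk"),
        )
        cfg = SceneConfig(
            shape=(512, 512), pixel_size=0.103, seed=3,
            noise=NoiseParams(gaussian_sd=5, poisson=True, background=50),
            tfm=TfmParams(patches=patches, bead_density=0.03),
        )
        loaded, relaxed, truth = make_tfm_scene(cfg)
        f = estimate_displacements(loaded, relaxed, 32, 0.5)
        rows = (f.origin[0] + np.arange(f.u.shape[0]) * f.grid_spacing).astype(int)
        cols = (f.origin[1] + np.arange(f.u.shape[1]) * f.grid_spacing).astype(int)
        tu = truth.displacement_true.u[np.ix_(rows, cols)]
        tv = truth.displacement_true.v[np.ix_(rows, cols)]
        rms = np.sqrt((((f.u - tu) ** 2 + (f.v - tv) ** 2) / f.pixel_size**2).mean())
        assert rms < 0.2

    def test_blank_images_rejected(self):
        img = IntensityImage(np.full((128, 128), 5.0), 0.103)
        with pytest.raises(ValueError):
            estimate_displacements(img, img, 32, 0.5)


class TestDriftCorrect:
    def _uniform_field(self, du, dv):
        return DisplacementField(
            np.full((16, 16), du), np.full((16, 16), dv), np.ones((16, 16), bool), 16, 0.103
        )

    def test_pure_drift_removed(self):
        mask = LabelMask(np.zeros((256, 256), np.int32), 0.103, "cell")
        f = drift_correct(self._uniform_field(0.3, -0.2), mask)
        assert np.abs(f.u).max() < 1e-12 and np.abs(f.v).max() < 1e-12

    def test_zero_field_unchanged(self):
        f = drift_correct(self._uniform_field(0.0, 0.0), None)
        assert np.abs(f.u).max() == 0

    def test_localized_deformation_shifted_by_minus_drift(self):
        u = np.full((16, 16), 0.5)
        u[7:9, 7:9] += 2.0  # deformation near the "cell"
        labels = np.zeros((256, 256), np.int32)
        labels[100:160, 100:160] = 1
        f = DisplacementField(u, np.zeros((16, 16)), np.ones((16, 16), bool), 16, 0.103)
        out = drift_correct(f, LabelMask(labels, 0.103, "cell"), margin_px=20)
        assert abs(out.u[0, 0]) < 1e-12
        assert out.u[7, 7] == pytest.approx(2.0)

    def test_insufficient_far_field_warns(self):
        from cellmech.tfm import TfmWarning

        labels = np.ones((256, 256), np.int32)  # cell covers everything
        f = self._uniform_field(0.4, 0.0)
        with pytest.warns(TfmWarning):
            out = drift_correct(f, LabelMask(labels, 0.103, "cell"))
        np.testing.assert_array_equal(out.u, f.u)

    def test_scene_drift_residual(self):
        cfg = SceneConfig(
            shape=(512, 512), pixel_size=0.103, seed=7,
            noise=NoiseParams(gaussian_sd=5, poisson=True, background=50),
            tfm=TfmParams(drift_px=(2.0, -1.0)),
        )
        loaded, relaxed, _ = make_tfm_scene(cfg)
        f = drift_correct(estimate_displacements(loaded, relaxed, 32, 0.5), None)
        rms = np.sqrt(((f.u**2 + f.v**2) / f.pixel_size**2).mean())
        assert rms < 0.05


class TestAverageTractionStress:
    def _mask(self, shape=(512, 512)):
        labels = np.zeros(shape, np.int32)
        labels[100:300, 100:300] = 1
        return LabelMask(labels, 0.103, "cell")

    def test_zero_traction(self):
        t = TractionField(np.zeros((31, 31)), np.zeros((31, 31)), 1e-4, 16, 0.103, (15.5, 15.5))
        assert average_traction_stress(t, self._mask())[1] == 0.0

    def test_constant_magnitude(self):
        t = TractionField(np.full((31, 31), 30.0), np.full((31, 31), 40.0), 1e-4, 16, 0.103, (15.5, 15.5))
        assert average_traction_stress(t, self._mask())[1] == pytest.approx(50.0)

    def test_half_and_half(self):
        tx = np.zeros((32, 32))
        tx[:, :16] = 100.0  # half the grid at 100 Pa, half at 0
        t = TractionField(tx, np.zeros((32, 32)), 1e-4, 16, 0.103, (8.0, 8.0))
        labels = np.ones((512, 512), np.int32)  # mask covers every node
        val = average_traction_stress(t, LabelMask(labels, 0.103, "cell"))[1]
        assert val == pytest.approx(50.0)

    def test_empty_mask_rejected(self):
        t = TractionField(np.zeros((8, 8)), np.zeros((8, 8)), 1e-4, 16, 0.103)
        with pytest.raises(ValueError):
            average_traction_stress(t, LabelMask(np.zeros((128, 128), np.int32), 0.103, "cell"))


class TestSubstrateModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            SubstrateModel(-1.0)
        with pytest.raises(ValueError):
            SubstrateModel(1e4, poisson_ratio=0.7)
        m = SubstrateModel(1e4)
        assert m.poisson_ratio == 0.5


@settings(deadline=None, max_examples=10, derandomize=True)
@given(alpha=st.floats(-5.0, 5.0))
def test_inverse_linearity_property(alpha):
    truth = _gaussian_dipole()
    d = boussinesq_forward(truth, _substrate())
    base = fttc_inverse(d, _substrate(), lam=1e-4)
    scaled = fttc_inverse(replace(d, u=alpha * d.u, v=alpha * d.v), _substrate(), lam=1e-4)
    np.testing.assert_allclose(scaled.tx, alpha * base.tx, rtol=1e-9, atol=1e-8)
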