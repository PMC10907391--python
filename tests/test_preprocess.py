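"""Preprocessing chain: registration, tophat, TV denoising, deconvolution."""

import numpy as np
import pytest
from scipy import ndimage

import fishcoder as fc
from conftest import render_single_spot


def textured_reference(shape=(160, 160), seed=0):
    """Disc-like nuclei pattern, the kind registration sees in practice."""
    rng = np.random.default_rng(seed)
    img = np.zeros(shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for _ in range(8):
        cy, cx = rng.uniform(25, shape[0] - 25, 2)
        r = rng.uniform(6, 10)
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = 50.0
    return ndimage.gaussian_filter(img, 2.0)


def make_stack(ref_planes):
    ref = np.stack(ref_planes)
    planes = np.stack([np.stack([p, p]) for p in ref_planes])
    return fc.ImageStack(planes, ref)


class TestRegistration:
    def test_identical_references_zero_shift(self):
        base = textured_reference()
        reg = fc.register_rounds(make_stack([base, base, base]))
        assert reg.registered
        for dy, dx in reg.shifts:
            assert abs(dy) < 0.05 and abs(dx) < 0.05

    def test_planted_integer_shift_recovered(self):
        base = textured_reference()
        moved = np.roll(np.roll(base, 3, axis=0), -2, axis=1)
        reg = fc.register_rounds(make_stack([base, moved]))
        dy, dx = reg.shifts[1]
        # correction shift undoes the planted (3, -2) drift
        assert abs(dy + 3) <= 0.1 and abs(dx - 2) <= 0.1

    def test_subpixel_shift_recovered_with_noise(self):
        rng = np.random.default_rng(1)
        base = textured_reference(seed=1)
        moved = ndimage.shift(base, (1.5, 0.0), order=3, mode="reflect")
        # SNR >= 5 relative to the disc amplitude
        noisy0 = base + rng.normal(0, 5, base.shape)
        noisy1 = moved + rng.normal(0, 5, base.shape)
        reg = fc.register_rounds(make_stack([np.clip(noisy0, 0, None), np.clip(noisy1, 0, None)]))
        dy, dx = reg.shifts[1]
        assert abs(dy + 1.5) <= 0.5 and abs(dx) <= 0.5

    def test_blank_reference_errors_with_round(self):
        base = textured_reference()
        with pytest.raises(ValueError, match="round 1"):
            fc.register_rounds(make_stack([base, np.zeros_like(base)]))

    def test_registration_rendering_roundtrip(self, small_codebook):
        """Residual drift after registration stays below 0.5 px."""
        genes = small_codebook.genes()
        for seed in range(10):
            fs = fc.FieldSpec(160, 160, 5, (7, 10), {g: 0.0 for g in genes})
            truth = fc.simulate_field(fs, small_codebook, rng_seed=seed)
            acq = fc.AcquisitionSpec(rng_seed=seed + 100, drift_sigma=0.8)
            stack = fc.render_stack(truth, small_codebook, acq)
            reg = fc.register_rounds(stack)
            for (ey, ex), (ty, tx) in zip(reg.shifts, truth.drifts):
                assert np.hypot(ey + ty, ex + tx) <= 0.5


class TestTophat:
    def test_constant_plane_maps_to_zero(self):
        out = fc.correct_background(np.full((64, 64), 7.3), 7)
        assert np.allclose(out, 0.0)

    def test_spot_preserved_gradient_removed(self):
        yy, xx = np.mgrid[0:96, 0:96]
        gradient = 0.5 * xx + 0.2 * yy
        spot = render_single_spot((96, 96), 48.3, 50.1, sigma=1.3, amp=1000)
        out = fc.correct_background(gradient + spot, 7)
        assert out.max() == pytest.approx(spot.max(), rel=0.10)
        corner = out[:20, :20]
        assert corner.mean() < 0.05 * spot.max()

    def test_nonnegative_on_random_input(self):
        rng = np.random.default_rng(2)
        out = fc.correct_background(rng.random((64, 64)) * 100, 5)
        assert out.min() >= 0

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            fc.correct_background(np.zeros((8, 8)), 0)


class TestRofDenoise:
    def test_constant_unchanged(self):
        plane = np.full((64, 64), 5.0)
        assert np.allclose(fc.denoise_rof(plane, 0.1), plane)

    def test_small_weight_approaches_identity(self):
        rng = np.random.default_rng(3)
        plane = rng.random((64, 64)) * 100
        dists = [
            np.linalg.norm(fc.denoise_rof(plane, w) - plane)
            for w in (0.2, 0.05, 0.01, 0.002)
        ]
        assert dists == sorted(dists, reverse=True)
        assert dists[-1] < 0.05 * np.linalg.norm(plane)

    def test_total_variation_decreases_on_noisy_edge(self):
        rng = np.random.default_rng(4)
        step = np.zeros((64, 64))
        step[:, 32:] = 50.0
        noisy = step + rng.normal(0, 5, step.shape)

        def tv(img):
            return np.abs(np.diff(img, axis=0)).sum() + np.abs(np.diff(img, axis=1)).sum()

        out = fc.denoise_rof(noisy, 0.1)
        assert tv(out) < tv(noisy)

    def test_mean_conserved(self):
        rng = np.random.default_rng(5)
        plane = rng.random((64, 64)) * 40
        out = fc.denoise_rof(plane, 0.1)
        assert out.mean() == pytest.approx(plane.mean(), rel=1e-3)


class TestRichardsonLucy:
    def test_delta_psf_is_identity(self):
        rng = np.random.default_rng(6)
        plane = rng.random((48, 48)) * 100 + 1
        psf = np.zeros((5, 5))
        psf[2, 2] = 1.0
        for n_iter in (1, 10):
            out = fc.deconvolve_rl(plane, psf, n_iter)
            assert np.allclose(out, plane, rtol=1e-6)

    def test_sharpens_matched_blur(self):
        spot = render_single_spot((64, 64), 32.0, 32.0, sigma=1.3, amp=1000)
        psf = fc.gaussian_psf(1.3)
        out = fc.deconvolve_rl(spot, psf, 20)
        assert out.max() > spot.max()

        def fwhm(img):
            prof = img[32]
            half = prof.max() / 2
            return (prof >= half).sum()

        assert fwhm(out) < fwhm(spot)

    def test_flux_conserved_on_interior_spot(self):
        spot = render_single_spot((96, 96), 48.0, 48.0, sigma=2.0, amp=500)
        out = fc.deconvolve_rl(spot, fc.gaussian_psf(2.0), 20)
        assert out.sum() == pytest.approx(spot.sum(), rel=0.01)

    def test_negative_psf_rejected(self):
        psf = np.full((3, 3), 1 / 9)
        psf[0, 0] = -0.1
        with pytest.raises(ValueError):
            fc.deconvolve_rl(np.ones((16, 16)), psf, 5)


@pytest.mark.parametrize(
    "op,rtol",
    [
        (lambda p: fc.correct_background(p, 5), 1e-6),
        (lambda p: fc.denoise_rof(p, 0.05), 1e-6),
        # RL uses FFT convolutions whose boundary handling propagates a
        # small global perturbation; equivariance holds only approximately
        (lambda p: fc.deconvolve_rl(p, fc.gaussian_psf(1.3), 10), 1e-4),
    ],
    ids=["tophat", "rof", "rl"],
)
def test_shift_equivariance_in_interior(op, rtol):
    """Translating the input translates the output (away from borders)."""
    spot = render_single_spot((96, 96), 40.0, 44.0, sigma=1.5, amp=800) + 3.0
    shifted = np.roll(np.roll(spot, 5, axis=0), -7, axis=1)
    a = np.roll(np.roll(op(spot), 5, axis=0), -7, axis=1)
    b = op(shifted)
    interior = (slice(20, 76), slice(20, 76))
    assert np.allclose(a[interior], b[interior], atol=rtol * spot.max())
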