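import numpy as np
import pytest

from natfactor import (
    GrayImage,
    PhantomSpec,
    decorrelation_curve,
    filament_phantom,
    gaussian_blur_renormalize,
    mae,
    ms_ssim,
    mse,
    psnr,
    rms_contrast,
)
from natfactor.errors import (
    DegenerateInputError,
    InvalidImageError,
    InvalidInputError,
    MissingMetadataError,
    UndefinedPSNRError,
)
from natfactor.metrics import _apodization_window
from natfactor.phantoms import structure_image


def _checkerboard(value=2.0, n=8):
    board = np.indices((n, n)).sum(axis=0) % 2
    return board.astype(float) * value


class TestMAE:
    def test_identical_images_zero(self, filament_corpus):
        img = filament_corpus[0]
        assert mae(img, img) == 0.0

    def test_hand_arithmetic(self):
        a = _checkerboard(2.0)
        b = np.ones((8, 8))
        assert mae(a, b) == 1.0

    def test_symmetry(self, rng):
        a = rng.uniform(0, 100, (16, 16))
        b = rng.uniform(0, 100, (16, 16))
        assert mae(a, b) == mae(b, a)

    def test_shape_mismatch(self):
        with pytest.raises(InvalidInputError):
            mae(np.zeros((8, 8)), np.zeros((8, 9)))

    def test_unit_scale_removes_intensity_units(self, rng):
        a = rng.uniform(0, 100, (16, 16))
        b = rng.uniform(0, 100, (16, 16))
        assert mae(10 * a, 10 * b, scale="unit") == pytest.approx(
            mae(a, b, scale="unit")
        )
        assert mae(a, b, scale="8bit") == pytest.approx(255 * mae(a, b, scale="unit"))


class TestPSNR:
    def test_noise_as_strong_as_signal(self):
        a = np.zeros((8, 8))
        b = np.full((8, 8), 255.0)
        assert psnr(a, b, max_intensity=255.0) == pytest.approx(0.0)

    def test_closed_form(self):
        a = np.zeros((8, 8))
        b = np.full((8, 8), np.sqrt(255.0))
        assert psnr(a, b, max_intensity=255.0) == pytest.approx(
            10 * np.log10(255.0), abs=1e-9
        )

    def test_halving_mse_adds_3dB(self, rng):
        noise = rng.standard_normal((16, 16))
        a = np.full((16, 16), 100.0)
        p1 = psnr(a + noise, a, max_intensity=255.0)
        p2 = psnr(a + noise / np.sqrt(2), a, max_intensity=255.0)
        assert p2 - p1 == pytest.approx(10 * np.log10(2), abs=1e-9)

    def test_identical_undefined(self):
        a = np.full((8, 8), 7.0)
        with pytest.raises(UndefinedPSNRError):
            psnr(a, a)

    def test_monotone_in_mse(self, rng):
        ref = np.full((16, 16), 100.0)
        noisy = [ref + s * rng.standard_normal((16, 16)) for s in (1.0, 2.0, 4.0)]
        values = [psnr(n, ref, max_intensity=255.0) for n in noisy]
        assert values[0] > values[1] > values[2]


class TestMSSSIM:
    def test_self_similarity(self, rng):
        a = rng.uniform(0, 255, (192, 192))
        assert ms_ssim(a, a) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_noise_ordering(self):
        rng = np.random.default_rng(2)
        ref = np.clip(structure_image(PhantomSpec(seed=2)), 0, 65535)
        values = []
        for level in (5, 20, 60, 150, 400):
            noisy = np.clip(ref + level * rng.standard_normal(ref.shape), 0, 65535)
            values.append(ms_ssim(noisy, ref))
        assert all(np.diff(values) < 0)

    def test_symmetry(self, rng):
        a = rng.uniform(0, 255, (192, 192))
        b = np.clip(a + rng.standard_normal((192, 192)) * 10, 0, 255)
        assert abs(ms_ssim(a, b) - ms_ssim(b, a)) < 1e-9

    def test_bounded(self, rng):
        for _ in range(5):
            a = rng.uniform(0, 255, (180, 180))
            b = rng.uniform(0, 255, (180, 180))
            assert 0.0 <= ms_ssim(a, b) <= 1.0

    def test_too_small_rejected(self):
        with pytest.raises(InvalidImageError):
            ms_ssim(np.zeros((64, 64)), np.zeros((64, 64)))

    def test_single_scale_matches_skimage(self, rng):
        """The per-scale SSIM agrees with the scikit-image reference
        implementation (small residual from boundary handling)."""
        from skimage.metrics import structural_similarity

        from natfactor.metrics import _ssim_components

        a = rng.uniform(0, 255, (192, 192))
        b = np.clip(a + 20 * rng.standard_normal((192, 192)), 0, 255)
        ours, _ = _ssim_components(a, b, 255.0)
        reference = structural_similarity(
            a, b, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=255.0,
        )
        assert ours == pytest.approx(reference, abs=1e-3)


class TestRMSContrast:
    def test_constant_zero(self):
        assert rms_contrast(np.full((8, 8), 42.0)) == 0.0

    def test_checkerboard(self):
        assert rms_contrast(_checkerboard(2.0)) == 1.0

    def test_offset_invariance(self, rng):
        a = rng.uniform(0, 100, (16, 16))
        assert rms_contrast(a + 50.0) == pytest.approx(rms_contrast(a))

    def test_population_normalization(self):
        img = np.zeros((8, 8))
        img[0, 0] = 8.0
        assert rms_contrast(img) == pytest.approx(np.std(img.ravel()))


class TestDecorrelation:
    def test_resolution_formula(self, filament_corpus):
        curve = decorrelation_curve(filament_corpus[0])
        assert curve.resolution_nm == pytest.approx(2 * 32.3 / curve.rc)
        assert curve.resolution_nm >= 2 * 32.3  # rc <= 1 always

    def test_d_bounded(self, filament_corpus):
        curve = decorrelation_curve(filament_corpus[1])
        assert np.all(curve.d_values >= -1 - 1e-12)
        assert np.all(curve.d_values <= 1 + 1e-12)

    def test_fifty_radii_cover_unit_interval(self, filament_corpus):
        curve = decorrelation_curve(filament_corpus[0])
        assert curve.radii.size == 50
        assert curve.radii[0] == pytest.approx(0.02)
        assert curve.radii[-1] == 1.0

    def test_blur_ordering(self):
        img = filament_phantom(PhantomSpec(seed=4))
        res = [
            decorrelation_curve(
                gaussian_blur_renormalize(img, k) if k > 1 else img
            ).resolution_nm
            for k in (1, 5, 9)
        ]
        assert res[0] <= res[1] <= res[2]

    def test_missing_pixel_size(self):
        img = GrayImage(np.random.default_rng(0).uniform(0, 255, (64, 64)), 16)
        with pytest.raises(MissingMetadataError):
            decorrelation_curve(img)

    def test_all_zero_degenerate(self):
        img = GrayImage(np.zeros((64, 64)), 16, pixel_size_nm=32.3)
        with pytest.raises(DegenerateInputError):
            decorrelation_curve(img)

    def test_masked_sum_equals_pearson_oracle(self):
        """d(r) via cumulative sums equals an explicit (uncentered) Pearson
        correlation between the spectrum and the masked phase-only spectrum."""
        img = filament_phantom(PhantomSpec(seed=1, size_px=64))
        curve = decorrelation_curve(img)
        px = img.pixels - img.pixels.mean()
        w = _apodization_window(64)
        px = px * w[:, None] * w[None, :]
        spec = np.fft.fft2(px)
        mag = np.abs(spec)
        normed = np.where(mag > 0, spec / np.where(mag > 0, mag, 1.0), 0.0)
        fr = np.fft.fftfreq(64) / 0.5
        rgrid = np.hypot(fr[None, :], fr[:, None])
        keep = rgrid > 0
        for i, r in enumerate(curve.radii):
            masked = np.where((rgrid <= r) & keep, normed, 0.0)
            num = float(np.real(np.sum(spec[keep] * np.conj(masked[keep]))))
            den = float(
                np.sqrt(np.sum(mag[keep] ** 2) * np.sum(np.abs(masked[keep]) ** 2))
            )
            d_oracle = num / den if den > 0 else 0.0
            assert curve.d_values[i] == pytest.approx(d_oracle, abs=1e-12)


class TestGaussianBlurRenormalize:
    def test_kernel_one_is_identity(self, filament_corpus):
        img = filament_corpus[0]
        out = gaussian_blur_renormalize(img, 1)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_even_kernel_rejected(self, filament_corpus):
        with pytest.raises(InvalidInputError):
            gaussian_blur_renormalize(filament_corpus[0], 4)

    def test_oversized_kernel_rejected(self):
        img = GrayImage(np.random.default_rng(0).uniform(0, 255, (64, 64)), 16)
        with pytest.raises(InvalidInputError):
            gaussian_blur_renormalize(img, 65)

    def test_contrast_drops_without_renormalization(self):
        for seed in range(10):
            img = filament_phantom(PhantomSpec(seed=seed, size_px=128))
            blurred = gaussian_blur_renormalize(img, 5, renormalize=False)
            assert rms_contrast(blurred) < rms_contrast(img)

    def test_renormalization_restores_range(self, filament_corpus):
        img = filament_corpus[0]
        out = gaussian_blur_renormalize(img, 5, renormalize=True)
        assert out.pixels.min() == pytest.approx(img.pixels.min())
        assert out.pixels.max() == pytest.approx(img.pixels.max())
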