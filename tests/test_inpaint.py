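"""Inpainting contract, random masks, SSIM, validity check."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from patchaudit import (
    RandomMaskParams,
    get_backend,
    inpaint,
    random_elliptical_mask,
    registered_backends,
    ssim,
    validity_check,
)


class TestBackendContract:
    """Shared conformance suite run against every registered backend."""

    @pytest.mark.parametrize("name", sorted(registered_backends()))
    def test_complement_unchanged_and_fill_in_range(self, name, rng):
        backend = get_backend(name)
        for case in range(20):
            img = rng.random((32, 32, 3)).astype(np.float32)
            mask = random_elliptical_mask((32, 32), rng=rng)
            out = backend.fill(img, mask)
            assert out.shape == img.shape
            assert np.array_equal(out[~mask], img[~mask])
            assert out.min() >= 0.0 and out.max() <= 1.0

    @pytest.mark.parametrize("name", sorted(registered_backends()))
    def test_empty_mask_returns_input(self, name, rng):
        img = rng.random((16, 16, 3))
        out = inpaint(img, np.zeros((16, 16), dtype=bool), name)
        assert np.array_equal(out, img)

    def test_unknown_backend_lists_registered(self):
        with pytest.raises(KeyError, match="biharmonic"):
            get_backend("neural")


class TestBiharmonic:
    def test_constant_image_fills_with_same_constant(self):
        img = np.full((24, 24, 3), 0.6)
        mask = np.zeros((24, 24), dtype=bool)
        mask[8:16, 8:16] = True
        out = inpaint(img, mask, "biharmonic")
        assert np.allclose(out, 0.6, atol=1e-6)

    def test_skin_image_inpaints_to_high_ssim(self, plain_images, rng):
        im = plain_images[0]
        mask = random_elliptical_mask(im.pixels.shape[:2], rng=rng)
        out = inpaint(im.pixels, mask, "biharmonic")
        assert ssim(im.pixels, out) >= 0.9


class TestRandomMask:
    def test_same_seed_identical(self):
        a = random_elliptical_mask((64, 64), rng=5)
        b = random_elliptical_mask((64, 64), rng=5)
        assert np.array_equal(a, b)

    def test_centroids_respect_boundary_ring(self, rng):
        params = RandomMaskParams(axes_range=(0.05, 0.1), boundary_ring=0.25)
        for _ in range(200):
            mask = random_elliptical_mask((64, 64), params, rng)
            ys, xs = np.nonzero(mask)
            cy, cx = ys.mean(), xs.mean()
            # centroid within ring + semi-axis reach of an edge
            reach = (0.25 + 0.1) * 64
            assert min(cy, 64 - cy) <= reach or min(cx, 64 - cx) <= reach

    def test_area_matches_rasterised_ellipse_oracle(self):
        params = RandomMaskParams(axes_range=(0.1, 0.1))
        rng = np.random.default_rng(0)
        side = 200
        checked = 0
        expected = np.pi * (0.1 * side) ** 2
        for _ in range(50):
            mask = random_elliptical_mask((side, side), params, rng)
            clipped = (
                mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
            )
            if clipped:
                continue  # area comparison only meaningful for whole ellipses
            assert abs(mask.sum() - expected) / expected < 0.02
            checked += 1
        assert checked >= 10

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RandomMaskParams(axes_range=(0.3, 0.2))
        with pytest.raises(ValueError):
            RandomMaskParams(boundary_ring=0.0)


def ssim_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Independent windowed SSIM: Gaussian-weighted moments per channel."""
    C1, C2 = 0.01**2, 0.03**2
    sig, truncate = 1.5, 3.5
    pad = int(truncate * sig + 0.5)  # 5 -> 11x11 window

    def stats(x):
        return gaussian_filter(x, sig, truncate=truncate, mode="reflect")

    vals = []
    for c in range(a.shape[2]):
        x, y = a[..., c].astype(float), b[..., c].astype(float)
        mx, my = stats(x), stats(y)
        vx = stats(x * x) - mx * mx
        vy = stats(y * y) - my * my
        vxy = stats(x * y) - mx * my
        s = ((2 * mx * my + C1) * (2 * vxy + C2)) / (
            (mx * mx + my * my + C1) * (vx + vy + C2)
        )
        vals.append(s[pad:-pad, pad:-pad].mean())
    return float(np.mean(vals))


class TestSSIM:
    def test_identity_is_one(self, rng):
        img = rng.random((32, 32, 3))
        assert ssim(img, img) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a, b = rng.random((32, 32, 3)), rng.random((32, 32, 3))
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)

    def test_zero_variance_closed_form(self):
        mx, my = 0.3, 0.7
        a = np.full((32, 32, 3), mx)
        b = np.full((32, 32, 3), my)
        c1 = 0.01**2
        expected = (2 * mx * my + c1) / (mx**2 + my**2 + c1)
        assert ssim(a, b) == pytest.approx(expected, abs=1e-9)

    def test_agrees_with_independent_windowed_oracle(self, rng):
        for _ in range(5):
            a = rng.random((40, 40, 3))
            b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1)
            assert ssim(a, b) == pytest.approx(ssim_oracle(a, b), abs=1e-6)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((8, 8, 3)), np.zeros((9, 8, 3)))


class TestValidityCheck:
    def test_constant_classifier_gives_zero_shift(
        self, constant_classifier, plain_images
    ):
        report = validity_check(constant_classifier, plain_images[:5], rng=0)
        assert report.delta_p_mean == 0.0
        assert report.frac_large_dev == 0.0

    def test_identity_backend_gives_zero_shift_and_unit_ssim(
        self, trained_classifier, plain_images
    ):
        report = validity_check(
            trained_classifier, plain_images[:5], backend="identity", rng=0
        )
        assert report.delta_p_mean == 0.0
        assert report.ssim_median == pytest.approx(1.0)

    def test_rejects_patched_images(self, constant_classifier, patched_images):
        with pytest.raises(ValueError, match="patch"):
            validity_check(constant_classifier, patched_images[:2], rng=0)

    def test_rejects_empty_set(self, constant_classifier):
        with pytest.raises(ValueError):
            validity_check(constant_classifier, [], rng=0)

    def test_reference_classifier_centred_near_zero(
        self, trained_classifier, plain_images
    ):
        report = validity_check(trained_classifier, plain_images, rng=1)
        assert abs(report.delta_p_mean) < 0.05
        assert report.ssim_median >= 0.9
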