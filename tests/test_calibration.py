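import math

import numpy as np
import pytest

from spot.calibration import (
    AffineTransform2D,
    FlatFieldMap,
    apply_transform,
    correct_flatfield,
    estimate_flatfield,
    fit_affine,
    localize_emitters,
)
from spot.optics_sim import DipoleEmitter, generate_bead_field, render_spot_stack


def grid_points(spacing, jitter, seed, extent=100.0):
    rng = np.random.default_rng(seed)
    base = np.array(
        [[x, y] for x in np.arange(10.0, extent, spacing)
         for y in np.arange(10.0, extent, spacing)]
    )
    return base + rng.uniform(-jitter, jitter, base.shape)


def gaussian_spot(shape, x0, y0, sigma=1.5, amp=1000.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2))


class TestLocalizeEmitters:
    def test_empty_image(self):
        assert len(localize_emitters(np.zeros((32, 32)), 10.0)) == 0

    def test_two_separated_spots(self):
        img = gaussian_spot((64, 64), 15, 20) + gaussian_spot((64, 64), 35, 40)
        loc = localize_emitters(img, 50.0)
        assert len(loc) == 2

    def test_subpixel_accuracy(self):
        img = gaussian_spot((32, 32), 10.30, 12.75)
        loc = localize_emitters(img, 50.0)
        assert len(loc) == 1
        assert np.abs(loc.coords[0] - [10.30, 12.75]).max() < 0.05


class TestFitAffine:
    def test_identity_on_identical_sets(self):
        pts = np.random.default_rng(0).uniform(10, 90, size=(20, 2))
        t = fit_affine(pts, pts)
        assert np.allclose(t.matrix, [[1, 0, 0], [0, 1, 0]], atol=1e-12)
        assert t.rms == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation(self):
        pts = grid_points(spacing=20.0, jitter=2.0, seed=1)
        t = fit_affine(pts, pts + [5.0, -3.0], match_radius=7.0)
        assert np.allclose(t.matrix[:, :2], np.eye(2), atol=1e-9)
        assert np.allclose(t.matrix[:, 2], [5.0, -3.0], atol=1e-9)

    def test_exact_recovery_of_random_affine(self):
        pts = grid_points(spacing=15.0, jitter=3.0, seed=2)[:50]
        m = np.array([[1.02, 0.03, 1.5], [-0.02, 0.98, -0.8]])
        dst = np.column_stack([pts, np.ones(len(pts))]) @ m.T
        t = fit_affine(pts, dst, match_radius=8.0)
        assert np.allclose(t.matrix, m, atol=1e-6)

    def test_jittered_residual_scales_with_sigma(self):
        # with isotropic Gaussian jitter of sd sigma on both channels the
        # fit residual approaches sigma * sqrt(2) (two jittered coordinates)
        rng = np.random.default_rng(3)
        pts = grid_points(spacing=10.0, jitter=2.0, seed=3, extent=200)
        sigma = 0.1
        t = fit_affine(pts, pts + rng.normal(0, sigma, pts.shape), match_radius=3.0)
        assert t.rms == pytest.approx(sigma * math.sqrt(2), rel=0.15)

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.linspace(0, 10, 8), np.linspace(0, 20, 8)])
        with pytest.raises(ValueError, match="collinear"):
            fit_affine(line, line + 0.0)
        with pytest.raises(ValueError):
            fit_affine(np.array([[0.0, 0.0]]), np.array([[0.0, 0.0]]))


class TestApplyTransform:
    def test_identity_bit_exact(self):
        img = np.random.default_rng(0).uniform(size=(40, 40))
        out = apply_transform(img, AffineTransform2D.identity())
        assert np.array_equal(out, img)

    def test_integer_translation_exact_shift(self):
        img = np.random.default_rng(1).uniform(size=(40, 40))
        t = AffineTransform2D(np.array([[1.0, 0, 3.0], [0, 1.0, 2.0]]))
        out = apply_transform(img, t)
        # out(x, y) = img(x+3, y+2); the right/bottom margin is zero-filled
        assert np.allclose(out[: 40 - 2, : 40 - 3], img[2:, 3:])
        assert np.all(out[:, -3:] == 0) and np.all(out[-2:, :] == 0)

    def test_roundtrip_on_smooth_image(self):
        yy, xx = np.mgrid[0:60, 0:60].astype(float)
        img = np.exp(-((xx - 30) ** 2 + (yy - 30) ** 2) / (2 * 12.0**2))
        ang = 0.07
        t = AffineTransform2D(
            np.array([[math.cos(ang), -math.sin(ang), 1.3],
                      [math.sin(ang), math.cos(ang), -0.7]])
        )
        back = apply_transform(apply_transform(img, t), t.inverse())
        interior = (slice(10, 50), slice(10, 50))
        assert np.abs(back[interior] - img[interior]).max() < 0.01 * np.ptp(img)

    def test_rotation_preserves_interior_intensity(self):
        yy, xx = np.mgrid[0:80, 0:80].astype(float)
        img = np.exp(-((xx - 40) ** 2 + (yy - 40) ** 2) / (2 * 8.0**2))
        ang = 0.3
        c, s = math.cos(ang), math.sin(ang)
        # rotate about the image center
        cx = cy = 40.0
        t = AffineTransform2D(
            np.array([[c, -s, cx - c * cx + s * cy], [s, c, cy - s * cx - c * cy]])
        )
        out = apply_transform(img, t)
        assert out.sum() == pytest.approx(img.sum(), rel=0.01)

    def test_singular_transform_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            AffineTransform2D(np.array([[1.0, 0, 0], [2.0, 0, 0]]))


class TestFlatField:
    def test_constant_image_gives_unit_map(self):
        ff = estimate_flatfield([np.full((64, 64), 7.0)])
        assert np.allclose(ff.data, 1.0)

    def test_replicates_equal_their_mean(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(1, 2, (32, 32)), rng.uniform(1, 2, (32, 32))
        ff_pair = estimate_flatfield([a, b])
        ff_mean = estimate_flatfield([(a + b) / 2])
        assert np.allclose(ff_pair.data, ff_mean.data)

    def test_known_envelope_recovered(self):
        rng = np.random.default_rng(5)
        shape = (128, 128)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        env = np.exp(-((xx - 64) ** 2 + (yy - 64) ** 2) / (2 * float(shape[0]) ** 2))
        beads = np.zeros(shape)
        for gx in np.arange(1.5, shape[1], 3.0):
            for gy in np.arange(1.5, shape[0], 3.0):
                x0 = gx + rng.uniform(-1.2, 1.2)
                y0 = gy + rng.uniform(-1.2, 1.2)
                beads += np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * 1.2**2))
        ff = estimate_flatfield([beads * env])
        target = env / env.mean()
        rms = np.sqrt(((ff.data - target) ** 2).mean())
        assert rms < 0.02

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            estimate_flatfield([np.zeros((16, 16))])

    def test_non_unit_mean_map_rejected(self):
        with pytest.raises(ValueError, match="unit mean"):
            FlatFieldMap(np.full((8, 8), 2.0))

    def test_unit_map_leaves_stack_unchanged(self, default_config):
        stack = render_spot_stack([DipoleEmitter(x=1000, y=1000)], default_config)
        out = correct_flatfield(stack, FlatFieldMap(np.ones(default_config.image_shape)))
        assert np.array_equal(out.frames, stack.frames)

    def test_correction_flattens_simulated_envelope(self, default_config):
        stack = render_spot_stack([DipoleEmitter(x=2000, y=2000)], default_config)
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        env = 1.0 + 0.4 * np.exp(-((xx - 20) ** 2 + (yy - 20) ** 2) / (2 * 64.0**2))
        env_unit = env / env.mean()
        from spot.optics_sim import RawSPOTStack

        shaded = RawSPOTStack(stack.frames * env_unit, default_config)
        corrected = correct_flatfield(shaded, FlatFieldMap(env_unit))
        assert np.allclose(corrected.frames, stack.frames, rtol=1e-10)

    def test_commutes_with_global_scaling(self, default_config):
        from spot.optics_sim import RawSPOTStack

        stack = render_spot_stack([DipoleEmitter(x=2000, y=2000)], default_config)
        ff = FlatFieldMap(np.ones(default_config.image_shape))
        scaled_then = correct_flatfield(
            RawSPOTStack(stack.frames * 3.0, default_config), ff
        ).frames
        then_scaled = correct_flatfield(stack, ff).frames * 3.0
        assert np.allclose(scaled_then, then_scaled)

    def test_shape_mismatch_rejected(self, default_config):
        stack = render_spot_stack([DipoleEmitter(x=1000, y=1000)], default_config)
        with pytest.raises(ValueError, match="shape"):
            correct_flatfield(stack, FlatFieldMap(np.ones((8, 8))))


def test_bead_registration_end_to_end():
    """Localization + mutual matching + affine fit recovers a random affine
    applied to 50 synthetic beads to better than 0.05 px RMS."""
    ang, scale = 0.015, 1.004
    m = np.array(
        [[scale * math.cos(ang), -math.sin(ang), 4.2],
         [math.sin(ang), scale * math.cos(ang), -2.7]]
    )
    img_a, img_b, _, _ = generate_bead_field(50, m, seed=11)
    t = fit_affine(
        localize_emitters(img_a, 50.0), localize_emitters(img_b, 50.0), match_radius=6.0
    )
    grid = np.array([[x, y] for x in (20, 120, 230) for y in (20, 120, 230)], float)
    truth = np.column_stack([grid, np.ones(len(grid))]) @ m.T
    rms = np.sqrt(((t.apply(grid) - truth) ** 2).sum(axis=1).mean())
    assert rms < 0.05
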