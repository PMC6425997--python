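"""Ratiometric chain: background, alignment, smoothing, β, ratio, activation."""

import numpy as np
import pytest

from uptakequant import fret as fr
from uptakequant import synthetic as syn
from uptakequant.types import FretStack


@pytest.fixture(scope="module")
def noiseless_stack():
    truth = syn.make_fret_truth(frames=3, seed=0)
    stack, truth = syn.generate_fret_stack(truth, noise_sd=0.0, seed=0)
    return stack, truth


class TestBackgroundCorrect:
    def test_subtracts_exactly_the_background_level(self, noiseless_stack):
        stack, truth = noiseless_stack
        corrected, masks = fr.background_correct(stack)
        fp = truth.cell_mask
        np.testing.assert_allclose(
            corrected.donor[:, fp], stack.donor[:, fp] - truth.background_level, atol=1e-9
        )
        np.testing.assert_allclose(corrected.donor[:, ~fp], 0.0, atol=1e-9)

    def test_all_background_frame_becomes_zero(self):
        flat = np.full((1, 32, 32), 80.0)
        stack = FretStack(flat, flat.copy(), flat.copy(), pixel_size=0.1)
        corrected, _ = fr.background_correct(stack)
        np.testing.assert_array_equal(corrected.donor, 0.0)

    def test_idempotent_on_zero_background(self, noiseless_stack):
        stack, _ = noiseless_stack
        once, masks = fr.background_correct(stack)
        twice, _ = fr.background_correct(once, masks)
        np.testing.assert_allclose(twice.acceptor, once.acceptor, atol=1e-9)


class TestAlignStack:
    def test_recovers_generated_drift(self):
        truth = syn.make_fret_truth(frames=2, seed=0)
        truth.drift_series[1] = (3, 0)
        stack, _ = syn.generate_fret_stack(truth, noise_sd=0.0, seed=0)
        aligned, shifts = fr.align_stack(stack)
        assert tuple(shifts[1]) == (-3, 0)
        # interior of the aligned frame equals the reference frame
        np.testing.assert_allclose(
            aligned.donor[1][5:-5, 5:-5], aligned.donor[0][5:-5, 5:-5], atol=1e-9
        )

    def test_zero_drift_gives_zero_shifts(self, noiseless_stack):
        stack, _ = noiseless_stack
        _, shifts = fr.align_stack(stack)
        np.testing.assert_array_equal(shifts, 0)

    def test_same_shift_applied_to_every_channel(self):
        truth = syn.make_fret_truth(frames=3, max_drift=4, seed=5)
        stack, truth = syn.generate_fret_stack(truth, noise_sd=0.0, seed=5)
        aligned, shifts = fr.align_stack(stack)
        for t in range(3):
            np.testing.assert_array_equal(shifts[t], -truth.drift_series[t])
        for arr in (aligned.donor, aligned.acceptor, aligned.particle):
            np.testing.assert_allclose(arr[1][8:-8, 8:-8], arr[0][8:-8, 8:-8], atol=1e-9)


class TestSmoothStack:
    def test_constant_image_unchanged(self):
        flat = np.full((1, 16, 16), 7.0)
        stack = FretStack(flat, flat.copy(), flat.copy(), pixel_size=0.1)
        out = fr.smooth_stack(stack)
        np.testing.assert_allclose(out.donor, 7.0)

    def test_hot_pixel_spreads_to_nine_means(self):
        frame = np.zeros((1, 9, 9))
        frame[0, 4, 4] = 9.0
        stack = FretStack(frame, frame.copy(), frame.copy(), pixel_size=0.1)
        out = fr.smooth_stack(stack)
        np.testing.assert_allclose(out.donor[0, 3:6, 3:6], 1.0)
        assert out.donor.sum() == pytest.approx(9.0)

    def test_noise_variance_reduced_about_ninefold(self):
        rng = np.random.default_rng(0)
        frame = rng.normal(0, 1, (1, 120, 120))
        stack = FretStack(frame, frame.copy(), frame.copy(), pixel_size=0.1)
        out = fr.smooth_stack(stack)
        ratio = frame[0, 10:-10, 10:-10].var() / out.donor[0, 10:-10, 10:-10].var()
        assert 7.0 < ratio < 11.0


class TestEstimateBleedthrough:
    def test_exact_on_noiseless_donor_only_cells(self):
        stacks, _ = syn.generate_donor_only(3, bleed_through=0.37, noise_sd=0.0, seed=2)
        assert fr.estimate_bleedthrough(stacks) == pytest.approx(0.37, abs=1e-6)

    def test_zero_leakage_estimates_near_zero(self):
        stacks, _ = syn.generate_donor_only(5, bleed_through=0.0, noise_sd=20.0, seed=2)
        assert abs(fr.estimate_bleedthrough(stacks)) < 0.01

    def test_constant_donor_is_degenerate(self):
        flat = np.full((1, 32, 32), 500.0)
        stack = FretStack(flat, flat.copy(), flat.copy(), pixel_size=0.1)
        with pytest.raises(ValueError, match="degenerate calibration"):
            fr.estimate_bleedthrough([stack])


class TestRatioMap:
    def test_inverts_the_forward_model_exactly(self):
        truth = syn.make_fret_truth(
            frames=2, baseline_activation=1.5, contact_gain=1.0, seed=0
        )
        stack, truth = syn.generate_fret_stack(truth, noise_sd=0.0, seed=0)
        corrected, _ = fr.background_correct(stack)
        rmap = fr.ratio_map(corrected, beta=truth.bleed_through)
        fp = truth.cell_mask
        np.testing.assert_allclose(rmap.ratio[:, fp], 1.5, atol=1e-6)

    def test_uncorrected_leakage_biases_the_ratio_by_beta(self):
        truth = syn.make_fret_truth(
            frames=1, baseline_activation=1.0, contact_gain=1.0, bleed_through=0.62, seed=0
        )
        stack, truth = syn.generate_fret_stack(truth, noise_sd=0.0, seed=0)
        corrected, _ = fr.background_correct(stack)
        rmap = fr.ratio_map(corrected, beta=0.0)
        np.testing.assert_allclose(rmap.ratio[0][truth.cell_mask], 1.62, atol=1e-6)

    def test_nan_exactly_where_acceptor_below_threshold_or_guarded(self):
        rng = np.random.default_rng(1)
        donor = rng.uniform(0, 100, (2, 20, 20))
        donor[0, :3, :3] = 0.0
        acceptor = rng.uniform(0, 100, (2, 20, 20))
        stack = FretStack(donor, acceptor, np.zeros_like(donor), pixel_size=0.1)
        threshold = 40.0
        rmap = fr.ratio_map(stack, beta=0.1, acceptor_threshold=threshold)
        expected_nan = (acceptor < threshold) | (donor <= 0)
        np.testing.assert_array_equal(np.isnan(rmap.ratio), expected_nan)
        assert rmap.n_division_guard == int(((acceptor >= threshold) & (donor <= 0)).sum())

    def test_invalid_beta_rejected(self):
        flat = np.full((1, 8, 8), 10.0)
        stack = FretStack(flat, flat.copy(), flat.copy(), pixel_size=0.1)
        with pytest.raises(ValueError, match="beta"):
            fr.ratio_map(stack, beta=1.2)


@pytest.fixture(scope="module")
def geometry():
    mask = np.zeros((64, 64), dtype=bool)
    yy, xx = np.mgrid[:64, :64]
    mask[(xx - 32) ** 2 + (yy - 32) ** 2 <= 25**2] = True
    masks = np.stack([mask] * 3)
    centroids = np.full((3, 2), ((32 + 25 + 2) * 0.1, 32 * 0.1))
    return masks, centroids


class TestActivationTrace:

    def test_uniform_ratio_map_gives_unit_activation(self, geometry):
        masks, centroids = geometry
        ratio = np.where(masks, 2.7, np.nan)
        rmap = fr.RatioMap(ratio=ratio, beta_used=0.62, acceptor_threshold=0.0)
        trace = fr.activation_trace(rmap, centroids, masks, pixel_size=0.1)
        np.testing.assert_allclose(trace.activation_ratio, 1.0, atol=1e-9)

    def test_missing_particle_frame_reported_missing(self, geometry):
        masks, centroids = geometry
        centroids = centroids.copy()
        centroids[1] = np.nan
        ratio = np.where(masks, 1.0, np.nan)
        rmap = fr.RatioMap(ratio=ratio, beta_used=0.62, acceptor_threshold=0.0)
        trace = fr.activation_trace(rmap, centroids, masks, pixel_size=0.1)
        assert np.isnan(trace.activation_ratio[1])
        assert np.isfinite(trace.activation_ratio[[0, 2]]).all()

    def test_activation_ratio_invariant_to_positive_scaling(self, geometry):
        masks, centroids = geometry
        rng = np.random.default_rng(3)
        ratio = np.where(masks, rng.uniform(0.5, 2.0, masks.shape), np.nan)
        r1 = fr.RatioMap(ratio=ratio, beta_used=0.62, acceptor_threshold=0.0)
        r2 = fr.RatioMap(ratio=5.0 * ratio, beta_used=0.62, acceptor_threshold=0.0)
        t1 = fr.activation_trace(r1, centroids, masks, pixel_size=0.1)
        t2 = fr.activation_trace(r2, centroids, masks, pixel_size=0.1)
        np.testing.assert_allclose(t2.activation_ratio, t1.activation_ratio, rtol=1e-12)

    def test_membrane_sector_twice_cytosol_recovered(self):
        # ground-truth construction: contact sector membrane band at 2x
        truth = syn.make_fret_truth(frames=6, engulf_start=0, engulf_stop=6, seed=0)
        stack, truth = syn.generate_fret_stack(truth, noise_sd=0.0, seed=0)
        rmap, trace, _, _ = fr.run_fret_pipeline(stack, beta=truth.bleed_through)
        assert np.all(np.abs(trace.activation_ratio - 2.0) <= 0.1)


class TestHeatmap:
    def test_lut_endpoints_clipping_and_nan(self, tmp_path):
        ratio = np.array([[[0.0, 1.0], [2.0, np.nan]]])
        rmap = fr.RatioMap(ratio=ratio, beta_used=0.62, acceptor_threshold=0.0)
        frames = fr.render_ratio_heatmap(rmap, lut_range=(0.5, 1.5), cmap="coolwarm",
                                         out_dir=tmp_path)
        rgba = frames[0]
        # below-range clips to the blue end, above-range to the red end
        np.testing.assert_array_equal(rgba[0, 0], rgba[0, 0])
        assert rgba[0, 0][2] > rgba[0, 0][0]  # blue extreme
        assert rgba[1, 0][0] > rgba[1, 0][2]  # red extreme
        np.testing.assert_array_equal(rgba[1, 1][:3], (0, 0, 0))  # NaN -> black
        assert (tmp_path / "ratio_000.png").exists()
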