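"""Registration-based RF comparison: transforms, scoring and fitting."""

import numpy as np
import pytest

from sparsedev import rfcompare as rc
from sparsedev.synthimg import GaborSpec, generate_gabor_rf


class TestStandardize:
    def test_window_sized_rf_passes_through(self, rng):
        rf = rng.standard_normal((16, 16))
        np.testing.assert_array_equal(rc.standardize_rf(rf, 16), rf)

    def test_delta_coordinates_bookkeeping(self):
        rf = np.zeros((32, 32))
        rf[20, 7] = -5.0  # peak by absolute value
        out = rc.standardize_rf(rf, 16)
        assert out.shape == (16, 16)
        r, c = np.unravel_index(np.argmax(np.abs(out)), out.shape)
        # crop starts at (12, 0): border-shifted inward in the column axis
        assert (r + 12, c + 0) == (20, 7)
        assert out[r, c] == -5.0

    def test_tie_breaks_to_first_row_major(self):
        rf = np.zeros((8, 8))
        rf[1, 2] = 1.0
        rf[5, 5] = -1.0  # same magnitude, later in row-major order
        out = rc.standardize_rf(rf, 4)
        assert out[1, 2 - 0] == 1.0 or 1.0 in out  # crop contains the first peak
        assert (out == 1.0).any() and not (out == -1.0).any()

    def test_window_too_large_raises(self):
        with pytest.raises(ValueError):
            rc.standardize_rf(np.zeros((8, 8)), 9)


class TestTransform:
    def test_identity_is_exact(self, smooth_gabor):
        out = rc.transform_rf(smooth_gabor, rc.SimilarityTransform())
        assert np.abs(out - smooth_gabor).max() < 1e-12

    def test_two_half_turns_are_identity_in_interior(self, smooth_gabor):
        half = rc.SimilarityTransform(rotation=np.pi)
        out = rc.transform_rf(rc.transform_rf(smooth_gabor, half), half)
        interior = (slice(4, 12), slice(4, 12))
        assert np.abs(out - smooth_gabor)[interior].max() < 1e-6

    def test_scale_then_inverse_scale_is_identity_in_interior(self, smooth_gabor):
        up = rc.SimilarityTransform(scale=1.2)
        down = rc.SimilarityTransform(scale=1 / 1.2)
        out = rc.transform_rf(rc.transform_rf(smooth_gabor, up), down)
        interior = (slice(4, 12), slice(4, 12))
        assert np.abs(out - smooth_gabor)[interior].max() < 1e-3

    def test_integer_translation_shifts_with_zero_fill(self, smooth_gabor):
        out = rc.transform_rf(smooth_gabor, rc.SimilarityTransform(dx=3, dy=-2))
        np.testing.assert_allclose(out[:, :3], 0.0, atol=1e-12)
        np.testing.assert_allclose(out[:-2 or None][14:], 0.0, atol=1e-12)
        np.testing.assert_allclose(out[0:14, 3:16], smooth_gabor[2:16, 0:13], atol=1e-12)

    def test_invalid_scale_raises(self):
        with pytest.raises(ValueError):
            rc.SimilarityTransform(scale=0.0)


class TestRSquared:
    def test_self_is_one(self, smooth_gabor):
        assert rc.r_squared(smooth_gabor, smooth_gabor) == pytest.approx(1.0)

    def test_affine_invariance_including_sign(self, smooth_gabor):
        assert rc.r_squared(smooth_gabor, -2.0 * smooth_gabor + 7.0) == pytest.approx(1.0)

    def test_constant_candidate_scores_zero(self, smooth_gabor):
        assert rc.r_squared(smooth_gabor, np.full_like(smooth_gabor, 2.0)) == 0.0

    def test_constant_target_rejected(self, smooth_gabor):
        with pytest.raises(ValueError):
            rc.r_squared(np.zeros_like(smooth_gabor), smooth_gabor)

    def test_shape_mismatch_raises(self, smooth_gabor):
        with pytest.raises(ValueError):
            rc.r_squared(smooth_gabor, smooth_gabor[:8, :8])


class TestFitSimilarity:
    def test_self_fit_is_perfect_identity(self, gabor_stack):
        for rf in gabor_stack[:3]:
            fit = rc.fit_similarity(rf, rf)
            assert fit.r_squared == pytest.approx(1.0, abs=1e-6)
            assert abs(fit.transform.dx) < 0.2 and abs(fit.transform.dy) < 0.2
            assert abs(fit.transform.scale - 1.0) < 0.02

    def test_known_transform_recovered(self, smooth_gabor):
        true = rc.SimilarityTransform(dx=1.0, dy=-1.5, rotation=np.deg2rad(30), scale=1.25)
        target = rc.transform_rf(smooth_gabor, true)
        fit = rc.fit_similarity(target, smooth_gabor)
        assert fit.r_squared >= 0.98
        rot_err = np.rad2deg(fit.transform.rotation - true.rotation) % 180.0
        rot_err = min(rot_err, 180.0 - rot_err)
        assert rot_err < 3.0
        assert abs(fit.transform.scale / true.scale - 1.0) < 0.05
        assert abs(fit.transform.dx - true.dx) < 1.0
        assert abs(fit.transform.dy - true.dy) < 1.0

    def test_matches_exhaustive_grid_oracle_on_8x8(self):
        """Optimizer R^2 within 0.02 of a brute-force fine transform grid."""
        spec = GaborSpec(
            center=(3.5, 3.5), orientation=0.4, frequency=0.18, phase=0.7,
            sigma_along=1.8, sigma_across=1.2,
        )
        cand = generate_gabor_rf(spec, 8)
        true = rc.SimilarityTransform(dx=0.6, dy=-0.8, rotation=0.5, scale=1.1)
        target = rc.transform_rf(cand, true)
        cand0 = cand - cand.mean()
        best = 0.0
        for rot in np.deg2rad(np.arange(0, 360, 5.0)):
            for sc in 2.0 ** np.linspace(-0.6, 0.6, 9):
                for dy in np.arange(-2.0, 2.5, 0.5):
                    for dx in np.arange(-2.0, 2.5, 0.5):
                        w = rc.transform_rf(cand0, rc.SimilarityTransform(dx, dy, rot, sc))
                        if np.ptp(w) > 0:
                            best = max(best, rc.r_squared(target, w))
        fit = rc.fit_similarity(target, cand)
        assert fit.r_squared >= best - 0.02

    def test_half_turn_equivalent_transform_matches_for_symmetric_pattern(self):
        """An even-phase Gabor is half-turn symmetric about its envelope
        center, so the equivalent transform reproduces the same image."""
        spec = GaborSpec(
            center=(9.0, 6.5), orientation=0.7, frequency=0.14, phase=0.0,
            sigma_along=2.5, sigma_across=1.8,
        )
        g = generate_gabor_rf(spec, 16)
        t = rc.SimilarityTransform(dx=0.8, dy=-0.6, rotation=0.5, scale=1.1)
        alt = rc.half_turn_equivalent(t, (spec.center[1], spec.center[0]), g.shape)
        a = rc.transform_rf(g, t)
        b = rc.transform_rf(g, alt)
        assert rc.r_squared(a, b) > 0.99

    def test_constant_target_raises(self, smooth_gabor):
        with pytest.raises(ValueError):
            rc.fit_similarity(np.zeros((16, 16)), smooth_gabor)

    def test_constant_candidate_scores_zero(self, smooth_gabor):
        fit = rc.fit_similarity(smooth_gabor, np.full((16, 16), 3.0))
        assert fit.r_squared == 0.0


class TestDictionary:
    def test_target_in_dictionary_selected_with_unit_score(self, gabor_stack):
        target = gabor_stack[2]
        fit = rc.best_fit_from_dictionary(target, gabor_stack)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-6)
        assert fit.candidate_index == 2

    def test_growth_never_decreases_score(self, gabor_stack):
        target = gabor_stack[0]
        small = rc.best_fit_from_dictionary(target, gabor_stack[3:5])
        large = rc.best_fit_from_dictionary(target, gabor_stack[3:])
        assert large.r_squared >= small.r_squared - 1e-12

    def test_empty_dictionary_raises(self, gabor_stack):
        with pytest.raises(ValueError):
            rc.best_fit_from_dictionary(gabor_stack[0], gabor_stack[:0])


class TestExplainableVariance:
    def test_duplicate_set_fully_explainable(self, smooth_gabor):
        rfs = np.stack([smooth_gabor] * 3)
        ev = rc.explainable_variance(rfs)
        np.testing.assert_allclose(ev.values, 1.0, atol=1e-6)
        assert ev.mean == pytest.approx(1.0, abs=1e-6)

    def test_similarity_family_highly_explainable(self, smooth_gabor):
        transforms = [
            rc.SimilarityTransform(),
            rc.SimilarityTransform(dx=1, rotation=0.4, scale=1.1),
            rc.SimilarityTransform(dy=-1, rotation=2.1, scale=0.9),
        ]
        rfs = np.stack([rc.transform_rf(smooth_gabor, t) for t in transforms])
        ev = rc.explainable_variance(rfs)
        assert ev.mean >= 0.95

    def test_noise_less_explainable_than_gabors(self, smooth_gabor, rng):
        transforms = [
            rc.SimilarityTransform(),
            rc.SimilarityTransform(dx=1, rotation=0.6),
            rc.SimilarityTransform(dy=1, scale=1.15),
        ]
        gabors = np.stack([rc.transform_rf(smooth_gabor, t) for t in transforms])
        noise = rng.standard_normal((3, 16, 16))
        assert rc.explainable_variance(noise).mean < rc.explainable_variance(gabors).mean

    def test_needs_two_rfs(self, smooth_gabor):
        with pytest.raises(ValueError):
            rc.explainable_variance(smooth_gabor[None])


class TestFractionExplained:
    def test_model_equals_targets_gives_unit_numerator(self, gabor_stack):
        targets = gabor_stack[:3]
        out = rc.fraction_explained(targets, targets)
        assert out["mean_model"] == pytest.approx(1.0, abs=1e-6)
        assert out["fraction"] >= 1.0 - 1e-9

    def test_fits_frame_columns(self, gabor_stack):
        out = rc.fraction_explained(gabor_stack[:2], gabor_stack[:2])
        frame = rc.fits_to_frame(out["model_fits"])
        assert list(frame.columns) == [
            "target", "best_candidate", "dx", "dy", "rot_deg", "scale", "r2",
        ]
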