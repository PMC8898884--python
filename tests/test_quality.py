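import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.ndimage import gaussian_filter

from cytosemi import (DeblurSettings, clarity_screen, deblur,
                      rescreen_after_deblur, smd2, standardize_size)


def _smd2_bruteforce(f):
    f = f.astype(float)
    total = 0.0
    for y in range(f.shape[0] - 1):
        for x in range(f.shape[1] - 1):
            total += abs(f[y, x] - f[y, x + 1]) * abs(f[y, x] - f[y + 1, x])
    return total


def _checkerboard(n=16, lo=0, hi=255):
    board = np.indices((n, n)).sum(axis=0) % 2
    return np.where(board, hi, lo).astype(float)


class TestSmd2:
    def test_constant_image_scores_zero(self):
        assert smd2(np.full((7, 9), 42.0)) == 0.0

    def test_hand_case_2x2(self):
        assert smd2(np.array([[0, 2], [4, 0]])) == 8.0

    def test_smoothing_reduces_checkerboard_score(self):
        board = _checkerboard()
        filtered = gaussian_filter(board, 1.0)
        assert smd2(board) > smd2(filtered)

    @given(arrays(np.uint8, (6, 7), elements=st.integers(0, 255)))
    @settings(max_examples=50, deadline=None)
    def test_matches_bruteforce_double_loop(self, img):
        assert smd2(img) == pytest.approx(_smd2_bruteforce(img))

    def test_translation_invariance_on_interior(self):
        rng = np.random.default_rng(0)
        patch = rng.integers(0, 255, (6, 6)).astype(float)
        a = np.zeros((20, 20))
        b = np.zeros((20, 20))
        a[4:10, 4:10] = patch
        b[9:15, 8:14] = patch
        assert smd2(a) == pytest.approx(smd2(b))

    def test_blur_monotone_over_sigmas(self):
        board = _checkerboard()
        scores = [smd2(gaussian_filter(board, s))
                  for s in (0.3, 0.7, 1.2, 1.8, 2.5)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            smd2(np.array([[1, 2]]))


class TestClarityScreen:
    def test_identical_images_all_pass(self):
        im = np.arange(16.0).reshape(4, 4)
        report, passing, failing = clarity_screen([im] * 5)
        assert passing == [0, 1, 2, 3, 4] and failing == []

    def test_forced_mean_partition(self):
        flat = np.zeros((4, 4))
        sharp = _checkerboard(4)
        report, passing, failing = clarity_screen([flat, sharp])
        assert failing == [0] and passing == [1]
        assert report.mean_threshold == pytest.approx(report.scores.mean())

    def test_partition_exhaustive_disjoint(self, blurred_half_dataset):
        samples, manifest = blurred_half_dataset
        report, passing, failing = clarity_screen([s.image for s in samples])
        assert sorted(passing + failing) == list(range(len(samples)))
        assert not set(passing) & set(failing)

    def test_unblurred_images_pass_when_half_is_blurred(self,
                                                        blurred_half_dataset):
        samples, manifest = blurred_half_dataset
        report, passing, failing = clarity_screen([s.image for s in samples])
        unblurred = set(np.flatnonzero(~manifest["blurred"].to_numpy()))
        assert unblurred <= set(passing)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            clarity_screen([])


class TestDeblur:
    def test_zero_iterations_is_identity(self):
        img = np.arange(64.0).reshape(8, 8)
        out = deblur(img, DeblurSettings(iterations=0))
        assert np.array_equal(out, img)

    def test_constant_image_is_stationary(self):
        img = np.full((10, 10), 120.0)
        out = deblur(img, DeblurSettings(iterations=20))
        assert np.allclose(out, img, atol=1e-8)

    def test_sharpens_matched_gaussian_blur(self, small_dataset):
        samples, _ = small_dataset
        sharp = samples[0].image.astype(float)
        blurred = gaussian_filter(sharp, 1.2, mode="nearest")
        out = deblur(blurred, DeblurSettings(kernel_sigma=1.2))
        assert smd2(out) >= smd2(blurred)

    def test_output_range_and_shape(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 255, (12, 15))
        out = deblur(img, DeblurSettings(iterations=5))
        assert out.shape == img.shape
        assert out.min() >= 0 and out.max() <= 255

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            DeblurSettings(epsilon=0)
        with pytest.raises(ValueError):
            DeblurSettings(step_size=-1)


class TestRescreen:
    def test_empty_failing_set(self):
        recovered, discarded, outputs = rescreen_after_deblur([], 10.0)
        assert recovered == [] and discarded == [] and outputs == {}

    def test_hopeless_image_discarded(self):
        flat = np.zeros((6, 6))
        recovered, discarded, _ = rescreen_after_deblur([flat], 1e9)
        assert discarded == [0] and recovered == []

    def test_lightly_blurred_image_recovered(self, small_dataset):
        samples, _ = small_dataset
        sharp = samples[0].image.astype(float)
        lightly = gaussian_filter(sharp, 0.8, mode="nearest")
        threshold = smd2(lightly) * 1.05  # just above its blurred score
        recovered, discarded, _ = rescreen_after_deblur(
            [lightly], threshold, DeblurSettings(kernel_sigma=0.8))
        assert recovered == [0]

    def test_partition_is_exhaustive(self, blurred_half_dataset):
        samples, _ = blurred_half_dataset
        report, passing, failing = clarity_screen([s.image for s in samples])
        failing_images = [samples[i].image for i in failing]
        rec, dis, _ = rescreen_after_deblur(failing_images,
                                            report.mean_threshold)
        assert sorted(rec + dis) == list(range(len(failing_images)))


class TestStandardizeSize:
    def test_uniform_square_output(self):
        rng = np.random.default_rng(0)
        images = [rng.uniform(0, 255, (h, w))
                  for h, w in [(8, 8), (10, 6), (5, 12), (9, 9)]]
        outs = standardize_size(images)
        sides = {o.shape for o in outs}
        assert len(sides) == 1
        (side,) = sides
        assert side[0] == side[1]

    def test_mean_edge_arithmetic(self):
        outs = standardize_size([np.zeros((4, 4)), np.zeros((2, 2))])
        assert all(o.shape == (3, 3) for o in outs)

    def test_aspect_preserving_white_padding(self):
        img = np.zeros((4, 2))
        outs = standardize_size([img, np.zeros((4, 4)), np.zeros((4, 6))])
        out = outs[0]
        assert out.shape == (4, 4)
        assert (out[:, 0] == 255).all() or (out[:, -1] == 255).all()

    def test_already_uniform_is_identity(self):
        rng = np.random.default_rng(2)
        images = [rng.uniform(0, 255, (6, 6)) for _ in range(3)]
        outs = standardize_size(images)
        assert all(np.allclose(o, i) for o, i in zip(outs, images))

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            standardize_size([])
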