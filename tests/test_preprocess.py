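"""Preprocessing: Otsu, background subtraction, cropping, sides, augmentation."""

import numpy as np
import pytest

from scintivur.phantom import PhantomConfig, generate_patient, kidney_mask
from oracles import brute_force_otsu

from scintivur.preprocess import (
    CROP_HEIGHT,
    CROP_WIDTH,
    KidneyROI,
    background_correct,
    augment,
    delineate_and_crop,
    normalise,
    otsu_threshold,
    preprocess_scan,
)


class TestOtsu:
    def test_two_point_histogram_separates_populations(self):
        img = np.zeros((20, 20), dtype=np.uint8)
        img[:7] = 255
        t = otsu_threshold(img)
        assert 0 <= t < 255
        assert np.array_equal(img > t, img == 255)

    def test_matches_exhaustive_search_on_bimodal_histograms(self, rng):
        for levels in [(30, 200), (10, 60), (100, 101)]:
            img = np.concatenate(
                [np.full(100, levels[0]), np.full(100, levels[1])]
            ).astype(np.uint8)
            rng.shuffle(img)
            img = img.reshape(10, 20)
            t = otsu_threshold(img)
            bt = brute_force_otsu(img)
            # either threshold must induce the same partition of the histogram
            assert np.array_equal(img > t, img > bt)

    def test_matches_exhaustive_search_on_random_images(self, rng):
        img = rng.integers(0, 256, size=(40, 40)).astype(np.uint8)
        assert np.array_equal(img > otsu_threshold(img), img > brute_force_otsu(img))

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            otsu_threshold(np.full((10, 10), 128, dtype=np.uint8))

    def test_phantom_foreground_covers_kidneys(self, noise_free_config):
        scan = generate_patient(noise_free_config, 0, 0, patient_seed=1)
        t = otsu_threshold(scan.image)
        fg = scan.image > t
        core_l = kidney_mask(noise_free_config, "left", threshold=0.9)
        core_r = kidney_mask(noise_free_config, "right", threshold=0.9)
        assert fg[core_l].mean() > 0.99 and fg[core_r].mean() > 0.99
        assert fg.mean() < 0.5


class TestBackgroundCorrect:
    def test_zero_background_is_identity(self, noise_free_config):
        cfg = PhantomConfig(noise_model="none", background_uptake=0.0,
                            cortical_uptake=185.0)
        scan = generate_patient(cfg, 0, 0, patient_seed=1)
        out = background_correct(scan.image)
        assert np.allclose(out, scan.image.astype(float))

    def test_uniform_background_subtracted(self, noise_free_config):
        scan = generate_patient(noise_free_config, 0, 0, patient_seed=1)
        b = noise_free_config.background_uptake
        out = background_correct(scan.image)
        # direct-subtraction oracle: corrected == clip(image - b)
        expected = np.clip(scan.image.astype(float) - b, 0.0, None)
        assert np.allclose(out, expected, atol=1.0)
        # kidney-to-background contrast does not decrease
        mask = kidney_mask(noise_free_config, "left", 0.9)
        bg = out[scan.image <= b + 1]
        assert out[mask].mean() - bg.mean() >= (
            scan.image[mask].mean() - scan.image[scan.image <= b + 1].mean()
        ) - 1.0

    def test_all_background_image_rejected(self, rng):
        img = rng.integers(20, 30, size=(200, 200)).astype(np.uint8)
        with pytest.raises(ValueError):
            background_correct(img)


class TestDelineateAndCrop:
    def test_output_shape_is_standard(self, default_scan):
        crop = delineate_and_crop(background_correct(default_scan.image))
        assert crop.image.shape == (CROP_HEIGHT, CROP_WIDTH)
        assert crop.midline_column == CROP_WIDTH // 2

    def test_midline_matches_phantom_symmetry_axis(self, noise_free_config):
        scan = generate_patient(noise_free_config, 0, 0, patient_seed=2)
        corrected = background_correct(scan.image)
        crop = delineate_and_crop(corrected)
        top, left, h, w = crop.crop_box
        true_mid = np.mean([c[1] for c in noise_free_config.kidney_centers])
        recovered_mid = left + w / 2.0
        assert abs(recovered_mid - true_mid) <= 2.0

    def test_crop_margins_at_least_ten_pixels(self, noise_free_config):
        scan = generate_patient(noise_free_config, 1, 2, patient_seed=5)
        corrected = background_correct(scan.image)
        crop = delineate_and_crop(corrected)
        level = otsu_threshold(corrected)
        rows = np.any(corrected > level, axis=1).nonzero()[0]
        top, left, h, w = crop.crop_box
        # vertical margins, where the source allowed them
        assert rows[0] - top >= min(10, rows[0])
        assert (top + h) - (rows[-1] + 1) >= min(10, corrected.shape[0] - rows[-1] - 1)

    def test_single_kidney_completed_by_mirroring(self, noise_free_config):
        # black out the right kidney entirely: only the left is detectable
        scan = generate_patient(noise_free_config, 0, 0, patient_seed=2)
        img = scan.image.copy().astype(float)
        img[kidney_mask(noise_free_config, "right", threshold=0.01)] = (
            noise_free_config.background_uptake
        )
        crop = delineate_and_crop(np.clip(img - noise_free_config.background_uptake, 0, None))
        assert crop.left_mask.sum() > 0 and crop.right_mask.sum() > 0
        # mirror symmetry of the two completed masks about the midline
        mirrored = crop.right_mask[:, ::-1]
        overlap = (crop.left_mask & mirrored).sum() / crop.left_mask.sum()
        assert overlap > 0.8

    def test_flat_image_rejected(self):
        with pytest.raises(ValueError):
            delineate_and_crop(np.zeros((256, 512)) + 5.0)


class TestSplitSides:
    def test_halves_partition_the_crop(self, default_scan):
        crop, left, right = preprocess_scan(default_scan.image, "P")
        assert left.image.shape == (224, 224) and right.image.shape == (224, 224)
        assert np.array_equal(
            np.concatenate([left.image, right.image], axis=1), crop.image
        )

    def test_symmetric_phantom_has_equal_means(self, noise_free_config):
        scan = generate_patient(noise_free_config, 0, 0, patient_seed=2)
        _, left, right = preprocess_scan(scan.image, "P")
        assert left.mean_intensity == pytest.approx(right.mean_intensity, rel=0.02)

    def test_severe_left_defect_lowers_left_mean(self, noise_free_config):
        scan = generate_patient(noise_free_config, 4, 0, patient_seed=2)
        _, left, right = preprocess_scan(scan.image, "P")
        assert left.mean_intensity < right.mean_intensity


class TestAugment:
    def _roi(self, rng) -> KidneyROI:
        return KidneyROI(
            side="left",
            image=rng.uniform(0, 255, size=(224, 224)),
            mean_intensity=128.0,
        )

    def test_seed_contract(self, rng):
        roi = self._roi(rng)
        a = augment(roi, seed=9)
        b = augment(roi, seed=9)
        c = augment(roi, seed=10)
        assert np.array_equal(a.image, b.image)
        assert not np.array_equal(a.image, c.image)

    def test_disabled_is_identity(self, rng):
        roi = self._roi(rng)
        assert augment(roi, seed=0, enabled=False) is roi

    def test_output_shape_and_range_over_many_seeds(self, rng):
        roi = self._roi(rng)
        for seed in range(50):
            out = augment(roi, seed=seed)
            assert out.image.shape == (224, 224)
            assert out.image.min() >= 0.0 and out.image.max() <= 255.0


class TestNormalise:
    def test_constant_at_mean_maps_to_zero(self):
        roi = KidneyROI(
            side="left", image=np.full((224, 224), 0.5 * 255), mean_intensity=127.5
        )
        assert np.allclose(normalise(roi, mean=0.5, std=0.25), 0.0)

    def test_identity_parameters_reduce_to_scaling(self, rng):
        img = rng.uniform(0, 255, size=(224, 224))
        out = normalise(img, mean=0.0, std=1.0)
        assert np.allclose(out, img / 255.0, atol=1e-6)
        assert out.min() >= 0.0 and out.max() <= 1.0


def test_full_pipeline_never_errors_on_default_cohort(small_cohort):
    scans, _ = small_cohort
    for scan in scans:
        crop, left, right = preprocess_scan(scan.image, scan.patient_id)
        assert crop.image.shape == (224, 448)
        assert 0.0 <= left.mean_intensity <= 255.0
        assert 0.0 <= right.mean_intensity <= 255.0


def test_pipeline_is_deterministic(default_scan):
    a = preprocess_scan(default_scan.image, "P")
    b = preprocess_scan(default_scan.image, "P")
    assert np.array_equal(a[0].image, b[0].image)
    assert a[1].mean_intensity == b[1].mean_intensity
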