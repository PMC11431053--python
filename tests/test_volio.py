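"""Volume I/O round trips, sliding-window extraction, preprocessing,
augmentation and oversampling."""

import numpy as np
import pytest
import tifffile

from octex.volio import (
    AugmentConfig,
    NormStats,
    OCTVolume,
    augment,
    compute_norm_stats,
    extract_patches,
    oversampling_weights,
    preprocess_patch,
    read_volume,
    window_offsets,
    write_volume,
)


class TestRoundTrip:
    def test_write_read_is_bit_identical(self, tmp_path, rng):
        frames = rng.integers(0, 256, size=(10, 64, 96), dtype=np.uint8)
        vol = OCTVolume(frames=frames, patient_id="P1")
        path = tmp_path / "v.tiff"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.frames, frames)

    def test_single_frame_tiff(self, tmp_path, rng):
        frame = rng.integers(0, 256, size=(32, 48), dtype=np.uint8)
        tifffile.imwrite(tmp_path / "one.tiff", frame)
        vol = read_volume(tmp_path / "one.tiff")
        assert vol.n_frames == 1
        np.testing.assert_array_equal(vol.frames[0], frame)

    def test_rgb_tiff_rejected(self, tmp_path, rng):
        rgb = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
        tifffile.imwrite(tmp_path / "rgb.tiff", rgb, photometric="rgb")
        with pytest.raises(ValueError, match="photometric|grayscale"):
            read_volume(tmp_path / "rgb.tiff")


class TestPatchExtraction:
    def test_window_count_formula(self, rng):
        """width 1000, window 600, stride 200 -> offsets {0, 200, 400}."""
        frames = rng.integers(0, 256, size=(10, 600, 1000), dtype=np.uint8)
        grid = extract_patches(OCTVolume(frames=frames), 600, 200)
        np.testing.assert_array_equal(grid.offsets, [0, 200, 400])
        assert grid.patches.shape == (10, 3, 600, 600)

    def test_patch_content_equals_frame_crop(self, rng):
        frames = rng.integers(0, 256, size=(2, 40, 100), dtype=np.uint8)
        grid = extract_patches(OCTVolume(frames=frames), 40, 30)
        np.testing.assert_array_equal(grid.patches[1, 2], frames[1, :40, 60:100])

    def test_window_equals_width_gives_single_window(self):
        assert list(window_offsets(600, 600, 200)) == [0]

    def test_degenerate_stride_gives_single_window(self):
        assert list(window_offsets(700, 600, 500)) == [0]

    def test_window_larger_than_frame_rejected(self, rng):
        frames = np.zeros((2, 600, 500), dtype=np.uint8)
        with pytest.raises(ValueError):
            extract_patches(OCTVolume(frames=frames), 600, 100)

    def test_short_frames_rejected(self):
        frames = np.zeros((2, 64, 600), dtype=np.uint8)
        with pytest.raises(ValueError, match="height"):
            extract_patches(OCTVolume(frames=frames), 128, 64)


class TestPreprocess:
    def test_resizes_600_to_224(self, rng):
        patch = rng.integers(0, 256, size=(600, 600), dtype=np.uint8)
        out = preprocess_patch(patch, NormStats(mean=120.0, std=30.0))
        assert out.shape == (224, 224)

    def test_constant_patch_with_matching_mean_is_zero(self):
        patch = np.full((64, 64), 100, dtype=np.uint8)
        out = preprocess_patch(patch, NormStats(mean=100.0, std=1.0), target_size=32)
        np.testing.assert_allclose(out, 0.0, atol=1e-6)

    def test_self_stats_give_zero_mean_unit_std(self, rng):
        patch = rng.integers(0, 256, size=(100, 100), dtype=np.uint8)
        stats = compute_norm_stats([patch], target_size=64)
        out = preprocess_patch(patch, stats, target_size=64)
        assert abs(out.mean()) < 1e-3
        assert abs(out.std() - 1.0) < 1e-3

    def test_zero_std_rejected(self):
        with pytest.raises(ValueError):
            NormStats(mean=0.0, std=0.0)


class TestAugment:
    def test_double_horizontal_flip_is_identity(self, rng):
        patch = rng.integers(0, 256, size=(32, 32), dtype=np.uint8)
        cfg = AugmentConfig(p_hflip=1.0, p_vflip=0.0, p_noise=0.0, p_brightness=0.0)
        np.testing.assert_array_equal(augment(augment(patch, cfg, 1), cfg, 2), patch)

    def test_all_probabilities_zero_is_identity(self, rng):
        patch = rng.integers(0, 256, size=(32, 32), dtype=np.uint8)
        np.testing.assert_array_equal(augment(patch, AugmentConfig.off(), 0), patch)

    def test_seeded_determinism(self, rng):
        patch = rng.integers(0, 256, size=(32, 32), dtype=np.uint8)
        cfg = AugmentConfig()
        np.testing.assert_array_equal(augment(patch, cfg, 42), augment(patch, cfg, 42))

    def test_output_stays_in_range(self):
        patch = np.full((16, 16), 250, dtype=np.uint8)
        cfg = AugmentConfig(p_noise=1.0, noise_sigma=50.0, p_brightness=1.0,
                            brightness_range=(1.5, 1.5))
        out = augment(patch, cfg, 0)
        assert out.dtype == np.uint8 and out.max() <= 255

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            AugmentConfig(p_hflip=1.5)


class TestOversampling:
    def test_inverse_class_count_weights(self):
        w = oversampling_weights(["A", "A", "A", "B"])
        np.testing.assert_allclose(w, [1 / 3, 1 / 3, 1 / 3, 1.0])
        # expected sampled frequency of B under these weights is 1/2
        assert w[3] / w.sum() == pytest.approx(0.5)

    def test_balanced_labels_uniform(self):
        w = oversampling_weights([0, 0, 1, 1])
        assert len(set(w)) == 1

    def test_monte_carlo_class_frequencies_uniform(self):
        """10^4 weighted draws from a 90/10 split give ~50/50 classes."""
        labels = np.array([0] * 90 + [1] * 10)
        w = oversampling_weights(labels)
        rng = np.random.default_rng(0)
        draws = rng.choice(labels, size=10_000, replace=True, p=w / w.sum())
        freq = (draws == 1).mean()
        assert abs(freq - 0.5) < 0.02

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            oversampling_weights([])


def test_mixed_frame_sizes_rejected(tmp_path, rng):
    with tifffile.TiffWriter(tmp_path / "mixed.tiff") as tw:
        tw.write(rng.integers(0, 256, size=(16, 16), dtype=np.uint8))
        tw.write(rng.integers(0, 256, size=(16, 24), dtype=np.uint8))
    with pytest.raises(ValueError, match="mixed"):
        read_volume(tmp_path / "mixed.tiff")
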