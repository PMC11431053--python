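"""Synthetic cohort generator: determinism, mask/label consistency,
class-conditional texture separability and patch purity."""

import numpy as np
import pytest
from scipy import stats

from octex import synthetic as syn


class TestGenerateVolume:
    def test_negative_classes_carry_no_lesion(self, small_config):
        sv = syn.generate_volume("MI", small_config, seed=7)
        assert not sv.lesion_mask.any()

    @pytest.mark.parametrize("cls", syn.CLASS_NAMES)
    def test_seeded_determinism_bit_identical(self, cls, small_config):
        a = syn.generate_volume(cls, small_config, seed=7)
        b = syn.generate_volume(cls, small_config, seed=7)
        np.testing.assert_array_equal(a.volume.frames, b.volume.frames)
        np.testing.assert_array_equal(a.lesion_mask, b.lesion_mask)

    def test_mask_nonempty_iff_positive(self, small_config):
        for cls in syn.CLASS_NAMES:
            sv = syn.generate_volume(cls, small_config, seed=11)
            assert sv.lesion_mask.any() == (cls in syn.POSITIVE_CLASSES)

    def test_intensities_within_range_and_shape(self, small_config):
        sv = syn.generate_volume("CY", small_config, seed=5)
        f = sv.volume.frames
        assert f.shape == (small_config.frame_count, small_config.frame_height,
                           small_config.frame_width)
        assert f.dtype == np.uint8

    def test_lesion_spans_minimum_extent(self, small_config):
        cfg = small_config
        for seed in range(10):
            sv = syn.generate_volume("HSIL", cfg, seed=seed)
            frames_hit = sv.lesion_mask.any(axis=1).sum()
            assert frames_hit >= cfg.lesion_min_extent[0]
            flags = syn.lesion_window_flags(sv, cfg.window_size, cfg.stride)
            # at least (3 frames x 3 windows) of fully covered windows
            assert (flags.sum(axis=1) >= cfg.lesion_min_extent[1]).sum() >= \
                cfg.lesion_min_extent[0]

    def test_unknown_class_rejected(self, small_config):
        with pytest.raises(ValueError, match="unknown class"):
            syn.generate_volume("XX", small_config, seed=0)

    def test_oversized_lesion_extent_rejected(self):
        with pytest.raises(ValueError):
            syn.SyntheticConfig(frame_count=10, lesion_min_extent=(11, 3))
        with pytest.raises(ValueError):
            syn.SyntheticConfig(frame_width=200, window_size=128, stride=64,
                                lesion_min_extent=(3, 5))


class TestLayeringStatistic:
    def test_cc_and_mi_separated_by_margin_at_seed_3(self):
        cfg = syn.SyntheticConfig()
        s_mi = syn.volume_layering_statistic(syn.generate_volume("MI", cfg, seed=3))
        s_cc = syn.volume_layering_statistic(syn.generate_volume("CC", cfg, seed=3))
        assert abs(s_mi - s_cc) > cfg.separation_margin

    def test_class_separability_over_100_volumes(self):
        """The fixed statistic splits negative from positive classes on at
        least 95% of 100 seeded volumes at the frozen threshold."""
        cfg = syn.SyntheticConfig()
        hits = 0
        n = 0
        for seed in range(20):
            for cls in syn.CLASS_NAMES:
                sv = syn.generate_volume(cls, cfg, seed=seed)
                stat = syn.volume_layering_statistic(sv)
                predicted_negative = stat > syn.LAYERING_THRESHOLD
                hits += predicted_negative == (cls in syn.NEGATIVE_CLASSES)
                n += 1
        assert n == 100
        assert hits / n >= 0.95


class TestGenerateCohort:
    def test_all_mi_cohort(self, small_config):
        cohort = syn.generate_cohort(10, {"MI": 1.0}, 2, small_config, seed=1)
        assert len(cohort) == 10
        assert sum(len(p.volumes) for p in cohort) == 20
        assert all(p.binary_label == 0 for p in cohort)

    def test_patient_level_binary_mapping(self, small_config):
        cohort = syn.generate_cohort(12, {"EP": 0.5, "CC": 0.5}, 1, small_config, seed=3)
        for p in cohort:
            assert p.binary_label == (1 if p.class_label == "CC" else 0)
            for sv in p.volumes:
                assert sv.volume.patient_id == p.patient_id

    def test_determinism(self, small_config):
        mix = {c: 0.2 for c in syn.CLASS_NAMES}
        a = syn.generate_cohort(8, mix, 1, small_config, seed=2)
        b = syn.generate_cohort(8, mix, 1, small_config, seed=2)
        for pa, pb in zip(a, b):
            assert pa.class_label == pb.class_label
            np.testing.assert_array_equal(pa.volumes[0].volume.frames,
                                          pb.volumes[0].volume.frames)

    def test_uniform_mix_class_counts(self, small_config):
        """Chi-square goodness of fit of patient class draws, pooled over
        many seeds, against the uniform mix."""
        mix = {c: 0.2 for c in syn.CLASS_NAMES}
        tiny = syn.SyntheticConfig(frame_count=3, frame_height=32, frame_width=96,
                                   window_size=32, stride=32)
        counts = {c: 0 for c in syn.CLASS_NAMES}
        for seed in range(50):
            for p in syn.generate_cohort(10, mix, 1, tiny, seed=seed):
                counts[p.class_label] += 1
        observed = np.array([counts[c] for c in syn.CLASS_NAMES])
        assert observed.sum() == 500
        _, p_value = stats.chisquare(observed)
        assert p_value > 0.01

    def test_bad_proportions_rejected(self, small_config):
        with pytest.raises(ValueError, match="sum"):
            syn.generate_cohort(5, {"MI": 0.5, "CY": 0.4}, 1, small_config, seed=0)


class TestPatchDataset:
    def test_negative_volume_yields_all_windows(self, small_config):
        cohort = syn.generate_cohort(1, {"MI": 1.0}, 1, small_config, seed=4)
        spec = syn.PatchSpec(window_size=small_config.window_size,
                             stride=small_config.stride)
        ds = syn.generate_patch_dataset(cohort, spec)
        n_windows = (small_config.frame_width - spec.window_size) // spec.stride + 1
        assert len(ds) == small_config.frame_count * n_windows
        assert set(ds.labels) == {syn.CLASS_NAMES.index("MI")}

    def test_purity_excludes_off_lesion_windows(self, small_config):
        spec = syn.PatchSpec(window_size=small_config.window_size,
                             stride=small_config.stride)
        n_windows = (small_config.frame_width - spec.window_size) // spec.stride + 1
        total = small_config.frame_count * n_windows
        excluded_somewhere = False
        for seed in range(6):
            cohort = syn.generate_cohort(1, {"HSIL": 1.0}, 1, small_config, seed=seed)
            sv = cohort[0].volumes[0]
            ds = syn.generate_patch_dataset(cohort, spec)
            flags = syn.lesion_window_flags(sv, spec.window_size, spec.stride,
                                            spec.min_lesion_coverage)
            kept = set(zip(ds.provenance["frame"], ds.provenance["window"]))
            assert kept == {tuple(map(int, fw)) for fw in np.argwhere(flags)}
            assert 0 < len(ds) <= total
            excluded_somewhere |= len(ds) < total
        assert excluded_somewhere  # off-lesion windows of positive volumes dropped

    def test_empty_cohort_gives_empty_dataset(self):
        ds = syn.generate_patch_dataset([])
        assert len(ds) == 0

    def test_provenance_round_trip(self, small_config):
        cohort = syn.generate_cohort(2, {"CY": 1.0}, 2, small_config, seed=9)
        ds = syn.generate_patch_dataset(
            cohort, syn.PatchSpec(small_config.window_size, small_config.stride))
        row = ds.provenance.iloc[17]
        sv = next(p for p in cohort if p.patient_id == row["patient_id"]).volumes[
            row["volume_index"]]
        off = row["window"] * small_config.stride
        expected = sv.volume.frames[row["frame"], : small_config.window_size,
                                    off : off + small_config.window_size]
        np.testing.assert_array_equal(ds.patches[17], expected)


def test_write_cohort_manifest(tmp_path, small_config):
    cohort = syn.generate_cohort(3, {"MI": 0.5, "HSIL": 0.5}, 1, small_config, seed=6)
    manifest = syn.write_cohort(cohort, tmp_path / "cohort")
    import pandas as pd

    from octex.volio import read_volume

    df = pd.read_csv(manifest)
    assert list(df.columns) == ["patient_id", "volume_path", "class", "binary_label"]
    assert len(df) == 3
    row = df.iloc[0]
    back = read_volume(manifest.parent / row["volume_path"])
    np.testing.assert_array_equal(back.frames, cohort[0].volumes[0].volume.frames)
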