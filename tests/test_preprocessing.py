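from collections import Counter

import numpy as np
import pytest

from histotune.preprocessing import (
    AugmentationConfig,
    DegenerateImageWarning,
    ImageRecord,
    augment_image,
    balance_by_augmentation,
    load_image_folder,
    partition_dataset,
    resize_image,
    save_image_folder,
    scale_image,
)


def record(pixels, label="a"):
    return ImageRecord(pixels=np.asarray(pixels), label=label)


class TestResize:
    def test_shape_contract(self, rng):
        img = record(rng.integers(0, 256, (256, 256, 3), dtype=np.uint8))
        assert resize_image(img).pixels.shape == (128, 128, 3)

    def test_constant_preserved(self):
        img = record(np.full((200, 180, 3), 77, dtype=np.uint8))
        out = resize_image(img)
        assert np.all(out.pixels == 77)

    def test_identity_resize(self, rng):
        px = rng.integers(0, 256, (128, 128, 3), dtype=np.uint8)
        out = resize_image(record(px))
        np.testing.assert_array_equal(out.pixels, px)

    def test_rejects_non_rgb(self):
        with pytest.raises(ValueError):
            resize_image(record(np.zeros((64, 64), dtype=np.uint8)))


class TestScale:
    def test_minmax_spans_unit_interval(self):
        px = np.arange(256, dtype=float).reshape(16, 16).repeat(3).reshape(16, 16, 3)
        out = scale_image(px, "minmax")
        assert out.min() == 0.0 and out.max() == 1.0

    def test_standard_moments(self, rng):
        out = scale_image(rng.integers(0, 256, (32, 32, 3)).astype(float), "standard")
        assert abs(out.mean()) < 1e-6
        assert abs(out.std() - 1.0) < 1e-6

    def test_normalize_constant_image(self):
        out = scale_image(np.full((8, 8, 3), 200.0), "normalize")
        assert np.all(out == 1.0)

    @pytest.mark.parametrize("method", ["standard", "minmax"])
    def test_degenerate_constant_warns_and_zeroes(self, method):
        with pytest.warns(DegenerateImageWarning):
            out = scale_image(np.full((4, 4, 3), 9.0), method)
        assert np.all(out == 0.0)

    def test_fuzzed_ranges(self, rng):
        for _ in range(20):
            px = rng.integers(0, 256, (8, 8, 3)).astype(float)
            assert scale_image(px, "minmax").max() <= 1.0
            assert scale_image(px, "minmax").min() >= 0.0
            out = scale_image(px, "maxabs")
            assert out.min() >= -1.0 and out.max() <= 1.0

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            scale_image(np.ones((2, 2, 3)), "robust")


class TestAugment:
    def test_identity_config(self, rng):
        px = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        out = augment_image(record(px), AugmentationConfig(), rng)
        np.testing.assert_array_equal(out.pixels, px)

    def test_horizontal_flip_is_involution(self, rng):
        px = rng.integers(0, 256, (16, 16, 3), dtype=np.uint8)
        cfg = AugmentationConfig(horizontal_flip=True)

        class AlwaysFlip:
            uniform = staticmethod(lambda a, b: (a + b) / 2.0)
            random = staticmethod(lambda: 0.0)  # < 0.5 -> flip applied

        once = augment_image(record(px), cfg, AlwaysFlip())
        twice = augment_image(once, cfg, AlwaysFlip())
        np.testing.assert_array_equal(twice.pixels, px)

    def test_rotation_moves_bright_pixel_on_annulus(self):
        px = np.zeros((41, 41, 3))
        px[20, 32] = 255.0  # radius 12 from center, on the x axis
        cfg = AugmentationConfig(rotation_deg=30.0)

        class FixedAngle:
            # uniform(-30, 30) -> +30 degrees; everything else neutral
            def uniform(self, a, b):
                return 30.0 if (a, b) == (-30.0, 30.0) else (a + b) / 2.0

            random = staticmethod(lambda: 1.0)

        out = augment_image(record(px), cfg, FixedAngle())
        y, x = np.unravel_index(np.argmax(out.pixels[:, :, 0]), (41, 41))
        r = np.hypot(y - 20.0, x - 20.0)
        assert abs(r - 12.0) < 1.5  # stays on the radius-12 annulus
        assert y != 20 or x != 32  # and actually moved

    def test_label_and_shape_preserved(self, rng):
        px = rng.integers(0, 256, (24, 24, 3), dtype=np.uint8)
        out = augment_image(record(px, "tumor"), AugmentationConfig.balancing_defaults(), rng)
        assert out.label == "tumor"
        assert out.pixels.shape == (24, 24, 3)

    def test_invalid_magnitudes_rejected(self):
        with pytest.raises(ValueError):
            AugmentationConfig(zoom=0.5)
        with pytest.raises(ValueError):
            AugmentationConfig(brightness=(1.5, 1.0))


class TestBalance:
    def make_set(self, counts, rng):
        recs = []
        for label, n in counts.items():
            for _ in range(n):
                recs.append(record(rng.integers(0, 256, (8, 8, 3), dtype=np.uint8), label))
        return recs

    def test_study_scale_counts(self, rng):
        recs = self.make_set({"normal": 2494, "OSCC": 2698}, rng)
        out = balance_by_augmentation(recs, seed=0)
        counts = Counter(r.label for r in out)
        assert counts == {"normal": 2698, "OSCC": 2698}
        assert len(out) == 5396

    def test_already_balanced_unchanged(self, rng):
        recs = self.make_set({"a": 5, "b": 5}, rng)
        assert balance_by_augmentation(recs, seed=0) == recs

    def test_single_source_class(self, rng):
        recs = self.make_set({"A": 1, "B": 3}, rng)
        out = balance_by_augmentation(recs, seed=0)
        counts = Counter(r.label for r in out)
        assert counts == {"A": 3, "B": 3}
        added = [r for r in out if r.provenance.startswith("aug:")]
        assert len(added) == 2 and all(r.label == "A" for r in added)

    def test_originals_retained(self, rng):
        recs = self.make_set({"a": 2, "b": 6}, rng)
        out = balance_by_augmentation(recs, seed=3)
        assert all(r in out for r in recs)

    def test_empty_class_error(self):
        with pytest.raises(ValueError):
            balance_by_augmentation([], seed=0)


class TestPartition:
    def test_study_proportions_at_ten_thousand(self):
        split = partition_dataset(list(range(10_000)), ratio=0.85, seed=0)
        assert split.sizes == (7225, 1275, 1500)

    def test_partition_law(self):
        items = list(range(97))
        split = partition_dataset(items, seed=4)
        parts = [set(split.train), set(split.validation), set(split.test)]
        assert parts[0] | parts[1] | parts[2] == set(items)
        assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])

    def test_determinism(self):
        a = partition_dataset(list(range(50)), seed=9)
        b = partition_dataset(list(range(50)), seed=9)
        assert a.train == b.train and a.validation == b.validation and a.test == b.test

    def test_proportions_converge(self):
        split = partition_dataset(list(range(10_000)), seed=2)
        n = 10_000
        assert abs(len(split.train) / n - 0.7225) < 0.001
        assert abs(len(split.validation) / n - 0.1275) < 0.001
        assert abs(len(split.test) / n - 0.15) < 0.001

    def test_too_small(self):
        with pytest.raises(ValueError):
            partition_dataset([1, 2], seed=0)

    def test_bad_ratio(self):
        with pytest.raises(ValueError):
            partition_dataset(list(range(10)), ratio=1.5, seed=0)


class TestFolderIO:
    def test_round_trip(self, tmp_path, rng):
        recs = [
            record(rng.integers(0, 256, (128, 128, 3), dtype=np.uint8), label)
            for label in ("normal", "normal", "OSCC")
        ]
        save_image_folder(recs, tmp_path / "ds")
        loaded = load_image_folder(tmp_path / "ds")
        assert Counter(r.label for r in loaded) == {"normal": 2, "OSCC": 1}
        originals = sorted((r.label, r.pixels.tobytes()) for r in recs)
        reloaded = sorted((r.label, r.pixels.tobytes()) for r in loaded)
        assert originals == reloaded
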