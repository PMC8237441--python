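"""Dataset loading, balancing and domain splits."""

import numpy as np
import pytest
from PIL import Image

import leafshot as ls
from leafshot.data import (PLANTVILLAGE_CLASSES, crop_of, domain_split,
                           stratified_split_indices)


def small_dataset(n_classes=2, per_class=3, size=16, seed=0):
    rng = np.random.default_rng(seed)
    blocks = [rng.random((per_class, size, size, 3)).astype(np.float32)
              for _ in range(n_classes)]
    return ls.ClassIndexedDataset([f"c{i}" for i in range(n_classes)], blocks,
                                  provenance="synthetic")


class TestLoadSave:
    def test_folder_round_trip(self, tmp_path):
        ds = small_dataset(2, 3)
        ls.save_image_folder(ds, tmp_path / "tree")
        back = ls.load_image_folder(tmp_path / "tree", image_size=(16, 16))
        assert back.class_names == ds.class_names
        assert back.counts == ds.counts
        # PNG round trip quantizes to 8 bits
        np.testing.assert_allclose(back.images_by_class[0],
                                   ds.images_by_class[0], atol=1 / 255 + 1e-6)

    def test_resize_to_84(self, tmp_path):
        d = tmp_path / "tree" / "leaf"
        d.mkdir(parents=True)
        arr = (np.random.default_rng(0).random((256, 256, 3)) * 255).astype(np.uint8)
        Image.fromarray(arr).save(d / "big.png")
        ds = ls.load_image_folder(tmp_path / "tree")
        img = ds.images_by_class[0][0]
        assert img.shape == (84, 84, 3)
        assert 0.0 <= img.min() and img.max() <= 1.0

    def test_empty_class_directory_is_an_error(self, tmp_path):
        (tmp_path / "tree" / "good").mkdir(parents=True)
        Image.new("RGB", (8, 8)).save(tmp_path / "tree" / "good" / "a.png")
        (tmp_path / "tree" / "empty_class").mkdir()
        with pytest.raises(ValueError, match="empty_class"):
            ls.load_image_folder(tmp_path / "tree")

    def test_no_classes_is_an_error(self, tmp_path):
        (tmp_path / "tree").mkdir()
        with pytest.raises(ValueError):
            ls.load_image_folder(tmp_path / "tree")

    def test_undecodable_file_is_reported_with_name(self, tmp_path):
        d = tmp_path / "tree" / "c"
        d.mkdir(parents=True)
        (d / "broken.png").write_bytes(b"not a png")
        with pytest.raises(ValueError, match="broken.png"):
            ls.load_image_folder(tmp_path / "tree")


class TestBalance:
    def test_exact_per_class_and_reproducible(self):
        ds = small_dataset(3, 10)
        b1 = ls.balance(ds, 4, seed=1)
        b2 = ls.balance(ds, 4, seed=1)
        assert b1.counts == [4, 4, 4]
        for a, b in zip(b1.images_by_class, b2.images_by_class):
            np.testing.assert_array_equal(a, b)
        b3 = ls.balance(ds, 4, seed=2)
        assert any(not np.array_equal(a, b)
                   for a, b in zip(b1.images_by_class, b3.images_by_class))

    def test_idempotent(self):
        ds = small_dataset(2, 8)
        once = ls.balance(ds, 5, seed=3)
        twice = ls.balance(once, 5, seed=3)
        for a, b in zip(once.images_by_class, twice.images_by_class):
            np.testing.assert_array_equal(a, b)

    def test_per_class_equal_to_smallest_returns_whole_class(self):
        ds = small_dataset(2, 6)
        out = ls.balance(ds, 6, seed=0)
        for a, b in zip(out.images_by_class, ds.images_by_class):
            np.testing.assert_array_equal(np.sort(a, axis=0), np.sort(b, axis=0))

    def test_too_small_class_error_names_class(self):
        ds = small_dataset(2, 3)
        with pytest.raises(ValueError, match="c0"):
            ls.balance(ds, 4)


class TestDomainSplits:
    def test_standard_splits_have_28_source_10_target(self):
        for name in ("split1", "split2", "split3"):
            sp = domain_split(name)
            assert len(sp.source_classes) == 28
            assert len(sp.target_classes) == 10
            assert not set(sp.source_classes) & set(sp.target_classes)

    def test_split1_target_is_the_ten_tomato_classes(self):
        sp = domain_split("split1")
        assert all(crop_of(c) == "Tomato" for c in sp.target_classes)
        assert sum(crop_of(c) == "Tomato" for c in PLANTVILLAGE_CLASSES) == 10

    def test_split2_target_crops(self):
        sp = domain_split("split2")
        crops = sorted({crop_of(c) for c in sp.target_classes})
        assert crops == ["Apple", "Cherry", "Grape"]
        counts = {cr: sum(crop_of(c) == cr for c in sp.target_classes) for cr in crops}
        assert counts == {"Apple": 4, "Cherry": 2, "Grape": 4}

    def test_split3_target_crops(self):
        sp = domain_split("split3")
        counts = {}
        for c in sp.target_classes:
            counts[crop_of(c)] = counts.get(crop_of(c), 0) + 1
        assert counts == {"Corn": 4, "Grape": 4, "Peach": 2}

    def test_ref27_takes_first_six_lexicographic(self):
        sp = domain_split("ref27")
        assert len(sp.target_classes) == 6
        assert len(sp.source_classes) == 32
        assert sp.target_classes == sorted(PLANTVILLAGE_CLASSES)[:6]
        override = list(PLANTVILLAGE_CLASSES[10:16])
        sp2 = domain_split("ref27", target_classes=override)
        assert sp2.target_classes == override

    def test_custom_requires_targets_and_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            domain_split("custom")
        with pytest.raises(ValueError):
            domain_split("split9")

    def test_apply_split_partitions_dataset(self):
        ds = small_dataset(6, 4)
        sp = domain_split("custom", ds.class_names, target_classes=["c1", "c4"])
        source, target = ls.apply_split(ds, sp)
        assert target.class_names == ["c1", "c4"]
        assert source.class_names == ["c0", "c2", "c3", "c5"]
        assert source.n_classes + target.n_classes == ds.n_classes

    def test_apply_split_unknown_class(self):
        ds = small_dataset(3, 4)
        sp = ls.DomainSplit("custom", ["c0", "nope"], ["c1"])
        with pytest.raises(ValueError, match="nope"):
            ls.apply_split(ds, sp)


class TestStratifiedSplit:
    def test_source_domain_arithmetic_28x1000(self):
        """28 classes x 1000 images at 20% -> 22,400 train / 5,600 validation."""
        y = np.repeat(np.arange(28), 1000)
        train, val = stratified_split_indices(y, 0.20, seed=0)
        assert len(train) == 22_400
        assert len(val) == 5_600
        # batch size 16 -> 1,400 optimizer steps per epoch
        assert int(np.ceil(len(train) / 16)) == 1_400

    def test_disjoint_stratified_reproducible(self):
        y = np.repeat(np.arange(4), [10, 11, 13, 20])
        t1, v1 = stratified_split_indices(y, 0.25, seed=7)
        t2, v2 = stratified_split_indices(y, 0.25, seed=7)
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(v1, v2)
        assert not set(t1) & set(v1)
        assert len(t1) + len(v1) == len(y)
        for c, n in zip(range(4), [10, 11, 13, 20]):
            held = (y[v1] == c).sum()
            assert abs(held - 0.25 * n) <= 1

    def test_fraction_bounds(self):
        y = np.repeat(np.arange(2), 5)
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                stratified_split_indices(y, bad)


def test_dataset_invariants_enforced():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):  # duplicate names
        ls.ClassIndexedDataset(["a", "a"],
                               [rng.random((2, 8, 8, 3)).astype(np.float32)] * 2)
    with pytest.raises(ValueError):  # out-of-range values
        ls.ClassIndexedDataset(["a"], [np.full((1, 8, 8, 3), 1.5, np.float32)])
    with pytest.raises(ValueError):  # empty class
        ls.ClassIndexedDataset(["a"], [np.zeros((0, 8, 8, 3), np.float32)])
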