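"""Folder-per-class image datasets and source/target domain splits.

A :class:`ClassIndexedDataset` stores 84x84x3 float images in [0, 1] grouped
by class.  A :class:`DomainSplit` partitions class names into disjoint
*source* (pretraining) and *target* (few-shot) domains.  The three standard
PlantVillage splits are expressed as crop-level partitions of the 38-class
dataset — e.g. split1 holds out the ten Tomato classes as the target domain
— and are resolved against class folder names by crop prefix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

#: Canonical folder names of the 38-class PlantVillage dataset (lexicographic).
PLANTVILLAGE_CLASSES = (
    "Apple___Apple_scab",
    "Apple___Black_rot",
    "Apple___Cedar_apple_rust",
    "Apple___healthy",
    "Blueberry___healthy",
    "Cherry_(including_sour)___Powdery_mildew",
    "Cherry_(including_sour)___healthy",
    "Corn_(maize)___Cercospora_leaf_spot Gray_leaf_spot",
    "Corn_(maize)___Common_rust_",
    "Corn_(maize)___Northern_Leaf_Blight",
    "Corn_(maize)___healthy",
    "Grape___Black_rot",
    "Grape___Esca_(Black_Measles)",
    "Grape___Leaf_blight_(Isariopsis_Leaf_Spot)",
    "Grape___healthy",
    "Orange___Haunglongbing_(Citrus_greening)",
    "Peach___Bacterial_spot",
    "Peach___healthy",
    "Pepper,_bell___Bacterial_spot",
    "Pepper,_bell___healthy",
    "Potato___Early_blight",
    "Potato___Late_blight",
    "Potato___healthy",
    "Raspberry___healthy",
    "Soybean___healthy",
    "Squash___Powdery_mildew",
    "Strawberry___Leaf_scorch",
    "Strawberry___healthy",
    "Tomato___Bacterial_spot",
    "Tomato___Early_blight",
    "Tomato___Late_blight",
    "Tomato___Leaf_Mold",
    "Tomato___Septoria_leaf_spot",
    "Tomato___Spider_mites Two-spotted_spider_mite",
    "Tomato___Target_Spot",
    "Tomato___Tomato_Yellow_Leaf_Curl_Virus",
    "Tomato___Tomato_mosaic_virus",
    "Tomato___healthy",
)

#: Target-domain crops of the three standard splits; the source is the rest.
SPLIT_TARGET_CROPS = {
    "split1": ("Tomato",),
    "split2": ("Apple", "Cherry", "Grape"),
    "split3": ("Corn", "Grape", "Peach"),
}

SPLIT_NAMES = ("split1", "split2", "split3", "ref27", "custom")


def crop_of(class_name: str) -> str:
    """Crop prefix of a PlantVillage-style class name.

    ``"Cherry_(including_sour)___Powdery_mildew"`` -> ``"Cherry"``;
    ``"Pepper,_bell___healthy"`` -> ``"Pepper"``.
    """
    head = class_name.split("___")[0]
    head = head.split(",")[0]
    head = head.split("_(")[0]
    return head


@dataclass
class ClassIndexedDataset:
    """Images grouped by integer class label, with a class-name registry.

    ``images_by_class[i]`` is a float32 array of shape (n_i, H, W, 3) with
    values in [0, 1], holding the images of ``class_names[i]``.
    """

    class_names: list
    images_by_class: list
    provenance: str = "synthetic"

    def __post_init__(self):
        if len(self.class_names) != len(set(self.class_names)):
            raise ValueError("class names must be unique")
        if len(self.class_names) != len(self.images_by_class):
            raise ValueError("one image block per class required")
        for name, block in zip(self.class_names, self.images_by_class):
            if len(block) == 0:
                raise ValueError(f"class {name!r} has no images")
            if block.ndim != 4 or block.shape[3] != 3:
                raise ValueError(f"class {name!r}: images must be (n, H, W, 3)")
            if float(block.min()) < 0.0 or float(block.max()) > 1.0:
                raise ValueError(f"class {name!r}: pixel values outside [0, 1]")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def counts(self) -> list:
        return [len(b) for b in self.images_by_class]

    def stacked(self):
        """All images as (X, y): one array plus integer labels in class order."""
        X = np.concatenate(self.images_by_class, axis=0)
        y = np.repeat(np.arange(self.n_classes), self.counts)
        return X, y

    def class_index(self, name: str) -> int:
        return self.class_names.index(name)


@dataclass
class DomainSplit:
    """Named partition of class names into disjoint source and target domains."""

    name: str
    source_classes: list
    target_classes: list

    def __post_init__(self):
        overlap = set(self.source_classes) & set(self.target_classes)
        if overlap:
            raise ValueError(f"source and target domains intersect: {sorted(overlap)}")


def domain_split(name: str, class_names=PLANTVILLAGE_CLASSES,
                 target_classes=None) -> DomainSplit:
    """Resolve a named split against a class registry.

    split1/split2/split3 select target classes by crop (28 source / 10 target
    on the full 38-class registry).  ``ref27`` takes the first six classes in
    lexicographic order as the target domain and the remaining classes as the
    source; pass ``target_classes`` to override which six.  ``custom``
    requires an explicit ``target_classes`` list.
    """
    names = list(class_names)
    if name in SPLIT_TARGET_CROPS:
        crops = SPLIT_TARGET_CROPS[name]
        target = [c for c in names if crop_of(c) in crops]
        source = [c for c in names if crop_of(c) not in crops]
        if tuple(names) == PLANTVILLAGE_CLASSES and (len(source), len(target)) != (28, 10):
            raise AssertionError("standard split must resolve to 28 source / 10 target classes")
    elif name == "ref27":
        target = list(target_classes) if target_classes is not None else sorted(names)[:6]
        source = [c for c in names if c not in set(target)]
    elif name == "custom":
        if target_classes is None:
            raise ValueError("custom split requires explicit target_classes")
        target = list(target_classes)
        source = [c for c in names if c not in set(target)]
    else:
        raise ValueError(f"unknown split {name!r}; expected one of {SPLIT_NAMES}")
    if not target or not source:
        raise ValueError(f"split {name!r} leaves an empty domain")
    return DomainSplit(name, source, target)


def load_image_folder(path, image_size=(84, 84)) -> ClassIndexedDataset:
    """Read a folder-per-class PNG/JPEG tree.

    Images are decoded as RGB, resized with bilinear interpolation to
    ``image_size`` and scaled to [0, 1].  Class order is the lexicographic
    order of the subdirectory names.
    """
    path = Path(path)
    subdirs = sorted(d for d in path.iterdir() if d.is_dir())
    if not subdirs:
        raise ValueError(f"no class subdirectories found under {path}")
    names, blocks = [], []
    for sub in subdirs:
        files = sorted(f for f in sub.iterdir()
                       if f.suffix.lower() in (".png", ".jpg", ".jpeg"))
        if not files:
            raise ValueError(f"class {sub.name!r} contains no images")
        imgs = []
        for f in files:
            try:
                with Image.open(f) as im:
                    im = im.convert("RGB").resize(
                        (image_size[1], image_size[0]), Image.BILINEAR)
                    imgs.append(np.asarray(im, dtype=np.float32) / 255.0)
            except Exception as exc:
                raise ValueError(f"cannot decode image {f}: {exc}") from exc
        names.append(sub.name)
        blocks.append(np.stack(imgs))
    return ClassIndexedDataset(names, blocks, provenance=str(path))


def save_image_folder(ds: ClassIndexedDataset, path) -> None:
    """Write the dataset as a folder-per-class PNG tree (8-bit)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, block in zip(ds.class_names, ds.images_by_class):
        sub = path / name
        sub.mkdir(exist_ok=True)
        for i, img in enumerate(block):
            arr = np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8)
            Image.fromarray(arr).save(sub / f"{i:05d}.png")


def balance(ds: ClassIndexedDataset, per_class: int, seed: int = 0) -> ClassIndexedDataset:
    """Randomly keep exactly ``per_class`` images in every class (no replacement).

    Selections are made in sorted index order so the operation is idempotent:
    balancing an already balanced dataset with the same arguments returns it
    unchanged.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    for name, block in zip(ds.class_names, ds.images_by_class):
        if len(block) < per_class:
            raise ValueError(
                f"class {name!r} has {len(block)} images, fewer than per_class={per_class}")
        idx = np.sort(rng.choice(len(block), size=per_class, replace=False))
        blocks.append(block[idx])
    return ClassIndexedDataset(list(ds.class_names), blocks, provenance=ds.provenance)


def apply_split(ds: ClassIndexedDataset, split: DomainSplit):
    """Partition a dataset into (source, target) by the split's class names."""
    known = set(ds.class_names)
    for c in list(split.source_classes) + list(split.target_classes):
        if c not in known:
            raise ValueError(f"split {split.name!r} names unknown class {c!r}")

    def subset(names):
        names = [c for c in ds.class_names if c in set(names)]  # keep registry order
        blocks = [ds.images_by_class[ds.class_index(c)] for c in names]
        return ClassIndexedDataset(names, blocks, provenance=ds.provenance)

    return subset(split.source_classes), subset(split.target_classes)


def stratified_split_indices(labels: np.ndarray, fraction: float, seed: int = 0):
    """Per-class holdout split: returns (rest_idx, held_idx).

    Every class contributes ``max(1, round(n_c * fraction))`` held-out
    samples, so class proportions are preserved to within one image.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    rest, held = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            raise ValueError(f"class {c} has fewer than 2 samples; cannot hold out")
        idx = rng.permutation(idx)
        n_held = max(1, int(round(len(idx) * fraction)))
        if n_held >= len(idx):
            n_held = len(idx) - 1
        held.append(idx[:n_held])
        rest.append(idx[n_held:])
    return np.sort(np.concatenate(rest)), np.sort(np.concatenate(held))
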