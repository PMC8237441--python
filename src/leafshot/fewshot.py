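"""Episodic N-way k-shot sampling and the baseline fine-tune/test protocol.

An *episode* is one few-shot task: N classes drawn at random from the target
domain, k labeled support images per class, a query set (default 15 per
class) for scoring, and an unlabeled pool drawn from the same classes and
disjoint from both.  The baseline protocol fine-tunes the transferred
model's two dense layers on the support set and reports query accuracy.

Because the convolution layers are frozen after transfer, fine-tuning
operates on the 256-dimensional global-average-pool features; the public
operations take images and compute those features internally, while the
experiment driver in :mod:`leafshot.evalreport` shares one feature cache
across methods and episodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .arch import ModelSpec
from .data import ClassIndexedDataset


@dataclass
class EpisodeConfig:
    n_way: int
    k_shot: int
    n_query: int = 15
    unlabeled_per_class: int | None = None  # None = all remaining images
    seed: int = 0

    def __post_init__(self):
        if self.n_way < 2:
            raise ValueError("n_way must be >= 2")
        if self.k_shot < 1 or self.n_query < 1:
            raise ValueError("k_shot and n_query must be >= 1")


@dataclass
class Episode:
    """One sampled N-way k-shot task.

    ``*_y`` labels are episode-local (0..N-1, indexing ``class_ids``).
    ``*_ci``/``*_wi`` record, for every sample, its dataset class index and
    its within-class image index, so precomputed per-class feature caches
    can be indexed without touching pixels.  ``pool_true_y`` keeps the true
    labels of the unlabeled pool for diagnostics only; no protocol reads it.
    """

    class_ids: np.ndarray
    class_names: list
    support_x: np.ndarray
    support_y: np.ndarray
    query_x: np.ndarray
    query_y: np.ndarray
    pool_x: np.ndarray
    pool_true_y: np.ndarray
    support_ci: np.ndarray = None
    support_wi: np.ndarray = None
    query_ci: np.ndarray = None
    query_wi: np.ndarray = None
    pool_ci: np.ndarray = None
    pool_wi: np.ndarray = None

    @property
    def n_way(self) -> int:
        return len(self.class_ids)


def sample_episode(target: ClassIndexedDataset, cfg: EpisodeConfig) -> Episode:
    """Draw an episode without replacement, reproducibly under ``cfg.seed``.

    Classes are drawn uniformly from the target domain; within each class
    the support, query and unlabeled sets are disjoint.
    """
    if cfg.n_way > target.n_classes:
        raise ValueError(
            f"n_way={cfg.n_way} exceeds the {target.n_classes} target classes")
    need = cfg.k_shot + cfg.n_query
    rng = np.random.default_rng(cfg.seed)
    class_ids = np.sort(rng.choice(target.n_classes, size=cfg.n_way, replace=False))

    sup, qry, pool = [], [], []
    for local, ci in enumerate(class_ids):
        block = target.images_by_class[ci]
        if len(block) < need:
            raise ValueError(
                f"class {target.class_names[ci]!r} has {len(block)} images; "
                f"episode needs k + n_query = {need}")
        perm = rng.permutation(len(block))
        s = perm[:cfg.k_shot]
        q = perm[cfg.k_shot:need]
        u = perm[need:]
        if cfg.unlabeled_per_class is not None:
            u = u[:cfg.unlabeled_per_class]
        sup.append((ci, s, local))
        qry.append((ci, q, local))
        pool.append((ci, u, local))

    def gather(parts):
        xs, ys, cis, wis = [], [], [], []
        for ci, wi, local in parts:
            xs.append(target.images_by_class[ci][wi])
            ys.append(np.full(len(wi), local))
            cis.append(np.full(len(wi), ci))
            wis.append(wi)
        return (np.concatenate(xs), np.concatenate(ys),
                np.concatenate(cis), np.concatenate(wis))

    sx, sy, sci, swi = gather(sup)
    qx, qy, qci, qwi = gather(qry)
    px, py, pci, pwi = gather(pool)
    return Episode(class_ids, [target.class_names[c] for c in class_ids],
                   sx, sy, qx, qy, px, py,
                   sci, swi, qci, qwi, pci, pwi)


@dataclass
class FineTuneConfig:
    """Settings for fine-tuning the two dense layers within an episode.

    The default epoch count trains the head to convergence on the few
    support samples; confident (>99.5%) pool predictions only appear once
    the softmax has saturated on the support set.
    """

    epochs: int = 500
    learning_rate: float = 1e-3
    batch_size: int | None = None  # None: full batch when n <= 64, else 16
    seed: int = 0
    reinit_between_rounds: bool = False


def _train_head(model: ModelSpec, feats: np.ndarray, labels: np.ndarray,
                cfg: FineTuneConfig, seed_offset: int = 0) -> None:
    """Train dense_128 + dense_out in place on precomputed backbone features."""
    labels = np.asarray(labels)
    if len(feats) == 0:
        raise ValueError("cannot fine-tune on an empty labeled set")
    n_out = model.impl["dense_out"].b.size
    if labels.min() < 0 or labels.max() >= n_out:
        raise ValueError(
            f"labels must lie in 0..{n_out - 1}, got range "
            f"[{labels.min()}, {labels.max()}]")
    d1, d2 = model.impl["dense_128"], model.impl["dense_out"]
    opt = nn.Adam([d1, d2], lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + seed_offset)
    n = len(feats)
    bs = cfg.batch_size if cfg.batch_size else (n if n <= 64 else 16)
    for _ in range(cfg.epochs):
        order = np.arange(n) if bs >= n else rng.permutation(n)
        for lo in range(0, n, bs):
            sel = order[lo:lo + bs]
            h = d1.forward(feats[sel], train=True)
            h = d2.forward(h, train=True)
            _, _, grad = nn.softmax_xent(h, labels[sel])
            d1.backward(d2.backward(grad))
            opt.step()


def fine_tune(model: ModelSpec, labeled_x: np.ndarray, labeled_y: np.ndarray,
              cfg: FineTuneConfig) -> ModelSpec:
    """Return a copy of ``model`` with only the two dense layers updated.

    The convolution weights of the returned model are numerically identical
    to the input's; the update is deterministic under ``cfg.seed``.
    """
    out = model.copy()
    feats = out.features(labeled_x)
    _train_head(out, feats, labeled_y, cfg)
    return out


def accuracy_from_probs(probs: np.ndarray, y: np.ndarray) -> float:
    return float((probs.argmax(axis=1) == np.asarray(y)).mean())


def episode_features(model: ModelSpec, ep: Episode) -> dict:
    """Backbone features of an episode's support / query / pool images."""
    return {
        "support": model.features(ep.support_x),
        "query": model.features(ep.query_x),
        "pool": model.features(ep.pool_x) if len(ep.pool_x) else np.zeros((0, 256), nn.DTYPE),
    }


def _run_baseline_feats(model: ModelSpec, feats: dict, ep: Episode,
                        cfg: FineTuneConfig):
    work = model.copy()
    _train_head(work, feats["support"], ep.support_y, cfg)
    probs = work.head_probs_from_features(feats["query"])
    return accuracy_from_probs(probs, ep.query_y), work


def run_baseline(model: ModelSpec, ep: Episode, ft_cfg: FineTuneConfig) -> float:
    """Fine-tune on the support set only; return query accuracy."""
    acc, _ = _run_baseline_feats(model, episode_features(model, ep), ep, ft_cfg)
    return acc
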