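"""Semi-supervised few-shot protocols with adaptive pseudo-label selection.

Both protocols start like the baseline: fine-tune the two dense layers on
the N*k support samples, then fix the model.  The fixed model predicts the
episode's unlabeled pool, and a sample is *selected* for pseudo-labeling
only when its prediction confidence — the maximum softmax probability — is
strictly greater than the selection threshold (default 99.5%).  The model
therefore decides adaptively how many pseudo-labels to trust, rather than
taking a fixed number.

* Single round: one selection pass; the model is fine-tuned again on the
  support set plus the selected pseudo-labeled samples, then tested.
* Iterative (two rounds): after the second fine-tune, the *remaining*
  unlabeled samples (pool minus round-1 selections) are predicted and
  selected again; a final fine-tune uses the support set plus both rounds'
  selections.

Each later fine-tune continues from the previous round's dense weights
(``FineTuneConfig.reinit_between_rounds`` restores the transferred head
first, for ablation).  When a round selects nothing, the extra fine-tune is
skipped, so an episode with no confident predictions degrades exactly to
the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arch import ModelSpec
from .fewshot import (Episode, FineTuneConfig, _train_head, accuracy_from_probs,
                      episode_features)


@dataclass
class SelectionRule:
    """Confidence threshold for pseudo-label selection (strictly greater than)."""

    threshold: float = 0.995

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


@dataclass
class PseudoLabelSet:
    """Unlabeled samples the model selected, with its labels and confidences."""

    samples: np.ndarray | None
    pseudo_labels: np.ndarray
    confidences: np.ndarray
    source_round: int = 1
    indices: np.ndarray | None = None  # positions in the candidate pool

    def __post_init__(self):
        n = len(self.pseudo_labels)
        if len(self.confidences) != n:
            raise ValueError("labels and confidences must have equal length")
        if self.samples is not None and len(self.samples) != n:
            raise ValueError("samples and labels must have equal length")

    def __len__(self) -> int:
        return len(self.pseudo_labels)


def predict_with_confidence(model: ModelSpec, samples: np.ndarray):
    """(predicted labels, confidences) of the fixed model on a batch of images.

    The label is the argmax of the softmax output and the confidence its
    maximum probability; the model is not modified.
    """
    samples = np.asarray(samples)
    if len(samples) == 0:
        raise ValueError("empty sample set")
    probs = model.forward(samples)
    return probs.argmax(axis=1), probs.max(axis=1)


def select_pseudo(labels, confidences, rule: SelectionRule,
                  samples: np.ndarray | None = None,
                  source_round: int = 1) -> PseudoLabelSet:
    """Keep exactly the samples with confidence strictly above the threshold."""
    labels = np.asarray(labels)
    confidences = np.asarray(confidences)
    if labels.shape[0] != confidences.shape[0]:
        raise ValueError("labels and confidences must have equal length")
    mask = confidences > rule.threshold
    idx = np.flatnonzero(mask)
    return PseudoLabelSet(
        samples=None if samples is None else samples[idx],
        pseudo_labels=labels[idx],
        confidences=confidences[idx],
        source_round=source_round,
        indices=idx,
    )


def _select_from_feats(model: ModelSpec, pool_feats: np.ndarray,
                       rule: SelectionRule, source_round: int) -> PseudoLabelSet:
    if len(pool_feats) == 0:
        empty = np.zeros(0, dtype=np.int64)
        return PseudoLabelSet(None, empty, empty.astype(float),
                              source_round, empty)
    probs = model.head_probs_from_features(pool_feats)
    return select_pseudo(probs.argmax(axis=1), probs.max(axis=1), rule,
                         source_round=source_round)


def _precision(pseudo: PseudoLabelSet, true_y: np.ndarray) -> float:
    if len(pseudo) == 0:
        return float("nan")
    return float((pseudo.pseudo_labels == true_y[pseudo.indices]).mean())


def _restore_head(work: ModelSpec, ref: ModelSpec) -> None:
    for name in ("dense_128", "dense_out"):
        work.impl[name].W = ref.impl[name].W.copy()
        work.impl[name].b = ref.impl[name].b.copy()


def _run_single_feats(model: ModelSpec, feats: dict, ep: Episode,
                      rule: SelectionRule, cfg: FineTuneConfig) -> dict:
    work = model.copy()
    # step 1: fine-tune on the support set, fix, predict the pool
    _train_head(work, feats["support"], ep.support_y, cfg)
    pseudo = _select_from_feats(work, feats["pool"], rule, source_round=1)
    # step 2: fine-tune again on support + selected pseudo-labeled samples
    if len(pseudo):
        if cfg.reinit_between_rounds:
            _restore_head(work, model)
        x2 = np.concatenate([feats["support"], feats["pool"][pseudo.indices]])
        y2 = np.concatenate([ep.support_y, pseudo.pseudo_labels])
        _train_head(work, x2, y2, cfg, seed_offset=1)
    probs = work.head_probs_from_features(feats["query"])
    return {
        "accuracy": accuracy_from_probs(probs, ep.query_y),
        "n_pseudo": len(pseudo),
        "pseudo_precision": _precision(pseudo, ep.pool_true_y),
    }


def _run_iterative_feats(model: ModelSpec, feats: dict, ep: Episode,
                         rule: SelectionRule, cfg: FineTuneConfig) -> dict:
    work = model.copy()
    # step 1: fine-tune on support, fix, select round-1 pseudo-labels
    _train_head(work, feats["support"], ep.support_y, cfg)
    p1 = _select_from_feats(work, feats["pool"], rule, source_round=1)
    # step 2: fine-tune on support + round-1, then predict the *rest* of the pool
    if len(p1):
        if cfg.reinit_between_rounds:
            _restore_head(work, model)
        x2 = np.concatenate([feats["support"], feats["pool"][p1.indices]])
        y2 = np.concatenate([ep.support_y, p1.pseudo_labels])
        _train_head(work, x2, y2, cfg, seed_offset=1)
    rest = np.setdiff1d(np.arange(len(feats["pool"])), p1.indices)
    p2 = _select_from_feats(work, feats["pool"][rest], rule, source_round=2)
    p2_pool_idx = rest[p2.indices] if len(p2) else np.zeros(0, dtype=np.int64)
    # step 3: fine-tune on support + both rounds of pseudo-labels
    if len(p1) + len(p2) > 0:
        if cfg.reinit_between_rounds:
            _restore_head(work, model)
        sel = np.concatenate([p1.indices, p2_pool_idx])
        x3 = np.concatenate([feats["support"], feats["pool"][sel]])
        y3 = np.concatenate([ep.support_y, p1.pseudo_labels, p2.pseudo_labels])
        _train_head(work, x3, y3, cfg, seed_offset=2)
    probs = work.head_probs_from_features(feats["query"])
    p2_precision = (float((p2.pseudo_labels == ep.pool_true_y[p2_pool_idx]).mean())
                    if len(p2) else float("nan"))
    return {
        "accuracy": accuracy_from_probs(probs, ep.query_y),
        "n_pseudo_round1": len(p1),
        "n_pseudo_round2": len(p2),
        "pseudo_precision_round1": _precision(p1, ep.pool_true_y),
        "pseudo_precision_round2": p2_precision,
    }


def run_single_ss(model: ModelSpec, ep: Episode, rule: SelectionRule,
                  ft_cfg: FineTuneConfig):
    """Single-round semi-supervised protocol; returns (query accuracy, n selected)."""
    res = _run_single_feats(model, episode_features(model, ep), ep, rule, ft_cfg)
    return res["accuracy"], res["n_pseudo"]


def run_iterative_ss(model: ModelSpec, ep: Episode, rule: SelectionRule,
                     ft_cfg: FineTuneConfig):
    """Two-round semi-supervised protocol; returns (accuracy, n round 1, n round 2)."""
    res = _run_iterative_feats(model, episode_features(model, ep), ep, rule, ft_cfg)
    return res["accuracy"], res["n_pseudo_round1"], res["n_pseudo_round2"]
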