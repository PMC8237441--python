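"""Multi-episode experiments: baseline vs. semi-supervised, aggregated.

For every k and episode index, one episode is sampled and *all* methods run
on that same episode from the same freshly transferred head (a paired
design, which removes episode-to-episode task difficulty from the method
comparison).  Episode seeds derive deterministically from the master seed,
so a whole experiment is reproducible bit for bit.

``PUBLISHED_BENCHMARK_5WAY`` records the mean accuracies reported by the
original PlantVillage study of this protocol (5-way, k in {1, 5, 10, 20},
ten episodes per cell, three domain splits); :func:`summarize_improvement`
applied to those tables reproduces the study's printed per-split average
improvements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .arch import ModelSpec, replace_head
from .data import ClassIndexedDataset
from .fewshot import (EpisodeConfig, FineTuneConfig, _run_baseline_feats,
                      sample_episode)
from .semisup import SelectionRule, _run_iterative_feats, _run_single_feats

METHODS = ("baseline", "single_ss", "iterative_ss")

#: Published 5-way mean accuracies (k: accuracy) for the three domain splits.
PUBLISHED_BENCHMARK_5WAY = {
    "split1": {
        "baseline":     {1: 0.328, 5: 0.467, 10: 0.640, 20: 0.732},
        "single_ss":    {1: 0.337, 5: 0.509, 10: 0.667, 20: 0.747},
        "iterative_ss": {1: 0.340, 5: 0.531, 10: 0.688, 20: 0.756},
    },
    "split2": {
        "baseline":     {1: 0.439, 5: 0.685, 10: 0.787, 20: 0.891},
        "single_ss":    {1: 0.447, 5: 0.747, 10: 0.857, 20: 0.897},
        "iterative_ss": {1: 0.464, 5: 0.769, 10: 0.892, 20: 0.919},
    },
    "split3": {
        "baseline":     {1: 0.507, 5: 0.631, 10: 0.772, 20: 0.893},
        "single_ss":    {1: 0.523, 5: 0.676, 10: 0.799, 20: 0.901},
        "iterative_ss": {1: 0.552, 5: 0.693, 10: 0.808, 20: 0.915},
    },
}


@dataclass
class ExperimentConfig:
    n_way: int = 5
    k_values: tuple = (1, 5)
    methods: tuple = METHODS
    n_episodes: int = 10
    n_query: int = 15
    unlabeled_per_class: int | None = None
    master_seed: int = 0
    rule: SelectionRule = field(default_factory=SelectionRule)
    ft: FineTuneConfig = field(default_factory=FineTuneConfig)

    def __post_init__(self):
        if self.n_episodes < 1:
            raise ValueError("n_episodes must be >= 1")
        if not self.k_values or any(k < 1 for k in self.k_values):
            raise ValueError("k_values must be non-empty and positive")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def episode_seed(master_seed: int, k: int, episode_index: int) -> int:
    """Deterministic per-episode seed, identical for every method (pairing)."""
    ss = np.random.SeedSequence([int(master_seed), int(k), int(episode_index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


class ResultTable:
    """Aggregated experiment results keyed by (method, k).

    ``frame`` holds mean/std accuracy and mean pseudo-label counts;
    ``per_episode`` maps (method, k) to the raw per-episode records.
    """

    def __init__(self, frame: pd.DataFrame, per_episode: dict | None = None,
                 config: dict | None = None):
        self.frame = frame.sort_values(["method", "k"]).reset_index(drop=True)
        self.per_episode = per_episode or {}
        self.config = config or {}
        bad = self.frame[(self.frame.mean_accuracy < 0) | (self.frame.mean_accuracy > 1)]
        if len(bad):
            raise ValueError("accuracies must lie in [0, 1]")

    @staticmethod
    def from_records(records: list, config: dict | None = None) -> "ResultTable":
        """Aggregate per-episode records (dicts with method, k, accuracy, ...)."""
        raw = pd.DataFrame(records)
        rows, per_episode = [], {}
        for (method, k), grp in raw.groupby(["method", "k"], sort=True):
            accs = grp["accuracy"].to_numpy()
            rows.append({
                "method": method,
                "k": int(k),
                "mean_accuracy": float(accs.mean()),
                "std_accuracy": float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
                "n_episodes": len(accs),
                "mean_n_pseudo_round1": float(grp.get("n_pseudo_round1", pd.Series(dtype=float)).mean()),
                "mean_n_pseudo_round2": float(grp.get("n_pseudo_round2", pd.Series(dtype=float)).mean()),
            })
            per_episode[(method, int(k))] = grp.reset_index(drop=True)
        return ResultTable(pd.DataFrame(rows), per_episode, config)

    @staticmethod
    def from_means(means: dict) -> "ResultTable":
        """Build a table from bare mean accuracies {(method, k): acc}.

        Used to run the improvement arithmetic on externally reported means.
        """
        rows = [
            {"method": m, "k": int(k), "mean_accuracy": float(a),
             "std_accuracy": float("nan"), "n_episodes": 0,
             "mean_n_pseudo_round1": float("nan"),
             "mean_n_pseudo_round2": float("nan")}
            for (m, k), a in means.items()
        ]
        return ResultTable(pd.DataFrame(rows))

    def mean_accuracy(self, method: str, k: int) -> float:
        sel = self.frame[(self.frame.method == method) & (self.frame.k == k)]
        if sel.empty:
            raise KeyError(f"no row for method={method!r}, k={k}")
        return float(sel.mean_accuracy.iloc[0])

    def accuracies(self, method: str, k: int) -> np.ndarray:
        return self.per_episode[(method, k)]["accuracy"].to_numpy()

    def __eq__(self, other) -> bool:
        if not isinstance(other, ResultTable):
            return NotImplemented
        if not self.frame.equals(other.frame):
            return False
        if set(self.per_episode) != set(other.per_episode):
            return False
        return all(self.per_episode[k].equals(other.per_episode[k])
                   for k in self.per_episode)


def run_experiment(cfg: ExperimentConfig, checkpoint: ModelSpec,
                   target: ClassIndexedDataset) -> ResultTable:
    """Run every method on paired episodes of the target domain.

    The backbone is frozen throughout, so features of the whole target
    dataset are computed once and shared across all episodes and methods.
    """
    if cfg.n_way > target.n_classes:
        raise ValueError("n_way exceeds the number of target classes")
    feats_by_class = [checkpoint.features(block) for block in target.images_by_class]

    records = []
    for k in cfg.k_values:
        for i in range(cfg.n_episodes):
            seed = episode_seed(cfg.master_seed, k, i)
            try:
                ep = sample_episode(target, EpisodeConfig(
                    cfg.n_way, k, cfg.n_query, cfg.unlabeled_per_class, seed))
                feats = {
                    "support": _gather(feats_by_class, ep.support_ci, ep.support_wi),
                    "query": _gather(feats_by_class, ep.query_ci, ep.query_wi),
                    "pool": _gather(feats_by_class, ep.pool_ci, ep.pool_wi),
                }
                model = replace_head(checkpoint, cfg.n_way, seed=seed)
                ft = FineTuneConfig(**{**asdict(cfg.ft), "seed": seed})
                for method in cfg.methods:
                    if method == "baseline":
                        acc, _ = _run_baseline_feats(model, feats, ep, ft)
                        res = {"accuracy": acc}
                    elif method == "single_ss":
                        res = _run_single_feats(model, feats, ep, cfg.rule, ft)
                        res["n_pseudo_round1"] = res.pop("n_pseudo")
                    else:
                        res = _run_iterative_feats(model, feats, ep, cfg.rule, ft)
                    records.append({"method": method, "k": k, "episode": i,
                                    "seed": seed, **res})
            except Exception as exc:
                raise RuntimeError(
                    f"episode failed (k={k}, episode={i}, seed={seed})") from exc
    return ResultTable.from_records(records, config=_config_dict(cfg))


def _gather(feats_by_class, ci, wi):
    return np.stack([feats_by_class[c][w] for c, w in zip(ci, wi)])


def _config_dict(cfg: ExperimentConfig) -> dict:
    d = asdict(cfg)
    d["k_values"] = list(cfg.k_values)
    d["methods"] = list(cfg.methods)
    return d


def summarize_improvement(table: ResultTable) -> dict:
    """Mean improvement over the baseline, in percentage points, per method.

    For each non-baseline method m present in the table:
    ``improvement_m = mean over k of (acc_m(k) - acc_baseline(k)) * 100``.
    The method rows must cover exactly the baseline's k values.
    """
    frame = table.frame
    base = frame[frame.method == "baseline"].set_index("k").mean_accuracy
    if base.empty:
        raise ValueError("table has no baseline rows")
    out = {}
    for method in frame.method.unique():
        if method == "baseline":
            continue
        accs = frame[frame.method == method].set_index("k").mean_accuracy
        if set(accs.index) != set(base.index):
            raise ValueError(f"method {method!r} does not cover the baseline's k values")
        out[method] = float((accs - base).mean() * 100.0)
    return out


def write_report(table: ResultTable, path) -> dict:
    """Write table CSV, JSON metadata and an accuracy-vs-k plot; returns paths."""
    if table.frame.empty:
        raise ValueError("cannot report an empty table")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    csv_path = path / "results.csv"
    table.frame.to_csv(csv_path, index=False)

    meta = {
        "config": table.config,
        "versions": {"leafshot": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "seeds": sorted({int(s) for grp in table.per_episode.values()
                         for s in grp.get("seed", pd.Series(dtype=int))}),
    }
    meta_path = path / "metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2))

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for method, grp in table.frame.groupby("method"):
        grp = grp.sort_values("k")
        ax.plot(grp.k, grp.mean_accuracy, marker="o", label=method)
    ax.set_xlabel("k-shot")
    ax.set_ylabel("mean accuracy")
    ax.legend()
    fig.tight_layout()
    plot_path = path / "accuracy_vs_k.png"
    fig.savefig(plot_path, dpi=120)
    plt.close(fig)
    return {"csv": csv_path, "metadata": meta_path, "plot": plot_path}


def published_table(split: str) -> ResultTable:
    """The published 5-way benchmark means for one domain split, as a table."""
    data = PUBLISHED_BENCHMARK_5WAY[split]
    return ResultTable.from_means({
        (method, k): acc
        for method, by_k in data.items() for k, acc in by_k.items()
    })
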