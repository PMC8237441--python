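"""Shared fixtures.

Model-building and the end-to-end benchmark are expensive (the CNN runs on
a NumPy engine), so anything reusable is session-scoped and built lazily.
"""

import numpy as np
import pytest

import leafshot as ls


@pytest.fixture(scope="session")
def backbone28():
    """Backbone built for a 28-class source domain (the standard split size)."""
    return ls.build_backbone((84, 84, 3), 28, seed=0)


@pytest.fixture(scope="session")
def tiny_target():
    """Small moderate-separability target domain: 6 classes x 20 images."""
    return ls.generate(ls.SyntheticSpec(n_classes=6, per_class=20, seed=5))


@pytest.fixture(scope="session")
def transferred6(backbone28):
    """The 28-class backbone transferred to a 6-class target head."""
    return ls.replace_head(backbone28, 6, seed=2)


@pytest.fixture(scope="session")
def tiny_episode(tiny_target):
    """A 3-way 2-shot episode with 3 queries per class on the tiny target."""
    return ls.sample_episode(
        tiny_target, ls.EpisodeConfig(n_way=3, k_shot=2, n_query=3, seed=9))


@pytest.fixture(scope="session")
def fast_ft():
    """Short head fine-tuning for unit tests of the episode protocols."""
    return ls.FineTuneConfig(epochs=25, seed=4)


@pytest.fixture(scope="session")
def benchmark_run():
    """The full paired synthetic benchmark (pretraining included); ~6 min CPU."""
    return ls.run_synthetic_benchmark(master_seed=0)
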