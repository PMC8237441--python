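"""Adaptive pseudo-label selection and the single / iterative protocols."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import leafshot as ls
from leafshot.semisup import SelectionRule, select_pseudo


def brute_force_select(labels, confidences, threshold):
    """Independent reference: a plain python filter."""
    return {i for i, c in enumerate(confidences) if c > threshold}


class TestSelection:
    def test_strict_inequality_at_the_boundary(self):
        sel = select_pseudo(np.array([0, 1, 2]),
                            np.array([0.999, 0.995, 0.2]), SelectionRule(0.995))
        assert sel.indices.tolist() == [0]
        assert sel.pseudo_labels.tolist() == [0]
        assert sel.confidences.tolist() == [0.999]

    def test_nothing_above_threshold_gives_empty_set(self):
        sel = select_pseudo(np.array([0, 1]), np.array([0.5, 0.995]),
                            SelectionRule(0.995))
        assert len(sel) == 0

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(1, 40))
            conf = rng.random(n)
            labels = rng.integers(0, 5, n)
            sel = select_pseudo(labels, conf, SelectionRule(0.7))
            assert set(sel.indices.tolist()) == brute_force_select(labels, conf, 0.7)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30),
           st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_lower_thresholds_select_supersets(self, confs, t1, t2):
        lo, hi = sorted((t1, t2))
        conf = np.array(confs)
        labels = np.zeros(len(conf), dtype=int)
        s_lo = set(select_pseudo(labels, conf, SelectionRule(lo)).indices.tolist())
        s_hi = set(select_pseudo(labels, conf, SelectionRule(hi)).indices.tolist())
        assert s_hi <= s_lo

    def test_length_mismatch_and_bad_threshold(self):
        with pytest.raises(ValueError):
            select_pseudo(np.array([0]), np.array([0.5, 0.6]), SelectionRule())
        with pytest.raises(ValueError):
            SelectionRule(1.0)
        with pytest.raises(ValueError):
            SelectionRule(0.0)


class TestPredictWithConfidence:
    def test_label_is_argmax_confidence_is_max(self, transferred6, tiny_target):
        x = tiny_target.images_by_class[0][:4]
        labels, conf = ls.predict_with_confidence(transferred6, x)
        probs = transferred6.forward(x)
        np.testing.assert_array_equal(labels, probs.argmax(axis=1))
        np.testing.assert_array_equal(conf, probs.max(axis=1))
        assert (conf <= 1.0).all() and (conf >= 1 / 6 - 1e-6).all()

    def test_batch_equals_per_sample_predictions(self, transferred6, tiny_target):
        x = tiny_target.images_by_class[1][:5]
        labels, conf = ls.predict_with_confidence(transferred6, x)
        for i in range(len(x)):
            li, ci = ls.predict_with_confidence(transferred6, x[i:i + 1])
            assert li[0] == labels[i]
            assert ci[0] == pytest.approx(conf[i], abs=1e-6)

    def test_empty_input_rejected(self, transferred6):
        with pytest.raises(ValueError):
            ls.predict_with_confidence(transferred6, np.zeros((0, 84, 84, 3)))


class TestProtocols:
    def test_no_selection_degrades_to_baseline(self, transferred6, tiny_episode, fast_ft):
        """With an unreachable threshold both SS protocols equal the baseline."""
        m = ls.replace_head(transferred6, 3, seed=7)
        rule = SelectionRule(0.999999)
        base = ls.run_baseline(m, tiny_episode, fast_ft)
        acc_s, n_s = ls.run_single_ss(m, tiny_episode, rule, fast_ft)
        acc_i, n1, n2 = ls.run_iterative_ss(m, tiny_episode, rule, fast_ft)
        assert n_s == 0 and n1 == 0 and n2 == 0
        assert acc_s == base
        assert acc_i == base

    def test_pseudo_labels_lie_in_episode_classes(self, transferred6, tiny_episode, fast_ft):
        m = ls.replace_head(transferred6, 3, seed=7)
        tuned = ls.fine_tune(m, tiny_episode.support_x, tiny_episode.support_y, fast_ft)
        labels, conf = ls.predict_with_confidence(tuned, tiny_episode.pool_x)
        sel = select_pseudo(labels, conf, SelectionRule(0.5),
                            samples=tiny_episode.pool_x)
        assert set(sel.pseudo_labels.tolist()) <= {0, 1, 2}
        assert len(sel.samples) == len(sel)
        assert (sel.indices < len(tiny_episode.pool_x)).all()

    def test_iterative_rounds_select_disjoint_samples(self, transferred6, tiny_target):
        """Round 2 only sees the pool minus round-1 selections."""
        from leafshot.fewshot import episode_features
        from leafshot.semisup import _select_from_feats, _run_iterative_feats
        ep = ls.sample_episode(tiny_target,
                               ls.EpisodeConfig(n_way=3, k_shot=3, n_query=3, seed=21))
        m = ls.replace_head(transferred6, 3, seed=3)
        # permissive rule so both rounds actually select
        rule = SelectionRule(0.5)
        cfg = ls.FineTuneConfig(epochs=40, seed=2)
        feats = episode_features(m, ep)
        res = _run_iterative_feats(m, feats, ep, rule, cfg)
        assert res["n_pseudo_round1"] + res["n_pseudo_round2"] <= len(ep.pool_true_y)
        acc, n1, n2 = ls.run_iterative_ss(m, ep, rule, cfg)
        assert (res["n_pseudo_round1"], res["n_pseudo_round2"]) == (n1, n2)
        assert 0.0 <= acc <= 1.0

    def test_protocols_do_not_mutate_the_checkpoint(self, transferred6, tiny_episode, fast_ft):
        m = ls.replace_head(transferred6, 3, seed=9)
        before = {n: (W.copy(), b.copy()) for n, (W, b) in m.conv_weights().items()}
        d128 = m.impl["dense_128"].W.copy()
        ls.run_single_ss(m, tiny_episode, SelectionRule(0.9), fast_ft)
        ls.run_iterative_ss(m, tiny_episode, SelectionRule(0.9), fast_ft)
        for n, (W, b) in m.conv_weights().items():
            np.testing.assert_array_equal(W, before[n][0])
        np.testing.assert_array_equal(m.impl["dense_128"].W, d128)
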