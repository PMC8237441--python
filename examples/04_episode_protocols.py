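"""One 5-way 5-shot episode: baseline vs. single vs. iterative self-training.

The baseline fine-tunes the two dense layers on the 25 support images and
scores 15 queries per class.  The semi-supervised protocols additionally
predict the episode's unlabeled pool and re-fine-tune on every sample whose
prediction confidence exceeds 99.5% (selected adaptively, once or twice).
A backbone pretrained on ten *different* synthetic classes provides the
frozen features.  Runtime is dominated by pretraining (~4 min on one core).
"""

import leafshot as ls

source = ls.generate(ls.SyntheticSpec(n_classes=10, per_class=30,
                                      separability=300.0, seed=1))
target = ls.generate(ls.SyntheticSpec(n_classes=10, per_class=60, seed=2))

backbone = ls.build_backbone((84, 84, 3), source.n_classes, seed=0)
ckpt, _ = ls.pretrain(backbone, source, ls.TrainConfig(max_epochs=4, patience=3, seed=0))

episode = ls.sample_episode(target, ls.EpisodeConfig(n_way=5, k_shot=5, seed=3))
model = ls.replace_head(ckpt, 5, seed=3)
ft = ls.FineTuneConfig(seed=3)
rule = ls.SelectionRule()  # confidence > 99.5%

acc_b = ls.run_baseline(model, episode, ft)
acc_s, n_pseudo = ls.run_single_ss(model, episode, rule, ft)
acc_i, n1, n2 = ls.run_iterative_ss(model, episode, rule, ft)

print(f"episode classes: {episode.class_names}")
print(f"baseline      : accuracy {acc_b:.3f}")
print(f"single SS     : accuracy {acc_s:.3f}  ({n_pseudo} pseudo-labels)")
print(f"iterative SS  : accuracy {acc_i:.3f}  ({n1} + {n2} pseudo-labels)")
print("\npseudo-label counts are chosen by the model itself: only pool samples")
print("predicted with >99.5% confidence are trusted for the next fine-tune.")
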