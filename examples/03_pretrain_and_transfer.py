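"""Pretrain the backbone on a source domain and transfer it.

Source-domain training uses batch size 16, Adam with default parameters,
categorical cross-entropy, and a stratified 20% validation split; the best
validation epoch is kept.  This example uses a small, easy source (6 classes
x 30 images, high separability) so it runs in ~2 minutes on one core.
"""

import leafshot as ls

source = ls.generate(ls.SyntheticSpec(n_classes=6, per_class=30,
                                      separability=300.0, seed=1))
model = ls.build_backbone((84, 84, 3), source.n_classes, seed=0)
best, history = ls.pretrain(model, source,
                            ls.TrainConfig(max_epochs=4, patience=3, seed=0))
print(history.to_string(index=False))
print(f"best epoch: {history.attrs['best_epoch']}")

transferred = ls.replace_head(best, 5, seed=2)
best.save("scratch_example_ckpt")
print(f"transferred head to 5 classes; trainable: {transferred.trainable_layers()}")
print("checkpoint written to scratch_example_ckpt.npz/.json")
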