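"""Build the CNN backbone and account for its parameters.

The network takes 84x84 RGB leaf images through seven 3x3 convolutions
(64-64-128-128-256-256-256 filters, same padding, two 2x2 max-pool stages),
a global average pool, a 128-unit dense layer and a softmax head.  The
printed table lists each layer's output shape and weight+bias count; after
transfer, only the two dense layers remain trainable.
"""

import leafshot as ls

model = ls.build_backbone((84, 84, 3), n_classes=28, seed=0)
print(f"{'layer':<12}{'kind':<16}{'output':<16}{'params':>10}")
for spec in model.layers:
    print(f"{spec.name:<12}{spec.kind:<16}{str(spec.output_shape):<16}"
          f"{spec.param_count:>10,}")
conv_total = sum(s.param_count for s in model.layers if s.kind == "conv")
print(f"\nconvolution stack total: {conv_total:,} parameters (frozen at transfer)")

transferred = ls.replace_head(model, 10, seed=1)
print(f"after transfer to a 10-class target: head has "
      f"{ls.count_parameters(transferred, 'dense_out'):,} parameters "
      f"(128*10 + 10); trainable layers: {transferred.trainable_layers()}")
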