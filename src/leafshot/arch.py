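"""The few-shot backbone: a compact VGG-style CNN for 84x84x3 leaf images.

The network is seven 3x3 same-padding convolutions (64, 64, 128, 128, 256,
256, 256 filters) interleaved with two 2x2 max-pool stages, a global average
pool, a 128-unit dense layer, and a softmax classification head whose width
N equals the number of classes.  There is no batch normalisation; every
parameterised layer carries weights plus biases only, so the parameter
counts are

    conv:  kh*kw*c_in*n_filters + n_filters
    dense: n_in*n_out + n_out

For transfer, :func:`replace_head` re-initialises the softmax head for the
target class count and freezes every convolution layer, leaving exactly the
two dense layers trainable.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn

#: (name, kind, width) rows of the backbone, input through head.
BACKBONE_PLAN = (
    ("input", "input", None),
    ("conv1", "conv", 64),
    ("conv2", "conv", 64),
    ("pool1", "maxpool", None),
    ("conv3", "conv", 128),
    ("conv4", "conv", 128),
    ("pool2", "maxpool", None),
    ("conv5", "conv", 256),
    ("conv6", "conv", 256),
    ("conv7", "conv", 256),
    ("gap", "globalavgpool", None),
    ("dense_128", "dense", 128),
    ("dense_out", "dense", None),  # width = n_classes
)

KERNEL = (3, 3)


@dataclass
class LayerSpec:
    """Static description of one layer: shape, parameter count, trainability."""

    name: str
    kind: str  # input | conv | maxpool | globalavgpool | dense
    output_shape: tuple
    n_filters_or_units: int | None = None
    kernel_size: tuple | None = None
    padding: str | None = None
    param_count: int = 0
    trainable: bool = False


class ModelSpec:
    """A built backbone: ordered :class:`LayerSpec` metadata plus live weights.

    ``impl`` maps layer name -> engine layer object (``None`` for the input
    row).  The softmax is applied by :meth:`forward`; the final dense layer
    itself produces logits.
    """

    def __init__(self, layers: list[LayerSpec], impl: dict, input_shape: tuple, head_classes: int):
        self.layers = layers
        self.impl = impl
        self.input_shape = tuple(input_shape)
        self.head_classes = int(head_classes)
        self._check()

    # -- construction helpers -------------------------------------------------

    def _check(self) -> None:
        for spec in self.layers:
            layer = self.impl.get(spec.name)
            if layer is None:
                if spec.param_count != 0:
                    raise ValueError(f"layer {spec.name} has no weights but param_count != 0")
                continue
            if getattr(layer, "has_params", False):
                stored = layer.W.size + layer.b.size
                if stored != spec.param_count:
                    raise ValueError(
                        f"layer {spec.name}: stored {stored} weights, spec says {spec.param_count}"
                    )

    def copy(self) -> "ModelSpec":
        """Deep copy: weight arrays are duplicated, never aliased."""
        impl = {}
        for spec in self.layers:
            layer = self.impl.get(spec.name)
            impl[spec.name] = copy.deepcopy(layer)
        return ModelSpec([copy.deepcopy(s) for s in self.layers], impl,
                         self.input_shape, self.head_classes)

    # -- introspection --------------------------------------------------------

    def layer(self, name: str) -> LayerSpec:
        for spec in self.layers:
            if spec.name == name:
                return spec
        raise KeyError(f"unknown layer: {name!r}")

    @property
    def layer_names(self) -> list[str]:
        return [s.name for s in self.layers]

    def trainable_layers(self) -> list[str]:
        return [s.name for s in self.layers if s.trainable and s.param_count > 0]

    def conv_weights(self) -> dict:
        """name -> (W, b) for every convolution layer (used by freeze checks)."""
        return {
            s.name: (self.impl[s.name].W, self.impl[s.name].b)
            for s in self.layers if s.kind == "conv"
        }

    # -- execution ------------------------------------------------------------

    def _ordered_impl(self):
        return [(s, self.impl[s.name]) for s in self.layers if self.impl.get(s.name) is not None]

    def _run(self, x: np.ndarray, upto: str | None = None, batch_size: int = 64) -> np.ndarray:
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim == 3:
            x = x[None]
        outs = []
        for lo in range(0, x.shape[0], batch_size):
            h = x[lo:lo + batch_size]
            for spec, layer in self._ordered_impl():
                h = layer.forward(h, train=False)
                if upto is not None and spec.name == upto:
                    break
            outs.append(h)
        return np.concatenate(outs, axis=0)

    def features(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Frozen-backbone representation: the global-average-pool output, (n, 256)."""
        return self._run(x, upto="gap", batch_size=batch_size)

    def logits(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        return self._run(x, upto=None, batch_size=batch_size)

    def forward(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities (softmax over the final dense layer)."""
        return nn.softmax(self.logits(x, batch_size=batch_size))

    def head_logits_from_features(self, feats: np.ndarray) -> np.ndarray:
        z = self.impl["dense_128"].forward(feats, train=False)
        return self.impl["dense_out"].forward(z, train=False)

    def head_probs_from_features(self, feats: np.ndarray) -> np.ndarray:
        return nn.softmax(self.head_logits_from_features(feats))

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        """Write ``<path>.npz`` (weights) and ``<path>.json`` (layer table + trainable mask)."""
        path = Path(path)
        arrays = {}
        for spec in self.layers:
            layer = self.impl.get(spec.name)
            if layer is not None and getattr(layer, "has_params", False):
                arrays[spec.name + "__W"] = layer.W
                arrays[spec.name + "__b"] = layer.b
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "input_shape": list(self.input_shape),
            "head_classes": self.head_classes,
            "layers": [asdict(s) for s in self.layers],
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @staticmethod
    def load(path) -> "ModelSpec":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        data = np.load(path.with_suffix(".npz"))
        specs = []
        impl = {}
        for row in meta["layers"]:
            row["output_shape"] = tuple(row["output_shape"])
            if row.get("kernel_size"):
                row["kernel_size"] = tuple(row["kernel_size"])
            spec = LayerSpec(**row)
            specs.append(spec)
            if spec.kind == "conv":
                impl[spec.name] = nn.Conv2D(
                    data[spec.name + "__W"], data[spec.name + "__b"],
                    relu=True, grad_input=spec.name != "conv1",
                )
            elif spec.kind == "dense":
                impl[spec.name] = nn.Dense(
                    data[spec.name + "__W"], data[spec.name + "__b"],
                    relu=spec.name == "dense_128",
                )
            elif spec.kind == "maxpool":
                impl[spec.name] = nn.MaxPool2x2()
            elif spec.kind == "globalavgpool":
                impl[spec.name] = nn.GlobalAvgPool()
            else:
                impl[spec.name] = None
        return ModelSpec(specs, impl, tuple(meta["input_shape"]), meta["head_classes"])


def build_backbone(input_shape=(84, 84, 3), n_classes: int = 28, seed: int = 0) -> ModelSpec:
    """Construct the backbone with Glorot-uniform weights; all layers trainable.

    ``input_shape`` is (height, width, channels); height and width must be
    divisible by 4 to survive the two pooling stages.
    """
    h, w, c = (int(v) for v in input_shape)
    if h <= 0 or w <= 0 or c <= 0:
        raise ValueError(f"input dimensions must be positive, got {input_shape}")
    if h % 4 or w % 4:
        raise ValueError("height and width must be divisible by 4 (two 2x2 pool stages)")
    if n_classes < 2:
        raise ValueError(f"n_classes must be >= 2, got {n_classes}")

    rng = np.random.default_rng(seed)
    specs: list[LayerSpec] = []
    impl: dict = {}
    cur = (h, w, c)
    for name, kind, width in BACKBONE_PLAN:
        if kind == "input":
            specs.append(LayerSpec(name, kind, cur))
            impl[name] = None
        elif kind == "conv":
            cin = cur[2]
            W = nn.he_uniform(rng, 9 * cin, (3, 3, cin, width))
            b = np.zeros(width, dtype=nn.DTYPE)
            cur = (cur[0], cur[1], width)
            specs.append(LayerSpec(name, kind, cur, width, KERNEL, "same",
                                   9 * cin * width + width, trainable=True))
            impl[name] = nn.Conv2D(W, b, relu=True, grad_input=name != "conv1")
        elif kind == "maxpool":
            cur = (cur[0] // 2, cur[1] // 2, cur[2])
            specs.append(LayerSpec(name, kind, cur))
            impl[name] = nn.MaxPool2x2()
        elif kind == "globalavgpool":
            cur = (cur[2],)
            specs.append(LayerSpec(name, kind, cur))
            impl[name] = nn.GlobalAvgPool()
        else:  # dense
            units = width if width is not None else n_classes
            n_in = cur[0]
            if name == "dense_128":  # ReLU layer: He; softmax head: Glorot
                W = nn.he_uniform(rng, n_in, (n_in, units))
            else:
                W = nn.glorot_uniform(rng, n_in, units, (n_in, units))
            b = np.zeros(units, dtype=nn.DTYPE)
            cur = (units,)
            specs.append(LayerSpec(name, kind, cur, units,
                                   param_count=n_in * units + units, trainable=True))
            impl[name] = nn.Dense(W, b, relu=name == "dense_128")
    return ModelSpec(specs, impl, (h, w, c), n_classes)


def replace_head(model: ModelSpec, n_target_classes: int, seed: int = 0) -> ModelSpec:
    """Transfer step: new Glorot-initialised softmax head of width N, zero biases.

    The returned model keeps every convolution weight bit-for-bit and the
    pretrained 128-unit dense layer; exactly the two dense layers are marked
    trainable and every convolution layer frozen.
    """
    if n_target_classes < 2:
        raise ValueError(f"n_target_classes must be >= 2, got {n_target_classes}")
    out = model.copy()
    rng = np.random.default_rng(seed)
    n_in = out.layer("dense_128").n_filters_or_units
    W = nn.glorot_uniform(rng, n_in, n_target_classes, (n_in, n_target_classes))
    b = np.zeros(n_target_classes, dtype=nn.DTYPE)
    out.impl["dense_out"] = nn.Dense(W, b, relu=False)
    for spec in out.layers:
        if spec.name == "dense_out":
            spec.output_shape = (n_target_classes,)
            spec.n_filters_or_units = n_target_classes
            spec.param_count = n_in * n_target_classes + n_target_classes
            spec.trainable = True
        elif spec.kind == "dense":
            spec.trainable = True
        else:
            spec.trainable = False
    out.head_classes = n_target_classes
    out._check()
    return out


def count_parameters(model: ModelSpec, layer_name: str) -> int:
    """Number of scalar weights + biases stored in the named layer."""
    spec = model.layer(layer_name)
    layer = model.impl.get(spec.name)
    if layer is None or not getattr(layer, "has_params", False):
        return 0
    n = int(layer.W.size + layer.b.size)
    assert n == spec.param_count
    return n
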