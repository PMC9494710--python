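"""The four gesture-classifier architectures and their size accounting.

Variants (all over a ``200 x 6 x 1`` input window, 16 classes):

* ``CNN`` — one 40x6 convolution (128 maps) + flatten classifier;
* ``CNN_LSTM`` — the same convolution feeding a 32-unit LSTM;
* ``CNN2D_LSTM`` — two convolutions (40x6 -> 128 maps, same padding;
  20x6 -> 8 maps, valid), reshaped to a 181x8 sequence, 32-unit LSTM;
* ``CNN2D_LSTM2D`` — as above with stacked 32- then 16-unit LSTMs.

Two size measures coexist deliberately.  ``size_estimate`` reproduces the
embedded-deployment budgeting convention this project targets: a conv layer
counts kernel_h*kernel_w*n_out*n_in, a reshape counts the product of its
output dims, an LSTM counts flattened-input-length*hidden, everything else
counts zero, and a literal list of training variables (128, 20, 32) is
added; kilobytes are total*4/1024.  That convention ignores biases and LSTM
gate quadrupling, so ``count_trainable_params`` provides the standard count
(conv (kh*kw*c_in+1)*c_out, dense (in+1)*out, LSTM 4*((in+hidden+1)*hidden))
which matches the training engine's own parameter arrays exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import prod

import numpy as np

from . import nn

VARIANTS = ("CNN", "CNN_LSTM", "CNN2D_LSTM", "CNN2D_LSTM2D")

DEFAULT_TRAINING_VARIABLES = (128, 20, 32)
BYTES_PER_PARAM = 4  # float32


@dataclass
class LayerSpec:
    """Declarative description of one layer in an architecture."""

    kind: str  # conv | maxpool | reshape | lstm | dropout | dense | leaky_relu | softmax
    kernel_h: int = 0
    kernel_w: int = 0
    n_in_maps: int = 0
    n_out_maps: int = 0
    padding_mode: str = "valid"  # same | valid | same_time
    pool_h: int = 1
    pool_w: int = 1
    reshape_mode: str = "seq"  # seq: (H,W,C)->(H, W*C); flat: (H,W,C)->(H*W*C,)
    hidden_units: int = 0
    return_sequences: bool = False
    dropout_rate: float = 0.0
    units: int = 0

    def __post_init__(self) -> None:
        if self.kind == "conv" and (self.kernel_h < 1 or self.kernel_w < 1):
            raise ValueError("conv kernel dims must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class ArchitectureSpec:
    """One network variant, layer by layer, plus its input contract."""

    variant: str
    layers: list[LayerSpec]
    input_shape: tuple[int, int, int] = (200, 6, 1)
    n_classes: int = 16

    def output_shapes(self) -> list[tuple[int, ...]]:
        """Chain per-layer output shapes; raises naming the offending layer."""
        return _chain_shapes(self)

    def to_json(self) -> str:
        return json.dumps(
            {
                "variant": self.variant,
                "input_shape": list(self.input_shape),
                "n_classes": self.n_classes,
                "layers": [vars(l) for l in self.layers],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        obj = json.loads(text)
        return cls(
            variant=obj["variant"],
            layers=[LayerSpec(**l) for l in obj["layers"]],
            input_shape=tuple(obj["input_shape"]),
            n_classes=obj["n_classes"],
        )


@dataclass
class SizeReport:
    """Budget-convention and true sizes of one architecture."""

    per_layer_sizes: list[tuple[str, int]]
    training_variables: list[int]
    total: int
    kilobytes: float
    trainable_params: int
    serialized_bytes: int | None = None

    def as_dict(self) -> dict:
        return {
            "per_layer_sizes": [[n, int(c)] for n, c in self.per_layer_sizes],
            "training_variables": [int(v) for v in self.training_variables],
            "total": int(self.total),
            "kilobytes": float(self.kilobytes),
            "trainable_params": int(self.trainable_params),
            "serialized_bytes": self.serialized_bytes,
        }

    def table(self) -> str:
        lines = [f"{'layer':<24}{'size':>12}"]
        for name, count in self.per_layer_sizes:
            lines.append(f"{name:<24}{count:>12}")
        lines.append(f"{'training variables':<24}{sum(self.training_variables):>12}")
        lines.append(f"{'total':<24}{self.total:>12}")
        lines.append(f"{'kilobytes':<24}{self.kilobytes:>12.2f}")
        lines.append(f"{'trainable params':<24}{self.trainable_params:>12}")
        return "\n".join(lines)


def _conv_out(h: int, w: int, l: LayerSpec) -> tuple[int, int]:
    def out(n, k, same):
        return n if same else n - k + 1

    same_h = l.padding_mode in ("same", "same_time")
    same_w = l.padding_mode == "same"
    ho, wo = out(h, l.kernel_h, same_h), out(w, l.kernel_w, same_w)
    if ho < 1 or wo < 1:
        raise ValueError(
            f"conv kernel {l.kernel_h}x{l.kernel_w} ({l.padding_mode}) does not fit "
            f"input {h}x{w}"
        )
    return ho, wo


def _chain_shapes(spec: ArchitectureSpec) -> list[tuple[int, ...]]:
    shape: tuple[int, ...] = tuple(spec.input_shape)
    shapes = []
    for idx, l in enumerate(spec.layers):
        where = f"layer {idx} ({l.kind})"
        if l.kind == "conv":
            if len(shape) != 3:
                raise ValueError(f"{where}: expected 3-D input, got {shape}")
            h, w, c = shape
            if c != l.n_in_maps:
                raise ValueError(f"{where}: {c} input maps, spec says {l.n_in_maps}")
            shape = (*_conv_out(h, w, l), l.n_out_maps)
        elif l.kind == "maxpool":
            h, w, c = shape
            shape = (h // l.pool_h, w // l.pool_w, c)
        elif l.kind == "reshape":
            if len(shape) != 3:
                raise ValueError(f"{where}: expected 3-D input, got {shape}")
            h, w, c = shape
            shape = (h * w * c,) if l.reshape_mode == "flat" else (h, w * c)
        elif l.kind == "lstm":
            if len(shape) != 2:
                raise ValueError(f"{where}: LSTM needs a (T, F) sequence, got {shape}")
            shape = (shape[0], l.hidden_units) if l.return_sequences else (l.hidden_units,)
        elif l.kind == "dense":
            if len(shape) != 1:
                raise ValueError(f"{where}: dense needs a flat input, got {shape}")
            shape = (l.units,)
        elif l.kind in ("dropout", "leaky_relu", "softmax"):
            pass
        else:
            raise ValueError(f"{where}: unknown layer kind {l.kind!r}")
        shapes.append(shape)
    if shapes[-1] != (spec.n_classes,):
        raise ValueError(
            f"architecture output {shapes[-1]} does not match n_classes={spec.n_classes}"
        )
    return shapes


def build_architecture(
    variant: str,
    input_shape: tuple[int, int, int] = (200, 6, 1),
    n_classes: int = 16,
    conv1_kernel: tuple[int, int] = (40, 6),
    conv1_maps: int = 128,
    conv2_kernel: tuple[int, int] = (20, 6),
    conv2_maps: int = 8,
    lstm_units: int = 32,
    lstm2_units: int = 16,
    dropout: float = 0.2,
    pool_size: int = 1,
) -> ArchitectureSpec:
    """Construct one of the four variants with overridable hyperparameters."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    c_in = input_shape[2]
    layers: list[LayerSpec] = []
    two_d = variant in ("CNN2D_LSTM", "CNN2D_LSTM2D")
    # the single-conv variants collapse the channel axis immediately; the
    # two-conv variants keep it (same padding) so the 20x6 kernel can span it
    layers.append(
        LayerSpec(
            kind="conv",
            kernel_h=conv1_kernel[0],
            kernel_w=conv1_kernel[1],
            n_in_maps=c_in,
            n_out_maps=conv1_maps,
            padding_mode="same" if two_d else "same_time",
        )
    )
    layers.append(LayerSpec(kind="maxpool", pool_h=pool_size, pool_w=1))
    if two_d:
        layers.append(
            LayerSpec(
                kind="conv",
                kernel_h=conv2_kernel[0],
                kernel_w=conv2_kernel[1],
                n_in_maps=conv1_maps,
                n_out_maps=conv2_maps,
                padding_mode="valid",
            )
        )
        layers.append(LayerSpec(kind="maxpool", pool_h=pool_size, pool_w=1))
    if variant == "CNN":
        layers.append(LayerSpec(kind="reshape", reshape_mode="flat"))
    else:
        layers.append(LayerSpec(kind="reshape", reshape_mode="seq"))
        if variant == "CNN2D_LSTM2D":
            layers.append(
                LayerSpec(kind="lstm", hidden_units=lstm_units, return_sequences=True)
            )
            layers.append(LayerSpec(kind="lstm", hidden_units=lstm2_units))
        else:
            layers.append(LayerSpec(kind="lstm", hidden_units=lstm_units))
    layers.append(LayerSpec(kind="dropout", dropout_rate=dropout))
    layers.append(LayerSpec(kind="dense", units=n_classes))
    layers.append(LayerSpec(kind="leaky_relu"))
    layers.append(LayerSpec(kind="softmax"))
    spec = ArchitectureSpec(variant, layers, tuple(input_shape), n_classes)
    spec.output_shapes()  # validate the chain eagerly
    return spec


def size_estimate(
    spec: ArchitectureSpec,
    training_variables: tuple[int, ...] = DEFAULT_TRAINING_VARIABLES,
) -> SizeReport:
    """Embedded flash budget under the kernel-volume accounting convention."""
    shapes = spec.output_shapes()
    in_shapes = [tuple(spec.input_shape)] + shapes[:-1]
    per_layer: list[tuple[str, int]] = []
    for idx, (l, s_in, s_out) in enumerate(zip(spec.layers, in_shapes, shapes)):
        if l.kind == "conv":
            count = l.kernel_h * l.kernel_w * l.n_out_maps * l.n_in_maps
        elif l.kind == "reshape":
            count = prod(s_out)
        elif l.kind == "lstm":
            count = prod(s_in) * l.hidden_units
        else:
            continue
        per_layer.append((f"{idx}:{l.kind}", count))
    total = sum(c for _, c in per_layer) + sum(training_variables)
    return SizeReport(
        per_layer_sizes=per_layer,
        training_variables=list(training_variables),
        total=total,
        kilobytes=total * BYTES_PER_PARAM / 1024.0,
        trainable_params=count_trainable_params(spec),
    )


def count_trainable_params(spec: ArchitectureSpec) -> int:
    """Standard trainable-parameter count (weights + biases, 4x LSTM gates)."""
    shapes = spec.output_shapes()
    in_shapes = [tuple(spec.input_shape)] + shapes[:-1]
    total = 0
    for l, s_in in zip(spec.layers, in_shapes):
        if l.kind == "conv":
            total += (l.kernel_h * l.kernel_w * l.n_in_maps + 1) * l.n_out_maps
        elif l.kind == "lstm":
            total += 4 * ((s_in[-1] + l.hidden_units + 1) * l.hidden_units)
        elif l.kind == "dense":
            total += (s_in[-1] + 1) * l.units
    return total


def build_network(spec: ArchitectureSpec, seed: int = 0) -> nn.Network:
    """Instantiate the architecture in the numpy training engine."""
    rng = np.random.default_rng(seed)
    shapes = spec.output_shapes()
    in_shapes = [tuple(spec.input_shape)] + shapes[:-1]
    layers: list[nn.Param | object] = []
    for idx, (l, s_in, s_out) in enumerate(zip(spec.layers, in_shapes, shapes)):
        if l.kind == "conv":
            layers.append(
                nn.Conv2D(
                    l.kernel_h, l.kernel_w, l.n_in_maps, l.n_out_maps,
                    padding=l.padding_mode, rng=rng, name=f"conv{idx}",
                )
            )
        elif l.kind == "maxpool":
            layers.append(nn.MaxPool2D(l.pool_h, l.pool_w))
        elif l.kind == "reshape":
            layers.append(nn.Reshape(s_out))
        elif l.kind == "lstm":
            layers.append(
                nn.LSTM(
                    s_in[-1], l.hidden_units, return_sequences=l.return_sequences,
                    rng=rng, name=f"lstm{idx}",
                )
            )
        elif l.kind == "dropout":
            layers.append(nn.Dropout(l.dropout_rate))
        elif l.kind == "dense":
            layers.append(nn.Dense(s_in[-1], l.units, rng=rng, name=f"dense{idx}"))
        elif l.kind == "leaky_relu":
            layers.append(nn.LeakyReLU())
        elif l.kind == "softmax":
            pass  # folded into the cross-entropy head
    net = nn.Network(layers, seed=seed)
    expected = count_trainable_params(spec)
    if net.n_params() != expected:
        raise AssertionError(
            f"engine reports {net.n_params()} parameters, declarative count is {expected}"
        )
    return net
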