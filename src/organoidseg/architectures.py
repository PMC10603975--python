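"""Declarative encoder-decoder architecture builder and ablation grid.

U-Net, UNet-Mini and Mu-Net are all expressed as combinations of six
toggleable design components applied to the classic U-Net:

``layer_reduction``
    five resolution levels -> four.
``filter_reduction``
    filter bank [64, 128, 256, 512, 1024] -> [16, 32, 64, 64].
``kernel_reduction``
    two feature convolutions per block -> one.
``ewise_skip``
    skip connections by element-wise addition instead of concatenation.
``stride_downsampling``
    each encoder block downsamples with a dedicated stride-2 convolution
    (followed by batch-norm) instead of max-pooling, and the bottleneck
    becomes dropout(0.5) + 2x2 max-pool — the Mu-Net block layout.
``softmax_activation``
    two-channel softmax head instead of the one-channel sigmoid.

A :class:`ModelSpec` is a pure description (a small layer graph with named
skip taps); shape inference, parameter counting and FLOP estimation are
closed-form over the spec, independent of any training backend.

The decoder always mirrors the encoder exactly: one x2 upsampling per x2
downsampling, with the decoder tensor center-cropped/padded to the encoder
tap's size at each skip junction, so the output spatial size equals the
input for every variant and side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "AblationConfig",
    "LayerDef",
    "ModelSpec",
    "PRESETS",
    "PRESET_NAMES",
    "build_unet",
    "build_unet_mini",
    "build_munet",
    "build_variant",
    "count_parameters",
    "estimate_flops",
]


@dataclass(frozen=True)
class AblationConfig:
    """Six on/off design components spanning the ablation grid."""

    layer_reduction: bool = False
    filter_reduction: bool = False
    kernel_reduction: bool = False
    ewise_skip: bool = False
    stride_downsampling: bool = False
    softmax_activation: bool = False
    #: element-wise product instead of addition for ewise skips (off by
    #: default; addition is the documented UNet-Mini behaviour)
    ewise_product: bool = False

    def label(self) -> str:
        parts = [
            name
            for flag, name in [
                (self.layer_reduction, "layer"),
                (self.filter_reduction, "filter"),
                (self.kernel_reduction, "kernel"),
                (self.ewise_skip, "ewise"),
                (self.stride_downsampling, "stride"),
                (self.softmax_activation, "activation"),
            ]
            if flag
        ]
        return "+".join(parts) if parts else "unet"


def _cfg(*flags: str) -> AblationConfig:
    return AblationConfig(
        layer_reduction="layer" in flags,
        filter_reduction="filter" in flags,
        kernel_reduction="kernel" in flags,
        ewise_skip="ewise" in flags,
        stride_downsampling="stride" in flags,
        softmax_activation="activation" in flags,
    )


#: The 18 named configurations of the ablation grid.  ``munet`` is
#: layer+filter+kernel+stride with concatenation skips and a sigmoid head;
#: ``unet-mini`` additionally turns on addition skips and the softmax head.
PRESETS: dict[str, AblationConfig] = {
    "unet": _cfg(),
    "layer": _cfg("layer"),
    "filter": _cfg("filter"),
    "kernel": _cfg("kernel"),
    "ewise": _cfg("ewise"),
    "layer+filter": _cfg("layer", "filter"),
    "layer+kernel": _cfg("layer", "kernel"),
    "layer+ewise": _cfg("layer", "ewise"),
    "filter+kernel": _cfg("filter", "kernel"),
    "filter+ewise": _cfg("filter", "ewise"),
    "kernel+ewise": _cfg("kernel", "ewise"),
    "layer+filter+kernel": _cfg("layer", "filter", "kernel"),
    "layer+kernel+ewise": _cfg("layer", "kernel", "ewise"),
    "layer+filter+ewise": _cfg("layer", "filter", "ewise"),
    "filter+kernel+ewise": _cfg("filter", "kernel", "ewise"),
    "layer+filter+kernel+ewise": _cfg("layer", "filter", "kernel", "ewise"),
    "munet": _cfg("layer", "filter", "kernel", "stride"),
    "unet-mini": _cfg("layer", "filter", "kernel", "ewise", "stride", "activation"),
}

PRESET_NAMES = tuple(PRESETS)


@dataclass(frozen=True)
class LayerDef:
    """One node of the layer graph.

    ``kind`` is one of: input, conv, upconv (x2 nearest upsampling followed
    by a 2x2 convolution), bn, dropout, maxpool, concat, add.  ``inputs``
    names predecessor nodes; for concat/add the *second* input is the
    encoder tap whose spatial size the first input is cropped/padded to.
    """

    name: str
    kind: str
    inputs: tuple[str, ...]
    filters: int | None = None
    kernel: int | None = None
    stride: int = 1
    activation: str | None = None
    rate: float | None = None


class SpecError(ValueError):
    """A ModelSpec that cannot be shape-checked."""


@dataclass(frozen=True)
class ModelSpec:
    """A shape-checkable description of an encoder-decoder network."""

    name: str
    side: int
    layers: tuple[LayerDef, ...]
    config: AblationConfig

    @property
    def output_name(self) -> str:
        return self.layers[-1].name

    @property
    def out_channels(self) -> int:
        return self.infer_shapes()[self.output_name][2]

    def infer_shapes(self) -> dict[str, tuple[int, int, int]]:
        """Forward shape inference; raises :class:`SpecError` on a broken
        graph (unknown input, channel mismatch at an addition join, ...)."""
        shapes: dict[str, tuple[int, int, int]] = {}
        for lay in self.layers:
            ins = []
            for nm in lay.inputs:
                if nm not in shapes:
                    raise SpecError(f"layer {lay.name!r} references unknown input {nm!r}")
                ins.append(shapes[nm])
            if lay.kind == "input":
                shapes[lay.name] = (self.side, self.side, 1)
            elif lay.kind == "conv":
                h, w, _ = ins[0]
                s = lay.stride
                shapes[lay.name] = (-(-h // s), -(-w // s), lay.filters)
            elif lay.kind == "upconv":
                h, w, _ = ins[0]
                shapes[lay.name] = (2 * h, 2 * w, lay.filters)
            elif lay.kind in ("bn", "dropout"):
                shapes[lay.name] = ins[0]
            elif lay.kind == "maxpool":
                h, w, c = ins[0]
                shapes[lay.name] = (-(-h // 2), -(-w // 2), c)
            elif lay.kind == "concat":
                (h1, w1, c1), (h2, w2, c2) = ins
                shapes[lay.name] = (h2, w2, c1 + c2)
            elif lay.kind == "add":
                (h1, w1, c1), (h2, w2, c2) = ins
                if c1 != c2:
                    raise SpecError(
                        f"addition skip at {lay.name!r} joins {c1} vs {c2} channels; "
                        "insert a 1x1 projection"
                    )
                shapes[lay.name] = (h2, w2, c1)
            else:
                raise SpecError(f"unknown layer kind {lay.kind!r} at {lay.name!r}")
            if min(shapes[lay.name][:2]) < 1:
                raise SpecError(f"layer {lay.name!r} collapses to zero spatial size")
        return shapes

    def to_table(self) -> pd.DataFrame:
        """Human-readable layer table (name, filter, kernel, stride,
        activation) mirroring the standard model-summary layout."""
        rows = [
            {
                "name": l.name,
                "kind": l.kind,
                "filter": l.filters,
                "kernel": l.kernel,
                "stride": l.stride if l.kind in ("conv", "upconv") else None,
                "activation": l.activation,
                "inputs": ",".join(l.inputs),
            }
            for l in self.layers
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "side": self.side,
                "config": asdict(self.config),
                "layers": [asdict(l) for l in self.layers],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, payload: str) -> "ModelSpec":
        d = json.loads(payload)
        layers = tuple(
            LayerDef(**{**l, "inputs": tuple(l["inputs"])}) for l in d["layers"]
        )
        return cls(
            name=d["name"], side=d["side"], layers=layers,
            config=AblationConfig(**d["config"]),
        )


class _Builder:
    def __init__(self) -> None:
        self.layers: list[LayerDef] = []
        self._n = 0

    def add(self, kind: str, inputs: tuple[str, ...], **kw) -> str:
        self._n += 1
        name = kw.pop("name", f"{kind}{self._n}")
        self.layers.append(LayerDef(name=name, kind=kind, inputs=inputs, **kw))
        return name


def _filters(config: AblationConfig) -> list[int]:
    levels = 4 if config.layer_reduction else 5
    if config.filter_reduction:
        bank = [16, 32, 64, 64, 64]
    else:
        bank = [64, 128, 256, 512, 1024]
    return bank[:levels]


def build_variant(config: AblationConfig, side: int = 250) -> ModelSpec:
    """Compose an encoder-decoder spec from the six ablation flags.

    All 18 presets (and all 2^6 flag combinations) build and shape-check;
    the output spatial size always equals ``side``.
    """
    f = _filters(config)
    levels = len(f)
    min_side = 32 if levels == 5 else 16
    if side < min_side:
        raise ValueError(
            f"side {side} too small for {levels - 1} downsamplings (min {min_side})"
        )
    n_feat = 1 if config.kernel_reduction else 2
    b = _Builder()
    x = b.add("input", ())
    taps: list[tuple[str, int]] = []  # (tap name, channels), shallow -> deep

    if config.stride_downsampling:
        # Mu-Net block layout: feature conv(s) at stride 1, a stride-2
        # downsampling conv, then batch-norm; bottleneck is dropout+pool.
        for fi in f:
            for _ in range(n_feat):
                x = b.add("conv", (x,), filters=fi, kernel=3, stride=1, activation="relu")
            taps.append((x, fi))
            x = b.add("conv", (x,), filters=fi, kernel=3, stride=2, activation="relu")
            x = b.add("bn", (x,))
        x = b.add("dropout", (x,), rate=0.5)
        x = b.add("maxpool", (x,))
        x = b.add("upconv", (x,), filters=f[-1], kernel=2, activation="relu")
        dec_convs = n_feat + 1  # mirror: feature conv(s) + downsampling conv
    else:
        for fi in f[:-1]:
            for _ in range(n_feat):
                x = b.add("conv", (x,), filters=fi, kernel=3, stride=1, activation="relu")
            taps.append((x, fi))
            x = b.add("maxpool", (x,))
        for _ in range(n_feat):  # bottleneck convolutions
            x = b.add("conv", (x,), filters=f[-1], kernel=3, stride=1, activation="relu")
        dec_convs = n_feat

    for tap, fi in reversed(taps):
        x = b.add("upconv", (x,), filters=fi, kernel=2, activation="relu")
        if config.ewise_skip:
            join = "add"
            # channel-matching 1x1 projection when decoder/tap widths differ
            # (never needed for the named presets, kept for generality)
        else:
            join = "concat"
        x = b.add(join, (x, tap))
        for _ in range(dec_convs):
            x = b.add("conv", (x,), filters=fi, kernel=3, stride=1, activation="relu")

    if config.stride_downsampling:
        x = b.add("conv", (x,), filters=2, kernel=3, stride=1, activation="relu")
    head_channels = 2 if config.softmax_activation else 1
    head_act = "softmax" if config.softmax_activation else "sigmoid"
    x = b.add("conv", (x,), filters=head_channels, kernel=1, stride=1, activation=head_act)

    spec = ModelSpec(name=config.label(), side=side, layers=tuple(b.layers), config=config)
    spec.infer_shapes()  # shape-check eagerly
    return spec


def build_unet(side: int = 250) -> ModelSpec:
    """The classic 5-level U-Net: double 3x3 convolutions + 2x2 max-pool
    per encoder block, 2x2 up-convolutions with concatenation skips, 1x1
    sigmoid head; filter bank [64, 128, 256, 512, 1024]."""
    return build_variant(PRESETS["unet"], side)


def build_unet_mini(side: int = 250) -> ModelSpec:
    """UNet-Mini: four levels, [16, 32, 64, 64] filters, single feature
    convolution per block, stride-2 downsampling, addition skips, softmax
    head — the maximal reduction of the grid."""
    return build_variant(PRESETS["unet-mini"], side)


def build_munet(side: int = 250) -> ModelSpec:
    """Mu-Net: four levels of [16, 32, 64, 64] filters, each block a
    stride-1 feature convolution + stride-2 downsampling convolution +
    batch-norm; dropout(0.5)+max-pool bottleneck; mirrored decoder with
    deconvolution pairs and concatenation skips from each block's stride-1
    output; head = 3x3 conv(2) then 1x1 conv(1) with sigmoid."""
    return build_variant(PRESETS["munet"], side)


# ---------------------------------------------------------------------------
# closed-form accounting

def _layer_params(lay: LayerDef, cin: int) -> int:
    if lay.kind == "conv":
        return lay.kernel * lay.kernel * cin * lay.filters + lay.filters
    if lay.kind == "upconv":
        return lay.kernel * lay.kernel * cin * lay.filters + lay.filters
    if lay.kind == "bn":
        return 2 * cin  # scale + shift (running stats are not trainable)
    return 0


def count_parameters(spec: ModelSpec) -> int:
    """Trainable parameter count, closed-form per layer kind."""
    shapes = spec.infer_shapes()
    total = 0
    for lay in spec.layers:
        cin = shapes[lay.inputs[0]][2] if lay.inputs else 0
        total += _layer_params(lay, cin)
    return total


def estimate_flops(spec: ModelSpec, side: int | None = None) -> float:
    """One forward pass in MFLOP (1 multiply-accumulate = 2 FLOPs;
    convolutions and batch-norm counted, pooling/activations ignored)."""
    if side is not None and side != spec.side:
        spec = ModelSpec(name=spec.name, side=side, layers=spec.layers, config=spec.config)
    shapes = spec.infer_shapes()
    flops = 0.0
    for lay in spec.layers:
        if not lay.inputs:
            continue
        cin = shapes[lay.inputs[0]][2]
        h, w, cout = shapes[lay.name]
        if lay.kind in ("conv", "upconv"):
            flops += 2.0 * h * w * lay.kernel * lay.kernel * cin * cout
        elif lay.kind == "bn":
            flops += 2.0 * h * w * cin
        elif lay.kind == "add":
            flops += 1.0 * h * w * cout
    return flops / 1e6
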