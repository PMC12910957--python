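"""The hybrid dilated/gated/depthwise-separable occupancy network (HDGS-Net).

The network maps a 16 x 146 x 1 dinucleotide one-hot matrix to a single
occupancy value.  After a global input batch normalization it applies four
parallel-branch convolution stages, each followed by batch normalization,
40 % dropout and a 1x3 stride-3 max pool:

* Conv Module A (applied twice) — five branches, 128 channels each:
  1x1, 1x3, 1x7 gated convolutions; 1x7 dilated conv (rate 3); 1x11 dilated
  conv (rate 5); concatenated output 640 channels.
* Conv Module B — four branches, 128 channels each: 1x1, 1x3, 1x7 gated;
  1x7 dilated (rate 3); output 512 channels.
* Conv Module C — three branches, 64 channels each: 1x1 and 1x3 gated,
  1x3 dilated (rate 2); the K>1 branches are depthwise separable
  (depthwise 1xK over the 512 input channels, then pointwise to 64), the
  cascaded separable stage of the architecture; output 192 channels.

All kernels are 1xK (height one), so the 16-row dinucleotide axis is carried
untouched to the flatten stage; the width trace under the four pools is
146 -> 48 -> 16 -> 5 -> 1 and the flattened feature vector has
16 * 1 * 192 = 3072 entries, feeding a fully connected 256 -> 32 -> 1 head.
Dilated branches are followed by ReLU; gated branches use their sigmoid gate
as the nonlinearity.  The regression head ends in ReLU (occupancy is
non-negative); the classification head ends in a sigmoid.

The reference configuration has 6,628,227 trainable parameters (6.6 M).
A scaled-down configuration (all branch channel widths divided by an integer
factor, default 8) preserves the full shape trace at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .nn import (BatchNorm, Conv1d, Dense, Dropout, Flatten, GatedConv, Layer,
                 MaxPool1d, Parallel, ReLU, SeparableConv1d, Sequential,
                 Sigmoid)

__all__ = [
    "BranchSpec", "ConvModuleSpec", "HDGSModelConfig", "HDGSNet",
    "reference_config", "build_hdgs", "count_parameters", "forward",
    "parameter_table", "reference_parameter_table",
]


@dataclass(frozen=True)
class BranchSpec:
    """One parallel branch: gated ('gc') or dilated ('dc') convolution."""

    kind: str                 # 'gc' | 'dc'
    kernel: int
    dilation: int = 1
    separable: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("gc", "dc"):
            raise ValueError(f"branch kind must be 'gc' or 'dc', got {self.kind!r}")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError("kernel width must be odd and positive")
        if self.dilation < 1:
            raise ValueError("dilation rate must be >= 1")


@dataclass(frozen=True)
class ConvModuleSpec:
    name: str
    branches: tuple[BranchSpec, ...]
    channels_per_branch: int

    @property
    def out_channels(self) -> int:
        return len(self.branches) * self.channels_per_branch


@dataclass(frozen=True)
class HDGSModelConfig:
    """Full architectural description of the network."""

    modules: tuple[ConvModuleSpec, ...]
    input_height: int = 16
    input_width: int = 146
    fc_widths: tuple[int, ...] = (256, 32)
    dropout: float = 0.4
    pool_width: int = 3
    head: str = "regression"  # or "classification"

    def __post_init__(self) -> None:
        if self.head not in ("regression", "classification"):
            raise ValueError(f"unknown head {self.head!r}")

    def scaled(self, factor: int) -> "HDGSModelConfig":
        """Divide every branch channel width by ``factor`` (shape trace and
        fully connected widths unchanged)."""
        mods = tuple(replace(m, channels_per_branch=max(1, m.channels_per_branch // factor))
                     for m in self.modules)
        return replace(self, modules=mods)


_MODULE_A = ConvModuleSpec("A", (
    BranchSpec("gc", 1), BranchSpec("gc", 3), BranchSpec("gc", 7),
    BranchSpec("dc", 7, dilation=3), BranchSpec("dc", 11, dilation=5),
), channels_per_branch=128)

_MODULE_B = ConvModuleSpec("B", (
    BranchSpec("gc", 1), BranchSpec("gc", 3), BranchSpec("gc", 7),
    BranchSpec("dc", 7, dilation=3),
), channels_per_branch=128)

_MODULE_C = ConvModuleSpec("C", (
    BranchSpec("gc", 1), BranchSpec("gc", 3, separable=True),
    BranchSpec("dc", 3, dilation=2, separable=True),
), channels_per_branch=64)


def reference_config(scale: int = 1, head: str = "regression") -> HDGSModelConfig:
    """The published architecture: modules A, A, B, C with branch widths
    128/128/128/64; ``scale`` > 1 divides every branch width for desk-scale
    work while keeping the 146 -> 48 -> 16 -> 5 -> 1 shape trace."""
    cfg = HDGSModelConfig(modules=(_MODULE_A, _MODULE_A, _MODULE_B, _MODULE_C),
                          head=head)
    return cfg.scaled(scale) if scale > 1 else cfg


def _build_branch(spec: BranchSpec, c_in: int, c_out: int,
                  rng: np.random.Generator) -> Layer:
    if spec.kind == "gc":
        return GatedConv(c_in, c_out, spec.kernel, spec.dilation,
                         separable=spec.separable, rng=rng)
    conv = (SeparableConv1d if (spec.separable and spec.kernel > 1) else Conv1d)(
        c_in, c_out, spec.kernel, spec.dilation, rng=rng)
    return Sequential([conv, ReLU()])


class HDGSNet:
    """Built network: folds the 16-row axis into the batch, runs the conv
    stages, and applies the fully connected head."""

    def __init__(self, config: HDGSModelConfig, net: Sequential,
                 stage_shapes: list[tuple[str, int, int]]):
        self.config = config
        self.net = net
        #: [(stage name, width after pool, channels)] for each conv stage
        self.stage_shapes = stage_shapes

    def forward(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        """Map N x 16 x 146 (x 1) feature matrices to N predictions."""
        x = np.asarray(batch, dtype=np.float32)
        if x.ndim == 4 and x.shape[-1] == 1:
            x = x[..., 0]
        h, w = self.config.input_height, self.config.input_width
        if x.ndim != 3 or x.shape[1:] != (h, w):
            raise ValueError(f"expected batch of shape N x {h} x {w}, got {x.shape}")
        n = x.shape[0]
        if n == 0:
            return np.zeros(0, dtype=np.float32)
        folded = x.reshape(n * h, w, 1)
        out = self.net.forward(folded, train=train)
        return out[:, 0]

    def backward(self, gy: np.ndarray) -> None:
        self.net.backward(np.asarray(gy, dtype=np.float32)[:, None])

    def params(self):
        return self.net.params()

    def get_weights(self) -> list[np.ndarray]:
        return [p.v.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p.v[...] = w

    def state(self) -> dict:
        """Weights plus batch-norm running statistics (for checkpointing)."""
        bn = [(l.running_mean.copy(), l.running_var.copy())
              for l in self._bn_layers()]
        return {"weights": self.get_weights(), "bn": bn}

    def load_state(self, state: dict) -> None:
        self.set_weights(state["weights"])
        for l, (m, v) in zip(self._bn_layers(), state["bn"], strict=True):
            l.running_mean[...] = m
            l.running_var[...] = v

    def _bn_layers(self):
        out = []

        def walk(layer):
            if isinstance(layer, BatchNorm):
                out.append(layer)
            for child in getattr(layer, "layers", []) + \
                    getattr(layer, "branches", []):
                walk(child)
        walk(self.net)
        return out


def build_hdgs(config: HDGSModelConfig, seed: int = 0) -> HDGSNet:
    """Build the network, validating the width trace stage by stage."""
    rng = np.random.default_rng(seed)
    layers: list[Layer] = [BatchNorm(1)]  # global input normalization
    width = config.input_width
    c_in = 1
    stage_shapes: list[tuple[str, int, int]] = []
    for level, mod in enumerate(config.modules):
        c_out = mod.channels_per_branch
        branches = [_build_branch(b, c_in, c_out, rng) for b in mod.branches]
        layers.append(Parallel(branches))
        layers.append(BatchNorm(mod.out_channels))
        layers.append(Dropout(config.dropout, rng))
        new_width = MaxPool1d.out_width(width, config.pool_width)
        if new_width < 1:
            raise ValueError(
                f"width {width} collapses below the pooling window at stage "
                f"{mod.name} (level {level})")
        layers.append(MaxPool1d(config.pool_width, config.pool_width))
        width = new_width
        c_in = mod.out_channels
        stage_shapes.append((mod.name, width, c_in))
    layers.append(Flatten(config.input_height))
    n_in = config.input_height * width * c_in
    for n_out in config.fc_widths:
        layers.append(Dense(n_in, n_out, rng=rng))
        layers.append(ReLU())
        n_in = n_out
    out = Dense(n_in, 1, rng=rng)
    if config.head == "regression":
        # start predictions at the dMean genome-wide mean (1.0) so the
        # output ReLU begins in its active region
        out.b.v[...] = 1.0
    layers.append(out)
    layers.append(ReLU() if config.head == "regression" else Sigmoid())
    return HDGSNet(config, Sequential(layers), stage_shapes)


def count_parameters(model: HDGSNet) -> int:
    """Total trainable parameters (kernels, biases, batch-norm scale/shift,
    dense weights)."""
    return sum(p.v.size for p in model.params())


def forward(model: HDGSNet, batch: np.ndarray) -> np.ndarray:
    """Evaluation-mode forward pass (deterministic)."""
    return model.forward(batch, train=False)


def parameter_table(model: HDGSNet) -> list[tuple[str, int]]:
    """Per-stage trainable-parameter counts (exportable manifest)."""
    rows: list[tuple[str, int]] = [("input_batchnorm", model.net.layers[0].n_params())]
    i = 1
    seen: dict[str, int] = {}
    for mod in model.config.modules:
        block = model.net.layers[i:i + 4]  # parallel, bn, dropout, pool
        seen[mod.name] = seen.get(mod.name, 0) + 1
        name = f"module_{mod.name}"
        if sum(1 for m in model.config.modules if m.name == mod.name) > 1:
            name += f"_level{seen[mod.name]}"
        rows.append((name, sum(l.n_params() for l in block)))
        i += 4
    rows.append(("head", sum(l.n_params() for l in model.net.layers[i:])))
    return rows


def reference_parameter_table() -> dict[str, int]:
    """Closed-form per-stage weight counts of the reference configuration,
    written out arithmetically (independent of the layer engine).

    Gated branches carry two kernel stacks (feature + gate) with a bias each;
    separable branches count K*C_in depthwise plus C_in*C_out pointwise with
    bias on the pointwise stage; batch norm has scale+shift per channel.
    """
    def gc(k, cin, cout):
        return 2 * (k * cin * cout + cout)

    def dc(k, cin, cout):
        return k * cin * cout + cout

    def gc_sep(k, cin, cout):
        return 2 * (k * cin + cin * cout + cout)

    def dc_sep(k, cin, cout):
        return k * cin + cin * cout + cout

    def bn(c):
        return 2 * c

    a1 = (gc(1, 1, 128) + gc(3, 1, 128) + gc(7, 1, 128)
          + dc(7, 1, 128) + dc(11, 1, 128) + bn(640))
    a2 = (gc(1, 640, 128) + gc(3, 640, 128) + gc(7, 640, 128)
          + dc(7, 640, 128) + dc(11, 640, 128) + bn(640))
    b = (gc(1, 640, 128) + gc(3, 640, 128) + gc(7, 640, 128)
         + dc(7, 640, 128) + bn(512))
    c = gc(1, 512, 64) + gc_sep(3, 512, 64) + dc_sep(3, 512, 64) + bn(192)
    head = (3072 * 256 + 256) + (256 * 32 + 32) + (32 * 1 + 1)
    table = {
        "input_batchnorm": bn(1),
        "module_A_level1": a1,
        "module_A_level2": a2,
        "module_B": b,
        "module_C": c,
        "head": head,
    }
    table["total"] = sum(table.values())
    return table
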