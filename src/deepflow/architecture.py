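"""The DeepFlow dual-path architecture.

The network stacks three-layer "dual-path" modules in the Inception
lineage: each module runs two parallel paths over its input and
concatenates their outputs channel-wise.  Path A is a 1x1 convolution
followed by a 3x3 convolution; path B is a 3x3 average pooling followed
by a 1x1 convolution — three weighted layers per module.  Reduction
variants use stride 2 in path A's 3x3 convolution and in path B's
pooling, halving the spatial side; they are placed first so that the
bulk of the convolutions runs on strongly reduced spatial dimensions.

The canonical configuration stacks 13 modules (3 reduction + 10 normal)
on a 64 px input; the three stride-2 stages bring 64 -> 32 -> 16 -> 8,
and a final 1x1 convolution produces 336 feature maps of size 8 x 8.
Global average pooling melts these into a 336-dimensional feature
vector that feeds both the softmax classifier head and any downstream
visualization.  Counting each module as 3 layers plus the final
convolution, the fully connected layer and the softmax classifier gives
the 42-layer depth reported by ``describe_architecture``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .errors import ConfigurationError

__all__ = [
    "ArchitectureConfig",
    "ArchSummary",
    "DualPathModule",
    "DeepFlowNetwork",
    "build_deepflow",
    "describe_architecture",
    "dual_path_forward",
    "default_width_schedule",
]

#: pooled feature dimension of the canonical network
DEFAULT_FEATURE_DIM = 336


def default_width_schedule(n_modules: int, n_reduction: int,
                           feature_dim: int = DEFAULT_FEATURE_DIM) -> list[int]:
    """Nondecreasing per-module output widths.

    Reduction modules ramp 32..96, normal modules ramp linearly from 112
    up to ``feature_dim - 24`` (312 for the canonical 336); the final 1x1
    convolution then lifts to ``feature_dim``.  For the canonical
    13-module / 3-reduction case this yields [32, 64, 96, 112, ..., 312].
    """
    n_norm = n_modules - n_reduction
    red = [int(round(w)) for w in np.linspace(32, 96, n_reduction)] if n_reduction else []
    norm = (
        [int(round(w)) for w in np.linspace(112, feature_dim - 24, n_norm)]
        if n_norm
        else []
    )
    return red + norm


@dataclass
class ArchitectureConfig:
    """Parametric description of a DeepFlow network."""

    input_side: int = 64
    input_channels: int = 2
    n_classes: int = 7
    n_modules: int = 13
    n_reduction_modules: int = 3
    width_schedule: list[int] | None = None
    feature_dim: int = DEFAULT_FEATURE_DIM
    activation: str = "relu"
    use_batchnorm: bool = True

    def __post_init__(self):
        if self.n_reduction_modules > self.n_modules:
            raise ConfigurationError("n_reduction_modules exceeds n_modules")
        if self.width_schedule is None:
            self.width_schedule = default_width_schedule(
                self.n_modules, self.n_reduction_modules, self.feature_dim
            )
        self.validate()

    def validate(self) -> None:
        if self.n_reduction_modules > self.n_modules:
            raise ConfigurationError("n_reduction_modules exceeds n_modules")
        if len(self.width_schedule) != self.n_modules:
            raise ConfigurationError(
                f"width_schedule has {len(self.width_schedule)} entries, "
                f"expected n_modules={self.n_modules}"
            )
        if any(b < a for a, b in zip(self.width_schedule, self.width_schedule[1:])):
            raise ConfigurationError("width_schedule must be nondecreasing")
        if self.activation != "relu":
            raise ConfigurationError(f"unsupported activation {self.activation!r}")
        if self.input_side < 8:
            raise ConfigurationError("input_side below minimal network input (8 px)")
        if self.final_spatial_side < 1:
            raise ConfigurationError("too many reductions for this input side")

    @property
    def final_spatial_side(self) -> int:
        s = self.input_side
        for _ in range(self.n_reduction_modules):
            s = (s + 1) // 2  # stride-2 'same' convolution: ceil(S/2)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ArchSummary:
    """Counted structure of an instantiated network."""

    n_modules: int
    layers_from_modules: int
    total_layers: int
    final_maps: int
    final_spatial_side: int
    feature_dim: int
    parameter_count: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


class DualPathModule(nn.Layer):
    """One dual-path module (normal or reduction).

    ``c_out`` is split between the paths, half each, with an odd
    remainder going to path A; ``c_out`` below 2 is not splittable.
    """

    def __init__(self, c_in: int, c_out: int, mode: str = "normal",
                 use_batchnorm: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        if mode not in ("normal", "reduction"):
            raise ConfigurationError(f"unknown module mode {mode!r}")
        if c_out < 2:
            raise ConfigurationError(
                f"c_out={c_out} cannot be split across two paths"
            )
        rng = rng or np.random.default_rng(0)
        stride = 2 if mode == "reduction" else 1
        c_a = c_out - c_out // 2
        c_b = c_out // 2

        def bn_act(c):
            layers = [nn.BatchNorm2d(c, dtype=dtype)] if use_batchnorm else []
            return layers + [nn.ReLU()]

        path_a = nn.Sequential(
            [nn.Conv2d(c_in, c_a, k=1, rng=rng, dtype=dtype)]
            + bn_act(c_a)
            + [nn.Conv2d(c_a, c_a, k=3, stride=stride, rng=rng, dtype=dtype)]
            + bn_act(c_a)
        )
        path_b = nn.Sequential(
            [nn.AvgPool2d(k=3, stride=stride),
             nn.Conv2d(c_in, c_b, k=1, rng=rng, dtype=dtype)]
            + bn_act(c_b)
        )
        self.body = nn.Parallel([path_a, path_b])
        self.mode, self.c_in, self.c_out = mode, c_in, c_out
        self.weighted_layers = 3  # two convs in path A, one in path B

    def params(self):
        return self.body.params()

    def forward(self, x, train=True):
        return self.body.forward(x, train=train)

    def backward(self, grad):
        return self.body.backward(grad)


def dual_path_forward(x: np.ndarray, mode: str, c_out: int,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Run a freshly initialised dual-path module on ``x``.

    ``x`` may be a single image stack (C, S, S) or a batch (N, C, S, S);
    the output matches the input's batchedness.
    """
    single = x.ndim == 3
    xb = x[None] if single else x
    mod = DualPathModule(xb.shape[1], c_out, mode=mode, rng=rng)
    out = mod.forward(xb.astype(np.float32), train=False)
    return out[0] if single else out


class DeepFlowNetwork:
    """Instantiated network: modules -> final conv -> pool -> dense -> softmax."""

    def __init__(self, config: ArchitectureConfig, seed: int = 0, dtype=np.float32):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        self.modules: list[DualPathModule] = []
        c_in = config.input_channels
        for i, c_out in enumerate(config.width_schedule):
            mode = "reduction" if i < config.n_reduction_modules else "normal"
            self.modules.append(
                DualPathModule(c_in, c_out, mode=mode,
                               use_batchnorm=config.use_batchnorm, rng=rng, dtype=dtype)
            )
            c_in = c_out
        final = [nn.Conv2d(c_in, config.feature_dim, k=1, rng=rng, dtype=dtype)]
        if config.use_batchnorm:
            final.append(nn.BatchNorm2d(config.feature_dim, dtype=dtype))
        final.append(nn.ReLU())
        self.final_conv = nn.Sequential(final)
        self.pool = nn.GlobalAvgPool()
        self.head = nn.Dense(config.feature_dim, config.n_classes, rng=rng, dtype=dtype)
        # populated by forward()
        self.module_outputs: list[np.ndarray] | None = None
        self.final_maps: np.ndarray | None = None
        self.features: np.ndarray | None = None

    # ---- core passes -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True,
                keep_intermediate: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.config.input_channels \
                or x.shape[2] != self.config.input_side or x.shape[3] != self.config.input_side:
            raise ConfigurationError(
                f"expected input (N, {self.config.input_channels}, "
                f"{self.config.input_side}, {self.config.input_side}), got {x.shape}"
            )
        outs = []
        for m in self.modules:
            x = m.forward(x, train=train)
            if keep_intermediate:
                outs.append(x)
        self.module_outputs = outs if keep_intermediate else None
        self.final_maps = self.final_conv.forward(x, train=train)
        self.features = self.pool.forward(self.final_maps, train=train)
        return self.head.forward(self.features, train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        g = self.pool.backward(g)
        g = self.final_conv.backward(g)
        for m in reversed(self.modules):
            g = m.backward(g)

    def parameters(self) -> list[nn.Param]:
        ps = []
        for m in self.modules:
            ps += m.params()
        ps += self.final_conv.params()
        ps += self.head.params()
        return ps

    # ---- inference helpers -------------------------------------------

    def _batched(self, images: np.ndarray, fn, batch_size: int = 256):
        parts = [
            fn(images[i : i + batch_size].astype(np.float32))
            for i in range(0, len(images), batch_size)
        ]
        return np.concatenate(parts, axis=0)

    def predict_proba(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self._batched(
            images, lambda b: nn.softmax(self.forward(b, train=False)), batch_size
        )

    def predict(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(images, batch_size).argmax(axis=1)

    def pooled_features(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        def fn(b):
            self.forward(b, train=False)
            return self.features

        return self._batched(images, fn, batch_size)

    def classify_features(self, features: np.ndarray) -> np.ndarray:
        """Softmax over the classifier head applied to pooled features."""
        return nn.softmax(features @ self.head.w.value.T + self.head.b.value)

    def activation_maps(self, images: np.ndarray, module_index: int,
                        batch_size: int = 256) -> np.ndarray:
        """Activations after module ``module_index`` (1-based)."""
        if not (1 <= module_index <= len(self.modules)):
            raise ConfigurationError(
                f"module_index {module_index} out of range [1, {len(self.modules)}]"
            )

        def fn(b):
            x = b
            for m in self.modules[:module_index]:
                x = m.forward(x, train=False)
            return x

        return self._batched(images, fn, batch_size)

    # ---- serialization -----------------------------------------------

    def _stateful(self):
        layers = []

        def walk(l):
            if isinstance(l, nn.Sequential):
                for s in l.layers:
                    walk(s)
            elif isinstance(l, nn.Parallel):
                for s in l.branches:
                    walk(s)
            elif isinstance(l, DualPathModule):
                walk(l.body)
            elif isinstance(l, nn.BatchNorm2d):
                layers.append(l)

        for m in self.modules:
            walk(m)
        walk(self.final_conv)
        return layers

    def save(self, path: str) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self._stateful()):
            arrays[f"bn{i}_mean"] = bn.run_mean
            arrays[f"bn{i}_var"] = bn.run_var
        np.savez(path, config=json.dumps(self.config.to_dict()), **arrays)

    @classmethod
    def load(cls, path: str) -> "DeepFlowNetwork":
        with np.load(path, allow_pickle=False) as z:
            config = ArchitectureConfig.from_dict(json.loads(str(z["config"])))
            net = cls(config)
            for i, p in enumerate(net.parameters()):
                p.value = z[f"p{i}"]
                p.grad = np.zeros_like(p.value)
            for i, bn in enumerate(net._stateful()):
                bn.run_mean = z[f"bn{i}_mean"]
                bn.run_var = z[f"bn{i}_var"]
        return net


def build_deepflow(config: ArchitectureConfig, seed: int = 0) -> DeepFlowNetwork:
    """Instantiate the network described by ``config`` (validated first)."""
    config.validate()
    return DeepFlowNetwork(config, seed=seed)


def describe_architecture(config: ArchitectureConfig,
                          network: DeepFlowNetwork | None = None) -> ArchSummary:
    """Counted structure, measured on an instantiated network.

    Shapes are read off a forward pass of a single blank image, not
    derived from config arithmetic alone.
    """
    net = network if network is not None else build_deepflow(config)
    x = np.zeros(
        (1, config.input_channels, config.input_side, config.input_side),
        dtype=np.float32,
    )
    net.forward(x, train=False)
    final_maps = net.final_maps.shape[1]
    final_side = net.final_maps.shape[2]
    layers_from_modules = sum(m.weighted_layers for m in net.modules)
    # final convolution + fully connected layer + softmax classifier
    total_layers = layers_from_modules + 3
    return ArchSummary(
        n_modules=len(net.modules),
        layers_from_modules=layers_from_modules,
        total_layers=total_layers,
        final_maps=final_maps,
        final_spatial_side=final_side,
        feature_dim=net.features.shape[1],
        parameter_count=int(sum(p.value.size for p in net.parameters())),
    )
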