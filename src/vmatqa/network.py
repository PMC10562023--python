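"""The multi-branch GPR prediction network.

Each input image (dose planes, MLC leaf position map, or cylindrical surface
dose) feeds a lightweight convolutional branch — three 3x3 convolution +
3x3/3 max-pooling stages (the first convolution is same-padded, the later
two valid), then a flatten and an affine embedding to 20 features.  Branch
embeddings are fused by elementwise addition, pass through a shared
ReLU -> BatchNorm -> Dropout(0.3) -> Affine(20->20) trunk, and nine parallel
Affine(20->1) heads emit the gamma passing rate at the nine %/mm criteria
simultaneously.

Three input configurations are supported:

* ``model1`` — sagittal + coronal + axial isocenter dose planes + MLPM,
* ``model2`` — the three dose planes only,
* ``model3`` — the unrolled cylindrical (phantom-like) surface dose only.

Deliberately shallow: with cohort-sized datasets (tens of plans) deeper
stacks overfit, so each branch has only three convolution layers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .errors import ConstructionError, ParameterError
from .nn import Adam, Affine, BatchNorm1D, Conv2D, Dropout, Flatten, Layer, MaxPool2D, Param, ReLU

CONV_CHANNELS = 16
EMBED_DIM = 20
N_OUTPUTS = 9

#: Input image shapes at clinical scale (rows, cols), one channel each.
DEFAULT_BRANCH_SHAPES: dict[str, tuple[int, int]] = {
    "sagittal": (68, 146),
    "coronal": (64, 200),
    "axial": (143, 242),
    "mlpm": (110, 178),
    "surface": (220, 680),
}

MODEL_BRANCHES: dict[str, tuple[str, ...]] = {
    "model1": ("sagittal", "coronal", "axial", "mlpm"),
    "model2": ("sagittal", "coronal", "axial"),
    "model3": ("surface",),
}


def _pool_out(n: int) -> int:
    if n < 3:
        raise ConstructionError(f"pooling input size {n} < kernel size 3")
    return (n - 3) // 3 + 1


def _conv_valid_out(n: int) -> int:
    if n < 3:
        raise ConstructionError(f"convolution input size {n} < kernel size 3")
    return n - 2


def branch_layer_shapes(input_shape: tuple[int, int]) -> dict[str, tuple[int, ...]]:
    """Intermediate output shapes (H, W, C) of one branch, by layer name."""
    h, w = input_shape
    shapes: dict[str, tuple[int, ...]] = {}
    shapes["Convolution_1"] = (h, w, CONV_CHANNELS)  # same-padded
    h, w = _pool_out(h), _pool_out(w)
    shapes["Max Pooling_1"] = (h, w, CONV_CHANNELS)
    h, w = _conv_valid_out(h), _conv_valid_out(w)
    shapes["Convolution_2"] = (h, w, CONV_CHANNELS)
    h, w = _pool_out(h), _pool_out(w)
    shapes["Max Pooling_2"] = (h, w, CONV_CHANNELS)
    h, w = _conv_valid_out(h), _conv_valid_out(w)
    shapes["Convolution_3"] = (h, w, CONV_CHANNELS)
    h, w = _pool_out(h), _pool_out(w)
    shapes["Max Pooling_3"] = (h, w, CONV_CHANNELS)
    shapes["Affine_1"] = (EMBED_DIM,)
    return shapes


@dataclass(frozen=True)
class BranchSpec:
    """One convolutional input branch (16 channels, 3 stages, 20-d embedding)."""

    name: str
    input_shape: tuple[int, int]

    @property
    def layer_shapes(self) -> dict[str, tuple[int, ...]]:
        return branch_layer_shapes(self.input_shape)

    @property
    def flat_features(self) -> int:
        h, w, c = self.layer_shapes["Max Pooling_3"]
        return h * w * c


@dataclass(frozen=True)
class NetworkConfig:
    """Input configuration and seeds for one network instance."""

    variant: str
    input_shapes: Optional[Mapping[str, tuple[int, int]]] = None
    dropout_rate: float = 0.3
    n_outputs: int = N_OUTPUTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in MODEL_BRANCHES:
            raise ParameterError(
                f"unknown variant {self.variant!r}; choose from {sorted(MODEL_BRANCHES)}"
            )

    @property
    def branch_names(self) -> tuple[str, ...]:
        return MODEL_BRANCHES[self.variant]

    def to_dict(self) -> dict:
        """Declarative form (variant, shapes, dropout, seed), JSON-ready."""
        return {
            "variant": self.variant,
            "input_shapes": {k: list(v) for k, v in (self.input_shapes or {}).items()},
            "dropout_rate": self.dropout_rate,
            "n_outputs": self.n_outputs,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "NetworkConfig":
        shapes = {k: tuple(v) for k, v in (data.get("input_shapes") or {}).items()}
        return cls(
            variant=data["variant"],
            input_shapes=shapes or None,
            dropout_rate=data.get("dropout_rate", 0.3),
            n_outputs=data.get("n_outputs", N_OUTPUTS),
            seed=data.get("seed", 0),
        )

    def branch_specs(self) -> tuple[BranchSpec, ...]:
        shapes = dict(DEFAULT_BRANCH_SHAPES)
        if self.input_shapes:
            shapes.update({k: tuple(v) for k, v in self.input_shapes.items()})
        return tuple(BranchSpec(name, shapes[name]) for name in self.branch_names)


class MultiBranchGprNet:
    """Multi-input CNN regressor for nine-criterion GPR prediction.

    Training-scale outputs are GPR/100 (unit scale); :meth:`predict` returns
    percentages.  Inference is deterministic: dropout is off and batch norm
    uses its running statistics.
    """

    def __init__(self, config: NetworkConfig, dtype=np.float32):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.specs = {spec.name: spec for spec in config.branch_specs()}
        self.branches: dict[str, list[Layer]] = {}
        for spec in config.branch_specs():
            name = spec.name
            spec.layer_shapes  # raises ConstructionError for infeasible shapes
            self.branches[name] = [
                Conv2D(1, CONV_CHANNELS, pad=1, rng=rng, name=f"{name}/Convolution_1", dtype=dtype),
                MaxPool2D(),
                Conv2D(CONV_CHANNELS, CONV_CHANNELS, pad=0, rng=rng,
                       name=f"{name}/Convolution_2", dtype=dtype),
                MaxPool2D(),
                Conv2D(CONV_CHANNELS, CONV_CHANNELS, pad=0, rng=rng,
                       name=f"{name}/Convolution_3", dtype=dtype),
                MaxPool2D(),
                Flatten(),
                Affine(spec.flat_features, EMBED_DIM, rng=rng,
                       name=f"{name}/Affine_1", dtype=dtype),
            ]
            # small positive embedding bias keeps the fused pre-ReLU features
            # mostly alive at initialization (batch-4 training is brittle to
            # early feature death)
            self.branches[name][-1].b.value[...] = 0.1
        # fused 20-d embedding -> shared trunk -> nine parallel heads
        self.relu = ReLU()
        self.bn = BatchNorm1D(EMBED_DIM, name="Batch Normalization", dtype=dtype)
        self.dropout = Dropout(config.dropout_rate, rng=np.random.default_rng(rng.integers(2**31)))
        self.affine2 = Affine(EMBED_DIM, EMBED_DIM, rng=rng, name="Affine_2", dtype=dtype)
        self.heads = [
            Affine(EMBED_DIM, 1, rng=rng, name=f"Affine_3_{i + 1}", dtype=dtype)
            for i in range(config.n_outputs)
        ]
        # start the heads at the unit scale of a typical passing rate; Adam
        # moves each weight by at most ~lr per step, so crawling from 0 to
        # ~0.9 would waste most of the epoch budget
        for head in self.heads:
            head.b.value[...] = 0.9

    # -- forward / backward -------------------------------------------------

    def _prepare(self, inputs: Mapping[str, np.ndarray]) -> dict[str, np.ndarray]:
        out = {}
        for name, spec in self.specs.items():
            if name not in inputs:
                raise ParameterError(f"missing input for branch {name!r}")
            x = np.asarray(inputs[name])
            if x.ndim == 2:
                x = x[None]
            if x.ndim == 3:
                x = x[:, None]
            if x.shape[2:] != spec.input_shape:
                raise ParameterError(
                    f"branch {name!r} expects {spec.input_shape}, got {x.shape[2:]}"
                )
            out[name] = x
        return out

    def forward(self, inputs: Mapping[str, np.ndarray], train: bool = False) -> np.ndarray:
        """Run the network; returns (N, n_outputs) on the unit (GPR/100) scale."""
        xs = self._prepare(inputs)
        fused = None
        for name, layers in self.branches.items():
            h = xs[name]
            for layer in layers:
                h = layer.forward(h, train)
            fused = h if fused is None else fused + h
        h = self.relu.forward(fused, train)
        h = self.bn.forward(h, train)
        h = self.dropout.forward(h, train)
        h = self.affine2.forward(h, train)
        return np.concatenate([head.forward(h, train) for head in self.heads], axis=1)

    def backward(self, grad: np.ndarray) -> None:
        d = sum(head.backward(grad[:, i : i + 1]) for i, head in enumerate(self.heads))
        d = self.affine2.backward(d)
        d = self.dropout.backward(d)
        d = self.bn.backward(d)
        d = self.relu.backward(d)
        for layers in self.branches.values():
            g = d
            for layer in reversed(layers):
                g = layer.backward(g)

    def predict(self, inputs: Mapping[str, np.ndarray]) -> np.ndarray:
        """Inference-mode prediction in GPR percent, shape (N, n_outputs)."""
        return self.forward(inputs, train=False) * 100.0

    # -- parameters and state ----------------------------------------------

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layers in self.branches.values():
            for layer in layers:
                out.extend(layer.params())
        for layer in (self.relu, self.bn, self.dropout, self.affine2, *self.heads):
            out.extend(layer.params())
        return out

    def get_state(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value.copy() for p in self.params()}
        state["Batch Normalization.running_mean"] = self.bn.running_mean.copy()
        state["Batch Normalization.running_var"] = self.bn.running_var.copy()
        return state

    def set_state(self, state: Mapping[str, np.ndarray]) -> None:
        for p in self.params():
            p.value[...] = state[p.name]
        self.bn.running_mean[...] = state["Batch Normalization.running_mean"]
        self.bn.running_var[...] = state["Batch Normalization.running_var"]

    # -- introspection -------------------------------------------------------

    def parameter_manifest(self) -> dict[str, int]:
        """Trainable parameter count per named layer (Table-style audit)."""
        manifest: dict[str, int] = {}
        for name, layers in self.branches.items():
            for layer in layers:
                ps = layer.params()
                if ps:
                    lname = ps[0].name.rsplit(".", 1)[0]
                    manifest[lname] = sum(p.size for p in ps)
        manifest["Batch Normalization"] = self.bn.gamma.size + self.bn.beta.size
        manifest["Affine_2"] = self.affine2.W.size + self.affine2.b.size
        for i, head in enumerate(self.heads):
            manifest[f"Affine_3_{i + 1}"] = head.W.size + head.b.size
        manifest["Affine_3"] = self.heads[0].W.size + self.heads[0].b.size
        return manifest

    def layer_shapes(self) -> dict[str, dict[str, tuple[int, ...]]]:
        """Per-branch intermediate output shapes, keyed like the manifest."""
        return {name: spec.layer_shapes for name, spec in self.specs.items()}


def build_network(config: NetworkConfig, dtype=np.float32) -> MultiBranchGprNet:
    """Construct the network for a variant; raises on infeasible input shapes."""
    return MultiBranchGprNet(config, dtype=dtype)


def count_parameters(network: MultiBranchGprNet, layer_name: str) -> int:
    """Trainable parameter count (weights + biases) of a named layer."""
    manifest = network.parameter_manifest()
    if layer_name not in manifest:
        raise KeyError(f"no layer named {layer_name!r}; known: {sorted(manifest)}")
    return manifest[layer_name]


def make_optimizer(network: MultiBranchGprNet, learning_rate: float = 1e-3) -> Adam:
    return Adam(network.params(), learning_rate=learning_rate)


def save_checkpoint(network: MultiBranchGprNet, path) -> None:
    """Write weights plus a parameter-count manifest for auditing (.npz)."""
    import json

    state = network.get_state()
    state["__manifest__"] = np.frombuffer(
        json.dumps(network.parameter_manifest()).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(network: MultiBranchGprNet, path) -> dict[str, int]:
    """Load weights saved by :func:`save_checkpoint`; returns the manifest.

    The stored manifest must match the network's own parameter accounting —
    a mismatch means the checkpoint belongs to a different configuration.
    """
    import json

    with np.load(path) as data:
        manifest = json.loads(bytes(data["__manifest__"]).decode())
        if manifest != network.parameter_manifest():
            raise ParameterError("checkpoint manifest does not match the network configuration")
        network.set_state({k: data[k] for k in data.files if k != "__manifest__"})
    return manifest
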