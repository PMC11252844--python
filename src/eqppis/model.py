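"""Dual-scale equivariant network for per-residue interface prediction.

The network runs a shared stack of residual EGCL layers over two views of
the same protein: the original contact graph, and a smaller subgraph picked
by learnable top-k pooling. The subgraph output is scattered back to the
original size, the two channels are fused by an elementwise maximum, and a
three-layer head (hidden -> 20 -> 10 -> 2, softmax) produces per-residue
interface probabilities. Because the layer weights are shared, each node is
updated with neighbourhood messages at two different scales without extra
parameters.

Coordinates are updated inside the stack (each channel carries its own
coordinate stream) and discarded after the last layer: only the invariant
feature stream reaches the prediction head, so output probabilities are
invariant under rotations, reflections and translations of the input
structure.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._autodiff import Tensor
from .egnn import EGCLParams, MLP, NodeState, egcl_forward, fuse_channels, residual_step
from .graph_construction import FEATURE_GROUPS, GROUP_WIDTHS, ProteinGraph
from .pooling import PoolingParams, pool, unpool


@dataclass
class ModelConfig:
    """Architecture hyperparameters."""

    n_layers: int = 6
    pooling_ratio: float = 0.6
    cutoff: float = 14.0
    hidden: int = 62
    head_dims: tuple[int, int, int] = (20, 10, 2)
    use_subgraph_channel: bool = True
    equivariant_mode: bool = True
    feature_groups: tuple[str, ...] = FEATURE_GROUPS
    dist_scale: float = 1.0
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        self.head_dims = tuple(self.head_dims)
        self.feature_groups = tuple(g.lower() for g in self.feature_groups)
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if len(self.head_dims) != 3 or self.head_dims[-1] != 2:
            raise ValueError("head must have three layers ending in width 2")
        unknown = set(self.feature_groups) - set(FEATURE_GROUPS)
        if unknown:
            raise ValueError(f"unknown feature group(s): {sorted(unknown)}")
        if not (0.0 < self.pooling_ratio <= 1.0):
            raise ValueError("pooling_ratio must lie in (0, 1]")

    @property
    def input_width(self) -> int:
        return sum(GROUP_WIDTHS[g] for g in self.feature_groups)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class Prediction:
    """Per-residue class probabilities and thresholded binary calls."""

    probabilities: np.ndarray  # (L, 2), rows sum to 1
    binary_calls: np.ndarray  # (L,) in {0, 1}
    threshold: float = 0.5

    @property
    def scores(self) -> np.ndarray:
        """Positive-class (interface) probability per residue."""
        return self.probabilities[:, 1]


class ModelParameters:
    """All learnable tensors: shared EGCL stack, pooling projection,
    optional input projection, and the prediction head."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        H = config.hidden
        self.config = config
        self.input_proj: tuple[Tensor, Tensor] | None = None
        if config.input_width != H:
            self.input_proj = (
                Tensor(
                    rng.normal(0, np.sqrt(1.0 / config.input_width), (config.input_width, H)),
                    requires_grad=True,
                    name="input.w",
                ),
                Tensor(np.zeros(H), requires_grad=True, name="input.b"),
            )
        self.egcl: list[EGCLParams] = [
            EGCLParams.create(
                H,
                rng,
                equivariant=config.equivariant_mode,
                dist_scale=config.dist_scale,
                name=f"egcl{l}",
            )
            for l in range(config.n_layers)
        ]
        self.pool_p = Tensor(
            rng.normal(0, 1.0, H) / np.sqrt(H), requires_grad=True, name="pool.p"
        )
        d0, d1, d2 = config.head_dims
        self.head = MLP([H, d0, d1, d2], rng, "head")

    def named_tensors(self) -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        if self.input_proj is not None:
            out += [("input.w", self.input_proj[0]), ("input.b", self.input_proj[1])]
        for lp in self.egcl:
            out += lp.named_tensors()
        out.append(("pool.p", self.pool_p))
        out += self.head.named_tensors()
        return out

    def tensors(self) -> list[Tensor]:
        return [t for _, t in self.named_tensors()]


def init_parameters(config: ModelConfig, seed: int | None = None) -> ModelParameters:
    """Deterministically initialise all parameters from a seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return ModelParameters(config, rng)


def count_parameters(config: ModelConfig) -> int:
    params = init_parameters(config, seed=0)
    return sum(t.data.size for t in params.tensors())


def select_feature_columns(
    features: np.ndarray, groups: Sequence[str]
) -> np.ndarray:
    """Slice a full 62-column feature matrix down to the requested groups
    (no-op if the matrix already has the selected width)."""
    groups = [g.lower() for g in groups]
    want = sum(GROUP_WIDTHS[g] for g in groups)
    if features.shape[1] == want:
        return features
    if features.shape[1] != sum(GROUP_WIDTHS.values()):
        raise ValueError(
            f"cannot select groups from a {features.shape[1]}-column matrix"
        )
    cols = []
    offset = 0
    for g in FEATURE_GROUPS:
        w = GROUP_WIDTHS[g]
        if g in groups:
            cols.extend(range(offset, offset + w))
        offset += w
    return features[:, cols]


def _run_stack(
    h: Tensor,
    x: Tensor,
    adjacency: np.ndarray,
    params: ModelParameters,
) -> Tensor:
    """Residual EGCL stack on one graph view; returns final node features."""
    state = NodeState(h=h, x=x)
    edges = np.nonzero(adjacency)
    for layer in params.egcl:
        out = egcl_forward(state, adjacency, layer, edges=edges)
        state = NodeState(h=residual_step(state.h, out.h), x=out.x)
    return state.h


def forward_tensor(
    graph: ProteinGraph, config: ModelConfig, params: ModelParameters
) -> Tensor:
    """Full forward pass returning the (L, 2) pre-softmax logits as a Tensor."""
    if graph.n_residues == 0:
        raise ValueError("empty graph")
    X = select_feature_columns(graph.features, config.feature_groups)
    if X.shape[1] != config.input_width:
        raise ValueError(
            f"feature width {X.shape[1]} does not match config ({config.input_width})"
        )
    h0 = Tensor(X)
    if params.input_proj is not None:
        w, b = params.input_proj
        h0 = h0 @ w + b

    h_orig = _run_stack(h0, Tensor(graph.coords), graph.adjacency, params)

    if config.use_subgraph_channel:
        pres = pool(
            h0,
            graph.adjacency,
            graph.coords,
            PoolingParams(p=params.pool_p, ratio=config.pooling_ratio),
        )
        h_sub = _run_stack(
            pres.sub_features_tensor,
            Tensor(pres.sub_coords),
            pres.sub_adjacency,
            params,
        )
        h_restored = unpool(h_sub, pres.idx, graph.n_residues)
        fused = fuse_channels(h_orig, h_restored)
    else:
        fused = h_orig

    return params.head(fused)


def log_softmax(logits: Tensor) -> Tensor:
    """Numerically stable row-wise log-softmax."""
    shift = logits - logits.data.max(axis=1, keepdims=True)
    return shift - shift.exp().sum(axis=1, keepdims=True).log()


def forward(
    graph: ProteinGraph, config: ModelConfig, params: ModelParameters
) -> Prediction:
    """Predict per-residue interface probabilities for one chain."""
    logits = forward_tensor(graph, config, params)
    logp = log_softmax(logits)
    probs = np.exp(logp.data)
    probs /= probs.sum(axis=1, keepdims=True)
    return Prediction(
        probabilities=probs,
        binary_calls=(probs[:, 1] >= config.threshold).astype(np.int64),
        threshold=config.threshold,
    )


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(
    path: str | Path,
    config: ModelConfig,
    params: ModelParameters,
    extra: dict | None = None,
) -> None:
    """Serialise config + parameters (+ optional training state) to JSON."""
    payload = {
        "config": config.to_dict(),
        "parameters": {name: t.data.tolist() for name, t in params.named_tensors()},
        "extra": extra or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> tuple[ModelConfig, ModelParameters, dict]:
    payload = json.loads(Path(path).read_text())
    config = ModelConfig.from_dict(payload["config"])
    params = init_parameters(config)
    stored = payload["parameters"]
    for name, t in params.named_tensors():
        arr = np.asarray(stored[name], dtype=np.float64)
        if arr.shape != t.data.shape:
            raise ValueError(f"checkpoint parameter {name} has shape {arr.shape}")
        t.data = arr
    return config, params, payload.get("extra", {})
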