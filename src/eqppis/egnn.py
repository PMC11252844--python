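"""E(n)-equivariant graph convolutional layer (EGCL) and fusion operations.

One EGCL pass over a residue graph computes, for every adjacent pair (i, j):

    m_ij = phi_e(h_i, h_j, ||x_i - x_j||^2 [, a_ij])

then updates coordinates equivariantly and features invariantly:

    x_i <- x_i + C * sum_j (x_i - x_j) * phi_x(m_ij),   C = 1/(M-1)
    m_i  = sum_j m_ij
    h_i <- phi_h(h_i, m_i)

Because coordinates enter only through squared pairwise distances, the
feature stream h is invariant under any rotation, reflection or translation
of the input coordinates, while the coordinate stream transforms
equivariantly. Messages are restricted to graph neighbours (the contact
graph defines which pairs interact). The three maps phi_e, phi_x, phi_h are
two-layer perceptrons with SiLU nonlinearities; phi_x ends in a single
linear unit without bias.

A non-equivariant ablation mode drops the distance term and the coordinate
update, reducing the layer to plain message passing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, maximum, segment_sum


class MLP:
    """A small fully-connected network over Tensors."""

    def __init__(
        self,
        sizes: list[int],
        rng: np.random.Generator,
        name: str = "mlp",
        final_bias: bool = True,
        final_activation: bool = False,
    ):
        self.name = name
        self.final_activation = final_activation
        self.layers: list[tuple[Tensor, Tensor | None]] = []
        for li, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            last = li == len(sizes) - 2
            w = Tensor(
                rng.normal(0.0, np.sqrt(1.0 / fan_in), size=(fan_in, fan_out)),
                requires_grad=True,
                name=f"{name}.w{li}",
            )
            b = (
                None
                if (last and not final_bias)
                else Tensor(np.zeros(fan_out), requires_grad=True, name=f"{name}.b{li}")
            )
            self.layers.append((w, b))

    def __call__(self, x: Tensor) -> Tensor:
        n = len(self.layers)
        for li, (w, b) in enumerate(self.layers):
            x = x @ w
            if b is not None:
                x = x + b
            if li < n - 1 or self.final_activation:
                x = x.silu()
        return x

    def named_tensors(self) -> list[tuple[str, Tensor]]:
        out = []
        for li, (w, b) in enumerate(self.layers):
            out.append((f"{self.name}.w{li}", w))
            if b is not None:
                out.append((f"{self.name}.b{li}", b))
        return out


@dataclass
class EGCLParams:
    """The three learned maps of one equivariant layer."""

    phi_e: MLP
    phi_x: MLP
    phi_h: MLP
    equivariant: bool = True
    dist_scale: float = 1.0

    @classmethod
    def create(
        cls,
        hidden: int,
        rng: np.random.Generator,
        d_edge: int = 0,
        equivariant: bool = True,
        dist_scale: float = 1.0,
        name: str = "egcl",
    ) -> "EGCLParams":
        edge_in = 2 * hidden + (1 if equivariant else 0) + d_edge
        phi_e = MLP([edge_in, hidden, hidden], rng, f"{name}.phi_e", final_activation=True)
        # the coordinate gate only needs a narrow bottleneck to emit one
        # scalar per edge; a full hidden-width inner layer buys nothing
        phi_x = MLP([hidden, 16, 1], rng, f"{name}.phi_x", final_bias=False)
        phi_h = MLP([2 * hidden, hidden, hidden], rng, f"{name}.phi_h")
        # damp the initial message and coordinate-update magnitudes: messages
        # are summed (not averaged) over neighbours, and coordinate updates
        # feed back into the next layer's distances, so unit-scale output
        # layers make a deep residual stack blow up at initialisation
        phi_e.layers[-1][0].data *= 0.1
        phi_x.layers[-1][0].data *= 0.001
        return cls(
            phi_e=phi_e,
            phi_x=phi_x,
            phi_h=phi_h,
            equivariant=equivariant,
            dist_scale=dist_scale,
        )

    def named_tensors(self) -> list[tuple[str, Tensor]]:
        return (
            self.phi_e.named_tensors()
            + self.phi_x.named_tensors()
            + self.phi_h.named_tensors()
        )


@dataclass
class NodeState:
    """Node features h and coordinates x flowing through the layer stack."""

    h: Tensor
    x: Tensor

    def __post_init__(self):
        if not isinstance(self.h, Tensor):
            self.h = Tensor(self.h)
        if not isinstance(self.x, Tensor):
            self.x = Tensor(self.x)
        if self.h.shape[0] != self.x.shape[0]:
            raise ValueError("h and x must agree on node count")
        if self.h.shape[0] < 1:
            raise ValueError("need at least one node")


def _edge_messages(
    params: "EGCLParams",
    h: Tensor,
    src: np.ndarray,
    dst: np.ndarray,
    dist2: Tensor | None,
    edge_attr: Tensor | None,
) -> Tensor:
    """phi_e over all directed edges.

    When phi_e has the standard two-layer shape, its first matmul is split
    into per-node products with the h_i / h_j row blocks of the weight
    matrix, so the expensive multiply runs once per node instead of once per
    edge; the result is algebraically identical to concatenating
    (h_i, h_j, d^2, a_ij) per edge and applying phi_e directly.
    """
    H = h.shape[1]
    layers = params.phi_e.layers
    if len(layers) == 2 and params.phi_e.final_activation:
        w0, b0 = layers[0]
        pre = (h @ w0.gather_rows(np.arange(H))).gather_rows(src) + (
            h @ w0.gather_rows(np.arange(H, 2 * H))
        ).gather_rows(dst)
        off = 2 * H
        if dist2 is not None:
            pre = pre + dist2 @ w0.gather_rows(np.arange(off, off + 1))
            off += 1
        if edge_attr is not None:
            pre = pre + edge_attr @ w0.gather_rows(
                np.arange(off, off + edge_attr.shape[1])
            )
        if b0 is not None:
            pre = pre + b0
        w1, b1 = layers[1]
        out = pre.silu() @ w1
        if b1 is not None:
            out = out + b1
        return out.silu()
    parts = [h.gather_rows(src), h.gather_rows(dst)]
    if dist2 is not None:
        parts.append(dist2)
    if edge_attr is not None:
        parts.append(edge_attr)
    return params.phi_e(concat(parts, axis=1))


def egcl_forward(
    state: NodeState,
    adjacency: np.ndarray,
    params: EGCLParams,
    edge_attr: np.ndarray | None = None,
    edges: tuple[np.ndarray, np.ndarray] | None = None,
) -> NodeState:
    """One equivariant message-passing step over the given contact graph.

    `edges` may carry a precomputed (src, dst) directed edge list for the
    adjacency, letting callers amortise the edge extraction across layers.
    """
    M = state.h.shape[0]
    adjacency = np.asarray(adjacency)
    if adjacency.shape != (M, M):
        raise ValueError(f"adjacency shape {adjacency.shape} does not match {M} nodes")
    if not np.array_equal(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    if M == 1:
        return state

    # directed edges (i=src receives from j=dst)
    src, dst = np.nonzero(adjacency) if edges is None else edges

    rel = dist2 = None
    if params.equivariant:
        rel = state.x.gather_rows(src) - state.x.gather_rows(dst)
        dist2 = (rel * rel).sum(axis=1, keepdims=True)
        if params.dist_scale != 1.0:
            dist2 = dist2 / params.dist_scale
    ea_t = None
    if edge_attr is not None:
        ea = np.asarray(edge_attr, dtype=np.float64)
        if ea.shape[0] != src.shape[0]:
            raise ValueError("edge_attr must have one row per directed edge")
        ea_t = Tensor(ea)

    m_edge = _edge_messages(params, state.h, src, dst, dist2, ea_t)

    x_new = state.x
    if params.equivariant:
        weights = params.phi_x(m_edge)  # (E, 1)
        coord_upd = segment_sum(rel * weights, src, M) * (1.0 / (M - 1))
        x_new = state.x + coord_upd

    m_node = segment_sum(m_edge, src, M)  # (M, H), zero rows for isolated nodes
    h_new = params.phi_h(concat([state.h, m_node], axis=1))
    return NodeState(h=h_new, x=x_new)


def residual_step(h_prev: Tensor, layer_out: Tensor) -> Tensor:
    """Identity-mapping residual connection: relu(h_prev + layer_out)."""
    if h_prev.shape != layer_out.shape:
        raise ValueError(f"shape mismatch: {h_prev.shape} vs {layer_out.shape}")
    return (h_prev + layer_out).relu()


def fuse_channels(h_original: Tensor, h_unpooled: Tensor) -> Tensor:
    """Elementwise maximum across the original-graph and subgraph channels."""
    return maximum(h_original, h_unpooled)
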