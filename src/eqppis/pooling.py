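"""Learnable top-k graph pooling and its inverse (unpooling).

Following the Graph U-Net lineage, nodes are scored by projecting their
features onto a learnable direction p (normalised, then squashed by a
sigmoid), the k = ceil(ratio*L) best-scoring nodes are kept, and the kept
features are gated by their scores so that selection remains differentiable.
The subgraph adjacency is the boolean square of the original adjacency
restricted to the kept nodes, which preserves connectivity between nodes
that were two hops apart before pooling. Unpooling scatters subgraph rows
back into a zero matrix of the original size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, scatter_rows


@dataclass
class PoolingParams:
    """Learnable projection vector p and the kept-node ratio."""

    p: Tensor
    ratio: float = 0.6

    def __post_init__(self):
        if not isinstance(self.p, Tensor):
            self.p = Tensor(np.asarray(self.p, dtype=np.float64), requires_grad=False)
        if self.p.data.ndim != 1:
            raise ValueError("projection vector p must be 1-D")
        if not (0.0 < self.ratio <= 1.0):
            raise ValueError("pooling ratio must lie in (0, 1]")


@dataclass
class PoolingResult:
    """Output of one pooling step.

    ``sub_features_tensor`` carries the autodiff graph (score gating keeps
    the projection p trainable); the plain-array fields are detached views.
    """

    idx: np.ndarray  # (k,) selected node indices, ascending
    scores: np.ndarray  # (L,) sigmoid node scores
    sub_features: np.ndarray  # (k, D) gated features, detached
    sub_adjacency: np.ndarray  # (k, k) binarised A^2 restriction
    sub_coords: np.ndarray  # (k, 3) coordinates of kept nodes, ungated
    sub_features_tensor: Tensor = field(repr=False, default=None)
    scores_tensor: Tensor = field(repr=False, default=None)


def top_k_indices(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores; ties broken by lower node index;
    returned in ascending index order."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    return np.sort(order[:k])


def pool(
    features: Tensor | np.ndarray,
    adjacency: np.ndarray,
    coords: np.ndarray,
    params: PoolingParams,
) -> PoolingResult:
    """Select the top-k nodes under the learnable projection and build the
    gated subgraph (features, adjacency, coordinates)."""
    X = features if isinstance(features, Tensor) else Tensor(features)
    L, D = X.shape
    if L == 0:
        raise ValueError("cannot pool an empty graph")
    if params.p.shape != (D,):
        raise ValueError(
            f"projection vector has length {params.p.shape[0]}, features have {D} columns"
        )
    p_norm = float(np.linalg.norm(params.p.data))
    if p_norm == 0.0:
        raise ValueError("projection vector p must be nonzero")
    adjacency = np.asarray(adjacency)
    if adjacency.shape != (L, L):
        raise ValueError("adjacency shape must match features")

    # y = X p / ||p|| ; scores = sigmoid(y)
    p_col = params.p.reshape(-1, 1)
    p_hat = p_col / (p_col * p_col).sum().sqrt()
    scores_t = (X @ p_hat).sigmoid()  # (L, 1)
    scores = scores_t.data.ravel().copy()

    k = max(1, math.ceil(params.ratio * L))
    idx = top_k_indices(scores, k)

    # gated feature rows: X(idx, :) ⊙ scores(idx) broadcast across columns
    sub_features_t = X.gather_rows(idx) * scores_t.gather_rows(idx)

    a2 = ((adjacency.astype(np.int64) @ adjacency.astype(np.int64)) > 0).astype(np.int8)
    sub_adj = a2[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub_adj, 0)

    return PoolingResult(
        idx=idx,
        scores=scores,
        sub_features=sub_features_t.data.copy(),
        sub_adjacency=sub_adj,
        sub_coords=np.asarray(coords, dtype=np.float64)[idx].copy(),
        sub_features_tensor=sub_features_t,
        scores_tensor=scores_t,
    )


def unpool(
    sub_features: Tensor | np.ndarray, idx: np.ndarray, original_size: int
) -> Tensor:
    """Scatter subgraph rows back to the original graph size: row idx[j] of
    the output equals row j of `sub_features`; every other row is zero."""
    t = sub_features if isinstance(sub_features, Tensor) else Tensor(sub_features)
    idx = np.asarray(idx, dtype=np.intp)
    if idx.shape[0] != t.shape[0]:
        raise ValueError("idx length must equal the subgraph row count")
    if len(np.unique(idx)) != len(idx):
        raise ValueError("duplicate indices in unpool")
    if idx.size and (idx.min() < 0 or idx.max() >= original_size):
        raise IndexError("unpool index out of range")
    return scatter_rows(t, idx, original_size)
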