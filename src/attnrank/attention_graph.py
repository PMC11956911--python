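"""Cross-layer attention pooling and graph construction.

The per-layer attention stack is collapsed into a single matrix by
pixel-wise (element-wise) max pooling, capturing the strongest attention
relationship between each token pair anywhere in the model.  That matrix is
then read as the weighted adjacency of a directed graph over residues:
entry (i, j) is the edge weight from query token i to key token j.  Since
post-softmax attention is strictly positive, the graph is effectively fully
connected, so it is kept as a dense matrix throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PooledAttention",
    "AttentionGraph",
    "max_pool_attention",
    "build_graph",
    "save_pooled",
    "load_pooled",
]


@dataclass(frozen=True)
class PooledAttention:
    """Element-wise max over the layer stack; entries in [0, 1]."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"pooled attention must be square, got {m.shape}")
        if (m < 0).any():
            raise ValueError("pooled attention entries must be non-negative")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class AttentionGraph:
    """Dense directed weighted graph; weights[i, j] = edge weight i -> j."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"graph weights must be square, got {w.shape}")
        if (w < 0).any():
            raise ValueError("graph weights must be non-negative")
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def max_pool_attention(stack: np.ndarray) -> PooledAttention:
    """Pixel-wise max pooling across all attention matrices in the stack.

    ``stack`` is ``(L, n, n)`` with L >= 1; output entry (i, j) is
    ``max_l stack[l, i, j]``.  NaNs are rejected with the offending layer
    named; mismatched shapes are rejected.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError(f"expected a (L, n, n) stack, got shape {stack.shape}")
    if stack.shape[0] < 1:
        raise ValueError("stack must contain at least one layer")
    if stack.shape[1] != stack.shape[2]:
        raise ValueError(f"attention matrices must be square, got {stack.shape[1:]}")
    pooled = stack.max(axis=0)
    # NaN and +inf both propagate through max, so one pass over the pooled
    # matrix suffices; scan per layer only to name the offender
    if not np.isfinite(pooled).all():
        nan_layers = np.where(np.isnan(stack).any(axis=(1, 2)))[0]
        if nan_layers.size:
            raise ValueError(f"NaN attention entries in layer(s) {nan_layers.tolist()}")
        raise ValueError("attention entries must be finite")
    return PooledAttention(matrix=pooled)


def build_graph(pooled: PooledAttention, *, zero_diagonal: bool = False) -> AttentionGraph:
    """Interpret the pooled matrix as a directed weighted adjacency.

    Self-loops (the diagonal, i.e. self-attention) are retained by default;
    ``zero_diagonal=True`` removes them for ablation.
    """
    weights = pooled.matrix.copy()
    if zero_diagonal:
        np.fill_diagonal(weights, 0.0)
    return AttentionGraph(weights=weights)


def save_pooled(path: str | Path, pooled_by_id: dict[str, PooledAttention]) -> None:
    """Cache pooled attention matrices to an NPZ archive keyed by sequence id."""
    np.savez_compressed(str(path), **{k: v.matrix for k, v in pooled_by_id.items()})


def load_pooled(path: str | Path) -> dict[str, PooledAttention]:
    with np.load(str(path)) as archive:
        return {k: PooledAttention(matrix=archive[k]) for k in archive.files}
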