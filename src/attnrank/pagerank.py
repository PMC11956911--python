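"""Weighted PageRank over the attention graph: per-residue importance.

Node importance is the stationary distribution of a random surfer who, with
probability ``damping`` (default 0.85), follows an outgoing edge chosen
proportionally to its attention weight, and otherwise teleports uniformly.
The fixed point is found by dense power iteration

    alpha <- (1 - d)/n * 1 + d * P^T alpha

from the uniform start, stopping when the L1 change drops below the
tolerance (1e-6) or after 100 iterations, and is finally renormalized to
sum exactly to 1.  Those defaults are part of the method definition; they
are exposed through :class:`PageRankConfig` but should rarely be changed.

The iteration is written as explicit dense matrix-vector products rather
than a graph-library call: attention graphs are fully connected, so dense
algebra is the natural representation, and the small hand-rolled solver can
be verified against an independent linear-solve oracle.

The convergence test uses the *absolute* L1 norm of successive iterates, so
the stringency of the stop rule does not depend on sequence length.  (Some
graph libraries scale the threshold with n; pass ``tolerance=n * tol`` to
reproduce that convention.)
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .attention_graph import AttentionGraph, build_graph, max_pool_attention
from .plm_adapter import ResidueView

__all__ = [
    "PageRankConfig",
    "ImportanceWeights",
    "transition_matrix",
    "pagerank",
    "residue_importance",
    "write_importance_tsv",
    "read_importance_tsv",
]


@dataclass(frozen=True)
class PageRankConfig:
    """Random-surfer parameters; defaults are the method's canonical values."""

    damping: float = 0.85
    max_iterations: int = 100
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 < self.damping < 1:
            raise ValueError(f"damping must be in (0, 1), got {self.damping}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass(frozen=True)
class ImportanceWeights:
    """Normalized per-residue importance (non-negative, sums to 1)."""

    weights: np.ndarray
    converged: bool = True
    iterations_used: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1:
            raise ValueError("weights must be a 1-D vector")
        if (w < 0).any():
            raise ValueError("importance weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"importance weights must sum to 1, got {w.sum()!r}")
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def transition_matrix(graph: AttentionGraph) -> np.ndarray:
    """Row-normalize edge weights; dangling rows become uniform 1/n."""
    w = graph.weights
    rowsum = w.sum(axis=1)
    n = graph.n
    out = np.empty_like(w)
    dangling = rowsum == 0
    live = ~dangling
    out[live] = w[live] / rowsum[live, None]
    out[dangling] = 1.0 / n
    return out


def pagerank(graph: AttentionGraph, config: PageRankConfig | None = None) -> ImportanceWeights:
    """Power-iterate the damped random-surfer update to its fixed point.

    Returns the last iterate with ``converged=False`` (and a warning) if the
    iteration cap is reached before the L1 change drops below tolerance.
    """
    config = config or PageRankConfig()
    p = transition_matrix(graph)
    n = graph.n
    alpha = np.full(n, 1.0 / n)
    teleport = (1.0 - config.damping) / n
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        # (P^T alpha)_j == (alpha P)_j; the row-major product avoids a transpose copy
        new = teleport + config.damping * (alpha @ p)
        if not np.isfinite(new).all():
            raise FloatingPointError("non-finite PageRank iterate")
        delta = np.abs(new - alpha).sum()
        alpha = new
        if delta < config.tolerance:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"PageRank did not converge in {config.max_iterations} iterations "
            f"(n={n}); returning the last iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    alpha = np.clip(alpha, 0.0, None)
    alpha /= alpha.sum()
    return ImportanceWeights(weights=alpha, converged=converged, iterations_used=iterations)


def residue_importance(
    view: ResidueView,
    config: PageRankConfig | None = None,
    *,
    zero_diagonal: bool = False,
) -> ImportanceWeights:
    """End-to-end single-protein importance: pool layers, build graph, rank.

    Deterministic — there is no randomness anywhere in the pipeline.
    """
    pooled = max_pool_attention(view.attention)
    graph = build_graph(pooled, zero_diagonal=zero_diagonal)
    return pagerank(graph, config)


def write_importance_tsv(
    path: str | Path,
    records: dict[str, tuple[str, ImportanceWeights]],
) -> None:
    """Write per-residue importance as TSV.

    ``records`` maps sequence_id -> (sequence, weights).  Columns:
    sequence_id, position (1-based), residue, importance, percentile_rank.
    """
    from .analysis import percentile_ranks

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sequence_id", "position", "residue", "importance", "percentile_rank"])
        for seq_id, (sequence, imp) in records.items():
            pct = percentile_ranks(imp)
            for i, (aa, w, p) in enumerate(zip(sequence, imp.weights, pct), start=1):
                writer.writerow([seq_id, i, aa, f"{w:.10e}", f"{p:.6f}"])


def read_importance_tsv(path: str | Path) -> dict[str, np.ndarray]:
    """Read importance TSV back as sequence_id -> weight vector (1-based order)."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t")
    expected = {"sequence_id", "position", "importance"}
    if not expected <= set(frame.columns):
        raise ValueError(f"importance TSV must have columns {sorted(expected)}")
    out: dict[str, np.ndarray] = {}
    for seq_id, group in frame.groupby("sequence_id", sort=False):
        group = group.sort_values("position")
        if not (group["position"].to_numpy() == np.arange(1, len(group) + 1)).all():
            raise ValueError(f"positions for {seq_id} are not contiguous from 1")
        out[str(seq_id)] = group["importance"].to_numpy(dtype=float)
    return out
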