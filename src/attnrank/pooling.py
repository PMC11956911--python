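"""Fixed-length sequence embeddings from token embeddings.

The importance-weighted average (method tag ``parti``) contracts the
``n x d`` token-embedding matrix with the normalized PageRank importance
vector, E_seq = sum_i alpha_i * E_tok,i.  Because the weights sum to one,
the result is a convex combination of token embeddings and its magnitude is
independent of sequence length.  Four parameter-free baselines are provided
for comparison: column-wise mean, sum and max over residue tokens, and the
[CLS] token embedding.  All reductions operate over residue tokens only
(special tokens are stripped upstream); accumulation is in float64, with
float32 applied only when archiving.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pagerank import ImportanceWeights, PageRankConfig, residue_importance
from .plm_adapter import ResidueView

__all__ = [
    "SequenceEmbedding",
    "METHODS",
    "weighted_pool",
    "mean_pool",
    "sum_pool",
    "max_pool_embed",
    "cls_pool",
    "pool_all",
    "save_embeddings",
    "load_embeddings",
]

METHODS = ("parti", "mean", "sum", "max", "cls")


@dataclass(frozen=True)
class SequenceEmbedding:
    """A single d-vector representing one protein, tagged by pooling method."""

    vector: np.ndarray
    method: str
    sequence_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        if v.ndim != 1:
            raise ValueError("embedding vector must be 1-D")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        object.__setattr__(self, "vector", v)

    @property
    def d(self) -> int:
        return self.vector.shape[0]


def _check_tokens(embeddings: np.ndarray) -> np.ndarray:
    embeddings = np.asarray(embeddings, dtype=np.float64)
    if embeddings.ndim != 2 or embeddings.shape[0] < 1:
        raise ValueError(f"token embeddings must be a non-empty n x d matrix, got {embeddings.shape}")
    return embeddings


def weighted_pool(
    embeddings: np.ndarray,
    weights: ImportanceWeights,
    sequence_id: str = "",
) -> SequenceEmbedding:
    """Importance-weighted average of token embeddings (E_seq)."""
    embeddings = _check_tokens(embeddings)
    if weights.n != embeddings.shape[0]:
        raise ValueError(
            f"weight length {weights.n} does not match {embeddings.shape[0]} token rows"
        )
    vector = weights.weights @ embeddings
    return SequenceEmbedding(vector=vector, method="parti", sequence_id=sequence_id)


def mean_pool(embeddings: np.ndarray, sequence_id: str = "") -> SequenceEmbedding:
    embeddings = _check_tokens(embeddings)
    return SequenceEmbedding(embeddings.mean(axis=0), "mean", sequence_id)


def sum_pool(embeddings: np.ndarray, sequence_id: str = "") -> SequenceEmbedding:
    embeddings = _check_tokens(embeddings)
    return SequenceEmbedding(embeddings.sum(axis=0), "sum", sequence_id)


def max_pool_embed(embeddings: np.ndarray, sequence_id: str = "") -> SequenceEmbedding:
    embeddings = _check_tokens(embeddings)
    return SequenceEmbedding(embeddings.max(axis=0), "max", sequence_id)


def cls_pool(view: ResidueView) -> SequenceEmbedding:
    """The [CLS] token embedding, where the backend provides one."""
    if view.cls_embedding is None:
        raise ValueError(
            f"the CLS-pooling baseline is undefined for backend {view.model_id!r}: "
            "the model has no [CLS] token"
        )
    return SequenceEmbedding(np.asarray(view.cls_embedding, float), "cls", view.sequence_id)


def pool_all(
    view: ResidueView,
    methods: tuple[str, ...] = METHODS,
    config: PageRankConfig | None = None,
    *,
    zero_diagonal: bool = False,
) -> tuple[dict[str, SequenceEmbedding], ImportanceWeights | None]:
    """Pool one protein with each requested method.

    Returns (embeddings keyed by method, importance weights if ``parti`` was
    among the methods else None).
    """
    out: dict[str, SequenceEmbedding] = {}
    importance: ImportanceWeights | None = None
    for method in methods:
        if method == "parti":
            importance = residue_importance(view, config, zero_diagonal=zero_diagonal)
            out[method] = weighted_pool(view.embeddings, importance, view.sequence_id)
        elif method == "mean":
            out[method] = mean_pool(view.embeddings, view.sequence_id)
        elif method == "sum":
            out[method] = sum_pool(view.embeddings, view.sequence_id)
        elif method == "max":
            out[method] = max_pool_embed(view.embeddings, view.sequence_id)
        elif method == "cls":
            out[method] = cls_pool(view)
        else:
            raise ValueError(f"unknown pooling method {method!r}")
    return out, importance


def save_embeddings(
    path: str | Path,
    embeddings: list[SequenceEmbedding],
    *,
    model_id: str = "",
    metadata: dict | None = None,
) -> None:
    """Archive embeddings to NPZ, one float32 array per (sequence_id, method).

    A ``__metadata__`` entry records model id, package version and any extra
    run configuration, so archives are self-describing.
    """
    from . import __version__

    arrays: dict[str, np.ndarray] = {}
    for emb in embeddings:
        if not emb.sequence_id:
            raise ValueError("archived embeddings need a sequence_id")
        arrays[f"{emb.sequence_id}::{emb.method}"] = emb.vector.astype(np.float32)
    meta = {"model_id": model_id, "package_version": __version__, **(metadata or {})}
    arrays["__metadata__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez_compressed(str(path), **arrays)


def load_embeddings(path: str | Path) -> tuple[dict[tuple[str, str], np.ndarray], dict]:
    """Load an embedding archive: {(sequence_id, method): vector}, metadata."""
    out: dict[tuple[str, str], np.ndarray] = {}
    meta: dict = {}
    with np.load(str(path)) as archive:
        for key in archive.files:
            if key == "__metadata__":
                meta = json.loads(archive[key].tobytes().decode())
                continue
            seq_id, method = key.rsplit("::", 1)
            out[(seq_id, method)] = archive[key].astype(np.float64)
    return out, meta
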