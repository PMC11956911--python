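"""Deterministic synthetic generators for attention stacks and embedding sets.

Every other module in the package is testable against these fixtures without
downloading a protein language model.  All generators are pure functions of a
:class:`FixtureSpec` (including its seed) and use numpy's PCG64
``default_rng``, so outputs are bit-stable across platforms.

Default shapes mimic an ESM2-style encoder scaled down (4 layers instead of
33, 16 embedding dimensions instead of 1280) to keep test runs sub-second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FixtureSpec",
    "random_attention_stack",
    "planted_hub_attention",
    "gaussian_class_embeddings",
    "random_token_embeddings",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters controlling the synthetic generators.

    Parameters
    ----------
    n : residue count of the simulated protein.
    L : number of transformer layers (attention matrices).
    d : token-embedding dimension.
    hub_positions : 0-based indices of residues whose attention columns are
        boosted by ``dominance`` in :func:`planted_hub_attention`.
    dominance : multiplicative boost (> 1) applied to hub columns.
    class_count, class_size : shape of the labelled embedding set produced by
        :func:`gaussian_class_embeddings`.
    class_separation : radius of the sphere on which class means are placed;
        members carry unit-variance isotropic noise, so separation 0 means the
        labels carry no signal and large separation means perfectly clustered.
    seed : seed for the pinned PCG64 generator.
    """

    n: int = 50
    L: int = 4
    d: int = 16
    hub_positions: tuple[int, ...] = (0,)
    dominance: float = 10.0
    class_count: int = 4
    class_size: int = 20
    class_separation: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n", "L", "d", "class_count", "class_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")


def _rng(spec: FixtureSpec, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng((spec.seed, salt))


def random_attention_stack(spec: FixtureSpec) -> np.ndarray:
    """Stack of ``L`` row-stochastic ``n x n`` matrices, rows ~ flat Dirichlet.

    Returns an array of shape ``(L, n, n)`` where every row of every layer
    sums to 1 (a post-softmax attention pattern with no planted structure).
    """
    rng = _rng(spec, salt=1)
    # Flat Dirichlet rows via normalized standard exponentials.
    raw = rng.standard_exponential(size=(spec.L, spec.n, spec.n))
    return raw / raw.sum(axis=2, keepdims=True)


def planted_hub_attention(spec: FixtureSpec) -> np.ndarray:
    """Attention stack whose hub columns draw boosted attention in every layer.

    Starting from :func:`random_attention_stack` (same seed), each hub
    column's entries are multiplied by ``spec.dominance`` and rows are
    renormalized.  With a large dominance factor the hub columns dominate the
    cross-layer max-pooled matrix with high probability, making the hub the
    top-ranked node under PageRank; the limit dominance -> 1 recovers the
    unstructured stack.
    """
    if not spec.hub_positions:
        raise ValueError("hub_positions must be non-empty")
    if spec.dominance <= 1:
        raise ValueError(f"dominance must be > 1, got {spec.dominance}")
    hubs = np.asarray(spec.hub_positions, dtype=int)
    if hubs.min() < 0 or hubs.max() >= spec.n:
        raise ValueError("hub_positions out of range")
    stack = random_attention_stack(spec).copy()
    stack[:, :, hubs] *= spec.dominance
    return stack / stack.sum(axis=2, keepdims=True)


def random_token_embeddings(spec: FixtureSpec) -> np.ndarray:
    """Unstructured ``n x d`` standard-normal token embeddings."""
    return _rng(spec, salt=2).standard_normal(size=(spec.n, spec.d))


def gaussian_class_embeddings(spec: FixtureSpec):
    """Labelled embedding set with controllable class separation.

    Class means are drawn uniformly on the sphere of radius
    ``spec.class_separation`` in ``d`` dimensions; each class contributes
    ``class_size`` members equal to its mean plus unit-variance Gaussian
    noise.  Returns a :class:`attnrank.retrieval.LabeledEmbeddingSet`.
    """
    from .retrieval import LabeledEmbeddingSet

    if spec.class_count < 2:
        raise ValueError("class_count must be >= 2")
    rng = _rng(spec, salt=3)
    directions = rng.standard_normal(size=(spec.class_count, spec.d))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    means = spec.class_separation * directions

    m = spec.class_count * spec.class_size
    embeddings = np.repeat(means, spec.class_size, axis=0)
    embeddings = embeddings + rng.standard_normal(size=(m, spec.d))
    labels = np.repeat([f"class_{c}" for c in range(spec.class_count)], spec.class_size)
    ids = np.array([f"seq_{i:05d}" for i in range(m)])
    return LabeledEmbeddingSet(embeddings=embeddings, labels=labels, ids=ids)
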