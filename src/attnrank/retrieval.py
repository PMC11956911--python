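"""Embedding-based retrieval evaluation.

Given a set of labelled sequence embeddings, each protein in turn acts as a
query and retrieves all other proteins ranked by descending cosine
similarity.  Two metrics summarize how well embedding geometry matches the
labels:

* **Precision@10% of class size** — among the top ``max(1, ceil(0.10 *
  (c - 1)))`` retrieved items (c = query's class size, query itself
  excluded), the fraction that share the query's class.
* **Mean reciprocal rank (MRR)** — average over queries of 1 / (rank of the
  first same-class item).

To remove class-imbalance effects, evaluation is repeated over many
class-balanced subsamples and reported as the across-round mean with its
standard error (sample SD / sqrt(rounds)).  Two pooling methods are
compared round-by-round with a two-sided Mann-Whitney U test, annotated
with significance stars (*** p<0.01, ** p<0.05, * p<0.10).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LabeledEmbeddingSet",
    "RetrievalTable",
    "RoundsResult",
    "MethodComparison",
    "cosine_retrieval",
    "precision_at_class_fraction",
    "reciprocal_rank",
    "mean_reciprocal_rank",
    "evaluate",
    "balanced_subsample_eval",
    "compare_methods",
]

logger = logging.getLogger(__name__)


@dataclass
class LabeledEmbeddingSet:
    """m embeddings with class labels and unique sequence ids."""

    embeddings: np.ndarray
    labels: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.embeddings = np.asarray(self.embeddings, dtype=float)
        self.labels = np.asarray(self.labels)
        self.ids = np.asarray(self.ids)
        m = self.embeddings.shape[0]
        if self.embeddings.ndim != 2:
            raise ValueError("embeddings must be an m x d matrix")
        if self.labels.shape != (m,) or self.ids.shape != (m,):
            raise ValueError("labels and ids must have one entry per embedding")
        uniq, counts = np.unique(self.ids, return_counts=True)
        if (counts > 1).any():
            raise ValueError(f"duplicate ids: {uniq[counts > 1].tolist()}")

    @property
    def m(self) -> int:
        return self.embeddings.shape[0]

    def class_sizes(self) -> dict[str, int]:
        uniq, counts = np.unique(self.labels, return_counts=True)
        return {str(u): int(c) for u, c in zip(uniq, counts)}

    def subset(self, indices: np.ndarray) -> "LabeledEmbeddingSet":
        return LabeledEmbeddingSet(
            embeddings=self.embeddings[indices],
            labels=self.labels[indices],
            ids=self.ids[indices],
        )


@dataclass(frozen=True)
class RetrievalTable:
    """Per-query metrics plus their arithmetic-mean aggregates."""

    per_query: pd.DataFrame  # columns: id, label, reciprocal_rank, precision_at_fraction
    mean_rr: float
    mean_precision: float
    n_queries: int
    fraction: float


@dataclass(frozen=True)
class RoundsResult:
    """Across-round aggregates of repeated class-balanced evaluation."""

    precision_rounds: np.ndarray
    mrr_rounds: np.ndarray
    mean_precision: float
    mean_mrr: float
    se_precision: float
    se_mrr: float
    n_rounds: int
    seed: int


@dataclass(frozen=True)
class MethodComparison:
    u_statistic: float
    p_value: float
    stars: str
    degenerate: bool = False


def _unit_rows(embeddings: np.ndarray, ids: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(embeddings, axis=1)
    zero = np.where(norms == 0)[0]
    if zero.size:
        raise ValueError(f"zero-norm embedding for id(s) {ids[zero].tolist()}")
    return embeddings / norms[:, None]


def cosine_retrieval(eset: LabeledEmbeddingSet, query_index: int) -> np.ndarray:
    """Indices of all non-query items, ranked by descending cosine similarity.

    Ties are broken by ascending sequence id so rankings are deterministic
    across implementations.
    """
    if eset.m < 2:
        raise ValueError("need at least two embeddings to retrieve")
    unit = _unit_rows(eset.embeddings, eset.ids)
    sims = unit @ unit[query_index]
    candidates = [i for i in range(eset.m) if i != query_index]
    candidates.sort(key=lambda i: (-sims[i], str(eset.ids[i])))
    return np.asarray(candidates, dtype=int)


def precision_at_class_fraction(
    eset: LabeledEmbeddingSet,
    query_index: int,
    fraction: float = 0.10,
    ranking: np.ndarray | None = None,
) -> float:
    """Precision among the top ceil(fraction * (c - 1)) retrieved items."""
    label = eset.labels[query_index]
    c = int((eset.labels == label).sum())
    if c < 2:
        raise ValueError(f"class {label!r} is a singleton; query has no valid retrieval")
    r = max(1, math.ceil(fraction * (c - 1)))
    if ranking is None:
        ranking = cosine_retrieval(eset, query_index)
    top = ranking[:r]
    return float((eset.labels[top] == label).mean())


def reciprocal_rank(
    eset: LabeledEmbeddingSet, query_index: int, ranking: np.ndarray | None = None
) -> float:
    """1 / rank of the first same-class item in the retrieval list."""
    if ranking is None:
        ranking = cosine_retrieval(eset, query_index)
    label = eset.labels[query_index]
    hits = np.where(eset.labels[ranking] == label)[0]
    if hits.size == 0:
        raise ValueError(f"query {eset.ids[query_index]!r} has no same-class candidate")
    return 1.0 / (int(hits[0]) + 1)


def evaluate(eset: LabeledEmbeddingSet, fraction: float = 0.10) -> RetrievalTable:
    """Run every eligible query; singleton-class queries are skipped with a log line."""
    rows = []
    sizes = eset.class_sizes()
    skipped = 0
    for q in range(eset.m):
        if sizes[str(eset.labels[q])] < 2:
            skipped += 1
            continue
        ranking = cosine_retrieval(eset, q)
        rows.append(
            {
                "id": str(eset.ids[q]),
                "label": str(eset.labels[q]),
                "reciprocal_rank": reciprocal_rank(eset, q, ranking),
                "precision_at_fraction": precision_at_class_fraction(eset, q, fraction, ranking),
            }
        )
    if skipped:
        logger.warning("skipped %d singleton-class query/queries", skipped)
    if not rows:
        raise ValueError("no eligible queries (every class is a singleton)")
    frame = pd.DataFrame(rows)
    return RetrievalTable(
        per_query=frame,
        mean_rr=float(frame["reciprocal_rank"].mean()),
        mean_precision=float(frame["precision_at_fraction"].mean()),
        n_queries=len(frame),
        fraction=fraction,
    )


def mean_reciprocal_rank(eset: LabeledEmbeddingSet) -> float:
    return evaluate(eset).mean_rr


def balanced_subsample_eval(
    eset: LabeledEmbeddingSet,
    class_size: int,
    n_rounds: int = 50,
    seed: int = 0,
    fraction: float = 0.10,
) -> RoundsResult:
    """Repeated class-balanced evaluation.

    Each round samples ``class_size`` members per class without replacement,
    evaluates mean precision and MRR on the subsample, and the rounds are
    summarized by their mean and standard error.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    sizes = eset.class_sizes()
    deficient = {k: v for k, v in sizes.items() if v < class_size}
    if deficient:
        raise ValueError(f"classes smaller than class_size={class_size}: {deficient}")
    rng = np.random.default_rng(seed)
    labels = np.unique(eset.labels)
    precisions = np.empty(n_rounds)
    mrrs = np.empty(n_rounds)
    for r in range(n_rounds):
        chosen = []
        for label in labels:
            members = np.where(eset.labels == label)[0]
            chosen.append(rng.choice(members, size=class_size, replace=False))
        table = evaluate(eset.subset(np.concatenate(chosen)), fraction)
        precisions[r] = table.mean_precision
        mrrs[r] = table.mean_rr

    def se(x: np.ndarray) -> float:
        return float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0

    return RoundsResult(
        precision_rounds=precisions,
        mrr_rounds=mrrs,
        mean_precision=float(precisions.mean()),
        mean_mrr=float(mrrs.mean()),
        se_precision=se(precisions),
        se_mrr=se(mrrs),
        n_rounds=n_rounds,
        seed=seed,
    )


def compare_methods(metric_rounds_a: np.ndarray, metric_rounds_b: np.ndarray) -> MethodComparison:
    """Two-sided Mann-Whitney U on per-round metrics of two pooling methods.

    Stars follow the convention *** p<0.01, ** p<0.05, * p<0.10.  If every
    value in both vectors is identical the test is degenerate and p = 1.
    """
    a = np.asarray(metric_rounds_a, dtype=float)
    b = np.asarray(metric_rounds_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two rounds per method to compare")
    if np.ptp(np.concatenate([a, b])) == 0:
        return MethodComparison(u_statistic=a.size * b.size / 2.0, p_value=1.0, stars="", degenerate=True)
    # exact U distribution when tie-free (small round counts), else normal approx
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "asymptotic" if has_ties else "exact"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if p < 0.01:
        stars_ = "***"
    elif p < 0.05:
        stars_ = "**"
    elif p < 0.10:
        stars_ = "*"
    else:
        stars_ = ""
    return MethodComparison(u_statistic=float(res.statistic), p_value=p, stars=stars_)
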