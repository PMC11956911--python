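"""Analyses of per-residue importance weights.

Three questions about an importance assignment are answered here:

* **Reproducibility across encoders** — do two models agree on which
  residues matter?  Measured as the Jaccard index between their top-k-percent
  importance sets, judged against two chance baselines: an exchangeable
  random-ranking null (two independent uniformly random rankings of the same
  protein) and an empirical null that pairs top sets from *different*
  proteins of the same length.
* **Functional enrichment** — are experimentally annotated residues (e.g.
  catalytic sites) concentrated in the upper tail of the importance
  distribution?  Reported as the percentile ranks of annotated residues plus
  a Mann-Whitney U test of annotated vs non-annotated importance weights.
* **Ranking utilities** — percentile ranks and deterministic top-percentile
  sets used by both analyses.
"""

from __future__ import annotations

import math
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pagerank import ImportanceWeights

__all__ = [
    "TopSet",
    "EnrichmentResult",
    "NullSummary",
    "percentile_ranks",
    "top_set",
    "jaccard",
    "random_jaccard_null",
    "empirical_null_jaccard",
    "annotation_enrichment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TopSet:
    """The ceil(k*n/100) highest-importance residue positions (1-based).

    Ties at the cutoff are broken by lower position index, so the set is a
    deterministic function of the weights, and invariant to any strictly
    monotone transformation of them.
    """

    positions: frozenset[int]
    k_percent: float
    n: int


@dataclass(frozen=True)
class EnrichmentResult:
    """Percentile ranks of annotated residues and a one-sided rank test.

    ``skew_statistic`` is the Mann-Whitney U of annotated vs non-annotated
    importance weights (alternative: annotated greater); ``degenerate`` is
    set — and the p-value is NaN — when the weights are tied to the point
    that the test carries no information (e.g. uniform importance).
    """

    percentile_ranks: np.ndarray
    n_annotated: int
    skew_statistic: float
    p_value: float
    degenerate: bool = False
    test: str = "mann-whitney-u-greater"


@dataclass(frozen=True)
class NullSummary:
    """Monte-Carlo summary of a Jaccard null distribution."""

    mean: float
    sd: float
    quantiles: dict[str, float]
    n_draws: int
    seed: int
    n_skipped: int = 0

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "quantiles": self.quantiles,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "n_skipped": self.n_skipped,
        }


def _as_weights(weights: ImportanceWeights | np.ndarray) -> np.ndarray:
    if isinstance(weights, ImportanceWeights):
        return weights.weights
    return np.asarray(weights, dtype=float)


def percentile_ranks(weights: ImportanceWeights | np.ndarray) -> np.ndarray:
    """Percentile rank of each residue's weight among all n weights.

    Average-rank tie handling, scaled so 100 marks the most important
    residue: ``100 * rank / n``.
    """
    w = _as_weights(weights)
    ranks = stats.rankdata(w, method="average")
    return 100.0 * ranks / w.shape[0]


def top_set_size(n: int, k_percent: float) -> int:
    return max(1, math.ceil(k_percent * n / 100.0))


def top_set(weights: ImportanceWeights | np.ndarray, k_percent: float) -> TopSet:
    """The top-k-percent importance set under the deterministic tie rule."""
    if not 0 < k_percent <= 100:
        raise ValueError(f"k_percent must be in (0, 100], got {k_percent}")
    w = _as_weights(weights)
    n = w.shape[0]
    size = top_set_size(n, k_percent)
    # stable sort on (-weight, position): ties at the cutoff go to lower index
    order = np.lexsort((np.arange(n), -w))
    positions = frozenset(int(i) + 1 for i in order[:size])
    return TopSet(positions=positions, k_percent=float(k_percent), n=n)


def jaccard(a: TopSet, b: TopSet) -> float:
    """|A ∩ B| / |A ∪ B| for two top sets over the same protein length."""
    if a.n != b.n:
        raise ValueError(f"top sets compare proteins of different lengths ({a.n} vs {b.n})")
    union = a.positions | b.positions
    if not union:
        return 1.0
    return len(a.positions & b.positions) / len(union)


def _summarize(values: np.ndarray, seed: int, n_skipped: int = 0) -> NullSummary:
    qs = np.quantile(values, [0.025, 0.25, 0.5, 0.75, 0.975])
    return NullSummary(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        quantiles={k: float(v) for k, v in zip(["q2.5", "q25", "q50", "q75", "q97.5"], qs)},
        n_draws=int(values.size),
        seed=seed,
        n_skipped=n_skipped,
    )


def random_jaccard_null(
    n: int, k_percent: float, n_draws: int = 10_000, seed: int = 0
) -> NullSummary:
    """Null agreement between two independent uniformly random rankings.

    Draws ``n_draws`` pairs of random importance rankings of ``n`` residues,
    forms each pair's top-k-percent sets and records their Jaccard index.
    This is the exchangeable-ranking chance model for cross-encoder
    agreement: |A ∩ B| is hypergeometric with k_abs draws from k_abs marked
    items among n.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    size = top_set_size(n, k_percent)
    # top set of a uniformly random ranking = first `size` entries of a
    # random permutation; vectorized via argpartition of random keys
    keys = rng.random(size=(2 * n_draws, n))
    tops = np.argpartition(keys, size - 1, axis=1)[:, :size]
    values = np.empty(n_draws)
    for i in range(n_draws):
        a = set(tops[2 * i].tolist())
        b = set(tops[2 * i + 1].tolist())
        values[i] = len(a & b) / len(a | b)
    return _summarize(values, seed)


def empirical_null_jaccard(
    importance_by_protein: dict[str, ImportanceWeights | np.ndarray],
    k_percent: float,
    n_pairs: int = 1000,
    seed: int = 0,
) -> NullSummary:
    """Chance agreement between top sets of *different* same-length proteins.

    Samples ``n_pairs`` pairs of distinct proteins with equal length and
    computes the cross-protein top-set Jaccard.  Draws that land on a length
    with no same-length partner are skipped and counted.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    by_length: dict[int, list[np.ndarray]] = {}
    for w in importance_by_protein.values():
        arr = _as_weights(w)
        by_length.setdefault(arr.shape[0], []).append(arr)
    eligible = {length: ws for length, ws in by_length.items() if len(ws) >= 2}
    if not eligible:
        raise ValueError("no pair of proteins shares a length; empirical null undefined")
    n_total = sum(len(v) for v in by_length.values())
    n_eligible = sum(len(v) for v in eligible.values())
    n_skipped = n_total - n_eligible
    if n_skipped:
        logger.info("empirical null: %d protein(s) have no same-length partner", n_skipped)

    rng = np.random.default_rng(seed)
    lengths = list(eligible)
    # sample lengths proportional to the number of distinct pairs they offer
    counts = np.array([len(eligible[l]) for l in lengths], dtype=float)
    probs = counts * (counts - 1)
    probs /= probs.sum()
    values = np.empty(n_pairs)
    for i in range(n_pairs):
        length = lengths[rng.choice(len(lengths), p=probs)]
        ia, ib = rng.choice(len(eligible[length]), size=2, replace=False)
        values[i] = jaccard(
            top_set(eligible[length][ia], k_percent),
            top_set(eligible[length][ib], k_percent),
        )
    return _summarize(values, seed, n_skipped=n_skipped)


def annotation_enrichment(
    weights: ImportanceWeights | np.ndarray,
    annotated_positions: set[int],
) -> EnrichmentResult:
    """Are annotated residues ranked among the most important positions?

    Positions are 1-based.  Reports the annotated residues' percentile ranks
    and a one-sided two-sample Mann-Whitney U test of importance weights,
    annotated vs the rest (equivalent to testing the annotated percentile
    ranks against the uniform-rank null).
    """
    w = _as_weights(weights)
    n = w.shape[0]
    if not annotated_positions:
        raise ValueError("annotated position set is empty")
    pos = np.asarray(sorted(annotated_positions), dtype=int)
    if pos.min() < 1 or pos.max() > n:
        bad = [int(p) for p in pos if p < 1 or p > n]
        raise ValueError(f"annotated positions out of range [1, {n}]: {bad}")
    pct = percentile_ranks(w)
    mask = np.zeros(n, dtype=bool)
    mask[pos - 1] = True
    annotated_ranks = pct[mask]

    if (~mask).sum() == 0 or np.ptp(w) == 0:
        # all residues annotated, or weights carry no ranking information:
        # a p-value here would be spurious
        return EnrichmentResult(
            percentile_ranks=annotated_ranks,
            n_annotated=int(mask.sum()),
            skew_statistic=float("nan"),
            p_value=float("nan"),
            degenerate=True,
        )
    result = stats.mannwhitneyu(w[mask], w[~mask], alternative="greater")
    return EnrichmentResult(
        percentile_ranks=annotated_ranks,
        n_annotated=int(mask.sum()),
        skew_statistic=float(result.statistic),
        p_value=float(result.pvalue),
        degenerate=False,
    )
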