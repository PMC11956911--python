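# attnrank

Attention-graph PageRank pooling for protein language models: per-residue
importance weights and fixed-length, length-independent protein sequence
embeddings derived from a transformer encoder's own attention matrices —
with no training, labels or tunable parameters.

## The problem

An encoder protein language model (PLM) such as ESM2 or protBERT turns a
protein of *n* residues into an *n × d* token-embedding matrix
**E**<sub>tok</sub>. Most sequence-level tasks (fold classification, enzyme
class retrieval, interaction prediction) need one fixed-length vector per
protein, so the matrix must be pooled. The standard parameter-free poolers —
mean, sum, max over tokens, or the [CLS] token — treat all residues alike
(or ignore them entirely), discarding the fact that a handful of catalytic
or structurally critical residues carry most of the functional signal.

The transformer already knows which residues matter: its post-softmax
attention matrices **A**<sub>l</sub> ∈ ℝ<sup>n×n</sup> (one per layer *l* =
1…*L*, after reducing heads) encode how strongly each residue attends to
each other residue. This package turns that internal signal into pooling
weights:

1. **Pixel-wise max pooling** across layers:
   **M**<sub>att</sub> = max<sub>l</sub> **A**<sub>l</sub> — the strongest
   attention relationship between each residue pair anywhere in the model.
2. **Graph construction**: read **M**<sub>att</sub> as the weighted
   adjacency of a directed graph (edge *i* → *j* = pooled attention of
   query *i* on key *j*).
3. **PageRank** with damping *d* = 0.85, at most 100 iterations,
   convergence tolerance 10⁻⁶, giving stationary node importances.
4. **Normalization**: α<sub>imp</sub> scaled to sum to 1.
5. **Weighted average**: **E**<sub>seq</sub> = Σ<sub>i</sub>
   α<sub>imp,i</sub> **E**<sub>tok,i</sub>.

Because α<sub>imp</sub> is a probability vector, **E**<sub>seq</sub> is a
convex combination of token embeddings and its magnitude does not grow with
sequence length. The weights themselves are interpretable: residues with
high α<sub>imp</sub> tend to coincide with experimentally annotated
functional sites.

The package also ships the four baseline poolers, the analyses used to
validate importance weights (cross-encoder top-*k* Jaccard agreement with
theoretical and empirical nulls, annotation-enrichment rank tests), cosine
retrieval evaluation (Precision@10% of class size, mean reciprocal rank,
class-balanced resampling, Mann-Whitney method comparison), and a
deterministic synthetic encoder so everything is testable offline.

## Worked example

```python
import numpy as np
from attnrank import FixtureSpec, planted_hub_attention, residue_importance
from attnrank.plm_adapter import ResidueView

n, hub = 60, 24
spec = FixtureSpec(n=n, L=4, d=16, seed=11, hub_positions=(hub,), dominance=8.0)
view = ResidueView(
    embeddings=np.random.default_rng(11).standard_normal((n, 16)),
    attention=planted_hub_attention(spec),
    sequence="M" + "A" * (n - 1),
)
imp = residue_importance(view)
print(imp.weights.argmax() + 1, round(imp.weights.max(), 4), round(imp.weights.sum(), 6))
```

prints `25 0.093 1.0`: the residue planted as an attention hub (1-based
position 25) receives the largest importance weight (0.093, against a
uniform baseline of 1/60 ≈ 0.017), and the weights sum to one as pooling
coefficients must. `examples/` contains five narrative scripts covering
each capability (importance ranking, pooling + archiving, cross-encoder
agreement, annotation enrichment, retrieval benchmarking); each prints its
numbers with a one-line interpretation.

There is also a thin CLI:

```bash
attnrank embed --fasta proteins.fasta --out-archive emb.npz --importance-tsv imp.tsv
attnrank agree imp_esm2.tsv imp_protbert.tsv --k 3 --k 10 --k 20
attnrank enrich imp.tsv catalytic_sites.tsv
attnrank eval-retrieval emb.npz labels.tsv --class-size 10 --rounds 50
```

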