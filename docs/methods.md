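# Methods

## The importance model

Given a length-*n* protein and an encoder PLM with *L* layers, the pipeline
consumes the post-softmax attention stack **A**₁…**A**_L (each *n × n* after
restriction to residue tokens) and the token embeddings **E**_tok ∈ ℝ^{n×d}.
Importance is the stationary distribution of a damped random surfer on the
directed graph whose adjacency is the element-wise maximum of the layer
matrices:

    M_att = max_l A_l                      (pixel-wise max pooling)
    α ← (1−d)/n · 1 + d · Pᵀ α             (power iteration from α = 1/n)

where P row-normalizes M_att (dangling rows, which can only arise from
all-zero attention rows, become uniform 1/n) and *d* = 0.85. Iteration stops
when the L1 change of successive iterates falls below 10⁻⁶ or after 100
iterations; the final vector is renormalized to sum exactly to 1. The
sequence embedding is the α-weighted average of token embeddings.

Assumptions worth stating explicitly:

* Attention is taken **post-softmax**; each layer is row-stochastic before
  special-token removal. Pre-softmax scores have no probabilistic reading as
  edge weights and are out of scope.
* The graph is **directed**: attention of query *i* on key *j* is not
  attention of *j* on *i*, and the asymmetry is preserved.
* Attention matrices of BERT-style encoders are strictly positive, so the
  graph is effectively complete; it is stored dense, and the per-protein
  cost is Θ(n²) per power-iteration step.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `damping` | 0.85 | probability of following an attention edge vs teleporting uniformly |
| `max_iterations` | 100 | cap on power-iteration steps; reaching it returns the last iterate with `converged=False` and a warning, not an error |
| `tolerance` | 1e-6 | absolute L1 threshold on successive iterates |
| `head_reduction` | `max` | element-wise max over heads within a layer; `mean` available |
| `zero_diagonal` | off | drop self-attention edges before PageRank (ablation) |

The three PageRank values are the method's canonical constants and are kept
as the package defaults. Head reduction is a genuinely open design point:
encoders emit H matrices per layer while the model is defined over one
per layer. Element-wise max is the default because it commutes with the
cross-layer max — the pooled matrix is then a single max over all layer-head
matrices, i.e. the strongest attention relationship anywhere in the model;
head-mean is exposed for comparison. Special tokens ([CLS]/EOS/pad) are
stripped **before** pooling and graph construction so importance mass is
distributed over residues only; the baseline poolers likewise operate over
residue tokens only, for comparability. Sequences longer than the encoder's
context window are a hard error: chunked attention has no defined semantics
here.

## Convergence convention

The stop rule uses the absolute L1 norm of successive iterates. Some graph
libraries scale the threshold with n (stopping at n·tol); the absolute
convention is chosen so stringency does not loosen with protein length, and
since the tolerance is configurable either behaviour is reproducible. With
damping 0.85 the iteration contracts geometrically; typical attention
graphs converge in well under 20 iterations.

Degenerate inputs: an all-zero attention matrix makes every row dangling,
the transition matrix uniform, and the output exactly 1/n. n = 1 returns
[1.0] without iteration being meaningful. Non-finite iterates (only possible
with non-finite input that slipped past validation) raise rather than
propagate.

## Ranking analyses

**Top-percentile sets.** The top-k% set has ⌈k·n/100⌉ members (minimum 1);
ties at the cutoff are broken by lower position index, making the set a
deterministic function of the weights and invariant under strictly monotone
transformations. The rounding rule is a package choice; nothing in the
method constrains it.

**Chance models for cross-encoder agreement.** The theoretical null draws
two independent uniformly random rankings and intersects their top sets —
under exchangeability |A∩B| is hypergeometric, which serves as an
independent oracle for the Monte-Carlo sampler. The empirical null pairs
top sets from *different* proteins of the same length, so it additionally
absorbs any positional bias a real encoder might have (e.g. systematically
weighting termini). For unstructured profiles the two nulls coincide by
construction.

**Annotation enrichment.** Reported as the percentile ranks (average-rank
ties, 100 = most important) of annotated residues, with a one-sided
two-sample Mann-Whitney U of importance weights, annotated vs rest. The
test choice is a package decision recorded in the result metadata; the
one-sided alternative reflects that only excess importance of annotated
residues is of interest. Uniform weights (or an annotation covering every
residue) make the test uninformative: the result is flagged `degenerate`
with a NaN p-value instead of a spurious number.

## Retrieval evaluation

Cosine retrieval excludes the query and breaks similarity ties by ascending
sequence id. "Precision@10% of class size" retrieves max(1, ⌈0.10·(c−1)⌉)
items for a query whose class has c members — the query itself is excluded
from both the candidate pool and the class count's numerator. Singleton
classes cannot be retrieved correctly; such queries are skipped with a
logged warning in batch evaluation and are an error when addressed
directly. MRR uses the first same-class hit only. Both metrics depend only
on cosine geometry and are invariant to global rotation and positive
rescaling of the embedding set.

Class-balanced resampling draws `class_size` members per class without
replacement per round; the across-round standard error is sample SD/√rounds.
Method comparison is a two-sided Mann-Whitney U on per-round metrics, using
the exact U distribution when the values are tie-free (round counts are
small) and the normal approximation otherwise, starred at p < 0.01 / 0.05 /
0.10. Identical vectors short-circuit to p = 1 with a degenerate flag.

## Synthetic fixtures: what they emulate and what they do not

The generators stand in for encoder outputs so the pipeline is testable
without a model download. `random_attention_stack` draws flat-Dirichlet
rows — row-stochastic but unstructured. `planted_hub_attention` multiplies
designated columns by a dominance factor (> 1) and renormalizes rows in
every layer, creating residues that verifiably concentrate attention; with
dominance 10 the hub is recovered as the top-ranked residue in 100/100
seeded fixtures. Because flat-Dirichlet entries are unbounded in ratio, a
finite dominance factor makes element-wise dominance of hub columns in the
pooled matrix overwhelmingly likely rather than certain; the recovery tests
are therefore stated over seeds, all of which pass.
`gaussian_class_embeddings` places class means on a sphere of radius
`class_separation` with unit-variance members: separation 0 is an exact
label-free null, large separation the perfect-clustering limit.

Fixture shapes default to an ESM2-like geometry scaled down (L = 4 layers,
d = 16 dimensions) so tests run in milliseconds. The synthetic backend wraps
residue-level stacks in [CLS]/EOS bookkeeping with residue rows placing zero
attention on special tokens, so stripping round-trips the planted stack
exactly; per-sequence seeds derive from CRC32 of the sequence. All
randomness flows through numpy's PCG64 `default_rng`, pinned for
cross-platform stability.

What passing these tests shows: the algorithmic pipeline is correct
(oracle-equivalent PageRank, exact pooling algebra, calibrated nulls,
deterministic outputs) and responds to planted structure as designed. What
it does not show: that real PLM attention exhibits hubs at functional
residues — the fixtures deliberately do not mimic real attention statistics
(sparsity, positional decay, head specialization), so biological claims
require real encoder outputs through the `HuggingFaceBackend`.

## Problem sizes and numerics

The verification suite uses 10-node graphs (×100) for oracle equivalence
against a dense linear solve (agreement ≤ 10⁻⁸ L∞ when iterated to a 10⁻¹³
tolerance), n = 50 fixtures for hub recovery, 1000 random instances for the
pooling identities, 80-embedding Gaussian sets for retrieval limits, 1000
simulations for type-I calibration, and lengths 100–1600 for the runtime
power-law fit (measured exponent ≈ 2.2, consistent with the Θ(n²)
per-iteration cost; no absolute times are asserted). Pooling accumulates in
float64 — archives store float32, adequate for cosine retrieval — and the
weighted average is verified against a scalar loop to 10⁻¹².

## Known limitations

* Decoder/autoregressive and attention-free architectures are out of scope;
  the attention-stack contract presumes an encoder with all-to-all
  attention.
* Dense Θ(n²) storage is the right trade-off for complete attention graphs
  but wasteful if a future backend emitted sparse attention.
* The empirical null requires same-length protein pairs; collections of
  all-distinct lengths cannot use it.
* Importance weights are normalized to sum to 1, so embeddings carry no
  length signal by design — tasks where length is informative (e.g.
  interaction propensity) may favour sum pooling, which is why the baseline
  is kept.
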