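"""Compare pooling methods by embedding-based class retrieval.

Builds a labelled Gaussian-cluster embedding set, degrades it differently per
'method' to mimic poolers of different quality, and reports Precision@10% of
class size and mean reciprocal rank over class-balanced sampling rounds with
Mann-Whitney significance stars against the best method.
"""

import numpy as np

from attnrank import FixtureSpec, gaussian_class_embeddings
from attnrank.retrieval import LabeledEmbeddingSet, balanced_subsample_eval, compare_methods

base = gaussian_class_embeddings(
    FixtureSpec(class_count=4, class_size=40, class_separation=3.0, d=32, seed=2)
)
rng = np.random.default_rng(3)
noise_per_method = {"parti": 0.0, "mean": 0.8, "sum": 0.8, "max": 2.5, "cls": 4.0}

rounds = {}
for method, extra_noise in noise_per_method.items():
    emb = base.embeddings + extra_noise * rng.standard_normal(base.embeddings.shape)
    eset = LabeledEmbeddingSet(emb, base.labels, base.ids)
    rounds[method] = balanced_subsample_eval(eset, class_size=20, n_rounds=50, seed=0)

print(f"{'method':<8}{'Precision@10%':>15}{'MRR':>10}   vs parti")
for method, res in rounds.items():
    stars = ""
    if method != "parti":
        stars = compare_methods(rounds["parti"].precision_rounds, res.precision_rounds).stars
    print(f"{method:<8}{res.mean_precision:>15.3f}{res.mean_mrr:>10.3f}   {stars}")
print("\n50 class-balanced rounds each; stars mark methods whose per-round "
      "precision differs from the reference (*** p<0.01, ** p<0.05, * p<0.10). "
      "Cleaner embeddings retrieve same-class proteins earlier, lifting both metrics.")
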