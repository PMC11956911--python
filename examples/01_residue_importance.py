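"""Rank the residues of one protein by attention-graph PageRank importance.

Builds a synthetic encoder attention stack with one planted hub residue,
runs the importance pipeline (cross-layer max pooling -> directed graph ->
PageRank -> normalization) and prints the top-ranked positions.
"""

import numpy as np

from attnrank import FixtureSpec, planted_hub_attention, residue_importance
from attnrank.analysis import percentile_ranks
from attnrank.plm_adapter import ResidueView

n, hub = 60, 24
spec = FixtureSpec(n=n, L=4, d=16, seed=11, hub_positions=(hub,), dominance=8.0)
view = ResidueView(
    embeddings=np.random.default_rng(11).standard_normal((n, 16)),
    attention=planted_hub_attention(spec),
    sequence="M" + "A" * (n - 1),
    sequence_id="demo_protein",
)

importance = residue_importance(view)
pct = percentile_ranks(importance)

print(f"protein length {n}, converged={importance.converged} "
      f"after {importance.iterations_used} iterations")
print("top 5 residues by importance (1-based position):")
for idx in np.argsort(importance.weights)[::-1][:5]:
    print(f"  position {idx + 1:3d}  weight {importance.weights[idx]:.4f}  "
          f"percentile {pct[idx]:5.1f}")
print(f"\nThe planted hub at position {hub + 1} draws boosted attention in every "
      "layer, so PageRank assigns it the largest stationary importance; the "
      "weights sum to 1 and act as pooling coefficients.")
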