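"""Are annotated functional residues ranked among the most important?

Emulates a catalytic-site enrichment analysis: importance profiles where the
'annotated' residues are planted attention hubs, versus a control where the
annotations are random positions.
"""

import numpy as np

from attnrank import FixtureSpec, annotation_enrichment, planted_hub_attention, residue_importance
from attnrank.plm_adapter import ResidueView

n = 120
rng = np.random.default_rng(5)

for label, planted in (("functional sites = attention hubs", True),
                       ("random annotations (control)", False)):
    annotated = set((rng.choice(n, 5, replace=False) + 1).tolist())
    hubs = tuple(p - 1 for p in annotated) if planted else (int(rng.integers(n)),)
    spec = FixtureSpec(n=n, L=4, seed=7, hub_positions=hubs, dominance=6.0)
    view = ResidueView(embeddings=np.zeros((n, 8)),
                       attention=planted_hub_attention(spec), sequence="A" * n)
    result = annotation_enrichment(residue_importance(view), annotated)
    print(f"{label}:")
    print(f"  annotated percentile ranks: "
          f"{np.sort(result.percentile_ranks)[::-1].round(1)}")
    print(f"  Mann-Whitney U={result.skew_statistic:.0f}, p={result.p_value:.2e}\n")

print("When annotations coincide with residues that concentrate attention, their "
      "percentile ranks pile up near 100 and the one-sided rank test rejects; "
      "random annotations sit uniformly and the test does not.")
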