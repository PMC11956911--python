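"""Do two encoders agree on which residues matter?

Computes importance profiles for the same proteins under two differently
seeded synthetic encoders that share the same planted hubs, then compares
their top-10% residue sets by Jaccard index against the random-ranking and
empirical same-length nulls.
"""

import numpy as np

from attnrank import (
    FixtureSpec,
    empirical_null_jaccard,
    jaccard,
    planted_hub_attention,
    random_jaccard_null,
    residue_importance,
    top_set,
)
from attnrank.plm_adapter import ResidueView


def importance_under_encoder(protein_seed: int, encoder_seed: int, n=80):
    hubs = tuple(np.random.default_rng(protein_seed).choice(n, 4, replace=False))
    spec = FixtureSpec(n=n, L=4, seed=1000 * encoder_seed + protein_seed,
                       hub_positions=hubs, dominance=6.0)
    view = ResidueView(embeddings=np.zeros((n, 8)),
                       attention=planted_hub_attention(spec), sequence="A" * n)
    return residue_importance(view)


k = 10.0
profiles_a = {f"p{i}": importance_under_encoder(i, encoder_seed=1) for i in range(12)}
profiles_b = {f"p{i}": importance_under_encoder(i, encoder_seed=2) for i in range(12)}

observed = [jaccard(top_set(profiles_a[p], k), top_set(profiles_b[p], k))
            for p in profiles_a]
random_null = random_jaccard_null(n=80, k_percent=k, n_draws=20_000, seed=0)
empirical = empirical_null_jaccard(profiles_a, k, n_pairs=2000, seed=0)

print(f"top-{k:.0f}% agreement between the two encoders, 12 proteins:")
print(f"  observed mean Jaccard:        {np.mean(observed):.3f}")
print(f"  random-ranking null mean:     {random_null.mean:.3f} (sd {random_null.sd:.3f})")
print(f"  empirical same-length null:   {empirical.mean:.3f} (sd {empirical.sd:.3f})")
print("\nBoth encoders see the same planted hubs, so observed agreement sits far "
      "above both chance baselines — the signature of a reproducible importance "
      "assignment rather than regional bias.")
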