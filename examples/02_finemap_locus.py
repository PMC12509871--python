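"""Fine-map a locus: adaptive search versus exhaustive enumeration.

Simulates sib-pair families (parents ungenotyped) with two causal variants,
computes the z-score panel, runs the adaptive deterministic search and the
exhaustive two-causal enumeration, and prints PIPs and signal clusters from
both.
"""

import numpy as np

from famfine import (
    EffectSpec,
    LocusModel,
    adaptive_dap,
    build_zpanel,
    exhaustive_posterior,
)
from famfine.simulate import (
    pick_causal_indices,
    simulate_families,
    simulate_haplotype_pool,
)

pool = simulate_haplotype_pool(LocusModel(p=30, seed=21))
rng = np.random.default_rng(3)
causal = pick_causal_indices(pool, 2, "additive", rng)
families, truth = simulate_families(
    pool, "sibpair", 1200, EffectSpec(causal_indices=causal), seed=5
)
panel = build_zpanel(families)

adaptive = adaptive_dap(panel)  # default lambda = 2.0, up to 5 causal factors
caviar_style = exhaustive_posterior(panel, K=2)  # all models up to 2 causal

print(f"true causal factors: {truth.causal_factor_names}")
for name, res in (("adaptive", adaptive), ("exhaustive K=2", caviar_style)):
    print(f"\n[{name}]  log10 normalizing constant = {res.log10_nc:.2f}")
    top = np.argsort(-res.pips)[:5]
    for i in top:
        label = truth.labels.get(res.factor_names[i], "?")
        print(f"  {res.factor_names[i]:>12}  PIP {res.pips[i]:.3f}  ({label})")
    for cid, cl in enumerate(res.clusters[:3]):
        members = ", ".join(res.factor_names[m] for m in cl.members)
        print(
            f"  cluster {cid}: combined PIP {cl.cluster_pip:.3f}, "
            f"min within-r2 {cl.min_r2:.2f}  [{members}]"
        )

# Both methods should concentrate PIP mass on the causal factors (or their
# tight LD proxies, which then share a cluster); the adaptive search
# reaches the same answer while evaluating far fewer configurations.
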