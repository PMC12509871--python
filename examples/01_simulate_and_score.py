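"""Simulate a family-based locus and compute association z-scores.

Builds a 20-variant locus with block-decaying LD, samples 800 trio families
with one causal variant acting additively on a quantitative trait, runs the
conditional score test for every factor and prints the strongest
associations together with the offspring-estimated correlation of their
genotypes with the causal factor.
"""

import numpy as np

from famfine import EffectSpec, LocusModel, build_zpanel
from famfine.simulate import (
    pick_causal_indices,
    simulate_families,
    simulate_haplotype_pool,
)

pool = simulate_haplotype_pool(LocusModel(p=20, seed=7))
rng = np.random.default_rng(11)
causal = pick_causal_indices(pool, 1, "additive", rng)
eff = EffectSpec(causal_indices=causal)
families, truth = simulate_families(pool, "trio", 800, eff, seed=13)

panel = build_zpanel(families, model="additive")
ci = panel.names.index(truth.causal_factor_names[0])

print(f"causal variant: {truth.causal_factor_names[0]} (index {causal[0]})")
print(f"{'factor':>12} {'z':>8} {'p':>10} {'n_inf':>6} {'r_causal':>9}")
order = np.argsort(-np.abs(panel.z))[:6]
for i in order:
    print(
        f"{panel.names[i]:>12} {panel.z[i]:8.2f} {panel.p_values[i]:10.2e} "
        f"{panel.n_informative[i]:6d} {panel.R[i, ci]:9.2f}"
    )

# The causal factor should carry the largest |z|; neighbours in LD carry
# attenuated copies of the signal (|z| roughly r times the causal z), which
# is exactly the ambiguity fine-mapping resolves.
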