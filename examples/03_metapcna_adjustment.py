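"""Build the proliferation metagene and adjust the cohort for its index.

The metagene is the 1% of compendium genes most positively correlated with
the anchor PCNA across normal tissues; its per-sample median expression is
the proliferation index.  Regressing every gene on the index removes the
proliferation axis: random signatures lose their outcome association.
Adjusting for a permuted index (the negative control) changes nothing —
the adjustment removes structure, not information capacity.
"""

import numpy as np

from sigsurv import (
    CohortParams,
    adjust_for_index,
    build_metagene,
    build_null,
    generate_linked,
    metagene_index,
    permuted_adjustment,
)

world = generate_linked(CohortParams(seed=1))
expr, clinical = world.expression, world.clinical

metagene = build_metagene(world.compendium, anchor="PCNA", top_fraction=0.01)
planted = set(world.planted_members)
print(f"metagene: {len(metagene)} genes, anchor {metagene.anchor!r}; "
      f"recovers planted module exactly: {set(metagene.genes) == planted}")

index = metagene_index(expr, metagene)
print(f"corr(index, latent factor) = "
      f"{np.corrcoef(index, world.truth.factor)[0, 1]:.3f}")

n_draws, size = 100, 200
frac = lambda m: (build_null(size, n_draws, m, clinical, seed=3).pvalues < 0.05).mean()
print(f"significant fraction of {n_draws} random {size}-gene signatures:")
print(f"  unadjusted cohort:        {frac(expr):.2f}")
print(f"  adjusted for index:       {frac(adjust_for_index(expr, index)):.2f}")
print(f"  permuted-index control:   "
      f"{frac(permuted_adjustment(expr, index, np.random.default_rng(3))):.2f}")
print("Interpretation: one proliferation surrogate carries nearly all the "
      "outcome association of random signatures.")
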