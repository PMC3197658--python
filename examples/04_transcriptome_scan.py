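"""Transcriptome-wide scans and the cell-cycle purge experiment.

Per-gene outcome association uses the same median-split/logrank machinery
as signatures; per-gene correlation with the proliferation index shows how
far the proliferation signal reaches beyond canonical cell-cycle genes —
which is why purging cell-cycle genes from a signature cannot rule out
proliferation as a confounder.
"""

import numpy as np

from sigsurv import (
    CohortParams,
    GeneSignature,
    build_metagene,
    compare_correlation_distributions,
    gene_outcome_scan,
    generate_linked,
    index_correlation_scan,
    metagene_index,
    purge_cell_cycle,
)

world = generate_linked(CohortParams(seed=1))
expr, clinical = world.expression, world.clinical
index = metagene_index(expr, build_metagene(world.compendium))

corr = index_correlation_scan(expr, index)
print(f"genes significantly correlated with the index: "
      f"{(corr['p_r'] < 0.05).mean():.0%} of {len(corr)}")

subset = expr.iloc[:800]  # desk-scale outcome scan
outcome = gene_outcome_scan(subset, clinical)
print(f"genes associated with outcome (p<0.05): "
      f"{(outcome['p'] < 0.05).mean():.0%} of {len(outcome)} scanned; "
      f"q<0.05: {(outcome['q'] < 0.05).mean():.0%}")

# purge experiment: remove the proliferation module ("cell-cycle genes")
# from a factor-loaded signature and ask whether the remainder still leans
# on proliferation
rng = np.random.default_rng(2)
module = set(world.planted_members)
loaded_outside_module = sorted(set(world.truth.loaded_genes) - module)
sig = GeneSignature(
    "stemness_like",
    "signature loaded on the factor, partly through cell-cycle genes",
    frozenset(list(rng.choice(loaded_outside_module, 150, replace=False))
              + sorted(module)[:50]),
)
cc_sets = [GeneSignature("cell_cycle", "known proliferation genes", frozenset(module))]
purged = purge_cell_cycle(sig, cc_sets)
background = sorted(set(expr.index) - set(world.truth.loaded_genes))
p_shift = compare_correlation_distributions(
    corr.loc[sorted(purged.genes)], corr.loc[background]
)
print(f"purged signature: {len(purged)} of {len(sig)} genes remain; "
      f"index-correlation shift vs background p = {p_shift:.1e}")
print("Interpretation: even with every known cell-cycle gene removed, the "
      "signature remains far more index-correlated than the array background.")
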