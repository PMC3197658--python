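import numpy as np
import pandas as pd
import pytest

from sigsurv.metapcna import build_metagene, metagene_index
from sigsurv.synthetic import CohortParams, generate_cohort, generate_linked


@pytest.fixture(scope="session")
def linked_world():
    """Default cohort + compendium sharing a proliferation module (seed 0)."""
    return generate_linked(CohortParams(seed=0))


@pytest.fixture(scope="session")
def metagene(linked_world):
    return build_metagene(linked_world.compendium)


@pytest.fixture(scope="session")
def meta_index(linked_world, metagene):
    return metagene_index(linked_world.expression, metagene)


@pytest.fixture(scope="session")
def small_cohort():
    """Small structureless cohort (no latent factor, no survival effect)."""
    params = CohortParams(
        n_samples=120, n_genes=500, frac_loaded=0.0, beta=0.0, seed=42
    )
    expr, clin, truth = generate_cohort(params)
    return expr, clin, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_expression():
    return pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, np.nan, 6.0]],
        index=pd.Index(["GA", "GB"], name="gene"),
        columns=["s1", "s2", "s3"],
    )
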