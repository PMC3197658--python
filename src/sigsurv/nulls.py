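"""Size-matched random-signature null distributions.

The null model for "is this signature associated with outcome?" is not "no
association" but "no more association than a random set of genes of the same
size".  These helpers draw random signatures from the measured gene
universe, push each through the scoring/median-split/survival pipeline, and
locate an observed signature within the resulting null distribution.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sigsurv.io import GeneSignature
from sigsurv.scoring import median_split, signature_score
from sigsurv.survival import SurvivalAssociation, cox_binary_hr

logger = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    """Survival associations of random signatures of one fixed size."""

    signature_size: int
    draws: pd.DataFrame  # columns: p, hr; one row per accepted draw
    seed: int
    n_draws: int
    n_redrawn: int = 0

    @property
    def pvalues(self) -> np.ndarray:
        return self.draws["p"].to_numpy()


@dataclass
class EmpiricalResult:
    """Observed signature located within its size-matched null.

    ``beats_best_5pct`` is the relevance criterion: the observed association
    is stronger than that of the best 5% of random signatures.
    """

    observed_p: float
    frac_null_better: float
    beats_best_5pct: bool
    beats_median: bool


def draw_random_signature(size: int, universe, rng: np.random.Generator) -> GeneSignature:
    """Sample ``size`` distinct genes uniformly from the universe.

    The universe is the set of genes actually measured on the array: a draw
    from the whole genome would be silently intersected down to the array
    anyway, so sampling the array is the same null with full control of size.
    """
    universe = list(universe)
    if not 1 <= size <= len(universe):
        raise ValueError(f"signature size {size} outside [1, {len(universe)}]")
    genes = rng.choice(universe, size=size, replace=False)
    return GeneSignature(f"random_{size}", "size-matched random signature", frozenset(genes))


def _one_draw(
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    size: int,
    rng: np.random.Generator,
) -> SurvivalAssociation:
    sig = draw_random_signature(size, matrix.index, rng)
    scores = signature_score(matrix, sig)
    groups = median_split(scores)
    return cox_binary_hr(
        groups.to_numpy(), clinical["time"].to_numpy(), clinical["event"].to_numpy()
    )


def build_null(
    size: int,
    n_draws: int,
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    seed: int,
    max_redraws_per_draw: int = 5,
) -> NullDistribution:
    """Null distribution of (logrank p, Cox HR) for random signatures.

    Each draw uses an RNG seeded deterministically from ``(seed, draw
    index)``, so any draw can be reproduced in isolation and results do not
    depend on execution order.  Degenerate draws (scoring or split failures)
    are redrawn and counted; if more than 10% of draws fail even after
    redraws the error propagates.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    clinical = clinical.loc[matrix.columns]
    rows = []
    n_redrawn = 0
    n_failed = 0
    for i in range(n_draws):
        rng = np.random.default_rng([seed, i])
        result = None
        for _attempt in range(1 + max_redraws_per_draw):
            try:
                result = _one_draw(matrix, clinical, size, rng)
                break
            except ValueError as exc:
                n_redrawn += 1
                logger.info("null draw %d redrawn: %s", i, exc)
        if result is None:
            n_failed += 1
            continue
        rows.append((i, result.p, result.hr))
    if n_failed > 0.10 * n_draws:
        raise ValueError(
            f"{n_failed}/{n_draws} null draws degenerate even after redraws"
        )
    draws = pd.DataFrame(rows, columns=["draw_index", "p", "hr"]).set_index("draw_index")
    return NullDistribution(
        signature_size=size,
        draws=draws,
        seed=seed,
        n_draws=len(draws),
        n_redrawn=n_redrawn,
    )


def empirical_significance(
    observed: SurvivalAssociation | float, null: NullDistribution
) -> EmpiricalResult:
    """Locate an observed association within its size-matched null.

    ``frac_null_better`` is the fraction of random signatures at least as
    significant as the observed one (p_null <= p_obs); ``beats_best_5pct``
    and ``beats_median`` compare the observed p to the null's 5% quantile
    and median.
    """
    p_obs = observed.p if isinstance(observed, SurvivalAssociation) else float(observed)
    p_null = null.pvalues
    if p_null.size == 0:
        raise ValueError("empty null distribution")
    frac = float((p_null <= p_obs).mean())
    return EmpiricalResult(
        observed_p=p_obs,
        frac_null_better=frac,
        beats_best_5pct=frac < 0.05,
        beats_median=p_obs < float(np.median(p_null)),
    )


def write_null(null: NullDistribution, tsv_path, sidecar_path=None, dataset_hash: str = "") -> None:
    """Persist a null distribution as TSV plus a JSON provenance sidecar."""
    out = null.draws.reset_index()
    out.insert(1, "size", null.signature_size)
    out.to_csv(tsv_path, sep="\t", index=False)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(
                {
                    "seed": null.seed,
                    "n_draws": null.n_draws,
                    "n_redrawn": null.n_redrawn,
                    "signature_size": null.signature_size,
                    "dataset_hash": dataset_hash,
                },
                fh,
                indent=2,
            )
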