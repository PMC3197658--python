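"""Proliferation metagene (meta-PCNA): construction, index, adjustment.

The meta-PCNA metagene is the small set of genes whose expression tracks the
proliferation marker PCNA most closely across a compendium of normal
tissues.  Its per-sample median expression — the meta-PCNA index — is a
proliferation surrogate, and regressing every gene on the index removes the
proliferation axis from an expression matrix while preserving each gene's
cohort mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class MetaGene:
    """Genes most positively correlated with an anchor across a compendium."""

    anchor: str
    genes: list[str]  # ordered by decreasing correlation with the anchor
    correlations: pd.Series  # per-member Pearson r with the anchor
    top_fraction: float

    def __len__(self) -> int:
        return len(self.genes)


def build_metagene(
    compendium: pd.DataFrame,
    anchor: str = "PCNA",
    top_fraction: float = 0.01,
) -> MetaGene:
    """Select the genes most positively correlated with the anchor.

    Pearson correlation of every gene with the anchor is computed across the
    compendium samples; the top ``ceil(top_fraction * n_genes)`` genes by
    descending r form the metagene.  The anchor itself (r = 1) always ranks
    first and is always a member.

    Raises
    ------
    ValueError
        If the anchor is absent or has zero variance, if the compendium has
        fewer than 3 samples, or if the selection would include a gene with
        non-positive correlation.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must lie in (0, 1)")
    if compendium.shape[1] < 3:
        raise ValueError("compendium needs at least 3 samples")
    if anchor not in compendium.index:
        raise ValueError(f"anchor gene {anchor!r} not in compendium")
    a = compendium.loc[anchor].to_numpy(dtype=float)
    if np.nanstd(a) == 0:
        raise ValueError(f"anchor gene {anchor!r} has zero variance")

    X = compendium.to_numpy(dtype=float)
    ac = a - a.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc**2).sum(axis=1) * (ac**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ ac) / denom
    r = pd.Series(r, index=compendium.index, name="r_with_anchor")
    r[anchor] = 1.0  # exact, regardless of rounding

    n_members = math.ceil(top_fraction * compendium.shape[0])
    ranked = r.dropna().sort_values(ascending=False, kind="mergesort")
    members = ranked.iloc[:n_members]
    if (members <= 0).any():
        raise ValueError(
            "top_fraction reaches into non-positively correlated genes; "
            "the metagene would not be a coherent co-expression module"
        )
    return MetaGene(
        anchor=anchor,
        genes=list(members.index),
        correlations=members,
        top_fraction=top_fraction,
    )


def metagene_index(matrix: pd.DataFrame, metagene: MetaGene) -> pd.Series:
    """Per-sample metagene index: median expression of member genes.

    Members absent from the matrix are dropped (count logged); missing
    entries are ignored per sample.
    """
    present = matrix.index.intersection(metagene.genes)
    if len(present) == 0:
        raise ValueError("no metagene member present in the matrix")
    n_dropped = len(metagene.genes) - len(present)
    if n_dropped:
        logger.info("metagene_index: %d members absent from matrix", n_dropped)
    values = np.nanmedian(matrix.loc[present].to_numpy(dtype=float), axis=0)
    return pd.Series(values, index=matrix.columns, name="index")


def adjust_for_index(matrix: pd.DataFrame, index: pd.Series) -> pd.DataFrame:
    """Remove the index's linear contribution from every gene.

    Each gene is regressed (OLS with intercept) on the index and replaced by
    its residual plus its cohort mean, so gene-wise means are preserved and
    every gene becomes uncorrelated with the index.  Genes with missing
    entries are fitted on their complete pairs; missing cells stay missing.

    Raises
    ------
    ValueError
        If the index is undefined for some sample or constant across samples.
    """
    if not matrix.columns.isin(index.index).all():
        raise ValueError("index must be defined for every sample in the matrix")
    idx = index.loc[matrix.columns].to_numpy(dtype=float)
    if np.ptp(idx) == 0:
        raise ValueError("index is constant across samples: rank-deficient fit")

    X = matrix.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    n_obs = obs.sum(axis=1)
    if np.any(n_obs < 3):
        raise ValueError("every gene needs at least 3 observed values to adjust")
    Xz = np.where(obs, X, 0.0)

    # per-gene OLS on the (complete-pair) index, closed form
    idx_mat = np.where(obs, idx[None, :], 0.0)
    mean_idx = idx_mat.sum(axis=1) / n_obs
    mean_x = Xz.sum(axis=1) / n_obs
    dev_idx = np.where(obs, idx[None, :] - mean_idx[:, None], 0.0)
    dev_x = np.where(obs, X - mean_x[:, None], 0.0)
    ss_idx = (dev_idx**2).sum(axis=1)
    if np.any(ss_idx == 0):
        raise ValueError("index constant over the observed samples of some gene")
    slope = (dev_x * dev_idx).sum(axis=1) / ss_idx
    adjusted = mean_x[:, None] + dev_x - slope[:, None] * dev_idx
    adjusted = np.where(obs, adjusted, np.nan)
    return pd.DataFrame(adjusted, index=matrix.index, columns=matrix.columns)


def permuted_adjustment(
    matrix: pd.DataFrame,
    index: pd.Series,
    rng: np.random.Generator,
    permutation: np.ndarray | None = None,
) -> pd.DataFrame:
    """Negative control: shuffle index values across samples, then adjust.

    A transformation that merely damages the data would weaken outcome
    association no matter what is regressed out; adjusting for a permuted
    index checks that the real adjustment removes structure, not signal
    capacity.  ``permutation`` can force a specific ordering (e.g. the
    identity, which reproduces :func:`adjust_for_index` exactly).
    """
    idx = index.loc[matrix.columns]
    if permutation is None:
        permutation = rng.permutation(len(idx))
    shuffled = pd.Series(idx.to_numpy()[permutation], index=idx.index, name=idx.name)
    return adjust_for_index(matrix, shuffled)


def write_metagene(metagene: MetaGene, path) -> None:
    """Persist as a two-column TSV (gene, r_with_anchor)."""
    metagene.correlations.rename_axis("gene").to_csv(path, sep="\t")


def read_metagene(path, anchor: str = "PCNA", top_fraction: float = 0.01) -> MetaGene:
    tab = pd.read_csv(path, sep="\t", index_col="gene")
    corr = tab["r_with_anchor"]
    return MetaGene(anchor=anchor, genes=list(corr.index), correlations=corr, top_fraction=top_fraction)
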