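"""Transcriptome-wide scans: outcome association and index correlation.

Single genes are pushed through the same median-split / logrank / Cox
machinery as signatures, so "26% of genes are associated with outcome" and
"58% of genes are correlated with the proliferation index" are computed on
an identical footing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sigsurv.io import GeneSignature
from sigsurv.scoring import median_split
from sigsurv.survival import cox_binary_hr, storey_qvalues

logger = logging.getLogger(__name__)


@dataclass
class SignatureSummary:
    """One signature's outcome association and its tie to the index."""

    name: str
    hr: float
    p: float
    abs_r_pc1_index: float


def gene_outcome_scan(matrix: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Per-gene outcome association (median split of the gene's expression).

    Returns a DataFrame indexed by gene with columns ``hr``, ``p`` (logrank)
    and ``q`` (Storey).  Genes whose expression yields a degenerate split
    are flagged with NaN and excluded from the q-value computation.
    """
    if matrix.shape[1] < 4:
        raise ValueError("gene scan needs at least 4 samples")
    clin = clinical.loc[matrix.columns]
    times = clin["time"].to_numpy()
    events = clin["event"].to_numpy()
    hrs = np.full(matrix.shape[0], np.nan)
    ps = np.full(matrix.shape[0], np.nan)
    n_failed = 0
    for i, (gene, row) in enumerate(matrix.iterrows()):
        try:
            groups = median_split(row)
            assoc = cox_binary_hr(groups.to_numpy(), times, events)
            hrs[i], ps[i] = assoc.hr, assoc.p
        except ValueError as exc:
            n_failed += 1
            logger.info("gene %s excluded from scan: %s", gene, exc)
    if n_failed:
        logger.info("gene_outcome_scan: %d genes degenerate", n_failed)
    out = pd.DataFrame({"hr": hrs, "p": ps}, index=matrix.index)
    out["q"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = storey_qvalues(out.loc[ok, "p"].to_numpy())
    return out


def index_correlation_scan(matrix: pd.DataFrame, index: pd.Series) -> pd.DataFrame:
    """Per-gene Pearson correlation with the index.

    Returns a DataFrame indexed by gene with columns ``r_index`` and ``p_r``
    (two-sided t-test on the correlation over complete pairs).  Zero-variance
    genes get NaN.
    """
    if not matrix.columns.isin(index.index).all():
        raise ValueError("index must be defined for every sample")
    idx = index.loc[matrix.columns].to_numpy(dtype=float)
    X = matrix.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    n = obs.sum(axis=1)
    idx_mat = np.where(obs, idx[None, :], 0.0)
    Xz = np.where(obs, X, 0.0)
    mean_x = Xz.sum(axis=1) / n
    mean_i = idx_mat.sum(axis=1) / n
    dev_x = np.where(obs, X - mean_x[:, None], 0.0)
    dev_i = np.where(obs, idx[None, :] - mean_i[:, None], 0.0)
    ss_x = (dev_x**2).sum(axis=1)
    ss_i = (dev_i**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (dev_x * dev_i).sum(axis=1) / np.sqrt(ss_x * ss_i)
        r = np.where((ss_x > 0) & (ss_i > 0), r, np.nan)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt(np.maximum(n - 2, 0) / np.maximum(1 - r**2, np.finfo(float).tiny))
    p = np.where(np.isnan(r), np.nan, 2 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1)))
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return pd.DataFrame({"r_index": r, "p_r": p}, index=matrix.index)


def hr_vs_correlation(summaries) -> tuple[float, float, float]:
    """Least-squares line of signature HR on |r(PC1, index)|.

    Accepts a list of :class:`SignatureSummary` or a DataFrame with columns
    ``hr`` and ``abs_r_pc1_index``.  Returns (slope, intercept, r_squared).
    """
    if isinstance(summaries, pd.DataFrame):
        x = summaries["abs_r_pc1_index"].to_numpy(dtype=float)
        y = summaries["hr"].to_numpy(dtype=float)
    else:
        x = np.array([s.abs_r_pc1_index for s in summaries], dtype=float)
        y = np.array([s.hr for s in summaries], dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 signature summaries")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: |r| identical across signatures")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def purge_cell_cycle(
    signature: GeneSignature, cc_sets: list[GeneSignature]
) -> GeneSignature | None:
    """Remove every gene present in any of the cell-cycle gene lists.

    Returns the purged signature, or None (with a warning) when nothing
    remains — a signature entirely inside the cell-cycle union.
    """
    cc_union: set[str] = set()
    for cc in cc_sets:
        cc_union |= cc.genes
    remaining = signature.genes - cc_union
    if not remaining:
        logger.warning("signature %s fully purged by cell-cycle sets", signature.name)
        return None
    return GeneSignature(
        signature.name + "_purged",
        f"{signature.description} (cell-cycle genes removed)",
        frozenset(remaining),
    )


def compare_correlation_distributions(
    set_rows: pd.DataFrame, background_rows: pd.DataFrame
) -> float:
    """Two-sided Mann-Whitney test on |r_index| of a gene set vs background.

    Quantifies whether a gene set remains more correlated with the
    proliferation index than the bulk of the array.  Overlapping gene ids in
    both tables are allowed but warned about.
    """
    a = set_rows["r_index"].abs().dropna().to_numpy()
    b = background_rows["r_index"].abs().dropna().to_numpy()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    overlap = set_rows.index.intersection(background_rows.index)
    if len(overlap):
        logger.warning(
            "compare_correlation_distributions: %d genes in both groups", len(overlap)
        )
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
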