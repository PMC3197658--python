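"""Signature scoring: median polish, PC1 score, median split.

A signature is turned into one number per patient by (1) restricting the
expression matrix to the signature's genes, (2) removing additive row/column
structure with Tukey's median polish, and (3) projecting samples onto the
first principal component of the polished residuals.  The cohort is then cut
at the median score into "low" and "high" groups for survival comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sigsurv.io import GeneSignature

logger = logging.getLogger(__name__)


@dataclass
class MedianPolishResult:
    """Additive decomposition X ~ overall + row_effects + col_effects + residuals."""

    overall: float
    row_effects: pd.Series
    col_effects: pd.Series
    residuals: pd.DataFrame
    converged: bool
    n_iter: int

    def fitted(self) -> pd.DataFrame:
        return (
            self.overall
            + self.residuals * 0
            + np.add.outer(self.row_effects.to_numpy(), self.col_effects.to_numpy())
        )


def median_polish(
    X: pd.DataFrame | np.ndarray,
    eps: float = 0.01,
    max_iter: int = 10,
) -> MedianPolishResult:
    """Tukey's median polish of a two-way table.

    Alternates subtracting row medians and column medians, accumulating them
    into row/column effects, until the sum of absolute residuals changes by
    less than ``eps`` (relative) or ``max_iter`` sweeps are done.  Missing
    entries are permitted and ignored by the medians.  The defaults (eps=0.01,
    max_iter=10) mirror the classic implementation in the R `stats` package.

    Returns
    -------
    MedianPolishResult
        With ``overall + row_effects[g] + col_effects[s] + residuals[g, s]``
        reconstructing the input entrywise (exact, by construction).
    """
    if isinstance(X, pd.DataFrame):
        index, columns = X.index, X.columns
        z = X.to_numpy(dtype=float).copy()
    else:
        z = np.asarray(X, dtype=float).copy()
        if z.ndim != 2:
            raise ValueError("median_polish expects a 2-D table")
        index = pd.RangeIndex(z.shape[0])
        columns = pd.RangeIndex(z.shape[1])
    nr, nc = z.shape
    if nr < 1 or nc < 1:
        raise ValueError("median_polish needs at least one row and one column")
    obs = ~np.isnan(z)
    if not obs.any(axis=1).all():
        raise ValueError("median_polish: a row is entirely missing")
    if not obs.any(axis=0).all():
        raise ValueError("median_polish: a column is entirely missing")

    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    oldsum = 0.0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        rdelta = np.nanmedian(z, axis=1)
        z -= rdelta[:, None]
        row += rdelta
        delta = np.median(col)
        col -= delta
        overall += delta

        cdelta = np.nanmedian(z, axis=0)
        z -= cdelta[None, :]
        col += cdelta
        delta = np.median(row)
        row -= delta
        overall += delta

        newsum = np.nansum(np.abs(z))
        converged = newsum == 0 or abs(newsum - oldsum) < eps * newsum
        if converged:
            break
        oldsum = newsum

    return MedianPolishResult(
        overall=float(overall),
        row_effects=pd.Series(row, index=index, name="row_effect"),
        col_effects=pd.Series(col, index=columns, name="col_effect"),
        residuals=pd.DataFrame(z, index=index, columns=columns),
        converged=converged,
        n_iter=n_iter,
    )


def signature_score(
    matrix: pd.DataFrame,
    signature: GeneSignature,
    min_genes: int = 2,
    impute: str = "median",
    eps: float = 0.01,
    max_iter: int = 10,
) -> pd.Series:
    """Per-sample PC1 score of a signature.

    Steps: restrict the matrix to signature genes; impute missing values
    (per-gene median, or drop incomplete genes with ``impute="drop-gene"``);
    median polish the submatrix and keep its residuals; compute the first
    principal component over samples (genes as variables, gene-centered,
    unscaled); orient the sign so the score correlates non-negatively with
    the mean expression of the signature's genes.

    Returns a centered score (mean 0) indexed by sample.

    Raises
    ------
    ValueError
        If fewer than ``min_genes`` signature genes are present in the
        matrix, or if the polished submatrix carries no variance.
    """
    genes = matrix.index.intersection(sorted(signature.genes))
    if len(genes) < min_genes:
        raise ValueError(
            f"signature {signature.name!r}: only {len(genes)} of "
            f"{len(signature)} genes present (need >= {min_genes})"
        )
    sub = matrix.loc[genes]
    if sub.isna().to_numpy().any():
        if impute == "median":
            med = sub.median(axis=1)
            sub = sub.apply(lambda col: col.fillna(med))
        elif impute == "drop-gene":
            sub = sub.dropna(axis=0)
            if sub.shape[0] < min_genes:
                raise ValueError(
                    f"signature {signature.name!r}: fewer than {min_genes} "
                    "complete genes after dropping missing rows"
                )
        else:
            raise ValueError(f"unknown impute mode {impute!r}")

    polished = median_polish(sub, eps=eps, max_iter=max_iter)
    resid = polished.residuals.to_numpy()
    # samples are observations, genes are variables; center each gene
    centered = (resid - resid.mean(axis=1, keepdims=True)).T
    if not np.any(np.abs(centered) > 1e-12):
        raise ValueError(
            f"signature {signature.name!r}: zero-variance submatrix after polishing"
        )
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 1e-12:
        raise ValueError(
            f"signature {signature.name!r}: zero-variance submatrix after polishing"
        )
    score = u[:, 0] * s[0]
    mean_expr = sub.mean(axis=0).to_numpy()
    if np.std(mean_expr) > 0 and np.corrcoef(score, mean_expr)[0, 1] < 0:
        score = -score
    return pd.Series(score, index=matrix.columns, name=signature.name)


def median_split(scores: pd.Series) -> pd.Series:
    """Split a cohort at the median score.

    Samples with score <= median go to ``"low"``, the rest to ``"high"``;
    with an even number of distinct scores this is an exact half split.
    Ties at the median all land in the low group.

    Raises
    ------
    ValueError
        For fewer than 4 samples or an all-equal (degenerate) score vector.
    """
    if len(scores) < 4:
        raise ValueError("median_split needs at least 4 samples")
    if scores.nunique() == 1:
        raise ValueError("degenerate split: all scores equal")
    med = scores.median()
    labels = np.where(scores <= med, "low", "high")
    out = pd.Series(labels, index=scores.index, name="group")
    if (out == "high").sum() == 0:
        raise ValueError("degenerate split: no samples above the median")
    return out


def write_scores(scores: pd.Series, groups: pd.Series, path) -> None:
    """Export scores and group labels as TSV (sample_id, score, group)."""
    pd.DataFrame({"score": scores, "group": groups}).to_csv(
        path, sep="\t", index_label="sample_id"
    )
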