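"""Readers, writers and harmonization for expression data and gene sets.

Conventions used throughout the package:

- An *expression matrix* is a :class:`pandas.DataFrame` with gene (or probe)
  symbols as the index and sample identifiers as columns, holding log2-scale
  expression values.  Missing measurements are ``NaN``.  Data are assumed to
  be already normalized and log-transformed; no normalization is performed
  here.
- A *clinical table* is a :class:`pandas.DataFrame` indexed by sample id with
  columns ``time`` (follow-up in years, strictly positive) and ``event``
  (1 = death/relapse observed, 0 = censored), plus an optional ``endpoint``
  label such as ``"OS"`` or ``"RFS"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Tokens treated as missing values in expression files.
MISSING_TOKENS = ("NA", "NaN", "nan", "")


@dataclass(frozen=True)
class GeneSignature:
    """A named set of gene symbols.

    Parameters
    ----------
    name
        Non-empty signature name.
    description
        Free-text description (may be empty).
    genes
        Non-empty, deduplicated set of gene symbols.
    """

    name: str
    description: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("signature name must be non-empty")
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


def validate_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check expression-matrix invariants (unique genes, >=2 samples)."""
    if matrix.index.has_duplicates:
        dups = matrix.index[matrix.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate gene identifiers: {dups}")
    if matrix.shape[1] < 2:
        raise ValueError("expression matrix needs at least 2 samples")
    if matrix.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers")
    return matrix


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV expression matrix.

    First column holds gene/probe identifiers, the header row sample ids.
    ``NA``, ``NaN`` and blank cells become missing; any other non-numeric
    cell raises with its row and column location.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    values = raw.mask(raw.isin(list(MISSING_TOKENS)))
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {values.iat[r, c]!r} at "
            f"gene {raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    numeric.index = numeric.index.astype(str)
    numeric.index.name = raw.index.name or "gene"
    return validate_expression(numeric)


def write_expression(matrix: pd.DataFrame, path) -> None:
    """Write a genes x samples TSV; missing entries serialize as ``NA``."""
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label=matrix.index.name or "gene")


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical follow-up TSV with columns sample_id, time, event.

    An optional ``endpoint`` column is carried through.  Times must be
    strictly positive and events binary.
    """
    tab = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "time", "event"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"{path}: missing clinical columns {sorted(missing)}")
    tab = tab.set_index("sample_id")
    return validate_clinical(tab)


def validate_clinical(tab: pd.DataFrame) -> pd.DataFrame:
    if tab.index.has_duplicates:
        raise ValueError("duplicate sample_id in clinical table")
    if not (tab["time"] > 0).all():
        raise ValueError("follow-up times must be strictly positive")
    if not tab["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    return tab


def write_clinical(tab: pd.DataFrame, path) -> None:
    tab.to_csv(path, sep="\t", index_label="sample_id")


def collapse_probes(matrix: pd.DataFrame, probe_to_gene: dict) -> pd.DataFrame:
    """Average probes mapping to the same gene; drop unmapped probes.

    The mean is arithmetic and ignores missing entries per cell, so a gene's
    value in a sample is the mean of its observed probes there.
    """
    if not probe_to_gene:
        raise ValueError("probe-to-gene mapping is empty")
    mapped = matrix.index.intersection(list(probe_to_gene))
    if len(mapped) == 0:
        raise ValueError("no probes in matrix are covered by the mapping")
    sub = matrix.loc[mapped]
    genes = pd.Index([probe_to_gene[p] for p in mapped], name="gene")
    collapsed = sub.groupby(genes, sort=True).mean()
    n_dropped = matrix.shape[0] - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    return collapsed


def read_aliases(path) -> dict[str, str]:
    """Read a two-column TSV (alias, current symbol) into a mapping.

    Current symbols always map to themselves, so passing an already-current
    symbol through the table is the identity.
    """
    tab = pd.read_csv(path, sep="\t", header=None, names=["alias", "symbol"], dtype=str)
    mapping = dict(zip(tab["alias"], tab["symbol"]))
    for sym in tab["symbol"]:
        mapping.setdefault(sym, sym)
    return mapping


def update_symbols(signature: GeneSignature, aliases: dict[str, str]) -> GeneSignature:
    """Map legacy symbols to current nomenclature, best-effort.

    Unknown symbols pass through unchanged; the result is deduplicated (two
    aliases of the same gene collapse to one member).
    """
    updated = frozenset(aliases.get(g, g) for g in signature.genes)
    return GeneSignature(signature.name, signature.description, updated)


def read_gmt(path) -> list[GeneSignature]:
    """Parse a GMT gene-set file (name <TAB> description <TAB> genes...).

    Duplicate genes within a line are deduplicated.  A line with fewer than
    three fields is an error naming the line number.
    """
    signatures = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            name, description = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            signatures.append(GeneSignature(name, description, genes))
    return signatures


def write_gmt(signatures: list[GeneSignature], path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, sig.description, *sorted(sig.genes)]) + "\n")


def filter_signatures(
    signatures: list[GeneSignature], min_size: int = 2
) -> list[GeneSignature]:
    """Drop trivially small gene sets (single-gene sets by default)."""
    return [s for s in signatures if len(s) >= min_size]
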