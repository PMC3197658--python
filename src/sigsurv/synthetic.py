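"""Generative models for cohorts and compendia with known ground truth.

The cohort generator emulates the statistical skeleton that the whole
analysis rests on: a single latent "proliferation" factor per patient that
(a) loads on a large fraction of the transcriptome and (b) drives the
hazard of death under a proportional-hazards model with right censoring.
The compendium generator emulates a small panel of normal tissues in which
a tight module of genes (containing the anchor gene PCNA) co-varies with
per-tissue proliferative activity.

Defaults mimic a ~300-patient breast-cancer cohort: 295 samples, a
4,000-gene desk-scale transcriptome with 55% of genes loaded on the factor,
log-hazard beta = 0.8 per factor SD, and a baseline hazard calibrated so
that the expected event fraction is 79/295.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd

from sigsurv.io import GeneSignature, write_clinical, write_expression, write_gmt


@dataclass
class CohortParams:
    """Parameters of the latent-factor survival cohort.

    Attributes
    ----------
    n_samples, n_genes
        Cohort dimensions.
    frac_loaded
        Fraction of genes with non-zero factor loading (exact by
        construction).
    loading_scale
        Mean |loading| of loaded genes; each loading is jittered by
        a uniform +/-30% factor.
    noise_sd
        SD of per-gene Gaussian measurement noise (log2 units).
    beta
        Log hazard ratio per unit of the latent factor.
    baseline_hazard
        Exponential baseline event rate (1/years); the default 0.024,
        together with beta=0.8 and the censoring scheme, realizes an
        expected event fraction of ~79/295.
    censor_time
        Administrative censoring horizon (years); individual follow-up is
        additionally cut at a Uniform(0, 2*censor_time) drop-out time.
    weibull_shape
        Shape of the Weibull event-time distribution (1 = exponential).
    random_signs
        Give loadings random signs instead of a coherent positive module.
    """

    n_samples: int = 295
    n_genes: int = 4000
    frac_loaded: float = 0.55
    loading_scale: float = 0.7
    noise_sd: float = 1.0
    beta: float = 0.8
    baseline_hazard: float = 0.024
    censor_time: float = 15.0
    weibull_shape: float = 1.0
    random_signs: bool = False
    baseline_mean: float = 7.0
    baseline_mean_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.frac_loaded <= 1:
            raise ValueError("frac_loaded must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")
        if self.n_samples < 4 or self.n_genes < 2:
            raise ValueError("cohort too small")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    factor: pd.Series  # latent proliferation value per sample
    loadings: pd.Series  # per-gene loading (0 for unloaded genes)
    beta: float
    event_fraction_realized: float

    @property
    def loaded_genes(self) -> list[str]:
        return list(self.loadings.index[self.loadings != 0])


def _gene_names(n: int, reserved: tuple[str, ...] = ()) -> list[str]:
    width = max(4, len(str(n)))
    names = list(reserved)
    i = 1
    while len(names) < n:
        name = f"G{i:0{width}d}"
        if name not in reserved:
            names.append(name)
        i += 1
    return names


def generate_cohort(
    params: CohortParams,
    gene_names: list[str] | None = None,
    loaded_genes: list[str] | None = None,
    loading_multipliers: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw one cohort: expression, clinical follow-up, ground truth.

    Model: factor p_i ~ N(0,1); loadings lambda_g = loading_scale * (1 + U(-0.3, 0.3))
    for a ``frac_loaded`` random subset of genes (0 otherwise);
    x_gi = mu_g + lambda_g p_i + noise_sd * eps_gi.  Event time follows a
    Weibull (default exponential) proportional-hazards law with rate
    baseline_hazard * exp(beta * p_i); follow-up is censored at the earlier
    of the administrative horizon and a uniform drop-out time.

    ``loaded_genes`` / ``loading_multipliers`` let callers plant a specific
    loaded set (e.g. a proliferation module shared with a compendium).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, g = params.n_samples, params.n_genes
    genes = list(gene_names) if gene_names is not None else _gene_names(g)
    if len(genes) != g:
        raise ValueError("gene_names length must equal n_genes")
    samples = [f"S{i + 1:04d}" for i in range(n)]

    factor = rng.standard_normal(n)
    n_loaded = round(params.frac_loaded * g)
    if loaded_genes is None:
        loaded_idx = rng.choice(g, size=n_loaded, replace=False)
    else:
        pos = {name: i for i, name in enumerate(genes)}
        loaded_idx = np.array([pos[name] for name in loaded_genes])
    loadings = np.zeros(g)
    jitter = rng.uniform(-0.3, 0.3, size=len(loaded_idx))
    lam = params.loading_scale * (1 + jitter)
    if params.random_signs:
        lam *= rng.choice([-1.0, 1.0], size=len(loaded_idx))
    loadings[loaded_idx] = lam
    if loading_multipliers:
        pos = {name: i for i, name in enumerate(genes)}
        for name, mult in loading_multipliers.items():
            loadings[pos[name]] *= mult

    mu = rng.normal(params.baseline_mean, params.baseline_mean_sd, size=g)
    X = (
        mu[:, None]
        + loadings[:, None] * factor[None, :]
        + params.noise_sd * rng.standard_normal((g, n))
    )
    expr = pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=samples)

    rate = params.baseline_hazard * np.exp(params.beta * factor)
    T = (rng.exponential(1.0, n) / rate) ** (1.0 / params.weibull_shape)
    drop_out = rng.uniform(0.0, 2.0 * params.censor_time, n)
    horizon = np.minimum(params.censor_time, drop_out)
    time = np.minimum(T, horizon)
    event = (T <= horizon).astype(int)
    clinical = pd.DataFrame(
        {"time": time, "event": event, "endpoint": "OS"},
        index=pd.Index(samples, name="sample_id"),
    )

    truth = SyntheticTruth(
        factor=pd.Series(factor, index=samples, name="factor"),
        loadings=pd.Series(loadings, index=expr.index, name="loading"),
        beta=params.beta,
        event_fraction_realized=float(event.mean()),
    )
    return expr, clinical, truth


def generate_compendium(
    n_tissues: int = 36,
    n_genes: int = 13077,
    frac_prolif: float = 0.01,
    loading_scale: float = 1.0,
    noise_sd: float = 0.25,
    seed: int = 0,
    gene_names: list[str] | None = None,
    planted_genes: list[str] | None = None,
    anchor: str = "PCNA",
) -> tuple[pd.DataFrame, list[str]]:
    """Normal-tissue compendium with a planted proliferation module.

    Per-tissue proliferative activity a_t ~ N(0,1); the anchor gene (PCNA)
    and ``ceil(frac_prolif * n_genes)`` module genes (anchor included) load
    on a_t with loading_scale (+/-30% jitter); every other gene is
    independent noise.  With the full-scale defaults (13,077 genes, 1%) the
    module has 131 members.

    Returns the expression matrix and the planted member list (the ground
    truth that metagene construction should recover).
    """
    if n_tissues < 3:
        raise ValueError("compendium needs at least 3 tissues")
    if not 0 < frac_prolif < 1:
        raise ValueError("frac_prolif must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    genes = (
        list(gene_names) if gene_names is not None else _gene_names(n_genes, (anchor,))
    )
    if len(genes) != n_genes:
        raise ValueError("gene_names length must equal n_genes")
    if anchor not in genes:
        raise ValueError(f"anchor {anchor!r} must be in the gene universe")
    tissues = [f"T{i + 1:02d}" for i in range(n_tissues)]

    n_members = math.ceil(frac_prolif * n_genes)
    if planted_genes is None:
        others = [g for g in genes if g != anchor]
        planted = [anchor] + list(rng.choice(others, size=n_members - 1, replace=False))
    else:
        planted = list(planted_genes)
        if anchor not in planted:
            raise ValueError("planted_genes must include the anchor")
        if len(planted) != n_members:
            raise ValueError(
                f"planted_genes must have ceil(frac_prolif*n_genes)={n_members} members"
            )

    activity = rng.standard_normal(n_tissues)
    loadings = np.zeros(len(genes))
    pos = {name: i for i, name in enumerate(genes)}
    planted_idx = np.array([pos[name] for name in planted])
    loadings[planted_idx] = loading_scale * (
        1 + rng.uniform(-0.3, 0.3, size=len(planted))
    )
    loadings[pos[anchor]] = loading_scale  # anchor loads at full scale, no jitter
    mu = rng.normal(7.0, 1.0, size=len(genes))
    X = (
        mu[:, None]
        + loadings[:, None] * activity[None, :]
        + noise_sd * rng.standard_normal((len(genes), n_tissues))
    )
    expr = pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=tissues)
    return expr, planted


#: Sizes used for the panel of 47 published-like signatures: a log-spaced
#: range from small curated sets to the two largest literature signatures
#: (714 and 1345 genes), single-gene sets excluded.
PUBLISHED_SIGNATURE_SIZES: tuple[int, ...] = (
    5, 7, 9, 10, 12, 14, 16, 18, 21, 24, 28, 32, 36, 40, 45, 50, 55, 60,
    65, 70, 76, 83, 90, 97, 105, 114, 123, 133, 144, 156, 169, 183, 198,
    214, 232, 251, 272, 294, 318, 344, 372, 403, 436, 472, 512, 714, 1345,
)


def published_like_signatures(
    world: "LinkedWorld",
    sizes: tuple[int, ...] = PUBLISHED_SIGNATURE_SIZES,
    seed: int = 0,
    n_prolif: int = 31,
    n_weak: int = 4,
) -> list[GeneSignature]:
    """Emulate a panel of published outcome signatures on a linked world.

    Published breast-cancer signatures are not uniformly random gene sets:
    meta-analyses show the large majority are proliferation-driven and
    overlap the proliferation cluster itself, while a minority (immune,
    stromal) are essentially unrelated to proliferation.  The panel drawn
    here mirrors that composition: ``n_prolif`` signatures take 60-100% of
    their genes from factor-loaded genes, with 30-70% of those coming from
    the proliferation module; ``n_weak`` signatures contain only 1-5 loaded
    genes; the remainder are drawn entirely from unloaded genes.
    """
    rng = np.random.default_rng([seed, 55])
    module = np.array(world.planted_members)
    loaded_nm = np.array(sorted(set(world.truth.loaded_genes) - set(module)))
    unloaded = np.array(sorted(set(world.expression.index) - set(world.truth.loaded_genes)))
    n_unrelated = len(sizes) - n_prolif - n_weak
    cats = np.array(["prolif"] * n_prolif + ["weak"] * n_weak + ["unrelated"] * n_unrelated)
    rng.shuffle(cats)
    signatures = []
    for cat, size in zip(cats, sizes):
        if cat == "prolif":
            k = round(rng.uniform(0.6, 1.0) * size)
            m = min(round(rng.uniform(0.3, 0.7) * k), len(module))
            genes = list(rng.choice(module, m, replace=False)) + list(
                rng.choice(loaded_nm, k - m, replace=False)
            )
        elif cat == "weak":
            k = min(int(rng.integers(1, 6)), size - 1)
            genes = list(rng.choice(loaded_nm, k, replace=False))
        else:
            genes = []
        genes += list(rng.choice(unloaded, size - len(genes), replace=False))
        signatures.append(
            GeneSignature(f"{cat}_{size}", f"{cat} synthetic signature", frozenset(genes))
        )
    return signatures


@dataclass
class LinkedWorld:
    """A cohort and a compendium sharing one proliferation module.

    The compendium's planted module is a subset of the cohort's
    factor-loaded genes, so a metagene built from the compendium indexes the
    cohort's latent factor — the setting in which adjustment should abolish
    random-signature outcome association.
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame
    truth: SyntheticTruth
    compendium: pd.DataFrame
    planted_members: list[str] = field(default_factory=list)


def generate_linked(
    params: CohortParams | None = None,
    n_tissues: int = 36,
    compendium_genes: int = 13077,
    frac_prolif: float = 0.01,
    compendium_noise_sd: float = 0.25,
    module_boost: float = 2.0,
    anchor: str = "PCNA",
) -> LinkedWorld:
    """Generate a cohort and compendium with a shared proliferation module.

    The cohort's gene universe contains the anchor; the compendium spans a
    larger universe (different platforms measure different genes) whose
    planted module is drawn from the cohort's loaded genes.  Module genes
    carry ``module_boost`` times the base loading in the cohort, reflecting
    that canonical proliferation genes are the most strongly
    proliferation-driven part of a tumor transcriptome.
    """
    params = params or CohortParams()
    params.validate()
    rng = np.random.default_rng([params.seed, 101])
    cohort_genes = _gene_names(params.n_genes, (anchor,))
    n_loaded = round(params.frac_loaded * params.n_genes)
    loadable = [g for g in cohort_genes if g != anchor]
    loaded = [anchor] + list(rng.choice(loadable, size=n_loaded - 1, replace=False))

    n_members = math.ceil(frac_prolif * compendium_genes)
    if n_members > n_loaded:
        raise ValueError("proliferation module larger than the cohort's loaded set")
    members = [anchor] + list(
        rng.choice([g for g in loaded if g != anchor], size=n_members - 1, replace=False)
    )
    multipliers = {g: module_boost for g in members}

    expr, clinical, truth = generate_cohort(
        params,
        gene_names=cohort_genes,
        loaded_genes=loaded,
        loading_multipliers=multipliers,
    )
    extra = compendium_genes - params.n_genes
    if extra < 0:
        raise ValueError("compendium_genes must be >= cohort n_genes")
    extra_names = [f"X{i + 1:05d}" for i in range(extra)]
    compendium, planted = generate_compendium(
        n_tissues=n_tissues,
        n_genes=compendium_genes,
        frac_prolif=frac_prolif,
        noise_sd=compendium_noise_sd,
        seed=int(rng.integers(2**31)),
        gene_names=cohort_genes + extra_names,
        planted_genes=members,
        anchor=anchor,
    )
    return LinkedWorld(
        expression=expr,
        clinical=clinical,
        truth=truth,
        compendium=compendium,
        planted_members=planted,
    )


def write_dataset(
    expr: pd.DataFrame,
    clinical: pd.DataFrame,
    truth: SyntheticTruth,
    outdir,
) -> None:
    """Write a generated cohort as standard TSVs plus a truth GMT."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(expr, outdir / "expression.tsv")
    write_clinical(clinical, outdir / "clinical.tsv")
    truth.factor.rename_axis("sample_id").to_csv(outdir / "truth_factor.tsv", sep="\t")
    truth.loadings.rename_axis("gene").to_csv(outdir / "truth_loadings.tsv", sep="\t")
    loaded = truth.loaded_genes
    if loaded:
        write_gmt(
            [GeneSignature("loaded_genes", "genes with non-zero factor loading", frozenset(loaded))],
            outdir / "truth_sets.gmt",
        )
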