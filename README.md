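# sigsurv

**Is your gene-expression signature really associated with breast-cancer
outcome — or would a random set of genes do just as well?**

`sigsurv` is a Python library for assessing the outcome association of
gene-expression signatures against the null model that actually matters:
*size-matched random signatures*. In breast-cancer expression cohorts most
random gene sets — and most single genes — are significantly associated
with survival, because a single proliferation axis correlates with more
than half of the transcriptome and with outcome. A signature's nominal Cox
or logrank p-value therefore carries almost no evidence about the biology
it was built to represent. The library implements:

- **Signature scoring** — a signature's per-patient score is the first
  principal component (PC1) of the expression submatrix restricted to the
  signature's genes, after Tukey median polish; the cohort is split at the
  median score and the two groups compared by logrank test and a Cox
  proportional-hazards fit (HR with Wald 95% CI, Efron ties).
- **Random-signature nulls** — for a signature of size *k*, the
  distribution of (p, HR) over random draws of *k* genes from the measured
  universe; a signature is called relevant only if it beats the best 5% of
  its null.
- **The meta-PCNA proliferation metagene** — the 1% of genes most
  positively correlated with the proliferation marker *PCNA* across a
  normal-tissue compendium; its per-sample median expression is the
  *meta-PCNA index*, a proliferation surrogate.
- **Proliferation adjustment** — each gene is regressed on the index and
  replaced by residual + gene mean. This abrogates the outcome association
  of random (and most published) signatures, while adjusting for a
  *permuted* index — the negative control — changes nothing.
- **Transcriptome scans** — per-gene outcome association (with Storey
  q-values), per-gene correlation with the index, the HR-vs-correlation
  relation across a signature panel, and the cell-cycle purge experiment.
- **Synthetic data with ground truth** — a generative model of the whole
  setting: one latent factor p_i ~ N(0,1) loading on a tunable fraction of
  genes (x_gi = mu_g + lambda_g p_i + noise), driving an exponential
  proportional-hazards event process, plus a normal-tissue compendium with
  a planted proliferation module.

The model in brief: with hazard h_i(t) = h0 · exp(beta · p_i) and a
signature score s ≈ p, the median split produces groups differing by
≈ 1.6 SD of p, so HR ≈ exp(1.6 · beta · corr(s, p)) — which is why a
signature's hazard ratio is almost a deterministic function of its
proliferation correlation.

## Worked example

```bash
python examples/02_signature_vs_random.py
```

```
signature 'model_system_marker' (100 genes):
  HR = 1.88 [1.20, 2.94], logrank p = 4.87e-03
  fraction of 200 random 100-gene signatures at least as significant: 1.00
  beats the best 5% of random signatures: False
  beats the median random signature:      False
```

A 100-gene signature drawn from the factor-loaded part of a synthetic
cohort is "significant" at p = 0.005 — and *every one* of 200 random
signatures of the same size did at least as well. The nominal p-value
answers the wrong question. The other example scripts demonstrate cohort
simulation (`01`), metagene construction and adjustment (`03` — the
significant fraction of random signatures drops from 1.00 to 0.01 after
adjustment, and stays at 1.00 under the permuted control), transcriptome
scans and the cell-cycle purge (`04`), and the HR-vs-proliferation
relation across a 47-signature panel (`05`, R² = 0.83).

A thin CLI mirrors the library (`sigsurv simulate | metapcna | assoc |
scan | purge`); run `sigsurv --help`.

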