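import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sigsurv.io import GeneSignature
from sigsurv.scoring import median_polish, median_split, signature_score
from sigsurv.synthetic import CohortParams, generate_cohort


class TestMedianPolish:
    def test_constant_matrix(self):
        r = median_polish(np.full((4, 5), 3.5))
        assert r.overall == 3.5
        np.testing.assert_allclose(r.row_effects, 0)
        np.testing.assert_allclose(r.col_effects, 0)
        np.testing.assert_allclose(r.residuals, 0)

    def test_exactly_additive_matrix(self):
        r = median_polish(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(r.residuals, 0, atol=1e-12)

    def test_outlier_cell_reference_decomposition(self):
        # 3x3 identity-like table with +10 planted at (0, 2); expected values
        # frozen from an independent run of the classic R routine at tight eps
        x = np.eye(3)
        x[0, 2] += 10
        r = median_polish(x, eps=1e-9, max_iter=100)
        assert r.overall == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(r.row_effects, [1, 0, 0], atol=1e-9)
        np.testing.assert_allclose(r.col_effects, [0, 0, 1], atol=1e-9)
        np.testing.assert_allclose(
            r.residuals, [[0, -1, 8], [0, 1, -1], [0, 0, 0]], atol=1e-9
        )
        ij = np.unravel_index(np.abs(r.residuals.to_numpy()).argmax(), (3, 3))
        assert ij == (0, 2)

    def test_default_parameters_reference_decomposition(self):
        # frozen from the same independent reference at default eps/maxiter
        x = np.array([[3.2, 1.5, 4.7, 2.1], [0.8, 5.5, 2.2, 3.3], [4.1, 0.6, 1.9, 5.0]])
        r = median_polish(x)
        assert r.overall == pytest.approx(2.75)
        np.testing.assert_allclose(r.row_effects, [-0.1, 0.0, 0.25], atol=1e-12)
        np.testing.assert_allclose(r.col_effects, [0.55, -1.15, -0.55, 0.55], atol=1e-12)
        np.testing.assert_allclose(
            r.residuals,
            [[0, 0, 2.6, -1.1], [-2.5, 3.9, 0, 0], [0.55, -1.25, -0.55, 1.45]],
            atol=1e-12,
        )

    @given(
        arrays(
            float,
            (6, 4),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_decomposition_reconstructs_input(self, x):
        r = median_polish(x)
        recon = (
            r.overall
            + r.row_effects.to_numpy()[:, None]
            + r.col_effects.to_numpy()[None, :]
            + r.residuals.to_numpy()
        )
        np.testing.assert_allclose(recon, x, atol=1e-8)

    def test_residual_medians_vanish_at_convergence(self, rng):
        for _ in range(20):
            x = rng.normal(size=(8, 6))
            r = median_polish(x, eps=0.0, max_iter=100)
            assert np.abs(np.median(r.residuals, axis=1)).max() < 1e-3
            assert np.abs(np.median(r.residuals, axis=0)).max() < 1e-3

    def test_missing_entries_allowed_but_not_full_lines(self):
        x = np.array([[1.0, np.nan, 3.0], [4.0, 5.0, 6.0]])
        r = median_polish(x)
        assert np.isnan(r.residuals.iloc[0, 1])
        with pytest.raises(ValueError, match="entirely missing"):
            median_polish(np.array([[np.nan, np.nan], [1.0, 2.0]]))


class TestSignatureScore:
    def _two_gene_matrix(self, rng, n=40):
        base = rng.normal(size=n)
        return pd.DataFrame(
            {"g1": base, "g2": 0.5 + 2.0 * base},
            index=[f"s{i}" for i in range(n)],
        ).T

    def test_two_correlated_genes_closed_form(self, rng):
        # For two genes g2 = a + b*g1 (b != 1) the polished residuals are a
        # rank-1 matrix proportional to the centered base profile, so the PC1
        # score must be collinear with the centered per-sample mean.
        m = self._two_gene_matrix(rng)
        sig = GeneSignature("pair", "", frozenset({"g1", "g2"}))
        score = signature_score(m, sig)
        mean_centered = m.mean(axis=0) - m.mean(axis=0).mean()
        corr = np.corrcoef(score, mean_centered)[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-10)
        assert score.mean() == pytest.approx(0.0, abs=1e-10)

    def test_orientation_non_negative_with_mean_expression(self, rng):
        expr, _, _ = generate_cohort(
            CohortParams(n_samples=60, n_genes=100, frac_loaded=0.5, seed=3)
        )
        for k in range(5):
            genes = frozenset(np.random.default_rng(k).choice(expr.index, 20, replace=False))
            score = signature_score(expr, GeneSignature(f"r{k}", "", genes))
            mean_expr = expr.loc[sorted(genes)].mean(axis=0)
            assert np.corrcoef(score, mean_expr)[0, 1] >= 0

    def test_disjoint_signature_errors(self, toy_expression):
        sig = GeneSignature("none", "", frozenset({"ZZ1", "ZZ2"}))
        with pytest.raises(ValueError, match="only 0 of 2"):
            signature_score(toy_expression, sig)

    def test_zero_variance_submatrix_errors(self):
        m = pd.DataFrame(np.ones((3, 6)), index=["a", "b", "c"])
        sig = GeneSignature("flat", "", frozenset({"a", "b"}))
        with pytest.raises(ValueError, match="zero-variance"):
            signature_score(m, sig)

    def test_invariant_to_per_gene_constant_shift(self, rng):
        expr, _, _ = generate_cohort(
            CohortParams(n_samples=50, n_genes=60, frac_loaded=0.5, seed=9)
        )
        sig = GeneSignature("s", "", frozenset(expr.index[:25]))
        s1 = signature_score(expr, sig)
        shifted = expr.add(pd.Series(rng.normal(scale=5, size=60), index=expr.index), axis=0)
        s2 = signature_score(shifted, sig)
        np.testing.assert_allclose(s1, s2, atol=1e-8)

    def test_rank_one_matrix_recovers_latent_factor(self, rng):
        n, g = 80, 30
        p = rng.normal(size=n)
        lam = rng.uniform(0.5, 1.5, g) * rng.choice([-1, 1], g)
        x = lam[:, None] * p[None, :] + 0.01 * rng.normal(size=(g, n))
        m = pd.DataFrame(x, index=[f"g{i}" for i in range(g)])
        score = signature_score(m, GeneSignature("r1", "", frozenset(m.index)))
        assert abs(np.corrcoef(score, p)[0, 1]) > 0.99

    def test_missing_values_imputed_or_dropped(self, rng):
        expr, _, _ = generate_cohort(
            CohortParams(n_samples=50, n_genes=40, frac_loaded=0.6, seed=4)
        )
        expr.iloc[0, :5] = np.nan
        sig = GeneSignature("s", "", frozenset(expr.index[:20]))
        s_med = signature_score(expr, sig, impute="median")
        s_drop = signature_score(expr, sig, impute="drop-gene")
        assert len(s_med) == len(s_drop) == 50
        # the two handling modes agree on the dominant axis
        assert abs(np.corrcoef(s_med, s_drop)[0, 1]) > 0.95


class TestMedianSplit:
    def test_even_cohort_splits_in_half(self):
        g = median_split(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
        assert list(g[g == "low"].index) == ["a", "b"]
        assert list(g[g == "high"].index) == ["c", "d"]

    def test_median_value_goes_low(self):
        g = median_split(pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde")))
        assert g["c"] == "low"
        assert (g == "low").sum() == 3

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            median_split(pd.Series([5.0, 5.0, 5.0, 5.0]))
        with pytest.raises(ValueError, match="at least 4"):
            median_split(pd.Series([1.0, 2.0, 3.0]))

    def test_partition_stable_under_sign_flip_even_distinct(self, rng):
        s = pd.Series(rng.normal(size=20))
        g1, g2 = median_split(s), median_split(-s)
        low1 = frozenset(g1[g1 == "low"].index)
        high2 = frozenset(g2[g2 == "high"].index)
        assert low1 == high2
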