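import numpy as np
import pandas as pd
import pytest

from sigsurv.metapcna import (
    MetaGene,
    adjust_for_index,
    build_metagene,
    metagene_index,
    permuted_adjustment,
    read_metagene,
    write_metagene,
)
from sigsurv.synthetic import generate_compendium


class TestBuildMetagene:
    def test_anchor_always_member_with_r_one(self):
        comp, _ = generate_compendium(n_genes=500, seed=1)
        mg = build_metagene(comp)
        assert "PCNA" in mg.genes
        assert mg.correlations["PCNA"] == 1.0
        assert mg.genes[0] == "PCNA" or mg.correlations.iloc[0] == 1.0

    def test_planted_module_recovered_exactly(self):
        comp, planted = generate_compendium(n_genes=2000, noise_sd=0.2, seed=2)
        mg = build_metagene(comp, top_fraction=0.01)
        assert set(mg.genes) == set(planted)
        assert (mg.correlations > 0).all()

    def test_member_count_is_ceiling_of_fraction(self):
        comp, planted = generate_compendium(n_genes=13077, seed=3)
        mg = build_metagene(comp, top_fraction=0.01)
        assert len(mg) == 131  # ceil(0.01 * 13077)
        assert len(planted) == 131

    def test_missing_or_flat_anchor_errors(self):
        comp, _ = generate_compendium(n_genes=300, seed=4)
        with pytest.raises(ValueError, match="not in compendium"):
            build_metagene(comp, anchor="NOPE")
        comp.loc["PCNA"] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            build_metagene(comp)

    def test_too_few_samples_errors(self):
        comp = pd.DataFrame(np.ones((10, 2)), index=[f"G{i}" for i in range(10)])
        with pytest.raises(ValueError, match="at least 3 samples"):
            build_metagene(comp, anchor="G0")

    def test_round_trip_through_tsv(self, tmp_path):
        comp, _ = generate_compendium(n_genes=400, seed=5)
        mg = build_metagene(comp)
        write_metagene(mg, tmp_path / "mg.tsv")
        back = read_metagene(tmp_path / "mg.tsv")
        assert back.genes == mg.genes
        np.testing.assert_allclose(back.correlations, mg.correlations)


class TestMetageneIndex:
    def _mg(self, genes):
        return MetaGene(
            anchor=genes[0],
            genes=list(genes),
            correlations=pd.Series(1.0, index=genes),
            top_fraction=0.01,
        )

    def test_single_gene_metagene_passthrough(self, toy_expression):
        idx = metagene_index(toy_expression, self._mg(["GA"]))
        pd.testing.assert_series_equal(
            idx, toy_expression.loc["GA"], check_names=False
        )

    def test_constant_members_give_constant_index(self):
        m = pd.DataFrame(np.full((3, 5), 2.5), index=["a", "b", "c"])
        idx = metagene_index(m, self._mg(["a", "b", "c"]))
        np.testing.assert_allclose(idx, 2.5)

    def test_invariant_to_member_order_and_missing_members(self, toy_expression):
        i1 = metagene_index(toy_expression, self._mg(["GA", "GB"]))
        i2 = metagene_index(toy_expression, self._mg(["GB", "GA"]))
        pd.testing.assert_series_equal(i1, i2)
        i3 = metagene_index(toy_expression, self._mg(["GA", "GB", "ABSENT"]))
        pd.testing.assert_series_equal(i1, i3)

    def test_no_members_present_errors(self, toy_expression):
        with pytest.raises(ValueError, match="no metagene member"):
            metagene_index(toy_expression, self._mg(["X1", "X2"]))


class TestAdjustForIndex:
    def _cohort(self, rng, g=40, n=60):
        idx = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        X = rng.normal(7, 1, size=(g, n)) + rng.normal(size=(g, 1)) * idx.to_numpy()
        m = pd.DataFrame(X, index=[f"g{i}" for i in range(g)], columns=idx.index)
        return m, idx

    def test_perfectly_linear_gene_becomes_flat_mean(self, rng):
        m, idx = self._cohort(rng)
        m.loc["g0"] = 2.0 + 3.0 * idx
        adj = adjust_for_index(m, idx)
        np.testing.assert_allclose(adj.loc["g0"], m.loc["g0"].mean(), atol=1e-10)

    def test_orthogonal_gene_unchanged(self, rng):
        m, idx = self._cohort(rng)
        v = rng.normal(size=len(idx))
        ci = (idx - idx.mean()).to_numpy()
        vc = v - v.mean()
        v_orth = vc - ci * (vc @ ci) / (ci @ ci)  # exactly uncorrelated with index
        m.loc["g1"] = 5.0 + v_orth
        adj = adjust_for_index(m, idx)
        np.testing.assert_allclose(adj.loc["g1"], m.loc["g1"], atol=1e-10)

    def test_residual_orthogonality_means_and_variances(self, rng):
        m, idx = self._cohort(rng)
        adj = adjust_for_index(m, idx)
        centered = adj.sub(adj.mean(axis=1), axis=0)
        corr_with_idx = centered @ (idx - idx.mean())
        np.testing.assert_allclose(corr_with_idx, 0, atol=1e-8)
        np.testing.assert_allclose(adj.mean(axis=1), m.mean(axis=1), atol=1e-10)
        assert (adj.var(axis=1) <= m.var(axis=1) + 1e-12).all()

    def test_adjustment_idempotent(self, rng):
        m, idx = self._cohort(rng)
        once = adjust_for_index(m, idx)
        twice = adjust_for_index(once, idx)
        np.testing.assert_allclose(twice.to_numpy(), once.to_numpy(), atol=1e-10)

    def test_missing_entries_fit_on_complete_pairs(self, rng):
        m, idx = self._cohort(rng, g=10)
        m.iloc[0, :7] = np.nan
        adj = adjust_for_index(m, idx)
        # independent per-gene oracle with numpy polyfit on observed pairs
        row = m.iloc[3].to_numpy()
        slope, intercept = np.polyfit(idx.to_numpy(), row, 1)
        expected = row - (intercept + slope * idx.to_numpy()) + row.mean()
        np.testing.assert_allclose(adj.iloc[3], expected, atol=1e-8)
        assert adj.iloc[0, :7].isna().all()

    def test_constant_index_errors(self, rng):
        m, idx = self._cohort(rng)
        with pytest.raises(ValueError, match="constant"):
            adjust_for_index(m, pd.Series(1.0, index=idx.index))


class TestPermutedAdjustment:
    def test_identity_permutation_equals_plain_adjustment(self, rng):
        idx = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        m = pd.DataFrame(
            rng.normal(size=(15, 30)), index=[f"g{i}" for i in range(15)], columns=idx.index
        )
        plain = adjust_for_index(m, idx)
        forced = permuted_adjustment(m, idx, rng, permutation=np.arange(30))
        np.testing.assert_allclose(forced.to_numpy(), plain.to_numpy())

    def test_means_preserved_by_permuted_adjustment(self, rng):
        idx = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
        m = pd.DataFrame(
            rng.normal(size=(15, 30)), index=[f"g{i}" for i in range(15)], columns=idx.index
        )
        out = permuted_adjustment(m, idx, rng)
        np.testing.assert_allclose(out.mean(axis=1), m.mean(axis=1), atol=1e-10)

    def test_preserves_outcome_association_on_linked_world(
        self, linked_world, meta_index
    ):
        # the negative control must not damage prognostic signal: a random
        # loaded signature stays significant after permuted adjustment
        from sigsurv.io import GeneSignature
        from sigsurv.scoring import signature_score
        from sigsurv.survival import signature_association

        expr, clin = linked_world.expression, linked_world.clinical
        rng = np.random.default_rng(8)
        genes = frozenset(rng.choice(linked_world.truth.loaded_genes, 100, replace=False))
        sig = GeneSignature("loaded", "", genes)
        p_before = signature_association(signature_score(expr, sig), clin).p
        perm = permuted_adjustment(expr, meta_index, np.random.default_rng(1))
        p_perm = signature_association(signature_score(perm, sig), clin).p
        adj = adjust_for_index(expr, meta_index)
        p_adj = signature_association(signature_score(adj, sig), clin).p
        assert p_before < 0.01 and p_perm < 0.01
        assert p_adj > p_before
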