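"""Cell QC, normalization, technical noise, and the disease-score equations."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from florascore.geneassoc import DiseaseGeneSet
from florascore.scdrs_core import (
    ControlScores,
    TechNoiseModel,
    cell_pvalues,
    celltype_association,
    estimate_tech_noise,
    exclude_subtypes,
    merge_subtypes,
    normalize_expression,
    qc_cells,
    raw_disease_score,
    sample_control_scores,
)


def _adata(x, cell_types=None, groups=None, genes=None):
    x = np.asarray(x, dtype=float)
    n, g = x.shape
    obs = pd.DataFrame(index=[f"c{i}" for i in range(n)])
    obs["cell_type"] = cell_types if cell_types is not None else "T"
    obs["group"] = groups if groups is not None else "severe"
    var = pd.DataFrame(index=genes if genes is not None else [f"g{j}" for j in range(g)])
    return ad.AnnData(X=x, obs=obs, var=var)


def _geneset(genes, weights):
    return DiseaseGeneSet(genes=pd.DataFrame({"gene_id": genes, "weight": weights}))


class TestQcCells:
    def test_sparse_cell_removed(self):
        x = np.ones((5, 300))
        x[0, 100:] = 0  # cell 0 expresses only 100 genes
        adata, report = qc_cells(_adata(x), min_genes=200, min_cells_per_gene=1)
        assert report["few_genes"] == 1
        assert adata.n_obs == 4

    def test_umi_exactly_at_threshold_removed(self):
        x = np.ones((4, 250))
        x[1] = 80  # total = 20_000 exactly -> removed (rule is ">=")
        adata, report = qc_cells(_adata(x), min_cells_per_gene=1)
        assert report["high_umi"] == 1
        assert "c1" not in adata.obs_names

    def test_constructed_fixture_tallies(self):
        rng = np.random.default_rng(83)
        genes = [f"MT-{j}" for j in range(5)] + [f"g{j}" for j in range(95)]
        x = rng.poisson(8.0, size=(100, 100)).astype(float) + 1  # all genes expressed
        x[:, :5] = 1.0  # baseline mito: 5/total, far below 15%
        for i in (0, 1, 2):
            x[i, 30:] = 0.0  # expresses 30 genes < 50
        for i in (3, 4):
            x[i] = 120.0  # total 12_000 >= 10_000
        for i in (5, 6):
            x[i, :5] = 200.0  # mito fraction >> 15%
        adata, report = qc_cells(
            _adata(x, genes=genes), min_genes=50, max_umi=10_000,
            max_mito_frac=0.15, min_cells_per_gene=1,
        )
        assert report == {"few_genes": 3, "high_umi": 2, "high_mito": 2, "rare_genes": 0}
        assert adata.n_obs == 93

    def test_empty_result_is_error(self):
        with pytest.raises(ValueError, match="every cell"):
            qc_cells(_adata(np.ones((3, 10))), min_genes=50)


class TestSubtypeSurgery:
    def test_exclude_counts_and_identity(self, nb_cells):
        out, n_removed = exclude_subtypes(nb_cells, {"A"})
        assert n_removed == 150
        assert set(out.obs["cell_type"]) == {"B"}
        same, zero = exclude_subtypes(nb_cells, set())
        assert zero == 0 and same.n_obs == nb_cells.n_obs

    def test_exclude_unknown_label_lists_valid(self, nb_cells):
        with pytest.raises(ValueError, match="valid"):
            exclude_subtypes(nb_cells, {"PLT"})

    def test_exclude_everything_is_error(self, nb_cells):
        with pytest.raises(ValueError, match="every cell"):
            exclude_subtypes(nb_cells, {"A", "B"})

    def test_merge_sums_source_counts(self, nb_cells):
        out = merge_subtypes(nb_cells, {"A": "AB", "B": "AB"})
        assert out.obs["cell_type"].value_counts().to_dict() == {"AB": 300}
        assert set(out.obs["cell_type_fine"]) == {"A", "B"}

    def test_merge_identity_keeps_counts(self, nb_cells):
        out = merge_subtypes(nb_cells, {"A": "A", "B": "B"})
        assert out.obs["cell_type"].value_counts().to_dict() == {"A": 150, "B": 150}

    def test_merge_unmapped_label_is_error(self, nb_cells):
        with pytest.raises(ValueError, match="unmapped"):
            merge_subtypes(nb_cells, {"A": "A"})


class TestNormalize:
    def test_closed_forms(self):
        adata = _adata(np.array([[0.0, 10.0], [5.0, 5.0]]))
        normalize_expression(adata)
        x = adata.layers["lognorm"]
        assert x[0, 0] == 0.0
        assert x[0, 1] == pytest.approx(np.log1p(1e4))
        assert x[1, 0] == pytest.approx(np.log1p(1e4 * 0.5))

    def test_three_by_three_hand_arithmetic(self):
        counts = np.array([[1.0, 2.0, 3.0], [4.0, 0.0, 6.0], [2.0, 2.0, 2.0]])
        adata = _adata(counts)
        normalize_expression(adata)
        totals = counts.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(
            adata.layers["lognorm"], np.log1p(1e4 * counts / totals), atol=1e-12
        )

    def test_zero_total_cell_is_error(self):
        adata = _adata(np.array([[1.0, 1.0], [0.0, 0.0]]))
        with pytest.raises(ValueError, match="zero-total"):
            normalize_expression(adata)


class TestTechNoise:
    def test_identical_genes_share_sigma(self):
        rng = np.random.default_rng(89)
        col = rng.normal(1.0, 0.5, size=200)
        adata = _adata(np.ones((200, 10)))
        adata.layers["lognorm"] = np.tile(col[:, None], (1, 10))
        noise = estimate_tech_noise(adata)
        assert noise.sigma.nunique() == 1

    def test_variance_floor(self):
        adata = _adata(np.ones((10, 4)))
        adata.layers["lognorm"] = np.ones((10, 4))  # zero variance everywhere
        noise = estimate_tech_noise(adata, n_bins=2)
        np.testing.assert_allclose(noise.sigma, 1e-2)

    def test_two_bins_with_known_variances(self):
        # 4 cells; 5 genes alternate +-1 around 0 (var 1), 5 alternate +-2
        # around 10 (var 4); two mean bins -> sigma 1 and 2
        low = np.tile([[-1.0], [1.0], [-1.0], [1.0]], (1, 5))
        high = 10 + 2 * np.tile([[-1.0], [1.0], [-1.0], [1.0]], (1, 5))
        adata = _adata(np.ones((4, 10)))
        adata.layers["lognorm"] = np.hstack([low, high])
        noise = estimate_tech_noise(adata, n_bins=2)
        np.testing.assert_allclose(noise.sigma.iloc[:5], 1.0)
        np.testing.assert_allclose(noise.sigma.iloc[5:], 2.0)


def _manual_noise(genes, sigma):
    return TechNoiseModel(sigma=pd.Series(sigma, index=genes, dtype=float), n_bins=1)


class TestRawScore:
    def test_single_gene_reduces_to_expression(self):
        adata = _adata(np.ones((3, 4)))
        adata.layers["lognorm"] = np.arange(12.0).reshape(3, 4)
        gs = _geneset(["g2"], [3.7])
        noise = _manual_noise(adata.var_names, [1.0, 2.0, 0.5, 1.0])
        np.testing.assert_allclose(raw_disease_score(adata, gs, noise), adata.layers["lognorm"][:, 2])

    def test_equal_weights_give_unweighted_mean(self):
        adata = _adata(np.ones((2, 3)))
        adata.layers["lognorm"] = np.array([[1.0, 2.0, 6.0], [0.0, 3.0, 3.0]])
        gs = _geneset(["g0", "g1", "g2"], [2.0, 2.0, 2.0])
        noise = _manual_noise(adata.var_names, [0.7, 0.7, 0.7])
        np.testing.assert_allclose(
            raw_disease_score(adata, gs, noise), adata.layers["lognorm"].mean(axis=1)
        )

    def test_hand_arithmetic_two_genes_two_cells(self):
        adata = _adata(np.ones((2, 2)))
        x = np.array([[1.0, 4.0], [2.0, 0.5]])
        adata.layers["lognorm"] = x
        gs = _geneset(["g0", "g1"], [2.0, 1.0])
        noise = _manual_noise(adata.var_names, [1.0, 2.0])
        # weights omega/sigma = (2, 0.5); denom 2.5
        expected = (2.0 * x[:, 0] + 0.5 * x[:, 1]) / 2.5
        np.testing.assert_allclose(raw_disease_score(adata, gs, noise), expected, atol=1e-12)

    def test_invariant_to_weight_rescaling(self, nb_cells):
        normalize_expression(nb_cells)
        noise = estimate_tech_noise(nb_cells)
        genes = list(nb_cells.var_names[:20])
        w = np.abs(np.random.default_rng(97).standard_normal(20)) + 0.1
        s1 = raw_disease_score(nb_cells, _geneset(genes, w), noise)
        s2 = raw_disease_score(nb_cells, _geneset(genes, 17.3 * w), noise)
        np.testing.assert_allclose(s1, s2, atol=1e-12)


class TestControlScores:
    def test_degenerate_pool_reproduces_disease_score(self, nb_cells):
        normalize_expression(nb_cells)
        noise = estimate_tech_noise(nb_cells)
        genes = list(nb_cells.var_names[:5])
        gs = _geneset(genes, [1.0, 2.0, 0.5, 1.5, 1.0])
        s = raw_disease_score(nb_cells, gs, noise)
        # candidate pool = G with one gene per matching bin: controls == G
        ctrl = sample_control_scores(
            nb_cells, gs, noise, B=3, n_mean_bins=5, n_var_bins=1,
            seed=1, candidate_genes=genes,
        )
        for b in range(3):
            np.testing.assert_allclose(ctrl.s_ctrl[:, b], s, atol=1e-12)

    def test_exchangeable_controls_match_disease_mean(self, nb_cells):
        normalize_expression(nb_cells)
        noise = estimate_tech_noise(nb_cells)
        genes = list(nb_cells.var_names[:30])
        gs = _geneset(genes, np.ones(30))
        s = raw_disease_score(nb_cells, gs, noise)
        ctrl = sample_control_scores(nb_cells, gs, noise, B=200, seed=3)
        assert ctrl.s_ctrl.mean() == pytest.approx(s.mean(), rel=0.05)

    def test_deterministic_given_seed(self, nb_cells):
        normalize_expression(nb_cells)
        noise = estimate_tech_noise(nb_cells)
        gs = _geneset(list(nb_cells.var_names[:10]), np.ones(10))
        c1 = sample_control_scores(nb_cells, gs, noise, B=10, seed=42)
        c2 = sample_control_scores(nb_cells, gs, noise, B=10, seed=42)
        np.testing.assert_array_equal(c1.s_ctrl, c2.s_ctrl)


class TestCellPvalues:
    def test_extreme_scores_hit_formula_bounds(self):
        rng = np.random.default_rng(101)
        ctrl = ControlScores(s_ctrl=rng.normal(0, 1, (4, 5)), B=5, n_mean_bins=1, n_var_bins=1)
        high = cell_pvalues(np.full(4, 100.0), ctrl)
        np.testing.assert_allclose(high.scores["pval"], 1 / (1 + 4 * 5))
        low = cell_pvalues(np.full(4, -100.0), ctrl)
        np.testing.assert_allclose(low.scores["pval"], 1.0)

    def test_hand_example_matches_double_loop(self):
        s_ctrl = np.array([[0.1, -0.2], [0.5, 0.3], [-0.4, 0.0]])
        s_raw = np.array([0.2, 0.1, -0.3])
        result = cell_pvalues(s_raw, ControlScores(s_ctrl=s_ctrl, B=2, n_mean_bins=1, n_var_bins=1))
        mu = s_ctrl.mean(axis=1)
        sd = np.maximum(s_ctrl.std(axis=1), 1e-12)
        norm = (s_raw - mu) / sd
        ctrl_norm = (s_ctrl - mu[:, None]) / sd[:, None]
        for c in range(3):
            count = sum(
                norm[c] <= ctrl_norm[cp, b] for cp in range(3) for b in range(2)
            )
            assert result.scores["pval"].iloc[c] == pytest.approx((1 + count) / (1 + 6), abs=1e-14)

    def test_bh_adjustment_dominates_raw_p(self):
        rng = np.random.default_rng(103)
        ctrl = ControlScores(s_ctrl=rng.normal(0, 1, (50, 20)), B=20, n_mean_bins=1, n_var_bins=1)
        res = cell_pvalues(rng.normal(0, 1, 50), ctrl)
        assert (res.scores["p_adj"] >= res.scores["pval"] - 1e-15).all()

    @given(
        st.integers(min_value=0, max_value=2**32 - 1),
        st.integers(min_value=2, max_value=12),
        st.integers(min_value=1, max_value=8),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_formula_bounds_property(self, data_seed, n_cell, B):
        """P_c in [1/(1+n_cell*B), 1] for arbitrary score configurations."""
        rng = np.random.default_rng(data_seed)
        ctrl = ControlScores(
            s_ctrl=rng.normal(0, 2, (n_cell, B)), B=B, n_mean_bins=1, n_var_bins=1
        )
        res = cell_pvalues(rng.normal(0, 5, n_cell), ctrl)
        lower = 1.0 / (1.0 + n_cell * B)
        assert (res.scores["pval"] >= lower - 1e-15).all()
        assert (res.scores["pval"] <= 1.0 + 1e-15).all()
        assert (res.scores["p_adj"] >= res.scores["pval"] - 1e-15).all()


class TestCelltypeAssociation:
    def test_no_significant_cells(self):
        sr = cell_pvalues(
            np.full(20, -100.0),
            ControlScores(
                s_ctrl=np.random.default_rng(1).normal(0, 1, (20, 10)),
                B=10, n_mean_bins=1, n_var_bins=1,
            ),
        )
        assoc = celltype_association(sr, pd.Series(["T"] * 20))
        assert assoc["prop_sig"].iloc[0] == 0.0
        assert assoc["assoc_p"].iloc[0] == pytest.approx(1.0)

    def test_null_gene_sets_keep_association_rate_near_nominal(self):
        """Random gene sets: few (type, trait) pairs reach assoc_p < 0.05."""
        from florascore import synth
        from florascore.scdrs_core import (
            estimate_tech_noise,
            normalize_expression,
            raw_disease_score,
            sample_control_scores,
        )

        rng = np.random.default_rng(211)
        genes = [f"g{i:03d}" for i in range(500)]
        spec = synth.CellPopSpec(
            cell_types=["A", "B"], n_cells_per_type={"A": 100, "B": 100},
            genes=genes, base_means=np.exp(rng.normal(0.5, 1.0, 500)),
        )
        hits = pairs = 0
        for rep in range(100):
            adata = synth.simulate_cells(spec, seed=5000 + rep)
            normalize_expression(adata)
            noise = estimate_tech_noise(adata)
            pick = rng.choice(500, 50, replace=False)
            gs = _geneset([genes[i] for i in pick], np.abs(rng.standard_normal(50)) + 0.2)
            s = raw_disease_score(adata, gs, noise)
            ctrl = sample_control_scores(adata, gs, noise, B=100, seed=6000 + rep)
            sr = cell_pvalues(s, ctrl, cell_ids=adata.obs_names)
            assoc = celltype_association(sr, adata.obs["cell_type"])
            hits += int((assoc["assoc_p"] < 0.05).sum())
            pairs += len(assoc)
        assert hits / pairs <= 0.08

    def test_injected_effect_ranks_target_type_first(self):
        """A 2-fold disease-gene shift in one type gives it the top signal."""
        from florascore import synth
        from florascore.scdrs_core import (
            estimate_tech_noise,
            normalize_expression,
            raw_disease_score,
            sample_control_scores,
        )

        rng = np.random.default_rng(223)
        genes = [f"g{i:03d}" for i in range(400)]
        base = np.exp(rng.normal(0.5, 1.0, 400))
        disease = [genes[i] for i in rng.choice(400, 20, replace=False)]
        wins = 0
        for s in range(20):
            spec = synth.CellPopSpec(
                cell_types=["T", "U", "V", "W"],
                n_cells_per_type={ct: 150 for ct in ["T", "U", "V", "W"]},
                genes=genes, base_means=base,
                disease_genes=disease, effect_log2=1.0, target_cell_types=["V"],
            )
            adata = synth.simulate_cells(spec, seed=7000 + s)
            normalize_expression(adata)
            noise = estimate_tech_noise(adata)
            gs = _geneset(disease, np.abs(rng.standard_normal(20)) + 0.5)
            sc = raw_disease_score(adata, gs, noise)
            ctrl = sample_control_scores(adata, gs, noise, B=50, seed=8000 + s)
            sr = cell_pvalues(sc, ctrl, cell_ids=adata.obs_names)
            nominal = (
                (sr.scores["pval"] < 0.05)
                .groupby(adata.obs["cell_type"].to_numpy())
                .mean()
            )
            wins += int(nominal.idxmax() == "V")
        assert wins >= 18

    def test_all_cells_significant(self):
        rng = np.random.default_rng(2)
        sr = cell_pvalues(
            np.full(400, 100.0),
            ControlScores(s_ctrl=rng.normal(0, 1, (400, 50)), B=50, n_mean_bins=1, n_var_bins=1),
        )
        assoc = celltype_association(sr, pd.Series(["T"] * 400))
        assert assoc["prop_sig"].iloc[0] == 1.0
        assert assoc["assoc_p"].iloc[0] < 1e-10
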