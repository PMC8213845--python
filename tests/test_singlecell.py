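import anndata as ad
import numpy as np
import pandas as pd
import pytest

import dnmkit as dk
from dnmkit import singlecell as sc


def _adata_with_qc(detected, total, mito):
    n = len(detected)
    obs = pd.DataFrame(
        {"detected_genes": detected, "total_reads": total, "mito_fraction": mito},
        index=[f"cell{i}" for i in range(n)],
    )
    return ad.AnnData(X=np.ones((n, 3)), obs=obs)


class TestCellQC:
    def test_thresholds_and_boundaries(self):
        adata = _adata_with_qc(
            detected=[1000, 999, 5000, 5000, 12000],
            total=[1e4, 1e4, 2e6, 1e4, 1e4],
            mito=[0.01, 0.01, 0.01, 0.03, 0.01],
        )
        kept = sc.cell_qc(adata)
        # 1000 detected genes is retained (strict <); high reads, high mito
        # and too many detected genes are removed
        assert list(kept.obs_names) == ["cell0"]

    def test_nominal_cells_retained(self):
        adata = _adata_with_qc([2000, 3000], [1e4, 2e4], [0.0, 0.01])
        assert sc.cell_qc(adata).n_obs == 2


class TestAucScore:
    def test_no_overlap_with_top_ranks_scores_zero(self):
        expr = [9, 8, 7, 6, 5, 1, 2]
        mask = [False] * 5 + [True, True]
        assert sc.auc_score(expr, mask, max_rank=5) == 0.0

    def test_top_ranked_set_reaches_analytic_maximum(self):
        n_genes, s, max_rank = 50, 4, 20
        expr = np.arange(n_genes, 0, -1)
        mask = np.zeros(n_genes, bool)
        mask[:s] = True
        # members at 0-based ranks 0..s-1: area = sum(max_rank - r) / (max_rank*s)
        expected = sum(max_rank - r for r in range(s)) / (max_rank * s)
        assert sc.auc_score(expr, mask, max_rank) == pytest.approx(expected)

    def test_hand_computed_step_curve(self):
        # 5 genes, max_rank 4, members at ranks 1 and 3 -> area 4+2 over 8
        assert sc.auc_score([50, 40, 30, 20, 10], [1, 0, 1, 0, 0], 4) == 0.75

    def test_rank_based_score_ignores_monotone_transforms(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(3.0, (20, 100))
        adata = ad.AnnData(X=x)
        adata.var_names = [f"G{i}" for i in range(100)]
        genes = [f"G{i}" for i in range(0, 30, 3)]
        a = sc.score_cells(adata, genes, max_rank=50, seed=7)
        adata2 = ad.AnnData(X=np.log1p(x) * 10)
        adata2.var_names = adata.var_names
        b = sc.score_cells(adata2, genes, max_rank=50, seed=7)
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_invalid_max_rank(self):
        with pytest.raises(ValueError):
            sc.auc_score([1, 2, 3], [True, False, False], 0)


class TestTopFraction:
    def test_ceiling_count(self):
        scores = pd.Series(np.arange(100) / 100, index=[f"c{i:03d}" for i in range(100)])
        assert len(sc.top_fraction_cells(scores, 0.05)) == 5
        scores3 = pd.Series([0.1, 0.2, 0.3], index=["a", "b", "c"])
        assert len(sc.top_fraction_cells(scores3, 0.5)) == 2

    def test_ties_break_by_cell_id(self):
        scores = pd.Series(0.5, index=[f"c{i:02d}" for i in range(40)][::-1])
        top = sc.top_fraction_cells(scores, 0.05)
        assert top == ["c00", "c01"]


class TestClusterBinomial:
    def test_conservation_and_expected_cluster_flat(self):
        labels = pd.Series(
            ["a"] * 100 + ["b"] * 100, index=[f"c{i:03d}" for i in range(200)]
        )
        top = [f"c{i:03d}" for i in range(5)] + [f"c{i:03d}" for i in range(100, 105)]
        table = sc.cluster_binomial_test(top, labels, expected_fraction=0.05)
        assert table["n_top"].sum() == len(top)
        assert (table["p_corrected"] > 0.05).all()  # exactly at expectation

    def test_concentrated_top_cells_flag_their_cluster(self):
        labels = pd.Series(
            ["big"] * 180 + ["small"] * 20, index=[f"c{i:03d}" for i in range(200)]
        )
        top = [f"c{i:03d}" for i in range(180, 190)]  # all top cells in 'small'
        table = sc.cluster_binomial_test(top, labels, expected_fraction=0.05)
        assert table.loc["small", "p_uncorrected"] == table["p_uncorrected"].min()
        assert table.loc["small", "p_corrected"] < 1e-6

    def test_external_bonferroni_denominator(self):
        labels = pd.Series(["a"] * 50, index=[f"c{i}" for i in range(50)])
        top = [f"c{i}" for i in range(10)]
        t1 = sc.cluster_binomial_test(top, labels, expected_fraction=0.05, n_tests=16)
        assert t1["p_corrected"].iloc[0] == pytest.approx(
            min(1.0, t1["p_uncorrected"].iloc[0] * 16)
        )


class TestClusterSignature:
    def test_recovers_simulated_signature(self):
        adata = dk.simulate_sc(
            400, 800, [0.25, 0.25, 0.25, 0.25], 30, upregulation=4.0, seed=3,
            target_cluster=2,
        )
        genes = sc.cluster_signature(adata, "c2", ["c0", "c1", "c3"])
        sig = set(adata.uns["signature_genes"])
        sensitivity = len(sig & set(genes)) / len(sig)
        assert sensitivity > 0.8

    def test_null_groups_yield_few_discoveries(self):
        adata = dk.simulate_sc(
            400, 800, [0.5, 0.5], 30, upregulation=1.0, seed=4, target_cluster=0,
            markers_per_cluster=0,
        )
        genes = sc.cluster_signature(adata, "c0", ["c1"])
        assert len(genes) <= 0.01 * 800  # FDR-controlled false positives

    def test_private_gene_is_included(self):
        rng = np.random.default_rng(5)
        x = rng.poisson(2.0, (40, 10))
        x[:20, 0] += 30
        x[20:, 0] = 0
        obs = pd.DataFrame(
            {"cluster": ["t"] * 20 + ["o"] * 20},
            index=[f"c{i}" for i in range(40)],
        )
        adata = ad.AnnData(X=x, obs=obs)
        adata.var_names = [f"G{i}" for i in range(10)]
        assert "G0" in sc.cluster_signature(adata, "t", ["o"])

    def test_overlapping_groups_rejected(self):
        adata = dk.simulate_sc(50, 200, [0.5, 0.5], 10, seed=6)
        with pytest.raises(ValueError):
            sc.cluster_signature(adata, "c0", ["c0", "c1"])


class TestHypergeomOverlap:
    def test_forced_overlap_enumeration(self):
        # |A|=|B|=2 drawn from 4, full overlap: P = 1/C(4,2) = 1/6
        k, p = sc.hypergeom_overlap({"a", "b"}, {"a", "b"}, {"a", "b", "c", "d"})
        assert k == 2
        assert p == pytest.approx(1 / 6)

    def test_disjoint_sets_p_one(self):
        k, p = sc.hypergeom_overlap({"a"}, {"b"}, {"a", "b", "c"})
        assert k == 0 and p == 1.0

    def test_members_outside_background_warned_and_dropped(self):
        with pytest.warns(UserWarning, match="excluded"):
            k, _ = sc.hypergeom_overlap({"a", "zzz"}, {"a"}, {"a", "b"})
        assert k == 1

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            sc.hypergeom_overlap({"a"}, {"a"}, set())
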