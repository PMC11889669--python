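"""QC filters, lineage scoring, multiplet flagging, and marker finding."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from uveitis_sc import annotation_qc as aq
from tests.conftest import make_adata


def _qc_adata(n_cells=5, n_genes=600, genes_per_cell=520, mito=0.05, seed=0):
    rng = np.random.default_rng(seed)
    X = np.zeros((n_cells, n_genes), dtype=int)
    for i in range(n_cells):
        on = rng.choice(n_genes, size=genes_per_cell, replace=False)
        X[i, on] = rng.integers(1, 5, size=genes_per_cell)
    mito = np.full(n_cells, mito) if np.isscalar(mito) else np.asarray(mito)
    return make_adata(X, mito_fraction=mito)


class TestQcFilter:
    def test_low_complexity_cell_removed_at_499_genes(self):
        adata = _qc_adata(n_cells=80, genes_per_cell=520)
        # cell 0 expresses exactly 499 genes
        X = adata.X.toarray()
        on = np.flatnonzero(X[0] > 0)
        X[0, on[499:]] = 0
        adata.X = X
        t = aq.QcThresholds(min_cells_per_gene=1)
        filtered, report = aq.qc_filter(adata, t)
        assert report.n_cells_low_genes == 1
        assert adata.obs_names[0] not in filtered.obs_names

    @pytest.mark.parametrize(
        "mito,kept", [(0.12, False), (0.005, False), (0.05, True), (0.11, True), (0.01, True)]
    )
    def test_mito_bounds_are_strict(self, mito, kept):
        mitos = np.full(30, 0.05)
        mitos[0] = mito
        adata = _qc_adata(n_cells=30, mito=mitos)
        filtered, _ = aq.qc_filter(adata, aq.QcThresholds(min_cells_per_gene=1))
        assert (adata.obs_names[0] in set(filtered.obs_names)) is kept

    def test_gene_filter_applied_after_cell_filter(self):
        adata = _qc_adata(n_cells=100, n_genes=600)
        t = aq.QcThresholds(min_cells_per_gene=70)
        filtered, report = aq.qc_filter(adata, t)
        cells_per_gene = (filtered.X > 0).sum(axis=0).A1
        assert (cells_per_gene >= 70).all()

    def test_all_passing_matrix_unchanged(self):
        adata = _qc_adata(n_cells=160)
        t = aq.QcThresholds(min_cells_per_gene=70)
        once, report = aq.qc_filter(adata, t)
        assert once.shape == adata.shape
        assert report.n_cells_low_genes == 0 and report.n_genes_low_cells == 0

    def test_idempotent_on_cohort_data(self, small_cohort):
        once, _ = aq.qc_filter(small_cohort.adata)
        twice, report2 = aq.qc_filter(once)
        assert once.shape == twice.shape
        assert report2.n_cells_low_genes == 0 and report2.n_genes_low_cells == 0
        assert report2.n_cells_mito == 0

    def test_empty_result_warns_not_crashes(self):
        adata = _qc_adata(n_cells=5, genes_per_cell=100)  # all below 500 genes
        with pytest.warns(UserWarning):
            filtered, _ = aq.qc_filter(adata)
        assert filtered.n_obs == 0


class TestNormalizeLogCpm:
    def test_closed_form_single_cell(self):
        adata = make_adata([[10, 0]])
        norm = aq.normalize_log_cpm(adata, target_sum=100)
        assert np.allclose(norm.X.toarray(), [[np.log1p(100.0), 0.0]])

    def test_all_zero_cell_stays_zero_with_warning(self):
        adata = make_adata([[0, 0], [1, 1]])
        with pytest.warns(UserWarning):
            norm = aq.normalize_log_cpm(adata)
        assert norm.X.toarray()[0] == pytest.approx([0.0, 0.0])

    def test_scale_invariance_per_cell(self):
        adata = make_adata([[3, 7, 0]])
        doubled = make_adata([[6, 14, 0]])
        a = aq.normalize_log_cpm(adata).X.toarray()
        b = aq.normalize_log_cpm(doubled).X.toarray()
        assert a == pytest.approx(b)


class TestScoreLineages:
    def _panel_adata(self):
        # cells: T-like, B-like, myeloid-like, NK-like
        genes = ["CD3D", "CD79A", "LYZ", "NCR1", "OTHER"]
        X = np.array(
            [
                [50, 0, 1, 0, 10],
                [0, 60, 0, 1, 10],
                [1, 0, 55, 0, 10],
                [0, 1, 0, 45, 10],
            ]
        )
        return make_adata(X, gene_names=genes)

    def test_marker_expression_drives_argmax(self):
        norm = aq.normalize_log_cpm(self._panel_adata())
        scores = aq.score_lineages(norm)
        assert scores.iloc[0].idxmax() == "T"
        assert scores.iloc[1].idxmax() == "B"
        assert scores.iloc[2].idxmax() == "myeloid"
        assert scores.iloc[3].idxmax() == "NK"

    def test_constant_marker_contributes_zero(self):
        X = np.array([[5, 1], [5, 9], [5, 4]])
        adata = make_adata(X, gene_names=["FLAT", "VAR"])
        scores = aq.score_lineages(adata, {"L": ["FLAT"]})
        assert np.allclose(scores["L"], 0.0)

    def test_identical_cells_identical_scores(self):
        X = np.array([[5, 1, 2], [5, 1, 2], [9, 0, 1]])
        adata = make_adata(X, gene_names=["CD3D", "CD79A", "LYZ"])
        scores = aq.score_lineages(
            adata, {"T": ["CD3D"], "B": ["CD79A"], "M": ["LYZ"]}
        )
        assert scores.iloc[0].equals(scores.iloc[1])

    def test_fully_missing_panel_is_error(self):
        adata = make_adata(np.ones((3, 2)), gene_names=["A", "B"])
        with pytest.raises(ValueError):
            aq.score_lineages(adata, {"T": ["CD3D"]})

    def test_partially_missing_panel_warns(self):
        adata = make_adata(np.eye(3), gene_names=["CD3D", "X", "Y"])
        with pytest.warns(UserWarning):
            aq.score_lineages(adata, {"T": ["CD3D", "MISSING"], "B": ["X"]})


class TestFlagMultiplets:
    def test_cell_high_in_two_lineages_flagged(self):
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(
            {"T": rng.normal(0, 1, 100), "B": rng.normal(0, 1, 100)}
        )
        scores.iloc[0] = [10.0, 10.0]  # far above both 90th percentiles
        flags = aq.flag_multiplets(scores)
        assert flags.iloc[0]

    def test_cell_high_in_one_lineage_not_flagged(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame(
            {"T": rng.normal(0, 1, 100), "B": rng.normal(0, 1, 100)}
        )
        scores.iloc[0] = [10.0, -10.0]
        assert not aq.flag_multiplets(scores).iloc[0]

    def test_pure_singlet_population_flags_at_most_ten_percent(self, small_cohort):
        gt = small_cohort.ground_truth.cells.set_index("barcode")
        singlets = small_cohort.adata[~gt["is_doublet"].to_numpy()]
        norm = aq.normalize_log_cpm(singlets)
        flags = aq.flag_multiplets(aq.score_lineages(norm))
        assert flags.mean() <= 0.10

    def test_rare_lineage_doublets_are_caught(self):
        # the decile rule has power when both component lineages are rare:
        # here two 6%-abundance lineages inside a dominant background
        rng = np.random.default_rng(2)
        n_bg, n_lin, n_doub = 880, 60, 30
        genes = ["CD79A", "NCR1"]
        bg = rng.poisson(0.2, size=(n_bg, 2))
        b_cells = np.column_stack([rng.poisson(30, n_lin), rng.poisson(0.2, n_lin)])
        nk_cells = np.column_stack([rng.poisson(0.2, n_lin), rng.poisson(30, n_lin)])
        doublets = b_cells[:n_doub] + nk_cells[:n_doub]
        X = np.vstack([bg, b_cells, nk_cells, doublets])
        X = np.column_stack([X, rng.poisson(5, size=(len(X), 30))])  # depth filler
        adata = make_adata(X, gene_names=genes + [f"F{i}" for i in range(30)])
        norm = aq.normalize_log_cpm(adata)
        scores = aq.score_lineages(norm, {"B": ["CD79A"], "NK": ["NCR1"]})
        flags = aq.flag_multiplets(scores)
        doublet_mask = np.zeros(len(X), dtype=bool)
        doublet_mask[-n_doub:] = True
        assert flags[doublet_mask].mean() >= 0.7
        assert flags[~doublet_mask].mean() <= 0.15

    def test_single_lineage_rejected(self):
        scores = pd.DataFrame({"T": np.arange(20.0)})
        with pytest.raises(ValueError):
            aq.flag_multiplets(scores)


class TestAssignClusterLineage:
    def test_pure_clusters_recover_truth(self, small_cohort):
        gt = small_cohort.ground_truth.cells.set_index("barcode")
        norm = aq.normalize_log_cpm(small_cohort.adata)
        scores = aq.score_lineages(norm)
        clusters = gt["cell_type"].reindex(scores.index)  # oracle clusters
        mapping, per_cell = aq.assign_cluster_lineage(scores, clusters)
        from uveitis_sc.synthetic_data import LINEAGE_GROUP

        for cluster, lineage in mapping.items():
            assert lineage == LINEAGE_GROUP[cluster]

    def test_single_cluster_single_entry(self):
        scores = pd.DataFrame({"T": [1.0, 2.0], "B": [0.0, 0.1]}, index=["a", "b"])
        mapping, _ = aq.assign_cluster_lineage(
            scores, pd.Series(["c0", "c0"], index=["a", "b"])
        )
        assert mapping == {"c0": "T"}

    def test_exact_tie_breaks_lexicographically_with_warning(self):
        scores = pd.DataFrame({"B": [1.0], "T": [1.0]}, index=["a"])
        with pytest.warns(UserWarning):
            mapping, _ = aq.assign_cluster_lineage(
                scores, pd.Series(["c0"], index=["a"])
            )
        assert mapping == {"c0": "B"}


def rank_sum_permutation_oracle(a, b):
    """Exhaustive two-sided rank-sum p over all assignments of the pooled data."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n, na = len(pooled), len(a)
    observed = ranks[:na].sum()
    mean = na * (n + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(n), na):
        t = ranks[list(combo)].sum()
        total += 1
        if abs(t - mean) >= abs(observed - mean) - 1e-12:
            count += 1
    return count / total


class TestFindMarkers:
    def _groups_adata(self, a_vals, b_vals, gene="G0"):
        X = np.array(a_vals + b_vals, dtype=float).reshape(-1, 1)
        adata = make_adata(X, gene_names=[gene])
        na = len(a_vals)
        a_cells = list(adata.obs_names[:na])
        b_cells = list(adata.obs_names[na:])
        return adata, a_cells, b_cells

    def test_identical_groups_excluded_at_fc_threshold(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        adata, a, b = self._groups_adata(vals, vals)
        out = aq.find_markers(adata, a, b, log2fc_min=1.0, min_pct=0.2)
        assert len(out) == 0

    def test_threshold_pairs_differ_between_major_and_subset_analyses(self):
        rng = np.random.default_rng(3)
        # log-scale values chosen so log2FC ~= 0.9 and ~25% inclusion
        a = [0.0] * 15 + list(rng.uniform(1.2, 1.4, 5))
        b = [0.0] * 15 + list(rng.uniform(0.8, 1.0, 5))
        adata, ga, gb = self._groups_adata(a, b)
        fc = np.log2(
            (np.expm1(np.array(a)).mean() + 1e-9)
            / (np.expm1(np.array(b)).mean() + 1e-9)
        )
        assert 0.25 <= fc < 1.0
        major = aq.find_markers(adata, ga, gb, log2fc_min=1.0, min_pct=0.20)
        subset = aq.find_markers(adata, ga, gb, log2fc_min=0.25, min_pct=0.10)
        assert len(major) == 0 and len(subset) == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_exhaustive_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 6)
        b = rng.normal(1, 1, 6)
        p_impl = aq.wilcoxon_rank_sum(a, b)
        p_oracle = rank_sum_permutation_oracle(a, b)
        assert p_impl == pytest.approx(p_oracle, abs=1e-10)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(5)
        n_genes = 2000
        X = np.exp(rng.normal(0, 1, size=(60, n_genes)))  # one distribution
        adata = make_adata(X)
        a = list(adata.obs_names[:30])
        b = list(adata.obs_names[30:])
        out = aq.find_markers(adata, a, b, log2fc_min=0.0, min_pct=0.0)
        assert len(out) == n_genes
        ks = stats.kstest(out["pval"], "uniform")
        assert ks.pvalue > 0.01

    def test_tiny_group_warns(self):
        adata, a, b = self._groups_adata([1.0, 2.0], [3.0, 4.0, 5.0])
        with pytest.warns(UserWarning):
            aq.find_markers(adata, a, b, log2fc_min=0.0, min_pct=0.0)
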