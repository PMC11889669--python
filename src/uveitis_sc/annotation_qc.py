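"""QC filtering, marker-score lineage assignment, and multiplet flagging.

Cells are kept if they express at least ``min_genes_per_cell`` unique
genes and carry a mitochondrial read fraction inside
(``mito_min``, ``mito_max``); genes are kept if expressed in at least
``min_cells_per_gene`` cells (applied after the cell filter).  Lineages
are scored per cell as the mean z-scored normalized expression of a
small marker panel (CD79A for B cells, CD3D for T cells, LYZ for
myeloid, NCR1 for NK by default); cells scoring in the top decile for
two or more lineages are flagged as multiplets and excluded from
differential expression.  Marker finding is a two-sided Wilcoxon
rank-sum per gene with fold-change and inclusion-percentage prefilters
and Benjamini-Hochberg correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_PANEL = {
    "B": ["CD79A"],
    "T": ["CD3D"],
    "myeloid": ["LYZ"],
    "NK": ["NCR1"],
}


@dataclass
class QcThresholds:
    min_genes_per_cell: int = 500
    min_cells_per_gene: int = 70
    mito_max: float = 0.11
    mito_min: float = 0.01

    def __post_init__(self):
        if not (0 <= self.mito_min < self.mito_max <= 1):
            raise ValueError("require 0 <= mito_min < mito_max <= 1")


@dataclass
class QcReport:
    n_cells_in: int = 0
    n_genes_in: int = 0
    n_cells_low_genes: int = 0
    n_cells_mito: int = 0
    n_genes_low_cells: int = 0
    n_cells_out: int = 0
    n_genes_out: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def qc_filter(
    adata: ad.AnnData, thresholds: QcThresholds | None = None
) -> tuple[ad.AnnData, QcReport]:
    """Apply cell then gene QC filters; strict mitochondrial bounds.

    Cells with fewer than ``min_genes_per_cell`` expressed genes, or with
    ``mito_fraction`` strictly above ``mito_max`` / strictly below
    ``mito_min``, are removed; genes expressed in fewer than
    ``min_cells_per_gene`` of the surviving cells are then removed.
    Idempotent: filtering a filtered matrix changes nothing.
    """
    t = thresholds or QcThresholds()
    X = sp.csr_matrix(adata.X)
    report = QcReport(n_cells_in=adata.n_obs, n_genes_in=adata.n_vars)

    genes_per_cell = (X > 0).sum(axis=1).A1
    low_genes = genes_per_cell < t.min_genes_per_cell
    report.n_cells_low_genes = int(low_genes.sum())

    if "mito_fraction" in adata.obs:
        mito = adata.obs["mito_fraction"].to_numpy()
        bad_mito = (mito > t.mito_max) | (mito < t.mito_min)
    else:
        bad_mito = np.zeros(adata.n_obs, dtype=bool)
    report.n_cells_mito = int((bad_mito & ~low_genes).sum())

    keep_cells = ~(low_genes | bad_mito)
    filtered = adata[keep_cells].copy()

    Xf = sp.csc_matrix(filtered.X)
    cells_per_gene = (Xf > 0).sum(axis=0).A1
    keep_genes = cells_per_gene >= t.min_cells_per_gene
    report.n_genes_low_cells = int((~keep_genes).sum())
    filtered = filtered[:, keep_genes].copy()

    report.n_cells_out = filtered.n_obs
    report.n_genes_out = filtered.n_vars
    if filtered.n_obs == 0 or filtered.n_vars == 0:
        warnings.warn("QC filtering produced an empty matrix")
    return filtered, report


def normalize_log_cpm(
    adata: ad.AnnData, target_sum: float = 1e4
) -> ad.AnnData:
    """Library-size normalization to ``target_sum`` counts per cell, then log1p.

    Stands in for variance-stabilizing normalization; deterministic and
    scale-invariant per cell.  All-zero cells stay all-zero (with a
    warning).
    """
    out = adata.copy()
    X = sp.csr_matrix(out.X).astype(float)
    libsize = np.asarray(X.sum(axis=1)).ravel()
    zero = libsize == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-count cells scaled to all-zero")
    scale = np.divide(target_sum, libsize, out=np.zeros_like(libsize), where=~zero)
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    out.X = X
    out.uns["normalization"] = {"method": "log_cpm", "target_sum": target_sum}
    return out


def score_lineages(
    adata_norm: ad.AnnData, panel: dict[str, list[str]] | None = None
) -> pd.DataFrame:
    """Per-cell lineage scores: mean of z-scored normalized marker expression.

    Genes missing from the matrix are dropped with a warning; a lineage
    whose whole panel is missing is a configuration error.  Zero-variance
    genes contribute 0 to the mean (guarded z-score).
    """
    panel = panel or DEFAULT_PANEL
    X = sp.csr_matrix(adata_norm.X)
    var_index = pd.Index(adata_norm.var_names)
    scores = {}
    for lineage, genes in panel.items():
        present = [g for g in genes if g in var_index]
        missing = set(genes) - set(present)
        if missing:
            warnings.warn(f"lineage {lineage}: markers not in matrix: {sorted(missing)}")
        if not present:
            raise ValueError(f"no marker genes of lineage {lineage!r} present in matrix")
        cols = var_index.get_indexer(present)
        sub = np.asarray(X[:, cols].todense())
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0)
        z = np.where(sd > 0, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        scores[lineage] = z.mean(axis=1)
    return pd.DataFrame(scores, index=adata_norm.obs_names)


def flag_multiplets(scores: pd.DataFrame, top_fraction: float = 0.10) -> pd.Series:
    """Flag cells scoring in the top decile for two or more lineages.

    Per-lineage cutoffs are the (1 - top_fraction) quantile over all
    cells pooled (linear interpolation); a cell strictly above the cutoff
    for >= 2 lineages is a multiplet.
    """
    if scores.shape[1] < 2:
        raise ValueError("multiplet flagging requires >= 2 scored lineages")
    if scores.shape[0] < 10:
        raise ValueError("multiplet flagging requires >= 10 cells")
    cutoffs = scores.quantile(1.0 - top_fraction, interpolation="linear")
    n_top = (scores > cutoffs).sum(axis=1)
    return (n_top >= 2).rename("multiplet")


def assign_cluster_lineage(
    scores: pd.DataFrame, cluster_labels: pd.Series
) -> tuple[dict, pd.Series]:
    """Map each cluster to the lineage with highest mean cell score.

    Ties break lexicographically with a warning.  Returns the
    cluster -> lineage map and the per-cell lineage implied by it.
    """
    if not cluster_labels.index.equals(scores.index):
        cluster_labels = cluster_labels.reindex(scores.index)
    if cluster_labels.isna().any():
        raise ValueError("every cell needs a cluster label")
    mapping = {}
    for cluster, grp in scores.groupby(cluster_labels):
        means = grp.mean(axis=0)
        best = means.max()
        winners = sorted(means.index[means == best])
        if len(winners) > 1:
            warnings.warn(
                f"cluster {cluster}: lineage score tie {winners}; "
                f"assigning {winners[0]!r}"
            )
        mapping[cluster] = winners[0]
    per_cell = cluster_labels.map(mapping).rename("lineage")
    return mapping, per_cell


# ---------------------------------------------------------------------------
# marker finding


def _dense_column(X, j) -> np.ndarray:
    col = X[:, j]
    return col.toarray().ravel() if sp.issparse(col) else np.asarray(col).ravel()


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact when both groups are small and the data are tie-free,
    otherwise the normal approximation with tie-corrected variance
    (no continuity correction, so the exact and asymptotic paths agree
    in the limit).
    """
    small = max(len(a), len(b)) <= 12
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.pvalue)


def find_markers(
    adata_norm: ad.AnnData,
    group_a_cells,
    group_b_cells,
    log2fc_min: float = 1.0,
    min_pct: float = 0.20,
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Differentially expressed genes between two cell groups.

    Genes are prefiltered: |log2FC| >= ``log2fc_min`` (fold change of
    mean expm1-normalized expression, with a small epsilon) and expressed
    in at least ``min_pct`` of cells in either group.  Survivors get a
    two-sided Wilcoxon rank-sum test and Benjamini-Hochberg adjustment.
    Sorted by log2FC descending.

    Major-lineage thresholds are (1.0, 0.20); within-lineage subset
    analyses use (0.25, 0.10).
    """
    idx_a = adata_norm.obs_names.get_indexer(pd.Index(group_a_cells))
    idx_b = adata_norm.obs_names.get_indexer(pd.Index(group_b_cells))
    if (idx_a < 0).any() or (idx_b < 0).any():
        raise ValueError("group contains barcodes absent from the matrix")
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("both groups must be non-empty")
    if min(len(idx_a), len(idx_b)) < 3:
        warnings.warn("a group has fewer than 3 cells; using exact test path")

    X = sp.csc_matrix(adata_norm.X)
    Xa, Xb = X[idx_a], X[idx_b]

    mean_a = np.expm1(Xa).mean(axis=0).A1 if sp.issparse(Xa) else np.expm1(Xa).mean(axis=0)
    mean_b = np.expm1(Xb).mean(axis=0).A1 if sp.issparse(Xb) else np.expm1(Xb).mean(axis=0)
    log2fc = np.log2((np.asarray(mean_a) + eps) / (np.asarray(mean_b) + eps))

    pct_a = np.asarray((Xa > 0).mean(axis=0)).ravel()
    pct_b = np.asarray((Xb > 0).mean(axis=0)).ravel()

    passes = (np.abs(log2fc) >= log2fc_min) & (
        (pct_a >= min_pct) | (pct_b >= min_pct)
    )
    genes = np.flatnonzero(passes)
    pvals = np.array(
        [
            wilcoxon_rank_sum(_dense_column(Xa, j), _dense_column(Xb, j))
            for j in genes
        ]
    )
    padj = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else np.array([])
    out = pd.DataFrame(
        {
            "gene": np.asarray(adata_norm.var_names)[genes],
            "log2fc": log2fc[genes],
            "pct_a": pct_a[genes],
            "pct_b": pct_b[genes],
            "pval": pvals,
            "padj": padj,
        }
    )
    return out.sort_values("log2fc", ascending=False).reset_index(drop=True)


def kmeans_cluster_labels(
    adata_norm: ad.AnnData, n_clusters: int = 8, n_pcs: int = 20, seed: int = 0
) -> pd.Series:
    """Reference k-means-on-PCs labeler (for tests and the synthetic pipeline).

    Cluster labels are pluggable throughout; this provides a deterministic
    source of them when none are supplied.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    X = np.asarray(sp.csr_matrix(adata_norm.X).todense())
    X = X - X.mean(axis=0)
    n_pcs = min(n_pcs, min(X.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit(pcs)
    return pd.Series(km.labels_.astype(str), index=adata_norm.obs_names, name="cluster")
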