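"""Simplified covarying neighborhood analysis (CNA).

Associates granular transcriptional neighborhoods with a binary
sample-level phenotype.  Cells are connected in a kNN graph in PC
space; each cell anchors a neighborhood defined by a short random walk
on the graph, and the neighborhood abundance matrix (NAM) records, for
every anchor, how the walked probability mass distributes across
samples.  PCA of the NAM (samples as observations, neighborhoods as
features) yields NAM-PCs; the phenotype is regressed on sample-level
NAM-PC scores, and every cell receives a neighborhood coefficient — the
correlation between its sample-abundance profile and the fitted
phenotype direction.  A global p-value comes from phenotype-label
permutation.

This is a deliberately simplified contract of published CNA: binary
phenotype only, no covariate adjustment, fixed walk depth (default 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components


@dataclass
class KnnGraph:
    adjacency: sp.csr_matrix  # symmetric, no self loops
    k: int
    n_components: int


@dataclass
class NeighborhoodAbundanceMatrix:
    raw: pd.DataFrame  # cells x samples, rows sum to 1
    standardized: pd.DataFrame  # each neighborhood standardized across samples
    steps: int


@dataclass
class CnaResult:
    coefficients: pd.Series  # per cell, in [-1, 1]
    global_p: float
    r2: float
    n_perm: int
    n_pcs: int


def build_knn_graph(pc_scores, k: int = 20) -> KnnGraph:
    """Euclidean kNN graph in PC space, symmetrized by union.

    Deterministic: neighbors are ordered by (distance, index), so
    distance ties resolve to the lower index.  Every node has degree
    >= k after union-symmetrization.
    """
    X = np.asarray(pc_scores, dtype=float)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < n_cells={n}")
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=min(2 * k + 1, n), metric="euclidean").fit(X)
    dist, idx = nn.kneighbors(X)
    rows, cols = [], []
    for i in range(n):
        # stable (distance, index) order, excluding self, first k
        order = sorted(
            (d, j) for d, j in zip(dist[i], idx[i]) if j != i
        )[:k]
        for _, j in order:
            rows.append(i)
            cols.append(j)
    A = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    A = A.maximum(A.T)  # union symmetrization
    A.setdiag(0)
    A.eliminate_zeros()
    n_comp, _ = connected_components(A, directed=False)
    if n_comp > 1:
        warnings.warn(f"kNN graph has {n_comp} connected components")
    return KnnGraph(adjacency=A, k=k, n_components=n_comp)


def compute_nam(
    graph: KnnGraph,
    sample_labels: pd.Series,
    steps: int = 3,
) -> NeighborhoodAbundanceMatrix:
    """Neighborhood abundance matrix from a ``steps``-step random walk.

    The walk starts at each anchor cell and follows the row-normalized
    adjacency; the landed mass is aggregated by sample label, so each
    row is the anchor neighborhood's composition across samples (sums
    to 1).  ``steps=0`` reduces to the anchor cell's own sample
    indicator.  Isolated nodes retain their mass (self-retaining walk,
    with a warning).  The standardized copy scales each neighborhood
    feature to mean 0, sd 1 across samples, ready for NAM-PCA.
    """
    A = graph.adjacency
    n = A.shape[0]
    labels = pd.Series(sample_labels)
    if len(labels) != n:
        raise ValueError("need one sample label per cell")
    deg = np.asarray(A.sum(axis=1)).ravel()
    isolated = deg == 0
    if isolated.any():
        warnings.warn(f"{int(isolated.sum())} isolated cells retain their own mass")
    inv_deg = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    P = sp.diags(inv_deg) @ A
    if isolated.any():
        P = P + sp.diags(isolated.astype(float))

    samples = pd.Index(sorted(labels.unique()))
    S = np.zeros((n, len(samples)))
    S[np.arange(n), samples.get_indexer(labels)] = 1.0
    M = S
    for _ in range(steps):
        M = P @ M
    raw = pd.DataFrame(M, index=labels.index, columns=samples)
    std = standardize_neighborhoods(raw)
    return NeighborhoodAbundanceMatrix(raw=raw, standardized=std, steps=steps)


def standardize_neighborhoods(raw: pd.DataFrame) -> pd.DataFrame:
    """Scale each neighborhood (row) to mean 0, sd 1 across samples.

    Neighborhoods are the features of the samples-as-observations PCA;
    constant neighborhoods scale to all-zero.
    """
    vals = raw.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((vals - mu) / sd, index=raw.index, columns=raw.columns)


def association_test(
    nam: NeighborhoodAbundanceMatrix,
    phenotype: pd.Series,
    n_perm: int = 1000,
    max_pcs: int | None = None,
    seed: int = 0,
) -> CnaResult:
    """Test association between neighborhood composition and a binary phenotype.

    NAM-PCA: samples are observations, standardized neighborhoods are
    features.  The phenotype (0/1 per sample) is regressed on the first
    ``max_pcs`` sample-level NAM-PC scores; the fitted values define the
    phenotype direction in sample space.  Each cell's neighborhood
    coefficient is the Pearson correlation of its abundance profile with
    that direction.  The global p permutes phenotype labels and compares
    the regression R^2.
    """
    y = phenotype.reindex(nam.raw.columns).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype missing for some samples")
    if len(np.unique(y)) < 2:
        raise ValueError("phenotype is constant")
    for v in np.unique(y):
        if (y == v).sum() < 2:
            raise ValueError("need >= 2 samples per phenotype value")

    # samples x neighborhoods
    Z = nam.standardized.to_numpy().T
    n_samples = Z.shape[0]
    if max_pcs is None:
        # keep regression df well below the sample count, otherwise the
        # fit saturates (R^2 -> 1) under null and alternative alike
        max_pcs = min(10, max(1, n_samples // 2 - 1))
    max_pcs = max(1, min(max_pcs, n_samples - 2))

    # PCA of samples in neighborhood space via SVD
    Zc = Z - Z.mean(axis=0)
    U, s, _ = np.linalg.svd(Zc, full_matrices=False)
    scores = U[:, :max_pcs] * s[:max_pcs]  # sample-level NAM-PC scores

    def fit_r2(yv: np.ndarray) -> tuple[float, np.ndarray]:
        yc = yv - yv.mean()
        X = scores
        beta, *_ = np.linalg.lstsq(X, yc, rcond=None)
        fitted = X @ beta
        ss_tot = float(yc @ yc)
        r2 = float(fitted @ fitted) / ss_tot if ss_tot else 0.0
        return r2, fitted

    r2_obs, fitted = fit_r2(y)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        r2_null, _ = fit_r2(rng.permutation(y))
        if r2_null >= r2_obs:
            exceed += 1
    global_p = (1 + exceed) / (1 + n_perm)

    # per-cell coefficient: correlation of abundance profile with fitted direction
    direction = fitted - fitted.mean()
    dnorm = np.linalg.norm(direction)
    M = nam.raw.to_numpy()
    Mc = M - M.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Mc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        coef = (Mc @ direction) / (norms * dnorm)
    coef = np.nan_to_num(coef, nan=0.0)
    coef = np.clip(coef, -1.0, 1.0)
    return CnaResult(
        coefficients=pd.Series(coef, index=nam.raw.index, name="neighborhood_coefficient"),
        global_p=float(global_p),
        r2=r2_obs,
        n_perm=n_perm,
        n_pcs=max_pcs,
    )


def gene_loadings(adata_norm, coefficients: pd.Series) -> pd.Series:
    """Per-gene correlation of expression with the neighborhood coefficients.

    Returns a descending-ranked gene -> score vector suitable for
    preranked GSEA; constant genes score 0.
    """
    X = np.asarray(sp.csr_matrix(adata_norm.X).todense(), dtype=float)
    c = coefficients.reindex(adata_norm.obs_names).to_numpy(dtype=float)
    cc = c - c.mean()
    cnorm = np.linalg.norm(cc)
    Xc = X - X.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (Xc.T @ cc) / (norms * cnorm)
    scores = np.nan_to_num(scores, nan=0.0)
    return pd.Series(scores, index=adata_norm.var_names).sort_values(ascending=False)


def check_patient_uniqueness(
    metadata: pd.DataFrame, allow_replicates: bool = False
) -> pd.DataFrame:
    """Drop replicate samples of the same patient before association.

    Repeat flares of one eye would otherwise count as independent
    observations.  Keeps the first sample per (patient, compartment);
    pass ``allow_replicates=True`` to skip the check.
    """
    if allow_replicates:
        return metadata
    return metadata.drop_duplicates(subset=["patient", "compartment"], keep="first")
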