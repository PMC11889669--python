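"""Sample-level compositional PCA with a Monte Carlo significance test.

Each sample is summarised by a feature vector combining the proportions
of its annotated immune cell types, clonality (Gini) of CD4 / CD8 T
cells and B cells, and clinical covariates (age, disease duration,
severity, local steroid use) — 26 features in the default configuration.
Columns are z-scored; PCA of the resulting correlation structure
separates samples by immunologic profile.  A Monte Carlo test judges
whether leading PCs capture more variance than expected by chance:
every column is permuted independently across samples and the
variance-explained spectrum recomputed, ``n_iter`` times.

A UMAP embedding of the first 10 PCs plus k-means (k=3) gives a
reproducible 3-way sample partition standing in for manually delineated
clusters, and standard contrasts (one-way ANOVA + Tukey HSD, Welch t,
simple linear regression) compare features across the partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SampleFeatureMatrix:
    """Z-scored samples x features matrix plus the scaling manifest."""

    X: pd.DataFrame
    manifest: pd.DataFrame  # per-feature: kind, mean, sd, imputed count


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x PCs
    loadings: pd.DataFrame  # features x PCs
    variance_explained: np.ndarray  # fraction per PC
    eigenvalues: np.ndarray

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.variance_explained)


@dataclass
class McPcTest:
    n_iter: int
    p: np.ndarray  # per-PC
    observed: np.ndarray  # observed variance_explained
    null_mean: np.ndarray
    null_sd: np.ndarray


def build_feature_matrix(
    clonality: pd.DataFrame,
    composition: pd.DataFrame,
    metadata: pd.DataFrame,
    clinical_features: tuple = ("age", "duration", "severity", "steroid_use"),
    gini_lineages: tuple = ("CD4", "CD8", "B"),
) -> SampleFeatureMatrix:
    """Assemble and z-score the per-sample feature matrix.

    ``composition``: samples x cell-type proportion table (rows sum to 1).
    ``clonality``: long table with sample / lineage / gini / tltc columns.
    ``metadata``: per-sample clinical table.  Gini values flagged TLTC
    (or missing) are imputed with the column mean before scaling, and the
    imputation is recorded in the manifest.  Constant columns are
    excluded with a warning.  Boolean clinical features are coded 0/1.
    """
    samples = composition.index
    rowsums = composition.sum(axis=1)
    if not np.allclose(rowsums, 1.0, atol=1e-9):
        raise ValueError("composition rows must sum to 1 before scaling")

    blocks = {f"prop_{c}": composition[c] for c in composition.columns}

    gini_wide = clonality.pivot(index="sample", columns="lineage", values="gini")
    tltc_wide = clonality.pivot(index="sample", columns="lineage", values="tltc")
    for lin in gini_lineages:
        col = gini_wide[lin].reindex(samples) if lin in gini_wide else pd.Series(np.nan, index=samples)
        if lin in tltc_wide:
            col = col.mask(tltc_wide[lin].reindex(samples).fillna(True).astype(bool))
        blocks[f"gini_{lin}"] = col

    meta = metadata.set_index("sample").reindex(samples)
    for feat in clinical_features:
        if feat not in meta:
            continue
        col = meta[feat]
        if col.dtype == bool or set(col.dropna().unique()) <= {0, 1, True, False}:
            col = col.astype(float)
        blocks[feat] = pd.to_numeric(col, errors="coerce")

    raw = pd.DataFrame(blocks, index=samples)

    manifest_rows = []
    scaled = {}
    for name, col in raw.items():
        n_imputed = int(col.isna().sum())
        if n_imputed:
            col = col.fillna(col.mean())
        mu, sd = col.mean(), col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"feature {name!r} is constant; excluded")
            continue
        scaled[name] = (col - mu) / sd
        manifest_rows.append(
            {"feature": name, "mean": mu, "sd": sd, "n_imputed": n_imputed,
             "kind": ("proportion" if name.startswith("prop_")
                      else "clonality" if name.startswith("gini_")
                      else "clinical")}
        )
    X = pd.DataFrame(scaled, index=samples)
    return SampleFeatureMatrix(X=X, manifest=pd.DataFrame(manifest_rows))


def _variance_explained(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecomposition of the feature covariance (ddof=1) of X."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    C = Xc.T @ Xc / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0, None)
    eigvecs = eigvecs[:, order]
    return eigvals / eigvals.sum(), eigvals, eigvecs


def run_pca(m: SampleFeatureMatrix, n_pcs: int | None = None) -> PcaResult:
    """PCA of the scaled feature matrix via covariance eigendecomposition.

    Deterministic sign convention: within each PC the feature with the
    largest |loading| gets a positive loading.
    """
    X = m.X.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3 or p < 2:
        raise ValueError("PCA needs >= 3 samples and >= 2 features")
    ve, eigvals, eigvecs = _variance_explained(X)
    rank = min(n - 1, p)
    if n_pcs is None:
        n_pcs = rank
    elif n_pcs > rank:
        warnings.warn(f"requested {n_pcs} PCs but rank is {rank}; truncating")
        n_pcs = rank
    eigvals, eigvecs, ve = eigvals[:n_pcs], eigvecs[:, :n_pcs], ve[:n_pcs]
    # sign convention
    for j in range(eigvecs.shape[1]):
        i_max = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[i_max, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    Xc = X - X.mean(axis=0)
    scores = Xc @ eigvecs
    pc_names = [f"PC{j + 1}" for j in range(n_pcs)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=m.X.index, columns=pc_names),
        loadings=pd.DataFrame(eigvecs, index=m.X.columns, columns=pc_names),
        variance_explained=ve,
        eigenvalues=eigvals,
    )


def variable_vectors(p: PcaResult, pc_x: int = 1, pc_y: int = 2) -> pd.DataFrame:
    """Per-feature 2D vectors in PC space (feature-PC correlations).

    Component = loading * sqrt(eigenvalue); for z-scored input this is
    the correlation of the feature with the PC score, so magnitudes are
    bounded by 1.
    """
    cx, cy = f"PC{pc_x}", f"PC{pc_y}"
    vx = p.loadings[cx] * np.sqrt(p.eigenvalues[pc_x - 1])
    vy = p.loadings[cy] * np.sqrt(p.eigenvalues[pc_y - 1])
    out = pd.DataFrame({cx: vx, cy: vy})
    out["magnitude"] = np.hypot(vx, vy)
    return out


def monte_carlo_pc_test(
    m: SampleFeatureMatrix, n_iter: int = 10000, seed: int = 0
) -> McPcTest:
    """Permutation null for the PCA variance-explained spectrum.

    Each iteration permutes every column independently across samples
    (destroying inter-feature correlation, preserving marginals) and
    recomputes variance explained.  Per-PC p-values use the +1 estimator
    p = (1 + #{null >= observed}) / (1 + n_iter).
    """
    if n_iter < 100:
        warnings.warn("n_iter < 100 gives very coarse p-values")
    X = m.X.to_numpy(dtype=float)
    n, p = X.shape
    observed = _variance_explained(X)[0]
    rng = np.random.default_rng(seed)
    exceed = np.zeros(observed.size)
    null_sum = np.zeros(observed.size)
    null_sumsq = np.zeros(observed.size)
    perm = np.empty_like(X)
    for _ in range(n_iter):
        for j in range(p):
            perm[:, j] = X[rng.permutation(n), j]
        ve = _variance_explained(perm)[0]
        exceed += ve >= observed
        null_sum += ve
        null_sumsq += ve**2
    pvals = (1.0 + exceed) / (1.0 + n_iter)
    null_mean = null_sum / n_iter
    null_sd = np.sqrt(np.maximum(null_sumsq / n_iter - null_mean**2, 0))
    return McPcTest(
        n_iter=n_iter, p=pvals, observed=observed,
        null_mean=null_mean, null_sd=null_sd,
    )


def embed_and_cluster(
    p: PcaResult,
    n_pcs: int = 10,
    k: int = 3,
    seed: int = 0,
    order_by: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """UMAP embedding of the leading PCs + k-means partition of samples.

    k-means runs on the PC scores themselves (not the embedding), so the
    partition does not depend on UMAP's stochastic layout.  Cluster
    labels are renamed A, B, C, ... ordered by descending mean of
    ``order_by`` (an adaptive-immunity score per sample; defaults to the
    PC1 score), making labels reproducible across runs.
    """
    from sklearn.cluster import KMeans

    scores = p.scores.iloc[:, : min(n_pcs, p.scores.shape[1])]
    n = scores.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n_samples={n}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(scores.to_numpy())
    raw = pd.Series(km.labels_, index=scores.index)

    basis = order_by.reindex(scores.index) if order_by is not None else scores.iloc[:, 0]
    means = basis.groupby(raw).mean().sort_values(ascending=False)
    rename = {old: chr(ord("A") + i) for i, old in enumerate(means.index)}
    labels = raw.map(rename).rename("cluster")

    if n > 3:
        import umap

        n_neighbors = int(np.clip(n - 1, 2, 15))
        emb = umap.UMAP(
            n_components=2, random_state=seed, n_neighbors=n_neighbors
        ).fit_transform(scores.to_numpy())
    else:
        emb = scores.to_numpy()[:, :2]
    embedding = pd.DataFrame(emb, index=scores.index, columns=["UMAP1", "UMAP2"])
    return embedding, labels


# ---------------------------------------------------------------------------
# contrasts

STAR_BANDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_notation(p: float) -> str:
    """Significance stars: ns / * / ** / *** / **** at 0.05/0.01/0.001/0.0001."""
    for cutoff, stars in STAR_BANDS:
        if p <= cutoff:
            return stars
    return "ns"


def cluster_contrasts(values: pd.Series, labels: pd.Series) -> dict:
    """One-way ANOVA across clusters with Tukey HSD pairwise comparisons."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    aligned = labels.reindex(values.index)
    groups = [values[aligned == g].to_numpy() for g in sorted(aligned.dropna().unique())]
    if len(groups) < 2:
        raise ValueError("ANOVA requires >= 2 groups")
    if all(np.ptp(g) == 0 for g in groups if len(g)):
        warnings.warn("zero within-group variance everywhere; exact separation")
    F, p = stats.f_oneway(*groups)
    tk = pairwise_tukeyhsd(values.to_numpy(), aligned.to_numpy())
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    )
    return {"F": float(F), "p": float(p), "stars": star_notation(float(p)),
            "tukey": tukey}


def welch_t(a, b) -> dict:
    """Unpaired t test with Welch's correction (Satterthwaite df)."""
    t, p = stats.ttest_ind(np.asarray(a), np.asarray(b), equal_var=False)
    return {"t": float(t), "p": float(p), "stars": star_notation(float(p))}


def simple_linreg(x, y) -> dict:
    """Simple linear regression: slope, intercept, R^2, p."""
    res = stats.linregress(np.asarray(x, float), np.asarray(y, float))
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "stars": star_notation(float(res.pvalue)),
    }
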