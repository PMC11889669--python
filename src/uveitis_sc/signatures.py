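"""Gene-set scoring per cell and preranked gene-set enrichment.

Per-cell scoring is rank-based: within each cell, all genes are ranked
by normalized expression (average ranks on ties) and the score of a set
is the mean rank of its members mapped to [0, 1] and centered at zero,
so a cell whose set genes sit at the top of its own expression ranking
scores near +0.5 and a cell where they sit at the bottom near -0.5.
Being rank-based, the score is invariant to any monotone transform of
the cell's expression vector.

Preranked GSEA is the classic weighted Kolmogorov-Smirnov running sum
over a ranked gene list, with a gene-permutation null for NES and p.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ValueError("gene set must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene set members must be unique")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (name <tab> description <tab> genes...)."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets.append(GeneSet(name=parts[0], genes=tuple(dict.fromkeys(parts[2:]))))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *s.genes]) + "\n")


def score_cells(adata_norm: ad.AnnData, gene_set: GeneSet) -> pd.Series:
    """Centered normalized mean-rank score of a gene set, per cell.

    score = (mean rank of set genes - 1) / (G - 1) - 0.5, with ranks
    ascending in expression (average rank on ties) over the G genes in
    the matrix.  Higher = set enriched in that cell.
    """
    present = [g for g in gene_set.genes if g in adata_norm.var_names]
    if not present:
        raise ValueError(
            f"no genes of set {gene_set.name!r} present in the matrix"
        )
    X = np.asarray(sp.csr_matrix(adata_norm.X).todense())
    G = X.shape[1]
    cols = pd.Index(adata_norm.var_names).get_indexer(present)
    ranks = stats.rankdata(X, axis=1)  # average ranks, ascending
    mean_rank = ranks[:, cols].mean(axis=1)
    score = (mean_rank - 1.0) / (G - 1.0) - 0.5 if G > 1 else np.zeros(X.shape[0])
    return pd.Series(score, index=adata_norm.obs_names, name=gene_set.name)


SIZE_GROUP_ORDER = ("singleton", "small", "medium", "large")


def score_by_size_group(
    scores: pd.Series, size_classes: pd.Series, min_cells: int = 2
) -> tuple[pd.DataFrame, float]:
    """Group per-cell scores by clonotype size class; one-way ANOVA across groups.

    Groups with fewer than ``min_cells`` cells are dropped with a
    warning.  The summary preserves the singleton < small < medium <
    large ordering.
    """
    import warnings

    aligned = size_classes.reindex(scores.index)
    groups, rows = [], []
    for label in SIZE_GROUP_ORDER:
        vals = scores[aligned == label].to_numpy()
        if len(vals) == 0:
            continue
        if len(vals) < min_cells:
            warnings.warn(f"size group {label!r} has <{min_cells} cells; dropped")
            continue
        groups.append(vals)
        rows.append(
            {
                "size_class": label,
                "n_cells": len(vals),
                "mean": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / np.sqrt(len(vals))),
            }
        )
    if len(groups) < 2:
        raise ValueError("ANOVA requires >= 2 groups with enough cells")
    _, p = stats.f_oneway(*groups)
    return pd.DataFrame(rows), float(p)


@dataclass
class EnrichmentResult:
    es: float
    nes: float
    p: float
    n_perm: int


def _running_sum_es(in_set: np.ndarray, weights: np.ndarray) -> float:
    """Extreme deviation of the weighted KS running sum over a ranked list."""
    n = in_set.size
    n_hits = int(in_set.sum())
    hit_w = np.where(in_set, weights, 0.0)
    total_hit = hit_w.sum()
    if total_hit == 0:
        return 0.0
    step_hit = hit_w / total_hit
    step_miss = np.where(in_set, 0.0, 1.0 / (n - n_hits))
    running = np.cumsum(step_hit - step_miss)
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(
    ranked: pd.Series,
    gene_set: GeneSet,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> EnrichmentResult:
    """Preranked GSEA of a gene -> score vector against one gene set.

    The ranking is sorted descending by score; hits advance the running
    sum by |score|^weight (normalized over hits), misses retreat it
    uniformly; ES is the extreme deviation.  The null permutes set
    membership over genes (``n_perm`` draws); NES divides ES by the mean
    |null ES| of the same sign, and p is the sign-matched permutation
    tail with the +1 correction.
    """
    if ranked.index.duplicated().any():
        raise ValueError("ranking contains duplicate genes")
    in_set_genes = [g for g in gene_set.genes if g in ranked.index]
    if not in_set_genes:
        raise ValueError(f"gene set {gene_set.name!r} disjoint from ranking")
    order = ranked.sort_values(ascending=False, kind="mergesort")
    weights = np.abs(order.to_numpy()) ** weight
    in_set = order.index.isin(in_set_genes)
    es = _running_sum_es(in_set, weights)

    rng = np.random.default_rng(seed)
    n, k = len(order), len(in_set_genes)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=k, replace=False)] = True
        null[i] = _running_sum_es(perm, weights)

    # sign-matched null: ES is compared against the same-sign portion of
    # the permutation distribution (as in standard preranked GSEA), which
    # keeps the p-value uniform under a random set
    same_sign = null[null >= 0] if es >= 0 else null[null < 0]
    denom = np.abs(same_sign).mean() if same_sign.size else np.nan
    nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
    if es >= 0:
        p = (1 + int((same_sign >= es).sum())) / (1 + same_sign.size)
    else:
        p = (1 + int((same_sign <= es).sum())) / (1 + same_sign.size)
    return EnrichmentResult(es=es, nes=float(nes), p=float(p), n_perm=n_perm)
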