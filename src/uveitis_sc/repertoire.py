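"""Clonotype aggregation, size classes, and Gini clonality.

A clonotype is the set of T (or B) cells in a sample sharing identical
receptor CDR3 sequences; its *size* is the number of cells.  Clonal
expansion within a sample is summarised two ways: the fraction of cells
belonging to expanded clonotypes (size >= 2), and a Gini coefficient on
the clonotype cell counts (0 = all clonotypes equal, -> 1 = a single
clonotype dominates).  Samples with too few cells of a lineage for the
clonality estimate to be stable are flagged TLTC ("too low to
calculate") rather than silently reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

# T cells get four size classes, B cells three.
T_SIZE_CLASSES = ("singleton", "small", "medium", "large")
B_SIZE_CLASSES = ("singleton", "small", "large")

#: Minimum cells of a lineage in a sample for a reportable Gini.
TLTC_MIN_CELLS = 50


def classify_clone_size(size: int, mode: str = "T") -> str:
    """Assign a clonotype size class.

    T mode: singleton (1), small (2-9), medium (10-19), large (>=20).
    B mode: singleton (1), small (2-9), large (>=10).
    """
    if size < 1:
        raise ValueError(f"clonotype size must be >= 1, got {size}")
    if mode not in ("T", "B"):
        raise ValueError(f"mode must be 'T' or 'B', got {mode!r}")
    if size == 1:
        return "singleton"
    if size <= 9:
        return "small"
    if mode == "B":
        return "large"
    return "medium" if size <= 19 else "large"


def gini(counts) -> float:
    """Discrete Gini coefficient of clonotype cell counts.

    For n clonotypes with counts sorted ascending, y_(1) <= ... <= y_(n),

        G = sum_i (2i - n - 1) * y_(i) / (n * sum_i y_(i))

    which equals the mean-absolute-difference form
    sum_ij |y_i - y_j| / (2 n^2 ybar).  No small-sample correction is
    applied; G = 0 for a single clonotype.
    """
    y = np.asarray(counts, dtype=float)
    if y.size == 0:
        raise ValueError("gini requires at least one clonotype count")
    if np.any(y < 1):
        raise ValueError("clonotype counts must be >= 1")
    n = y.size
    if n == 1:
        return 0.0
    y = np.sort(y)
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * y) / (n * y.sum()))


@dataclass
class ClonalityStats:
    """Per-sample, per-lineage clonal expansion summary."""

    gini: float
    fraction_expanded: float
    n_cells: int
    n_clonotypes: int
    tltc_flag: bool


def clonality_stats(
    table: pd.DataFrame,
    sample: str | None = None,
    lineage: str | None = None,
    min_cells: int = TLTC_MIN_CELLS,
) -> ClonalityStats:
    """Clonality summary for one sample x lineage slice of a clonotype table.

    ``table`` holds one row per clonotype with at least a ``size`` column
    (and ``sample`` / ``lineage`` columns if filtering here).  The Gini is
    always computed, but ``tltc_flag`` marks it non-reportable when the
    slice holds fewer than ``min_cells`` cells.
    """
    sub = table
    if sample is not None:
        sub = sub[sub["sample"] == sample]
    if lineage is not None:
        sub = sub[sub["lineage"] == lineage]
    sizes = sub["size"].to_numpy()
    n_cells = int(sizes.sum())
    if sizes.size == 0:
        return ClonalityStats(
            gini=float("nan"),
            fraction_expanded=float("nan"),
            n_cells=0,
            n_clonotypes=0,
            tltc_flag=True,
        )
    g = gini(sizes)
    frac = float(sizes[sizes >= 2].sum() / n_cells)
    return ClonalityStats(
        gini=g,
        fraction_expanded=frac,
        n_cells=n_cells,
        n_clonotypes=int(sizes.size),
        tltc_flag=n_cells < min_cells,
    )


def clonality_table(
    table: pd.DataFrame, min_cells: int = TLTC_MIN_CELLS
) -> pd.DataFrame:
    """Clonality stats for every (sample, lineage) combination present."""
    rows = []
    for (s, lin), _ in table.groupby(["sample", "lineage"]):
        st = clonality_stats(table, sample=s, lineage=lin, min_cells=min_cells)
        rows.append(
            {
                "sample": s,
                "lineage": lin,
                "gini": st.gini,
                "fraction_expanded": st.fraction_expanded,
                "n_cells": st.n_cells,
                "n_clonotypes": st.n_clonotypes,
                "tltc": st.tltc_flag,
            }
        )
    return pd.DataFrame(rows)


def assign_clonotype_lineage(cell_lineages: pd.Series) -> str:
    """Lineage of a clonotype by majority vote of its cells; ties -> unconventional."""
    counts = cell_lineages.value_counts()
    if counts.size == 0:
        return "unconventional"
    top = counts[counts == counts.iloc[0]]
    if top.size > 1:
        warnings.warn("clonotype lineage tie; assigning 'unconventional'")
        return "unconventional"
    return str(top.index[0])


def aggregate_clonotypes(cells: pd.DataFrame) -> pd.DataFrame:
    """Build a clonotype table from per-cell assignments.

    ``cells`` has one row per cell with columns ``barcode``, ``sample``,
    ``compartment``, ``patient``, ``clonotype_key`` and ``lineage``.
    Cells with a null clonotype key ("no data") are dropped.  Returns one
    row per (clonotype_key, sample) with size, member barcodes and a
    majority-vote lineage.
    """
    with_tcr = cells[cells["clonotype_key"].notna()]
    rows = []
    for (key, s), grp in with_tcr.groupby(["clonotype_key", "sample"]):
        rows.append(
            {
                "clonotype_key": key,
                "sample": s,
                "patient": grp["patient"].iloc[0],
                "compartment": grp["compartment"].iloc[0],
                "lineage": assign_clonotype_lineage(grp["lineage"]),
                "size": len(grp),
                "barcodes": list(grp["barcode"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "clonotype_key",
            "sample",
            "patient",
            "compartment",
            "lineage",
            "size",
            "barcodes",
        ],
    )


def persistent_clonotypes(
    flare_a: pd.DataFrame, flare_b: pd.DataFrame
) -> pd.DataFrame:
    """Clonotypes shared between two flares of the same patient.

    Returns the intersection by clonotype key with per-flare cell-count
    frequencies (suitable for a flare-1 vs flare-2 scatter).
    """

    def freqs(tbl: pd.DataFrame) -> pd.Series:
        sizes = tbl.groupby("clonotype_key")["size"].sum()
        return sizes / sizes.sum()

    fa, fb = freqs(flare_a), freqs(flare_b)
    shared = fa.index.intersection(fb.index)
    return pd.DataFrame(
        {
            "clonotype_key": shared,
            "freq_flare_a": fa.loc[shared].to_numpy(),
            "freq_flare_b": fb.loc[shared].to_numpy(),
        }
    ).reset_index(drop=True)
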