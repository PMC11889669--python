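"""Eye-vs-blood clonotype enrichment and the antigen-activated classifier.

For each clonotype observed in a patient's eye, its cell frequency in the
eye compartment is compared with the matched peripheral-blood sample as a
log-fold ratio (LFR).  Clonotypes that are both expanded in the eye
(>= ``size_min`` cells) and eye-enriched (LFR strictly greater than
``lfr_min``) are classified *antigen-activated*: cells most likely to
have undergone local antigen-driven clonal expansion rather than having
immigrated as pre-expanded blood clones.

Frequencies use a pseudocount in numerator and denominator,
f = (n + c) / (N + c), so that clonotypes absent from one compartment
still yield a finite, antisymmetric LFR.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from uveitis_sc.repertoire import classify_clone_size

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_SIZE_MIN = 5
DEFAULT_LFR_MIN = 1.0


def compute_lfr(
    n_eye: float,
    N_eye: float,
    n_blood: float,
    N_blood: float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    base: float = 2.0,
) -> float:
    """Log-fold ratio of a clonotype's eye vs blood cell frequency.

    lfr = log_base( ((n_eye + c) / (N_eye + c)) / ((n_blood + c) / (N_blood + c)) )

    Antisymmetric under swapping the two compartments.
    """
    for v in (n_eye, N_eye, n_blood, N_blood):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if n_eye > N_eye or n_blood > N_blood:
        raise ValueError("clonotype count exceeds compartment total")
    if N_eye < 1 or N_blood < 1:
        raise ValueError("compartment totals must be >= 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    c = pseudocount
    f_eye = (n_eye + c) / (N_eye + c)
    f_blood = (n_blood + c) / (N_blood + c)
    return math.log(f_eye / f_blood, base)


def classify_antigen_activated(
    n_eye: int,
    lfr: float,
    size_min: int = DEFAULT_SIZE_MIN,
    lfr_min: float = DEFAULT_LFR_MIN,
) -> bool:
    """True iff the eye clonotype has >= size_min cells and LFR strictly > lfr_min."""
    if n_eye < 0:
        raise ValueError("n_eye must be non-negative")
    return bool(n_eye >= size_min and lfr > lfr_min)


def compute_enrichment(
    clonotypes: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    size_min: int = DEFAULT_SIZE_MIN,
    lfr_min: float = DEFAULT_LFR_MIN,
    by_lineage: bool = True,
    base: float = 2.0,
) -> pd.DataFrame:
    """Per-clonotype eye/blood enrichment table for a whole cohort.

    ``clonotypes`` is a clonotype table (one row per clonotype x sample,
    columns ``clonotype_key``, ``patient``, ``compartment``, ``lineage``,
    ``size``).  Clonotypes are matched between a patient's eye and blood
    compartments by key.  Compartment totals N are cells with TCR data of
    the same lineage (``by_lineage=True``, mirroring separate CD4 / CD8
    analyses) or all T cells pooled.

    Returns one row per clonotype observed in the eye, with counts,
    frequencies, LFR, size class and the antigen-activated call.
    """
    rows = []
    for patient, grp in clonotypes.groupby("patient"):
        eye = grp[grp["compartment"] == "eye"]
        blood = grp[grp["compartment"] == "blood"]
        blood_sizes = blood.set_index("clonotype_key")["size"]
        for lin, eye_lin in eye.groupby("lineage"):
            if by_lineage:
                N_eye = int(eye[eye["lineage"] == lin]["size"].sum())
                N_blood = int(blood[blood["lineage"] == lin]["size"].sum())
            else:
                N_eye = int(eye["size"].sum())
                N_blood = int(blood["size"].sum())
            if N_eye < 1:
                continue
            for _, row in eye_lin.iterrows():
                n_eye = int(row["size"])
                n_blood = int(blood_sizes.get(row["clonotype_key"], 0))
                lfr = compute_lfr(
                    n_eye, N_eye, n_blood, max(N_blood, 1),
                    pseudocount=pseudocount, base=base,
                )
                rows.append(
                    {
                        "clonotype_key": row["clonotype_key"],
                        "patient": patient,
                        "sample": row["sample"],
                        "lineage": lin,
                        "n_eye": n_eye,
                        "n_blood": n_blood,
                        "N_eye": N_eye,
                        "N_blood": N_blood,
                        "f_eye": n_eye / N_eye,
                        "f_blood": n_blood / N_blood if N_blood else 0.0,
                        "lfr": lfr,
                        "size_class": classify_clone_size(n_eye, "T"),
                        "antigen_activated": classify_antigen_activated(
                            n_eye, lfr, size_min=size_min, lfr_min=lfr_min
                        ),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "clonotype_key", "patient", "sample", "lineage",
            "n_eye", "n_blood", "N_eye", "N_blood",
            "f_eye", "f_blood", "lfr", "size_class", "antigen_activated",
        ],
    )


def antigen_activated_fraction(
    enrichments: pd.DataFrame,
    sample: str,
    lineage_scope: str | list[str] | None = None,
    min_cells: int = 50,
) -> dict:
    """Antigen-activated cells as a percentage of eye T cells in a sample.

    Numerator: eye cells belonging to antigen-activated clonotypes;
    denominator: eye T cells with TCR data in ``lineage_scope`` (a single
    lineage, a list, or None for all).  Samples whose denominator falls
    below ``min_cells`` are flagged excluded rather than reported.
    """
    sub = enrichments[enrichments["sample"] == sample]
    if lineage_scope is not None:
        scopes = [lineage_scope] if isinstance(lineage_scope, str) else lineage_scope
        sub = sub[sub["lineage"].isin(scopes)]
    denom = int(sub["n_eye"].sum())
    numer = int(sub.loc[sub["antigen_activated"], "n_eye"].sum())
    if denom == 0:
        return {"sample": sample, "percent": float("nan"), "n_cells": 0,
                "n_activated": 0, "excluded": True}
    return {
        "sample": sample,
        "percent": 100.0 * numer / denom,
        "n_cells": denom,
        "n_activated": numer,
        "excluded": denom < min_cells,
    }


def enrichment_bins(
    enrichments: pd.DataFrame, bin_width: float = 0.5
) -> pd.DataFrame:
    """Histogram of LFR values per size class (closed-left, half-open bins).

    Returns a long table with columns ``size_class``, ``bin_left``,
    ``bin_right``, ``count``; bin edges are integer multiples of
    ``bin_width``.
    """
    lfr = enrichments["lfr"].to_numpy()
    if not np.all(np.isfinite(lfr)):
        raise ValueError("LFR values must be finite")
    lo = math.floor(lfr.min() / bin_width) * bin_width
    # every value lands in a closed-left half-open bin, including edge values
    n_bins = int(math.floor((lfr.max() - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    rows = []
    for sc, grp in enrichments.groupby("size_class"):
        vals = grp["lfr"].to_numpy()
        # np.histogram's last bin is closed on the right; widen it so the
        # closed-left half-open convention holds for the max value too.
        counts, _ = np.histogram(vals, bins=np.append(edges[:-1], edges[-1] + 1e-9))
        for left, right, cnt in zip(edges[:-1], edges[1:], counts):
            rows.append(
                {"size_class": sc, "bin_left": left, "bin_right": right,
                 "count": int(cnt)}
            )
    return pd.DataFrame(rows)
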