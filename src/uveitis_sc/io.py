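"""Readers and writers for the pipeline's on-disk formats.

Expression data travel as 10x-style MatrixMarket triplets (matrix.mtx +
barcodes.tsv + features.tsv per sample) and are held in memory as an
:class:`anndata.AnnData` (cells x genes, sparse integer counts, per-cell
metadata in ``.obs``).  V(D)J contigs use the 10x
``filtered_contig_annotations.csv`` dialect.  Clonotype identity is
patient-scoped: 10x clonotype ids are per-sample, so clonotypes are
keyed by the sorted set of (chain, CDR3) pairs, nucleotide sequence by
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

VDJ_REQUIRED_COLUMNS = ("barcode", "chain", "cdr3", "cdr3_nt")
VALID_CHAINS = ("TRA", "TRB", "TRG", "TRD", "IGH", "IGK", "IGL")


class FormatError(ValueError):
    """Malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# expression matrices


def write_expression(adata: ad.AnnData, outdir: str | Path) -> None:
    """Write an expression matrix as matrix.mtx + barcodes.tsv + features.tsv.

    The matrix is stored genes x cells as in CellRanger output; per-cell
    metadata columns go to ``cell_meta.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sp.csr_matrix(adata.X)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X.T.astype(int))
    pd.Series(adata.obs_names).to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.var_names).to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False
    )
    if adata.obs.shape[1]:
        adata.obs.to_csv(outdir / "cell_meta.tsv", sep="\t")


def read_expression(indir: str | Path) -> ad.AnnData:
    """Read a matrix.mtx / barcodes.tsv / features.tsv triplet.

    Round-trips :func:`write_expression` bit-exactly on integer counts.
    Raises :class:`FormatError` on missing files, dimension mismatches or
    negative entries.
    """
    indir = Path(indir)
    for name in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
        if not (indir / name).exists():
            raise FormatError(f"missing {name} in {indir}")
    M = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx"))).T
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
    if M.shape[0] != len(barcodes) or M.shape[1] != len(features):
        raise FormatError(
            f"matrix shape {M.shape} does not match "
            f"{len(barcodes)} barcodes x {len(features)} features"
        )
    if M.data.size and M.data.min() < 0:
        raise FormatError("count matrix contains negative entries")
    if barcodes.duplicated().any():
        raise FormatError("duplicate barcodes within sample")
    adata = ad.AnnData(
        X=M.astype(np.int64),
        obs=pd.DataFrame(index=pd.Index(barcodes.astype(str)).rename(None)),
        var=pd.DataFrame(index=pd.Index(features.astype(str)).rename(None)),
    )
    meta_path = indir / "cell_meta.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta.index = meta.index.astype(str)
        adata.obs = meta.loc[adata.obs_names]
    return adata


# ---------------------------------------------------------------------------
# V(D)J contigs


@dataclass
class VdjReadReport:
    n_rows: int = 0
    n_dropped_empty_cdr3: int = 0
    n_dropped_duplicates: int = 0
    warnings: list = field(default_factory=list)


def read_vdj(path: str | Path) -> tuple[pd.DataFrame, VdjReadReport]:
    """Read a 10x ``filtered_contig_annotations.csv``-style contig table.

    Rows with an empty CDR3 are dropped and counted.  Duplicate
    (barcode, chain) rows are resolved deterministically: highest
    ``umis`` wins, ties broken by lexicographically smallest ``cdr3_nt``.
    """
    df = pd.read_csv(path, dtype=str)
    report = VdjReadReport(n_rows=len(df))
    missing = [c for c in VDJ_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"contig file missing required columns: {missing}")
    if len(df) == 0:
        return df, report

    empty = df["cdr3"].isna() | (df["cdr3"].str.strip() == "") | (df["cdr3"] == "None")
    report.n_dropped_empty_cdr3 = int(empty.sum())
    df = df[~empty].copy()

    bad_chain = ~df["chain"].isin(VALID_CHAINS)
    if bad_chain.any():
        report.warnings.append(
            f"{int(bad_chain.sum())} contigs with unrecognized chain kept as-is"
        )

    if "umis" in df.columns:
        df["_umis"] = pd.to_numeric(df["umis"], errors="coerce").fillna(0)
    else:
        df["_umis"] = 0
    df = df.sort_values(
        ["barcode", "chain", "_umis", "cdr3_nt"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    before = len(df)
    df = df.drop_duplicates(subset=["barcode", "chain"], keep="first")
    report.n_dropped_duplicates = before - len(df)
    return df.drop(columns="_umis").reset_index(drop=True), report


def normalize_barcode(barcode: str) -> str:
    """Strip a 10x GEM-well suffix such as ``-1`` from a barcode."""
    if "-" in barcode:
        stem, _, suffix = barcode.rpartition("-")
        if suffix.isdigit():
            return stem
    return barcode


def clonotype_key(contigs: pd.DataFrame, use_nt: bool = True) -> str:
    """Patient-scoped clonotype key: sorted (chain, CDR3) pairs joined.

    Nucleotide CDR3s by default (the stricter identity); amino-acid
    keying by ``use_nt=False``.
    """
    col = "cdr3_nt" if use_nt else "cdr3"
    pairs = sorted(zip(contigs["chain"], contigs[col]))
    return "|".join(f"{chain}:{seq}" for chain, seq in pairs)


@dataclass
class MatchReport:
    n_cells: int = 0
    n_matched: int = 0
    n_no_data: int = 0
    n_contig_barcodes_unmatched: int = 0

    @property
    def fraction_matched(self) -> float:
        return self.n_matched / self.n_cells if self.n_cells else 0.0


def match_vdj_to_cells(
    adata: ad.AnnData,
    contigs: pd.DataFrame,
    use_nt: bool = True,
) -> tuple[pd.Series, MatchReport]:
    """Assign each cell a clonotype key, or null for "no data".

    Barcodes are suffix-normalized on both sides before joining.  Contig
    barcodes absent from the matrix are ignored and counted.  Returns a
    per-cell Series indexed like ``adata.obs_names`` (NaN = no TCR data)
    and a match report.
    """
    report = MatchReport(n_cells=adata.n_obs)
    cell_index = {normalize_barcode(bc): bc for bc in adata.obs_names}
    keys = pd.Series(pd.NA, index=adata.obs_names, dtype=object, name="clonotype_key")
    if len(contigs):
        grouped = contigs.groupby(contigs["barcode"].map(normalize_barcode))
        for bc, grp in grouped:
            if bc not in cell_index:
                report.n_contig_barcodes_unmatched += 1
                continue
            keys.loc[cell_index[bc]] = clonotype_key(grp, use_nt=use_nt)
    report.n_matched = int(keys.notna().sum())
    report.n_no_data = report.n_cells - report.n_matched
    return keys, report


# ---------------------------------------------------------------------------
# sample metadata


SAMPLE_META_REQUIRED = ("sample", "patient", "compartment")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-sample clinical metadata TSV and validate basics."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_META_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"sample metadata missing columns: {missing}")
    if df["sample"].duplicated().any():
        raise FormatError("duplicate sample ids in metadata")
    bad = ~df["compartment"].isin(["eye", "blood"])
    if bad.any():
        raise FormatError("compartment must be 'eye' or 'blood'")
    return df


def validate_cohort(
    expr_by_sample: dict[str, ad.AnnData], metadata: pd.DataFrame
) -> list[str]:
    """Cross-check matrices against metadata; returns a list of problems."""
    problems = []
    meta_samples = set(metadata["sample"])
    for s in expr_by_sample:
        if s not in meta_samples:
            problems.append(f"sample {s} has a matrix but no metadata row")
    for s in meta_samples - set(expr_by_sample):
        problems.append(f"sample {s} in metadata but no matrix found")
    return problems
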