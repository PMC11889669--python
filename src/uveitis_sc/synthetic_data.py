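"""Synthetic paired eye/blood single-cell cohorts with planted ground truth.

Each simulated patient contributes one aqueous-humor ("eye") and one
peripheral-blood sample.  Cells carry a true cell type (CD4 T, CD8 T,
B, myeloid, NK) drawn from a subtype-specific Dirichlet composition;
counts follow a negative-binomial model with lineage markers elevated
in their own lineage, and a mitochondrial fraction drawn per cell from
a Beta distribution is attached as metadata and realized as counts on
designated MT- genes.  T (and B) cells belong to clonotypes: the
background repertoire is a truncated discrete power law shared between
compartments (so background clones have similar eye and blood
frequencies), a configurable number of *antigen-driven* clonotypes per
eye sample are planted with eye frequency exceeding blood frequency by
a configurable factor, and their cells receive a mean shift on a
designated TCR-signaling gene program.  A fraction of clonotypes is
peripherally pre-expanded (large in blood, not eye-enriched),
reproducing the two clouds of an eye-vs-blood clonotype frequency
plot.  Cross-lineage doublets are injected by summing two cell
profiles.

The generator is fully deterministic given its seed, and every planted
property is recorded in a :class:`GroundTruth` object so downstream
stages (QC, multiplet flagging, enrichment, program scoring,
compositional PCA, CNA) can be validated against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from uveitis_sc import io as uio
from uveitis_sc.repertoire import aggregate_clonotypes

CELL_TYPES = ("CD4_T", "CD8_T", "gdT", "B", "myeloid", "NK")
LINEAGE_GROUP = {
    "CD4_T": "T", "CD8_T": "T", "gdT": "T", "B": "B",
    "myeloid": "myeloid", "NK": "NK",
}
CANONICAL_MARKERS = {"T": "CD3D", "B": "CD79A", "myeloid": "LYZ", "NK": "NCR1"}
MT_GENES = ("MT-ND1", "MT-CO1", "MT-CO2", "MT-CYB", "MT-ATP6")

# Eye compositions per clinical subtype: an adaptive-skewed profile
# (granulomatous chronic disease), an effector-T profile, and an
# innate/myeloid-skewed profile (HLA-B27 AAU-like).  T fractions sit in
# the 35-90% range seen in real ocular infiltrates.
DEFAULT_SUBTYPE_COMPOSITION = {
    "adaptive": {"CD4_T": 0.43, "CD8_T": 0.17, "gdT": 0.03, "B": 0.15,
                 "myeloid": 0.12, "NK": 0.10},
    "effector": {"CD4_T": 0.37, "CD8_T": 0.23, "gdT": 0.05, "B": 0.05,
                 "myeloid": 0.15, "NK": 0.15},
    "innate": {"CD4_T": 0.23, "CD8_T": 0.09, "gdT": 0.05, "B": 0.05,
               "myeloid": 0.43, "NK": 0.15},
}
BLOOD_COMPOSITION = {"CD4_T": 0.28, "CD8_T": 0.19, "gdT": 0.04, "B": 0.15,
                     "myeloid": 0.24, "NK": 0.10}

# Fine-grained cell states nested inside each coarse type: 19 states, the
# granularity at which sample compositions enter the 26-feature PCA
# (19 state proportions + CD4/CD8/B Gini + 4 clinical covariates).
FINE_STATES = {
    "CD4_T": {"CD4_resting": 0.35, "CD4_effector": 0.40,
              "CD4_cytotoxic": 0.10, "Treg": 0.15},
    "CD8_T": {"CD8_resting": 0.35, "CD8_effector": 0.50, "CD8_cytotoxic": 0.15},
    "gdT": {"gdT_resting": 0.40, "gdT_effector": 0.40, "MAIT": 0.20},
    "B": {"B_naive": 0.80, "plasmablast": 0.20},
    "myeloid": {"macrophage": 0.55, "DC1": 0.10, "DC2": 0.15,
                "pDC": 0.10, "CCR7_DC": 0.10},
    "NK": {"NK_cytotoxic": 0.60, "NK_chemokine": 0.40},
}


class SizingError(ValueError):
    """Planted clone cells exceed the compartment's cell budget."""


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults describe a 12-patient paired cohort with 2,000 eye and
    4,000 blood cells per patient, 20 planted antigen-driven clones per
    eye sample (8-40 cells each, eye/blood frequency ratio >= 4 before
    sampling noise), a power-law background repertoire shared between
    compartments, 5% cross-lineage doublets, and a TCR-signaling
    program shifted by one natural-log unit in antigen-driven cells.
    """

    n_patients: int = 12
    cells_per_eye_sample: int = 2000
    cells_per_blood_sample: int = 4000
    subtype_labels: tuple = ("adaptive", "effector", "innate")
    subtype_composition: dict | None = None
    composition_concentration: float = 150.0
    n_antigen_clones: int = 20
    antigen_clone_size_range: tuple = (8, 40)
    antigen_eye_blood_ratio: float = 4.0
    peripheral_clone_rate: float = 0.02
    blood_overlap_prob: float = 1.0
    clone_size_tail: float = 2.5
    clone_size_max: int = 30
    program_effect: float = 1.0
    doublet_rate: float = 0.05
    mito_beta_params: tuple = (2.0, 30.0)
    n_genes: int = 1000
    markers_per_lineage: int = 5
    n_program_genes: int = 30
    marker_fold: float = 8.0
    nb_dispersion: float = 10.0
    target_library_size: float = 2000.0
    tcr_capture_rate: float = 0.85
    seed: int = 0

    def __post_init__(self):
        if self.subtype_composition is None:
            self.subtype_composition = {
                s: DEFAULT_SUBTYPE_COMPOSITION[s]
                for s in self.subtype_labels
                if s in DEFAULT_SUBTYPE_COMPOSITION
            }
        for s, props in self.subtype_composition.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"composition of subtype {s!r} sums to {total}")
        for name in ("n_patients", "cells_per_eye_sample", "cells_per_blood_sample",
                     "n_genes", "markers_per_lineage"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.doublet_rate < 0.5):
            raise ValueError("doublet_rate must be in [0, 0.5)")
        lo, hi = self.antigen_clone_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid antigen_clone_size_range")
        if self.clone_size_tail <= 1:
            raise ValueError("clone_size_tail must be > 1")
        a, b = self.mito_beta_params
        if a <= 0 or b <= 0:
            raise ValueError("mito_beta_params must be positive")


@dataclass
class GroundTruth:
    """Planted truth for every cell, clonotype and sample."""

    cells: pd.DataFrame  # barcode, sample, patient, compartment, cell_type, is_doublet, program
    clonotypes: pd.DataFrame  # clonotype_key, patient, lineage, antigen_driven, peripheral_expanded
    samples: pd.DataFrame  # sample, subtype


@dataclass
class Cohort:
    adata: ad.AnnData
    clonotypes: pd.DataFrame
    contigs: pd.DataFrame
    metadata: pd.DataFrame
    ground_truth: GroundTruth
    config: CohortConfig


# ---------------------------------------------------------------------------
# deterministic CDR3 tokens


_CHAIN_CODE = {"TRA": 0, "TRB": 1, "IGH": 2, "IGK": 3}


def _cdr3_nt(patient_num: int, clone_idx: int, chain: str) -> str:
    """Unique CDR3 nucleotide token, deterministic, length divisible by 3.

    Encodes (patient, clonotype, chain) in base 4 over ACGT; eye and
    blood cells of one patient's clonotype therefore share CDR3s, while
    clonotypes never collide across patients.
    """
    ident = (patient_num * 1_000_000 + clone_idx) * 4 + _CHAIN_CODE[chain]
    digits = []
    for _ in range(15):
        digits.append("ACGT"[ident % 4])
        ident //= 4
    return "TGT" + "".join(digits)


def _cdr3_aa(nt: str) -> str:
    table = {"A": "A", "C": "S", "G": "G", "T": "L"}
    return "C" + "".join(table[c] for c in nt[3::3]) + "F"


def _chains_for(lineage: str) -> tuple[str, str]:
    return ("TRA", "TRB") if lineage in ("CD4", "CD8") else ("IGH", "IGK")


def _clone_key(patient_num: int, clone_idx: int, lineage: str) -> str:
    pairs = sorted(
        (chain, _cdr3_nt(patient_num, clone_idx, chain))
        for chain in _chains_for(lineage)
    )
    return "|".join(f"{c}:{s}" for c, s in pairs)


# ---------------------------------------------------------------------------
# repertoire construction


@dataclass
class _CloneSpec:
    key_idx: int
    lineage: str  # CD4 / CD8 / B
    eye_count: int
    blood_count: int
    antigen: bool = False
    peripheral: bool = False


def _power_law_weights(rng, n: int, alpha: float, s_max: int) -> np.ndarray:
    support = np.arange(1, s_max + 1)
    probs = support.astype(float) ** (-alpha)
    probs /= probs.sum()
    return rng.choice(support, size=n, p=probs).astype(float)


def _planted_clones(
    rng, config: CohortConfig, start_idx: int, lineage: str,
    n_eye_lin: int, n_blood_lin: int, n_clones: int,
) -> list[_CloneSpec]:
    """Antigen-driven clones: eye frequency >= ratio x blood frequency.

    Sizes are uniform over ``antigen_clone_size_range``; draws whose
    total exceeds 90% of the lineage's eye cells are rejected and
    redrawn (truncation of the joint size distribution), so planted
    clones always leave room for a background repertoire.
    """
    if n_clones == 0:
        return []
    lo, hi = config.antigen_clone_size_range
    budget = 0.9 * n_eye_lin
    if n_clones * lo > budget:
        raise SizingError(
            f"{n_clones} planted {lineage} clones of >= {lo} cells cannot fit "
            f"in {n_eye_lin} eye {lineage} T cells"
        )
    for _ in range(200):
        sizes = rng.integers(lo, hi + 1, size=n_clones)
        if sizes.sum() <= budget:
            break
    else:
        raise SizingError(
            f"planted {lineage} clones do not fit in {n_eye_lin} eye cells"
        )
    ratio = config.antigen_eye_blood_ratio
    specs = []
    for j, s in enumerate(sizes):
        r = rng.uniform(ratio, 2 * ratio)
        b = int(np.floor((s / n_eye_lin) / r * n_blood_lin))
        specs.append(
            _CloneSpec(
                key_idx=start_idx + j,
                lineage=lineage,
                eye_count=int(s),
                blood_count=b,
                antigen=True,
            )
        )
    return specs


def _background_clones(
    rng, config: CohortConfig, start_idx: int, n_slots: int, lineage: str,
    n_bg_eye: int, n_bg_blood: int,
) -> list[_CloneSpec]:
    """Shared-repertoire background clones for one lineage of one patient.

    A patient-level clonotype weight vector (truncated power law)
    drives multinomial sampling of both compartments, so background
    clones have similar eye and blood frequencies (apparent absence
    from blood emerges from sampling, as for rare recirculating
    clones).  Each clonotype is present in blood with probability
    ``blood_overlap_prob``, and a ``peripheral_clone_rate`` fraction of
    CD8 clonotypes is boosted in blood only — pre-expanded peripheral
    clones, which in real cohorts are essentially confined to memory
    CD8 T cells.
    """
    K = n_slots
    w = _power_law_weights(rng, K, config.clone_size_tail, config.clone_size_max)
    overlap = rng.random(K) < config.blood_overlap_prob
    peripheral_rate = config.peripheral_clone_rate if lineage == "CD8" else 0.0
    peripheral = rng.random(K) < peripheral_rate
    boost = rng.uniform(10.0, 30.0, size=K)
    w_blood = w * np.where(overlap | peripheral, 1.0, 0.0)
    w_blood = np.where(peripheral, w_blood * boost, w_blood)

    eye_counts = (
        rng.multinomial(n_bg_eye, w / w.sum()) if n_bg_eye > 0 else np.zeros(K, int)
    )
    blood_counts = (
        rng.multinomial(n_bg_blood, w_blood / w_blood.sum())
        if n_bg_blood > 0 and w_blood.sum() > 0
        else np.zeros(K, int)
    )
    specs = []
    for j in range(K):
        if eye_counts[j] == 0 and blood_counts[j] == 0:
            continue
        specs.append(
            _CloneSpec(
                key_idx=start_idx + j,
                lineage=lineage,
                eye_count=int(eye_counts[j]),
                blood_count=int(blood_counts[j]),
                peripheral=bool(peripheral[j]),
            )
        )
    return specs


def _patient_repertoire(
    rng, config: CohortConfig, n_by_type: dict
) -> list[_CloneSpec]:
    """All clonotypes of one patient: planted + background T, background B.

    Planted clones are split between CD4 and CD8 proportionally to the
    eye T-cell composition, so myeloid-skewed subtypes with few CD8
    cells are not overloaded.
    """
    n_cd4_eye = int(n_by_type["eye"]["CD4_T"])
    n_cd8_eye = int(n_by_type["eye"]["CD8_T"])
    total_t = max(n_cd4_eye + n_cd8_eye, 1)
    n_cd4_planted = int(round(config.n_antigen_clones * n_cd4_eye / total_t))
    n_cd8_planted = config.n_antigen_clones - n_cd4_planted

    specs: list[_CloneSpec] = []
    idx = 0
    for lin, ct, n_planted in (
        ("CD4", "CD4_T", n_cd4_planted),
        ("CD8", "CD8_T", n_cd8_planted),
    ):
        n_eye_lin = int(n_by_type["eye"][ct])
        n_blood_lin = int(n_by_type["blood"][ct])
        planted = _planted_clones(
            rng, config, idx, lin, n_eye_lin, n_blood_lin, n_planted
        )
        idx += n_planted
        eye_planted = sum(s.eye_count for s in planted)
        blood_planted = sum(s.blood_count for s in planted)
        n_slots = max(n_eye_lin - eye_planted, 20)
        bg = _background_clones(
            rng, config, idx, n_slots, lin,
            n_eye_lin - eye_planted, n_blood_lin - blood_planted,
        )
        idx += n_slots
        specs.extend(planted + bg)

    n_b_eye = int(n_by_type["eye"]["B"])
    n_b_blood = int(n_by_type["blood"]["B"])
    n_slots = max(n_b_eye, 20)
    specs.extend(
        _background_clones(rng, config, idx, n_slots, "B", n_b_eye, n_b_blood)
    )
    return specs


# ---------------------------------------------------------------------------
# gene panel and expression model


def _gene_names(config: CohortConfig) -> tuple[list, dict, list]:
    markers: dict[str, list[str]] = {}
    names: list[str] = []
    for lin, canonical in CANONICAL_MARKERS.items():
        lin_markers = [canonical] + [
            f"{lin.upper()}M{i}" for i in range(2, config.markers_per_lineage + 1)
        ]
        markers[lin] = lin_markers
        names.extend(lin_markers)
    program = [f"TCRSIG{i + 1}" for i in range(config.n_program_genes)]
    names.extend(program)
    names.extend(MT_GENES)
    n_bg = config.n_genes - len(names)
    if n_bg < 0:
        raise ValueError("n_genes too small for the marker/program/MT panel")
    names.extend(f"GENE{i:04d}" for i in range(n_bg))
    return names, markers, program


def program_gene_set(config: CohortConfig | None = None):
    """The planted TCR-signaling program as a GeneSet."""
    from uveitis_sc.signatures import GeneSet

    config = config or CohortConfig()
    return GeneSet(
        name="TCR_PROGRAM",
        genes=tuple(f"TCRSIG{i + 1}" for i in range(config.n_program_genes)),
    )


# ---------------------------------------------------------------------------
# main generator


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a paired eye/blood cohort with planted ground truth.

    Returns a :class:`Cohort` bundling the expression matrix (AnnData,
    cells x genes sparse counts with sample / patient / compartment /
    mito_fraction metadata), a clonotype table aggregated from the
    emitted contigs, the 10x-dialect contig table, per-sample clinical
    metadata, the ground truth, and the config.  Identical configs and
    seeds give identical cohorts.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    gene_names, markers, program_genes = _gene_names(config)
    gene_index = pd.Index(gene_names)
    n_genes = len(gene_names)
    mt_cols = gene_index.get_indexer(MT_GENES)
    program_cols = gene_index.get_indexer(program_genes)

    base = rng.lognormal(mean=0.0, sigma=0.8, size=n_genes)
    base[mt_cols] = 0.0  # MT counts are added from the drawn mito fraction
    base = base / base.sum() * config.target_library_size

    type_means = {}
    for ct in CELL_TYPES:
        mu = base.copy()
        own = LINEAGE_GROUP[ct]
        for lin, lin_markers in markers.items():
            cols = gene_index.get_indexer(lin_markers)
            mu[cols] = base[cols] * (config.marker_fold if lin == own else 0.25)
        type_means[ct] = mu

    subtypes = list(config.subtype_composition)
    theta = config.nb_dispersion
    lineage_to_type = {"CD4": "CD4_T", "CD8": "CD8_T", "B": "B"}

    X_blocks, obs_blocks, gt_cell_blocks = [], [], []
    gt_clonotype_rows, gt_sample_rows = [], []
    contig_frames, meta_rows = [], []

    for p in range(config.n_patients):
        patient = f"P{p:02d}"
        subtype = subtypes[p % len(subtypes)]
        props_mean = np.array(
            [config.subtype_composition[subtype][ct] for ct in CELL_TYPES]
        )
        eye_props = rng.dirichlet(props_mean * config.composition_concentration)
        blood_props = rng.dirichlet(
            np.array([BLOOD_COMPOSITION[ct] for ct in CELL_TYPES])
            * config.composition_concentration
        )
        gt_sample_rows.append({"sample": f"{patient}E", "subtype": subtype})
        gt_sample_rows.append({"sample": f"{patient}B", "subtype": subtype})

        n_by_type = {
            "eye": dict(zip(
                CELL_TYPES, rng.multinomial(config.cells_per_eye_sample, eye_props)
            )),
            "blood": dict(zip(
                CELL_TYPES, rng.multinomial(config.cells_per_blood_sample, blood_props)
            )),
        }

        clone_specs = _patient_repertoire(rng, config, n_by_type)
        for spec in clone_specs:
            gt_clonotype_rows.append(
                {
                    "clonotype_key": _clone_key(p, spec.key_idx, spec.lineage),
                    "patient": patient,
                    "lineage": spec.lineage,
                    "antigen_driven": spec.antigen,
                    "peripheral_expanded": spec.peripheral,
                }
            )

        for compartment in ("eye", "blood"):
            sample = f"{patient}{'E' if compartment == 'eye' else 'B'}"
            counts_by_type = n_by_type[compartment]
            n_cells = int(sum(counts_by_type.values()))
            cell_types = np.repeat(
                list(CELL_TYPES), [counts_by_type[ct] for ct in CELL_TYPES]
            )
            barcodes = np.array([f"{sample}:C{i:05d}" for i in range(n_cells)])

            # fine-grained state within each coarse type (annotation depth
            # used for the sample composition features; no separate
            # expression program)
            fine_types = np.empty(n_cells, dtype=object)
            for ct in CELL_TYPES:
                rows = np.flatnonzero(cell_types == ct)
                states = list(FINE_STATES[ct])
                split = rng.dirichlet(
                    np.array(list(FINE_STATES[ct].values())) * 50.0
                )
                fine_types[rows] = rng.choice(states, size=len(rows), p=split)

            # clonotype membership for T and B cells
            clone_of_cell = np.full(n_cells, -1, dtype=int)  # index into clone_specs
            for lin, ct in lineage_to_type.items():
                members = [
                    (si, s.eye_count if compartment == "eye" else s.blood_count)
                    for si, s in enumerate(clone_specs)
                    if s.lineage == lin
                ]
                pool = np.repeat(
                    [si for si, _ in members], [c for _, c in members]
                )
                rng.shuffle(pool)
                slots = np.flatnonzero(cell_types == ct)
                n_assign = min(len(pool), len(slots))
                clone_of_cell[slots[:n_assign]] = pool[:n_assign]
            antigen_spec = np.array([s.antigen for s in clone_specs])
            program_cell = np.zeros(n_cells, dtype=bool)
            has_clone = clone_of_cell >= 0
            program_cell[has_clone] = antigen_spec[clone_of_cell[has_clone]]

            # doublets: injected among cells outside planted clones so the
            # planted frequencies stay exact
            n_doublets = int(round(config.doublet_rate * n_cells))
            eligible = np.flatnonzero(~program_cell)
            doublet_idx = (
                rng.choice(eligible, size=n_doublets, replace=False)
                if n_doublets > 0
                else np.array([], dtype=int)
            )
            is_doublet = np.zeros(n_cells, dtype=bool)
            is_doublet[doublet_idx] = True
            clone_of_cell[doublet_idx] = -1  # doublets carry no V(D)J data

            # expression: gamma-poisson around the cell-type mean
            M = np.empty((n_cells, n_genes))
            for ct in CELL_TYPES:
                M[cell_types == ct] = type_means[ct]
            if config.program_effect != 0:
                M[np.ix_(program_cell, program_cols)] *= np.exp(config.program_effect)
            X = rng.poisson(rng.gamma(theta, M / theta)).astype(np.int64)

            if n_doublets:
                partner_types = []
                for i in doublet_idx:
                    own_group = LINEAGE_GROUP[cell_types[i]]
                    others = [c for c in CELL_TYPES if LINEAGE_GROUP[c] != own_group]
                    weights = np.array(
                        [counts_by_type[c] for c in others], dtype=float
                    )
                    p_choice = weights / weights.sum() if weights.sum() else None
                    partner_types.append(rng.choice(others, p=p_choice))
                Mp = np.stack([type_means[ct] for ct in partner_types])
                X[doublet_idx] += rng.poisson(rng.gamma(theta, Mp / theta)).astype(
                    np.int64
                )

            # mitochondrial counts proportional to the drawn fraction
            a, b = config.mito_beta_params
            mito_frac = rng.beta(a, b, size=n_cells)
            non_mt_total = X.sum(axis=1)
            mt_total = np.round(non_mt_total * mito_frac / (1 - mito_frac)).astype(
                np.int64
            )
            X[:, mt_cols] = rng.multinomial(
                mt_total, np.full(len(MT_GENES), 1 / len(MT_GENES))
            )

            X_blocks.append(sp.csr_matrix(X))
            obs_blocks.append(
                pd.DataFrame(
                    {
                        "sample": sample,
                        "patient": patient,
                        "compartment": compartment,
                        "mito_fraction": mito_frac,
                    },
                    index=barcodes,
                )
            )
            gt_cell_blocks.append(
                pd.DataFrame(
                    {
                        "barcode": barcodes,
                        "sample": sample,
                        "patient": patient,
                        "compartment": compartment,
                        "cell_type": cell_types,
                        "fine_type": fine_types,
                        "is_doublet": is_doublet,
                        "program": program_cell,
                    }
                )
            )

            # contigs, thinned by the capture rate
            captured = rng.random(n_cells) < config.tcr_capture_rate
            rows = np.flatnonzero(has_clone & ~is_doublet & captured)
            if len(rows):
                recs = []
                local_ids: dict[int, int] = {}
                for i in rows:
                    spec = clone_specs[clone_of_cell[i]]
                    local = local_ids.setdefault(spec.key_idx, len(local_ids) + 1)
                    for chain in _chains_for(spec.lineage):
                        nt = _cdr3_nt(p, spec.key_idx, chain)
                        recs.append(
                            (
                                f"{barcodes[i]}-1", chain, _cdr3_aa(nt), nt,
                                100, 4, f"clonotype{local}", sample,
                            )
                        )
                contig_frames.append(
                    pd.DataFrame(
                        recs,
                        columns=["barcode", "chain", "cdr3", "cdr3_nt", "reads",
                                 "umis", "raw_clonotype_id", "sample"],
                    )
                )

        # clinical metadata, loosely linked to subtype
        age = float(
            np.clip(rng.normal(46, 14) + (8 if subtype == "adaptive" else 0), 18, 85)
        )
        duration = float(rng.exponential(300 if subtype != "innate" else 60))
        severity = int(rng.integers(1, 5))
        steroid = bool(rng.random() < 0.68)
        # the innate/myeloid-skewed subtype models HLA-B27 AAU
        hla_b27 = subtype == "innate"
        for compartment in ("eye", "blood"):
            meta_rows.append(
                {
                    "sample": f"{patient}{'E' if compartment == 'eye' else 'B'}",
                    "patient": patient,
                    "compartment": compartment,
                    "diagnosis": subtype,
                    "granulomatous_kp": subtype == "adaptive",
                    "anatomic": "AU" if rng.random() < 0.8 else "PU",
                    "age": round(age, 1),
                    "duration": round(duration, 1),
                    "severity": severity,
                    "steroid_use": int(steroid),
                    "hla_b27": hla_b27,
                }
            )

    adata = ad.AnnData(
        X=sp.vstack(X_blocks).tocsr(),
        obs=pd.concat(obs_blocks),
        var=pd.DataFrame(index=gene_index),
    )
    contigs = (
        pd.concat(contig_frames, ignore_index=True)
        if contig_frames
        else pd.DataFrame(
            columns=["barcode", "chain", "cdr3", "cdr3_nt", "reads", "umis",
                     "raw_clonotype_id", "sample"]
        )
    )
    gt = GroundTruth(
        cells=pd.concat(gt_cell_blocks, ignore_index=True),
        clonotypes=pd.DataFrame(gt_clonotype_rows),
        samples=pd.DataFrame(gt_sample_rows),
    )
    clonotypes = _clonotype_table_from_contigs(contigs, gt.cells)
    return Cohort(
        adata=adata,
        clonotypes=clonotypes,
        contigs=contigs,
        metadata=pd.DataFrame(meta_rows),
        ground_truth=gt,
        config=config,
    )


def _clonotype_table_from_contigs(
    contigs: pd.DataFrame, gt_cells: pd.DataFrame
) -> pd.DataFrame:
    """Aggregate the emitted contigs into a clonotype table.

    Mirrors what the io + repertoire stages recover from the serialized
    files, so planted clone frequencies are measured on the captured
    repertoire.
    """
    cols = ["clonotype_key", "sample", "patient", "compartment", "lineage",
            "size", "barcodes"]
    if contigs.empty:
        return pd.DataFrame(columns=cols)
    df = contigs.copy()
    df["barcode"] = df["barcode"].map(uio.normalize_barcode)
    df["pair"] = df["chain"] + ":" + df["cdr3_nt"]
    df = df.sort_values(["sample", "barcode", "pair"], kind="mergesort")
    keys = (
        df.groupby(["sample", "barcode"], sort=False)["pair"]
        .agg("|".join)
        .rename("clonotype_key")
        .reset_index()
    )
    info = gt_cells.set_index("barcode")
    lineage_of_type = {"CD4_T": "CD4", "CD8_T": "CD8", "B": "B"}
    keys["patient"] = info["patient"].reindex(keys["barcode"]).to_numpy()
    keys["compartment"] = info["compartment"].reindex(keys["barcode"]).to_numpy()
    keys["lineage"] = (
        info["cell_type"].reindex(keys["barcode"]).map(lineage_of_type).to_numpy()
    )
    return aggregate_clonotypes(keys)


def emulate_null_feature_matrix(
    n_samples: int, n_features: int, seed: int = 0
) -> pd.DataFrame:
    """I.i.d. standard-normal samples x features matrix (Monte Carlo null)."""
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.standard_normal((n_samples, n_features)),
        index=[f"S{i:03d}" for i in range(n_samples)],
        columns=[f"F{j:02d}" for j in range(n_features)],
    )


# ---------------------------------------------------------------------------
# serialization


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Serialize a cohort to the pipeline's external formats.

    Per-sample MTX triplets under ``<sample>/``, contigs as 10x-dialect
    ``filtered_contig_annotations.csv`` per sample, metadata and ground
    truth as TSV, config as YAML.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sample in cohort.adata.obs["sample"].unique():
        mask = (cohort.adata.obs["sample"] == sample).to_numpy()
        uio.write_expression(cohort.adata[mask], outdir / str(sample))
        sub_contigs = cohort.contigs[cohort.contigs["sample"] == sample]
        sub_contigs.drop(columns="sample").to_csv(
            outdir / str(sample) / "filtered_contig_annotations.csv", index=False
        )
    cohort.metadata.to_csv(outdir / "sample_metadata.tsv", sep="\t", index=False)
    cohort.ground_truth.cells.to_csv(
        outdir / "ground_truth_cells.tsv", sep="\t", index=False
    )
    cohort.ground_truth.clonotypes.to_csv(
        outdir / "ground_truth_clonotypes.tsv", sep="\t", index=False
    )
    cohort.ground_truth.samples.to_csv(
        outdir / "ground_truth_samples.tsv", sep="\t", index=False
    )
    cfg = asdict(cohort.config)
    for key, val in cfg.items():
        if isinstance(val, tuple):
            cfg[key] = list(val)
    with open(outdir / "cohort_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
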