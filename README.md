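# uveitis-sc

Analysis pipeline for paired eye/blood single-cell RNA + V(D)J profiling
of intraocular inflammation, built for studies that biopsy aqueous humor
from uveitis patients alongside matched peripheral blood. It is aimed at
computational immunologists who want the repertoire and compositional
statistics of such studies as tested, reusable functions rather than
one-off notebook code.

## What it computes

**Clonality.** T/B cells sharing identical CDR3 sequences form a
clonotype of size *s* (singleton *s*=1, small 2–9, medium 10–19, large
≥20; B cells use singleton / small / large ≥10). Within-sample
inequality of clonotype sizes is summarised by the discrete Gini
coefficient over ascending-ordered counts *y₍ᵢ₎*:

    G = Σᵢ (2i − n − 1) y₍ᵢ₎ / (n Σᵢ y₍ᵢ₎),   G ∈ [0, 1)

together with the fraction of cells in expanded (*s* ≥ 2) clonotypes.
Lineages with < 50 cells in a sample are flagged TLTC ("too low to
calculate").

**Tissue enrichment.** Each eye clonotype's frequency is compared with
the patient's blood as a log-fold ratio with pseudocount *c*:

    LFR = log₂[ ((n_eye + c)/(N_eye + c)) / ((n_blood + c)/(N_blood + c)) ]

Clonotypes with ≥ 5 eye cells **and** LFR > 1 are classified
*antigen-activated* — cells most likely expanded by local antigen rather
than imported as pre-expanded blood clones.

**Annotation & QC.** Cells pass QC with ≥ 500 unique genes and a
mitochondrial fraction in (1%, 11%); genes need ≥ 70 expressing cells.
Lineages are scored per cell as the mean z-scored log-CPM of marker
panels (CD3D, CD79A, LYZ, NCR1); cells in the top decile of ≥ 2 lineage
scores are flagged multiplets. Marker genes come from a two-sided
Wilcoxon rank-sum test with fold-change/inclusion prefilters and BH
correction.

**Programs.** Rank-based per-cell gene-set scores (e.g. a TCR-signaling
program compared across clonotype size groups, one-way ANOVA) and
classic preranked GSEA with a gene-permutation null.

**Sample-level structure.** A 26-feature matrix per eye sample (19
cell-state proportions, CD4/CD8/B Gini, age, duration, severity,
steroid use) feeds a PCA whose leading components are tested against a
Monte Carlo column-permutation null; samples are embedded (UMAP of 10
PCs) and partitioned by k-means (k = 3), with ANOVA + Tukey HSD, Welch
t, and linear-regression contrasts.

**Covarying neighborhood analysis (simplified).** A kNN graph in PC
space, random-walk neighborhoods, a neighborhood abundance matrix
(cells × samples), NAM-PCA, and a permutation association test against
a binary phenotype (e.g. HLA-B27), yielding per-cell neighborhood
coefficients and a ranked gene vector for GSEA.

Every stage is exercised end-to-end by a synthetic cohort generator
(`uveitis_sc.synthetic_data`) that plants ground truth: lineage-
structured negative-binomial expression, heavy-tailed shared eye/blood
repertoires, eye-enriched antigen-driven clones carrying a TCR-program
shift, peripherally pre-expanded CD8 blood clones, cross-lineage
doublets, and Beta-distributed mitochondrial fractions.

## Worked example

```python
from uveitis_sc import synthetic_data as synth, enrichment, repertoire

cohort = synth.generate_cohort(synth.CohortConfig(
    n_patients=2, cells_per_eye_sample=500, cells_per_blood_sample=1000,
    n_genes=400, n_antigen_clones=5, antigen_clone_size_range=(5, 12), seed=11))

print("Gini of [1, 1, 1, 1, 96]:", repertoire.gini([1, 1, 1, 1, 96]))

t_clones = cohort.clonotypes.query("lineage in ('CD4', 'CD8')")
enr = enrichment.compute_enrichment(t_clones)
hits = enr.query("antigen_activated").sort_values("lfr", ascending=False)
print(hits[["patient", "lineage", "n_eye", "n_blood", "lfr", "size_class"]]
      .head(4).to_string(index=False))

cd4 = repertoire.clonality_stats(t_clones, sample="P00E", lineage="CD4")
print(f"P00E CD4: gini={cd4.gini:.3f} expanded={cd4.fraction_expanded:.2f} "
      f"cells={cd4.n_cells} TLTC={cd4.tltc_flag}")

frac = enrichment.antigen_activated_fraction(enr, "P00E")
print(f"antigen-activated T cells in P00E: {frac['percent']:.1f}% "
      f"of {frac['n_cells']} T cells with TCR data")
```

prints

```
Gini of [1, 1, 1, 1, 96]: 0.76
patient lineage  n_eye  n_blood      lfr size_class
    P01     CD4      8        1 2.882788      small
    P01     CD4     10        2 2.587332     medium
    P00     CD4      7        1 2.532993      small
    P01     CD8      8        2 2.526546      small
P00E CD4: gini=0.377 expanded=0.71 cells=178 TLTC=False
antigen-activated T cells in P00E: 20.2% of 243 T cells with TCR data
```

The four strongest antigen-activated calls are clonotypes with 7–10 eye
cells that are nearly absent from the matched blood (LFR ≈ 2.5–2.9,
i.e. a 6–7× frequency excess in the eye). Patient P00's eye CD4
compartment is visibly oligoclonal (Gini 0.38, 71% of cells in expanded
clones), and a fifth of its TCR-matched T cells sit in antigen-activated
clonotypes.

The same stages are available from the shell:

```bash
uveitis-pipeline simulate --seed 3 --n-patients 12 --outdir cohort/
uveitis-pipeline io-validate cohort/
uveitis-pipeline run-all --seed 3 --outdir run/
```

`run-all` writes per-stage TSV tables (clonality, clonotype enrichment,
antigen-activated fractions, the sample feature matrix, PCA + Monte
Carlo report, sample clusters, CNA coefficients and gene loadings) plus
a manifest carrying the seed and config hash.

## Layout

| module | contents |
| --- | --- |
| `synthetic_data` | cohort generator with planted ground truth |
| `io` | MTX/contig/metadata readers + writers, clonotype keying |
| `annotation_qc` | QC filters, lineage scores, multiplets, marker finding |
| `repertoire` | size classes, Gini, clonality stats, flare persistence |
| `enrichment` | LFR, antigen-activated classifier, per-sample fractions |
| `signatures` | per-cell gene-set scores, size-group ANOVA, preranked GSEA |
| `composition` | feature matrix, PCA, Monte Carlo test, clustering, contrasts |
| `cna` | kNN graph, NAM, association test, gene loadings |
| `pipeline_cli` | `uveitis-pipeline` orchestration |

`docs/methods.md` documents the models, defaults, and known
limitations.
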