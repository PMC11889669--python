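# Methods

## Data model

A cohort is a set of patients, each contributing one aqueous-humor
("eye") and one peripheral-blood sample. Expression travels as an
`AnnData` of sparse integer counts (cells × genes) with per-cell
metadata (sample, patient, compartment, mitochondrial fraction);
V(D)J data as a 10x-style contig table (one row per barcode × chain
with CDR3 amino-acid and nucleotide sequences). Because 10x clonotype
ids are only unique within a sample, clonotypes are keyed by the sorted
set of (chain, CDR3-nucleotide) pairs within a patient, which lets the
same clone be matched between eye and blood and between disease flares.
Amino-acid keying is available but nucleotide identity is the stricter
default. Barcode GEM-well suffixes (`-1`) are stripped on both sides of
the expression/V(D)J join; duplicate (barcode, chain) contigs resolve
to the highest-UMI row, ties to the lexicographically smallest CDR3,
so parsing is deterministic.

## QC, annotation, multiplets

Cells are kept with ≥ 500 unique genes and mitochondrial fraction
strictly inside (0.01, 0.11); genes are kept when expressed in ≥ 70 of
the surviving cells (cell filter first, then gene filter). The bounds
are treated as strict inequalities. Normalization is library-size
scaling to 10,000 counts followed by log1p — a deliberate, deterministic
stand-in for variance-stabilizing transforms, so all downstream
rank-based statistics are unaffected by per-cell depth.

Lineage scores are the mean of per-gene z-scored normalized expression
over a marker panel (defaults: CD3D for T, CD79A for B, LYZ for
myeloid, NCR1 for NK; zero-variance genes contribute 0). Cluster →
lineage assignment takes the highest mean score, ties breaking
lexicographically with a warning. A cell strictly above the pooled
90th-percentile cutoff (linear-interpolation quantile over all samples)
for two or more lineages is flagged a multiplet and excluded from
differential expression.

**Operating regime of the multiplet rule.** A cross-lineage doublet's
library is the sum of two cells, so after per-cell normalization each
component's markers appear at roughly half their pure-cell level. For a
lineage comprising fraction *f* of the cohort, the pooled top-decile
cutoff sits at the (1 − 0.1/*f*) quantile *within* that lineage —
above the depth-halved doublet level whenever *f* exceeds roughly 0.12.
The rule therefore has high recall only for doublets whose two
component lineages are both rare, and near-zero recall for doublets
involving the dominant T or myeloid compartments of a realistic ocular
infiltrate. This is a property of the decile construction itself, not
of any particular score; the test suite asserts the behaviours that do
hold (false-positive rate on singlets, recall on rare-lineage pairs)
and documents the measured recall on realistic compositions.

Marker finding is a two-sided Wilcoxon rank-sum per gene, exact for
small tie-free groups and otherwise the tie-corrected normal
approximation without continuity correction (so the two paths agree in
the limit). Genes are prefiltered by |log2FC| — computed as
log2((mean expm1 + ε)/(mean expm1 + ε)), ε = 1e-9 — and by expression
in at least `min_pct` of cells in either group. Two threshold pairs are
conventional: (1.0, 20%) for major lineages, (0.25, 10%) for
within-lineage subsets. P-values are BH-adjusted.

## Repertoire statistics

Clonotype size classes: T cells singleton / 2–9 / 10–19 / ≥ 20;
B cells singleton / 2–9 / ≥ 10. The Gini coefficient uses the
ordered-statistic form G = Σ(2i − n − 1)y₍ᵢ₎/(nΣy) on clonotype cell
counts, no small-sample correction, pinned in the tests against the
pairwise mean-absolute-difference form. Gini is computed on cell counts
(not frequencies-of-frequencies), is scale-invariant, and strictly
increases when a cell moves from the smallest to the largest clone.
Samples with < 50 cells of a lineage keep their computed Gini but carry
a TLTC flag marking it non-reportable. Clonotype lineage (CD4/CD8/B) is
the majority vote of member cells; ties go to "unconventional".
Cells without TCR data ("no data") never enter clonality statistics.

## Eye/blood enrichment

Frequencies use a pseudocount in numerator and denominator,
f = (n + c)/(N + c) with c = 1 by default, which keeps the LFR finite
and antisymmetric when a clonotype is absent from one compartment; the
classification is insensitive to c over the range 0.5–2 (tested at
≥ 95% agreement). Denominators are lineage-specific (CD4 clonotypes
against CD4 totals), matching separate CD4/CD8 analyses; a pooled mode
exists. The antigen-activated call is n_eye ≥ 5 AND LFR strictly > 1.
Per-sample antigen-activated fractions report the percentage of
TCR-matched eye T cells in activated clonotypes and carry an exclusion
flag when the denominator is below 50 cells.

## Gene-program scoring and GSEA

The per-cell score of a gene set is rank-based: genes are ranked within
each cell by normalized expression (average ranks on ties) and the
score is (mean rank of set genes − 1)/(G − 1) − 0.5, so it is invariant
to any monotone per-cell transform, 0 for the whole-transcriptome set,
and maximal when the set occupies the top ranks. Scores are compared
across clonotype size groups (ordered singleton < small < medium <
large; groups under 2 cells dropped) with one-way ANOVA.

Preranked GSEA is the classic weighted Kolmogorov–Smirnov running sum
(weight 1 by default) with a gene-permutation null. The observed ES is
compared against the same-sign portion of the null: NES = ES / mean
|same-sign null ES| and p = (1 + #{same-sign null at least as extreme})
/ (1 + #same-sign null). Dividing instead by the full permutation count
while conditioning on sign would concentrate null p-values on (0, 0.5);
the same-sign convention keeps them uniform, which the suite verifies.

## Sample-level composition

The default feature matrix has 26 columns per eye sample: 19 cell-state
proportions (4 CD4 states, 3 CD8, 3 unconventional-T, 2 B, 5 myeloid,
2 NK; summing to 1 before scaling), CD4/CD8/B Gini, and age (years),
disease duration (days), severity (ordinal 1–4), steroid use (0/1).
TLTC Gini entries are imputed with the column mean and the imputation
is recorded in the feature manifest; constant columns are excluded with
a warning; all columns are z-scored (ddof = 1).

PCA is the eigendecomposition of the feature covariance of the scaled
matrix, deterministic up to sign, with the convention that each PC's
largest-|loading| feature is positive. Variable vectors are
loading × √eigenvalue — the feature–PC correlation for z-scored input,
so magnitudes are bounded by 1.

The Monte Carlo significance test permutes every column independently
across samples (destroying inter-feature correlation, preserving
marginals), recomputes the variance-explained spectrum, and reports
per-PC p = (1 + #{null ≥ observed})/(1 + n_iter); 10,000 iterations by
default, scaled to 1,000 in the test suite's replicated calibration
runs. Calibration is nominal by construction. Power depends on the
planted eigenvalue clearing the Marchenko–Pastur bulk of the
permutation null: at 25 samples × 26 features the noise edge is ≈
(1 + √(p/n))² ≈ 4, so a planted correlated block needs eigenvalue
above that (e.g. four perfectly correlated columns) to be detectable —
a single duplicated pair (eigenvalue 2) is buried in the bulk and in
fact slightly *lowers* PC1's share. The power tests therefore use a
detectable block; the single-pair scenario is reported as measured.

Sample clustering runs k-means (k = 3, fixed seed, 10 restarts) on the
first 10 PC scores — not on the UMAP embedding, which is computed only
for display — and relabels clusters A/B/C by descending mean of an
ordering score (PC1 by default) so labels are reproducible. Duplicated
feature rows always co-cluster, mirroring repeat-flare samples from the
same eye. Group contrasts: one-way ANOVA with Tukey HSD, Welch t
(Satterthwaite df), simple linear regression, and the conventional
star bands at 0.05/0.01/0.001/0.0001.

## Simplified covarying neighborhood analysis

Cells are joined by a Euclidean kNN graph in PC space (k = 20 default;
union-symmetrized; distance ties to the lower index). Each cell anchors
a neighborhood: the distribution of a `steps`-step random walk (default
3) along the row-normalized adjacency, aggregated by sample — the
neighborhood abundance matrix (NAM), rows summing to 1. Deeper walks
smooth the NAM monotonically toward the graph's stationary
distribution. Each neighborhood is standardized across samples and
NAM-PCA treats samples as observations. The binary phenotype is
regressed on the leading NAM-PC scores; the number of PCs defaults to
min(10, n_samples/2 − 1) because letting the regression df approach the
sample count saturates R² under null and alternative alike. The global
p-value permutes phenotype labels (R² statistic, +1 estimator); each
cell's neighborhood coefficient is the Pearson correlation between its
abundance profile and the fitted phenotype direction, bounded in
[−1, 1] and sign-symmetric under phenotype relabeling. Gene loadings
are per-gene correlations of expression with the coefficient vector,
ranked for preranked GSEA. Replicate samples of a patient are dropped
before association (override available). This is a deliberately reduced
form of published covarying neighborhood analysis: binary phenotypes
only, no covariate adjustment, fixed walk depth.

## Synthetic cohort generator

The generator emulates the statistical structure of a paired
eye/blood uveitis cohort; its defaults are the conditions under which
the pipeline's recovery properties are stated.

* **Cohort**: 12 patients, one eye (2,000 cells) and one blood (4,000
  cells) sample each, cycling through three clinical subtypes whose eye
  compositions are adaptive-skewed, effector-T-skewed, and
  innate/myeloid-skewed (HLA-B27-AAU-like; this subtype carries the
  HLA-B27 flag). Per-sample compositions are Dirichlet draws
  (concentration 150) around subtype means; blood uses one common mean.
  Coarse types (CD4 T, CD8 T, unconventional T, B, myeloid, NK) carry
  the expression differences; a nested 19-state annotation adds
  compositional granularity for the feature matrix.
* **Expression**: gamma-Poisson (negative binomial, dispersion θ = 10)
  around per-gene base means (log-normal, normalized to a 2,000-count
  library), with an 8× marker fold-up in the owning lineage and 0.25×
  elsewhere; 1,000 genes by default. Mitochondrial fractions are
  Beta(2, 30) per cell, attached as metadata and realized as counts on
  five MT- genes, so the QC filter is exercised end to end.
* **Repertoire**: per patient and lineage, a background clonotype
  weight vector from a truncated discrete power law (exponent 2.5,
  max weight 30) drives multinomial sampling of both compartments —
  background clones thus share eye/blood frequencies, and apparent
  absence from blood arises from sampling alone. 2% of CD8 background
  clonotypes are peripherally pre-expanded (blood weights boosted
  10–30×), confined to CD8 because peripheral expansion in such cohorts
  is essentially a memory-CD8 phenomenon. 20 antigen-driven clones per
  eye sample are planted with sizes uniform on 8–40 (joint draws
  exceeding 90% of the lineage's eye cells are redrawn) and blood
  counts set so the eye/blood frequency ratio is at least 4. Their
  cells receive a one-natural-log-unit mean shift on a 30-gene
  TCR-signaling program. T-cell contigs (TRA+TRB; B cells IGH+IGK) are
  emitted for 85% of cells (capture thinning), with deterministic
  patient-scoped CDR3 tokens.
* **Doublets**: 5% of cells per sample become cross-lineage doublets by
  adding a second, different-lineage profile; doublets are drawn
  outside planted clones (so planted frequencies stay exact) and carry
  no V(D)J data.
* **Determinism**: one `numpy` Generator seeded from the config; equal
  configs give byte-identical serialized cohorts.

What the generator does **not** emulate: batch effects, ambient RNA,
sequence-level receptor realism (CDR3s are arbitrary tokens), doublet
enrichment among large cells, per-state expression programs for the 19
fine states, or clinical covariates with realistic correlation
structure. Passing recovery tests therefore demonstrate correctness of
the statistical machinery under a clean generative model, not
robustness to the technical artifacts of real droplet data.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run the default cohort
(12 × 6,000 cells, 1,000 genes) for classifier recovery, the doublet
rule, and the clone-size trend; 2-patient, 300–400-gene cohorts for
replicated null calibrations (50 seeds); 25 × 26 matrices with 200
replicates × 1,000 iterations for Monte Carlo calibration; and
12-sample, ~480-cell populations for CNA calibration (200 replicates)
and power (20 seeds). These sizes keep the full validation run within
a few minutes on one CPU while leaving every statistical conclusion
replicated across seeds.

## Known limitations

* The multiplet rule's recall limitation on abundant lineages (above).
* The Monte Carlo PC test only detects planted structure above the
  permutation null's spectral bulk (above).
* Clonotype matching assumes exact CDR3-nucleotide identity; no
  allowance for sequencing error or convergent recombination.
* The CNA reimplementation is intentionally minimal; effect sizes are
  not comparable to the published method's FDR-controlled outputs.
* Clinical covariates in the generator are weakly informative
  placeholders; the composition PCA's clinical axes are not expected to
  reproduce any particular cohort's loadings.
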