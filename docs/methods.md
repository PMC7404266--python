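# Methods

## Scope and data model

`tsmeth` integrates three matched data layers over a panel of tissues:
a gene × sample TPM matrix with a sample sheet (sample → tissue, batch);
per-sample per-CpG bisulfite methylation calls (chromosome, 1-based
position, strand, methylated fraction, effective coverage — the format
produced by BSMAP-style methylation callers, or bedGraph); and, for the
association stage, an array-style probe × sample beta-value matrix with a
probe manifest and a phenotype table. A GENCODE-like GTF supplies gene
structure. All internal genomic arithmetic is 0-based half-open; GTF input
is 1-based closed and regions are interchanged on disk as BED6.

## Promoter windows

Each gene is anchored at the TSS of a single representative transcript: the
transcript whose TSS is 5′-most in transcription direction, ties broken by
lexicographically smallest transcript id. Annotations do not record which
transcript a promoter "belongs" to, so a deterministic rule is required;
this one is stable under transcript reordering and favours the longest
upstream extent.

Three windows are derived per gene (t = 1-based TSS, '+' strand shown;
'-' strand windows are mirrored in transcription direction):

| kind     | 0-based half-open interval | span |
|----------|---------------------------|------|
| proximal | [t−201, t+49)             | 250 bp: 200 up + TSS + 49 down |
| typical  | [t−2001, t−1)             | 2000 bp immediately upstream |
| expanded | [t−2001, end of first intron) | ≥ 2000 bp |

The "200 upstream / 50 downstream" proximal convention counts the TSS base
itself as the first downstream base, giving a fixed 250 bp span; offsets
alone do not determine inclusivity, so the convention is pinned here and
tested. Intervals are clipped at coordinate 0 with a `clipped_at_origin`
flag. For a single-exon representative transcript the expanded window has
no first intron; it runs to the transcript 3′ end and is flagged
`no_first_intron` rather than failing.

## Expression processing and Tau

Genes are kept if detected anywhere (TPM > 0 in ≥ 1 sample); before
specificity scoring the stricter filter max TPM ≥ 1 applies (a gene whose
maximum is exactly 1 is kept — the boundary is inclusive by a literal
reading of "less than 1 in all samples"). Log transformation is
log₂(TPM + 1), the common transcriptomics convention; pairwise sample
correlations (Pearson) are summarised as means over unordered within- and
between-tissue pairs, excluding zero-variance samples with a warning.

Tau is computed on linear per-tissue mean TPM (not log), applying the mean
profile directly to the formula; a gene is a TSG when τ ≥ 0.8 (inclusive)
and is assigned to the argmax tissue, first-in-order on ties with an
explicit `tie_flag`. Tau is scale-invariant and bounded in [0, 1]; both are
property-tested.

## Methylation aggregation

Calls below 10× effective coverage are discarded at read time (bedGraph
input has no coverage column; the filter is skipped with a warning).
Region methylation is the **unweighted** arithmetic mean of member-CpG
ratios — averaging the per-CpG levels, not pooling read counts — with a
coverage-weighted mean behind a flag; cells with fewer than `min_cpgs`
(default 1) member CpGs are missing, not zero. '+' and '−' strand
cytosines are independent records; no dyad merging is attempted, matching
per-cytosine caller output. Membership of a 1-based call position p in a
region [start, end) is start < p ≤ end, implemented by binary search over
per-chromosome sorted positions and verified against a naive per-base scan
in tests.

## Integration

Per TSG, Pearson's r between log₂(TPM+1) expression and proximal promoter
methylation is computed across **all** matched samples pooled over tissues
— the tissue-driven contrast is the signal of interest — with pairwise
deletion of missing methylation cells and a minimum of 10 complete pairs
(below it, or under zero variance, r is undefined and the gene is reported
unclassified). Direction is `negative` (r ≤ −0.3), `positive` (r ≥ 0.3,
boundaries inclusive) or `none`.

Methylation patterns of selected genes are z-scaled per gene (so
clustering is invariant to per-gene affine transforms) and grouped by
K-means with k = 5, 10 restarts, best inertia, fixed seed required. Genes
with any missing cell are dropped from clustering rather than imputed.
Rows within each cluster are ordered by average-linkage hierarchical
clustering on 1 − Pearson correlation distance for heatmap rendering.

## Enrichment

Gene lists are tested against user GMT collections with the one-sided
upper-tail hypergeometric probability P[X ≥ k] (N = background, K = set ∩
background, n = query) and BH adjustment across sets. The tail is verified
against exhaustive enumeration of draws for small universes. No external
enrichment service is queried.

## EWAS

Probes are restricted to those inside expanded promoters of one tissue's
TSGs. The association model regresses each probe's beta value on a
case/control indicator plus covariates (age, sex coded F=0/M=1; BMI when
testing the secondary diabetes trait), with listwise deletion of samples
missing any covariate. The effect is the outcome coefficient and p a
two-sided Wald test — methylation-as-response linear modelling is the
dominant EWAS convention; a logistic model (status as response) and an
M-value transform (log₂(β/(1−β)), β clipped to [10⁻³, 1−10⁻³]) are
available behind flags. The linear fit is closed-form and vectorised over
probes sharing one design matrix; tests cross-check effects, standard
errors and p-values against an independent per-probe OLS fit.

Discovery significance is Bonferroni: p ≤ α/m with m the probes actually
tested (non-missing p). Validation additionally requires replication
p < 0.05 in independent data **and** a concordant effect sign; the sign
requirement goes beyond a bare nominal-p criterion but is standard
practice, and can be switched off. Constant-beta probes are flagged with
missing p rather than failing the run.

## Synthetic data

The generator emulates the study design the analysis assumes: 5 tissues ×
10 matched samples by default, genes on one synthetic chromosome with
2-exon transcripts (10 kb spacing; 5% single-exon genes exercise the
degenerate expanded-promoter path). Defaults: 40 negatively coupled TSGs,
20 positively coupled (the 2:1 ratio the analysis expects to recover), 140
null genes — null genes dominate, as in real genomes, which keeps the
genome-wide proximal-vs-typical hypomethylation contrast visible.

* **Expression**: log₂(TPM+1)-scale Gaussian draws (sd 0.5): TSGs at mean
  6 in the target tissue and 0.5 elsewhere; null genes at a per-gene
  baseline drawn once from N(3, 1.5) and shared across tissues (clipped at
  0.5), which reproduces the qualitative QC signature of real panels —
  high within-tissue and lower but positive between-tissue sample
  correlation.
* **Methylation**: region level per gene × sample from Beta(2, 18)
  (hypomethylated, mean 0.1) where expression is high under negative
  coupling and Beta(18, 2) (mean 0.9) elsewhere; reversed for positive
  coupling; null promoters Beta(2, 18) everywhere. Eight CpGs per promoter
  sit tight around the TSS (inside proximal, outside typical); eight
  background CpGs per gene sit in the upstream typical window at
  Beta(6, 14) (mean 0.3). Per-CpG ratio = region level + N(0, 0.03)
  clipped to [0, 1]; coverage ~ Poisson(30).
* **EWAS**: discovery 200 cases / 250 controls, replication 380/379 (759),
  500 probes of which 3 are true DMPs with case mean shifted by Δβ = 0.08;
  per-probe baselines Uniform(0.2, 0.8) and within-group draws from a Beta
  distribution moment-matched to the target mean and sd 0.03. Age
  ~ N(50, 8) and sex ~ Bernoulli(0.5) are independent of status by
  default; a confounding mode shifts case ages upward (+4 years each way)
  and adds an age slope (0.002 β/year) to every probe, for verifying that
  covariate adjustment removes the spurious signal. BMI is drawn higher in
  cases; a secondary diabetes label follows BMI through a logistic link
  with 5% missingness.

All randomness flows from one `numpy` Generator seeded by the config; the
same seed yields byte-identical output files, and the emitted files parse
through the package's own readers warning-free.

What the simulation does **not** model: read-level noise, CpG
co-methylation/LD structure, batch effects on methylation, array probe
chemistry, cell-type composition, genomic inflation. Passing the planted-
truth recovery tests therefore demonstrates the pipeline's correctness and
calibration under its stated assumptions, not performance on real cohorts.

## Numerical and degenerate-input choices

* Tau of an all-zero profile is an error (normalisation undefined), as is
  an expression matrix sample missing from the sample sheet, or a query
  gene outside the enrichment background.
* Zero-variance variables (samples in QC, probes in EWAS, gene rows in
  clustering) are excluded/flagged with warnings, never silently zeroed.
* Undefined correlations are reported as missing and classified `none`.
* The K-means stage is the only stochastic analysis step; its seed is a
  required config field and is echoed to provenance.

## Problem sizes

Default simulated sizes (200 genes, 50 samples, 16 CpGs/gene, 500 probes,
~1200 cohort samples) were chosen so the full pipeline and its planted-
truth checks run in seconds on one CPU while leaving all analysis
thresholds at their study values (τ ≥ 0.8, |r| ≥ 0.3, depth ≥ 10,
Bonferroni α = 0.05, k = 5); every size is a config field.
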