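# Methods

This note documents the models, defaults and design choices behind
`stagesig`, and what its synthetic-data tests do and do not demonstrate.

## Data model

Expression is any non-negative, TPM-like abundance table (features ×
samples) at gene or isoform level; the package treats any such abundance
as TPM-like and does not distinguish RSEM's scaled estimates from TPM.
Gene and isoform matrices are joined to a clinical table (stage I–IV, age,
gender, follow-up months, death indicator) by sample id at load time;
samples present in only one source are dropped with a warning. Missing
expression values are not permitted; missing age/gender are allowed and
excluded only from multivariate survival fits.

## Filtering

Isoforms (and, by default, genes) are kept when expression exceeds
0.001 TPM — strictly — in at least half (⌈n/2⌉) of the early-stage **or**
of the late-stage discovery samples. The filter is idempotent. The
threshold is deliberately permissive: it removes unexpressed annotation
rows, not low-expression biology.

## Isoform structure

The *major isoform* of a gene is the isoform with the largest mean
abundance across discovery samples (ties broken by smallest id, logged);
choosing per-sample majors instead is exposed as an option but makes the
"major isoform" an unstable feature. Its *ratio* is, by default, the mean
over samples (with nonzero gene abundance) of major/gene; the ratio of
means is available as an alternative since aggregate-vs-per-sample
averaging is a genuinely open choice. "Multi-exon genes" are approximated
by genes with ≥ 2 annotated isoforms in the mapping, because exon models
are not an input.

## Moderated differential expression

DE runs on log2(x + 0.01); the pseudocount is of the order of the
expression filter threshold and configurable. The two-group model is a
difference of group means with pooled residual variance s² on d = n₁+n₂−2
degrees of freedom. The empirical-Bayes prior (d₀, s₀²) is fitted by
method-of-moments on e = log s² − ψ(d/2) + log(d/2): the excess of
var(e) over ψ′(d/2) is ψ′(d₀/2) (inverted by Newton iteration on the
trigamma function), and log s₀² = ē + ψ(d₀/2) − log(d₀/2). When the
excess variance is non-positive the prior degrees of freedom are infinite
(estimates above 10⁶ are treated the same); then s₀² is the mean of the
s², every posterior variance equals s₀², and the reference distribution
is normal. Forcing d₀ = 0 recovers the ordinary pooled t-test exactly,
which is the main unit-level oracle. Zero-variance features under d₀ = 0
get p = 0 (nonzero fold change) or 1, with a warning.

Fold change ≥ 2 is interpreted as |log₂FC| ≥ 1 on the model coefficient,
not as a ratio of raw means. BH adjustment is the standard step-up
procedure. The gene-priority combination rule removes *all* significant
isoforms of any gene that is itself significant — the strictest reading of
"only gene signatures were selected" — and tags provenance
(gene_only / isoform_only / both). No precision weights and no covariates
enter the DE design; the comparison is two-group by construction.

## Consensus stability

Each of H resamples draws ⌊0.8·n⌋ patients and ⌊0.8·m⌋ features
independently, without replacement (the joint-vs-independent choice is
undocumented in the consensus-clustering tradition this follows;
independent draws are assumed). Engines:

* **hierarchical** — average linkage on 1 − Spearman rank correlation
  between patient profiles, cut at 2 clusters;
* **kmeans** — k = 2 k-means (10 restarts, seeded) on per-feature
  rank-transformed, standardized profiles. Centroid methods are undefined
  for correlation dissimilarity, so the rank transform serves as a
  Euclidean surrogate consistent with Spearman.

Because Spearman correlation is invariant to any shift applied uniformly
across a patient's whole profile, group differences are only visible to
the hierarchical engine through *heterogeneous* (mixed-direction or
mixed-magnitude) signatures — which real DE signatures are; the test
fixtures therefore plant balanced up/down effects.

M(i,j) is the ratio of co-clustering to co-sampling counts; never
co-sampled pairs get 0.5 (maximal uncertainty) with a warning — at
H = 500 and 80% sampling the expected co-sampling count is ≈ 0.64·H, so
this is practically unreachable. SS is linear in M, equals 1 exactly on
the perfect label indicator, and is computed over unordered pairs. The
final partition cuts 1 − M by average linkage; an all-ones (degenerate)
consensus is forcibly split at the first patient and flagged. Accuracy
matches the two clusters to the two stages by the better of the two
assignments and is reported rounded half-up to one decimal. One published
worked example (57/315 misclassified reported as 81.6%) is arithmetically
inconsistent with its own counts (258/315 = 81.9%); accuracy here is
always computed from counts. Ranking for "top-k signatures" (ascending
FDR, ties by descending |log₂FC|) is a package choice; the source
analyses do not state theirs.

## Enrichment

Upper-tail hypergeometric p per set, BH across tested sets, selection at
FDR ≤ 0.05. The universe defaults to all features surviving the
expression filter, mapped to gene ids — the original web-service universe
is not recoverable offline — and is overridable. Sets with fewer than 5
members inside the universe are skipped (also a package default, stated
as such).

## Survival screen

Validation cohort = stage II/III samples (configurable); the median split
(high = strictly above the validation-cohort median; ties go low) feeds a
univariate Cox PH fit on the group indicator (Efron tie handling; Breslow
available through lifelines). Wald p-values are BH-adjusted per feature
level — the 39-gene / 92-isoform style of reporting suggests separate
lists — with the log-rank p reported alongside. Only selected features
are refit with age (years, continuous) and a male indicator. Kaplan–Meier
median survival is the smallest time with S(t) ≤ 0.5 and is reported as
absent when the curve never reaches 0.5.

## Synthetic cohort generator

The generator is the package's test bed and defines its study conditions:
234/81/165 early/late/validation samples by default, desk-scale 2000
genes, isoform counts per gene from {1: 0.35, 2: 0.30, 3: 0.20, 4: 0.15},
within-gene proportions Dirichlet(0.5) — calibrated by Monte-Carlo so
that ~62% of major isoforms exceed a 0.8 ratio overall (~41% among
multi-isoform genes) — gene baselines log-normal (log₂ mean 4, sd 1.5),
log2-scale noise sd 0.5, planted |log₂FC| = 2.

Planted classes: *gene_de* multiplies all isoforms of a gene by 2^±2 in
late samples; *isoform_only_de* shifts one isoform whose proportion is
set to 1/(2(f−1)) so the expected gene-level fold stays at 1.5,
below threshold; *switch* genes rescale two isoforms to proportions
(1/(f+1), f/(f+1)) of their combined mass and move them by f and 1/f —
an algebraically exact cancellation at the gene level. The gene matrix is
the per-sample sum of isoform rows, exactly, so conservation is a testable
invariant.

Survival uses one latent binary risk axis per cohort: each prognostic
feature shifts expression by its direction × 2² in the high-risk half of
the validation samples, and hazards are exponential (baseline median 90
months) multiplied by exp(1.25) for the high-risk group; censoring is
administrative Uniform(0, τ) with τ solved by bisection for the requested
censor rate (0.6 default, near the event fraction seen in stage II/III
kidney cohorts). Discovery samples carry stage effects but no survival
effect.

What the generator does **not** emulate: read-assignment uncertainty and
its isoform-level noise, correlated co-expression structure, per-sample
library-size artifacts, multiple independent prognostic axes, or the
~70%-of-multi-exon-genes-express-several-isoforms statistic (here
essentially all annotated isoforms are expressed). Passing recovery tests
therefore shows the pipeline's statistics behave as designed under their
own assumptions — not that real cohorts will yield comparable effect
recovery.

## Numerical choices and degeneracies

* Trigamma inversion: Newton iteration from x₀ = 0.5 + 1/y, tolerance
  1e-12 relative; prior df capped at 10⁶ ("infinite").
* Consensus seeds: one master generator spawns per-resample seeds, so a
  run is reproducible from a single integer.
* Accuracy rounding: half-up to one decimal (display convention only;
  comparisons in code use counts).
* Degenerate inputs: constant features are rejected by the median split
  and skipped (logged) in the screen; an all-distinct label vector makes
  ES = 0 and SS undefined (error); empty filter results raise with advice
  rather than returning an empty matrix.
* Problem sizes in tests are desk-scale (hundreds of genes, tens to
  hundreds of samples, H = 30–100 resamples), chosen so the planted
  effects are comfortably identifiable at the stated thresholds.

## Known limitations

Two-group DE only (no covariate adjustment, no precision weights); k is
fixed at 2 in the consensus machinery (no cluster-count selection or
CDF-based diagnostics); no proportional-hazards diagnostics or
time-varying covariates; no transcript-structure (domain-level)
comparison of switching isoforms; enrichment is overlap-based, not
topology-aware.
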