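# Methods

## Synthetic cohort model

The generator emulates the features of Illumina EPIC beta matrices that the
pipeline's statistics actually touch, and nothing upstream of them (no IDAT
intensities, no Infinium I/II chemistry bias, no FFPE/fresh-frozen batch
term).

Each probe receives a cohort-wide base mean drawn from a 50/50 mixture of
Beta(2,18) and Beta(18,2) — the bimodal marginal typical of array betas,
with most CpGs near-unmethylated or near-methylated. Group structure is
planted at the level of group means: a group's *signature probes* (disjoint
across groups) are shifted by a fixed delta on the beta scale, in whichever
direction keeps the mean inside [0.01, 0.99]; configurations where neither
direction fits are rejected. A group may instead *share* another group's
signature (fully or a leading fraction), which is how sibling entities with
zero or few true differential probes are planted. Additional per-pair
plantings shift only the second group of the pair, leaving third-party
contrasts untouched. Per-sample noise is Gaussian on the logit2 (M-value)
scale around the group mean, so observed betas stay strictly inside (0,1).
Shifting the *mean* on the beta scale (rather than shifting on the logit
scale and mapping back) makes the planted group mean difference exactly the
configured delta, which is the scale on which the DMP effect threshold and
all recovery checks are phrased.

Detection p-values are drawn uniformly below half the failure threshold for
clean samples; a designated bad sample has exactly round(fraction ×
n_probes) random probes pushed above the threshold, so its reported failure
fraction matches the configuration to within 1/n_probes.

The default study-shaped cohort mirrors a hepato-pancreato-ovarian tumor
landscape: 23 diagnosis groups totalling 430 samples (group sizes as
published for that cohort), 20,000 probes, signature size 300 probes at
delta 0.30, noise SD 0.5 on the logit2 scale (≈ 0.09 beta-scale SD at
beta 0.5 — heterogeneity typical of FFPE tumor cohorts). Two plantings
encode the cohort's known biology: the hepatic mucinous cystic neoplasm
group (MCN-L) shares the pancreatic group's (MCN-P) signature completely
(the zero-DMP sibling pair), and the mucinous borderline ovarian tumor
group shares 60% of it plus a smaller own signature, making it the nearest
non-sibling entity.

What the generator does **not** emulate — probe-type chemistry, spatial
artefacts, batch effects, copy-number-driven beta shifts, cellularity
gradients — bounds what passing tests show: they validate the statistics
and bookkeeping of the pipeline under a clean planted model, not robustness
to real-world array artefacts.

## Quality control and feature selection

A sample is excluded when more than 10% of its probes have detection
p > 0.01. The 0.01 probe-level threshold is the field convention; the 10%
sample-level cap is configurable (the motivating cohort excluded its only
failing sample at 14%). Exclusion is monotone in the cap. Sex-chromosome
probes are dropped by default (configurable) since external cohorts of
unknown sex composition may enter a landscape. The landscape feature space
is the k = 10,000 probes with the largest across-sample standard deviation
of beta values; SD is computed on betas (the heatmap/t-SNE convention in
methylation-classifier work), ties break lexicographically by probe id, and
selection is idempotent. The M-value transform m = log2(β/(1−β)) with
clipping at ε = 10⁻³ is provided for statistics on the variance-stabilised
scale.

## Moderated differential methylation

The two-group statistic follows the standard empirical-Bayes moderation
scheme: per-probe pooled variance s²_g on d = n₁+n₂−2 df, shrunk as
s̃² = (d₀s₀² + d s²)/(d₀+d), with t̃ referred to a t distribution on d₀+d
df. The prior is fitted by the method of moments on z = log s²: under the
scaled-F model E[z] and Var[z] are closed forms in digamma/trigamma of the
degrees of freedom, and d₀ solves a trigamma inversion (Newton iteration,
monotone convergence). When the observed spread of log variances does not
exceed pure sampling noise the fit returns d₀ = ∞ (complete shrinkage,
normal reference distribution); with fewer than 50 probes the fit is
considered unreliable and the statistic falls back to the ordinary pooled
t (d₀ = 0); a matrix with zero variance everywhere degenerates to
exact-equality calls (t = ±∞ where means differ) with a warning.

The analysis scale is beta by default, so the reported effect ("logFC" in
the convention of array pipelines fed beta values) is the group delta-beta
and the |Δβ| > 0.3 call threshold is a 30-point methylation difference;
M-value input is equally valid. Benjamini–Hochberg adjustment is step-up
with cumulative-minimum enforcement, applied per pairwise contrast (the
per-contrast convention of the upstream tools), not jointly across the 253
pairs. Groups with fewer than two samples are skipped with a warning rather
than merged.

Calibration: under the global synthetic null the raw-p frequency below α
stays within 3 binomial standard errors of α at 20,000 probes (the
acceptance suite asserts this at α = 0.01 and 0.05). Power: at the planted
delta 0.35 with n = 10 vs 10 and logit-noise SD 0.1 (the recovery-check
condition), recall is ≥ 0.95 with < 1% false calls. At the study cohort's
noisier default (SD 0.5) the |Δβ| > 0.3 effect filter alone caps recall
near ~0.94, because observed deltas scatter around the planted 0.35 — an
intrinsic property of a hard effect-size threshold, documented here rather
than hidden.

## Landscape construction

Distance is 1 − Pearson correlation between samples over the selected
probes; linkage is average, for both the dendrogram and the consensus base
clusterer. t-SNE runs on 50 principal components (stability), perplexity
30, 1,000 iterations, mandatory seed. Because a t-SNE plot is read
qualitatively, the package exposes a quantitative surrogate — k-nearest-
neighbour label purity in the embedding — instead of any visual grouping
rule.

Consensus clustering resamples 80% of samples without replacement B times
(library default B = 500; the bundled study-scale runs use B = 200, which
the operation contract (B ≥ 10) covers and which leaves consensus values
stable to ±0.05), cuts each clustering at k = number of sheet groups, and
records co-cluster/co-draw frequencies; pairs never co-drawn are reported
missing (NaN), not zero. Since the correlation distance between two samples
does not depend on which other samples were drawn, the full distance matrix
is computed once and indexed per resample — mathematically identical to
recomputing it.

The consensus-degree comparison takes the upper-triangle within-reference
consensus values versus the reference-vs-group values, Mann–Whitney
two-sided per group, BH across groups. All-constant identical inputs (e.g.
an all-ones consensus) are defined as p = 1 rather than delegated to the
rank test, whose tie correction degenerates there.

## Relatedness network

Bin intervals are implemented as exact integer sets {0}, [1,999],
[1000,4999], [5000,9999], [10000,14999]; a count ≥ 15,000 produces no edge.
One graph is built with bin-labelled edges (equivalent to five thresholded
networks read together). Isolated groups are annotated with their
minimum-count partner and the exact count; ties keep all tied partners.
Layout and aesthetics are left to consumers; the artifact emits structure
(GraphML and a flat edge TSV) only.

## TSS direction calls and enrichment

"TSS probe" means the manifest TSS flag (modelling the TSS200/TSS1500
categories). The contrast orientation must be explicit
(`lesion_is_group_b`); positive lesion-oriented delta (hypermethylated
promoter) marks the gene inhibited, negative activated. A gene with
conflicting probe signs is assigned by the sign of its mean delta and
logged; an exactly cancelling gene gets no direction. The enrichment
universe is the genes with ≥ 1 TSS probe surviving filters — the universe
defines the hypergeometric margin, so removing genes from it changes p by
design. The test is one-sided over-representation (upper tail including the
observed overlap), BH across sets.

## Deconvolution

Gene activity = 1 − mean TSS beta is the simplest monotone promoter-
methylation-to-expression surrogate and is exposed as a pluggable
transform. The constrained least-squares problem min‖Sf−a‖², f ≥ 0,
Σf = 1 is solved two ways: the default augments the system with a
sum-to-one row weighted 10⁴ and solves NNLS (renormalising the ~10⁻⁸
residual slack), and an exact KKT active-set solver for the
equality-constrained problem serves as the reference; the test suite
requires agreement within 10⁻⁶ and checks the active-set solution against
exhaustive support enumeration and grid search. Recovery on 200 Dirichlet
mixtures of 4 types with noise at 5% of the signature's signal SD: RMSE
< 0.05 per entry, per-type bias < 0.01. Group comparison of fractions uses
the Shapiro–Wilk gate at α = 0.05 per group: unpaired Welch t when both
groups pass, Mann–Whitney otherwise, with star categories at 0.05, 0.01,
10⁻³ and 10⁻⁴.

## Pipeline

Stages write into a run directory with a `.done` sentinel each and a
manifest (seed, parameter hash, full parameter dump); re-running skips
completed stages unless forced, and identical config + seed reproduce
outputs byte-identically. Every random stage takes an explicit seed. The
bundled problem sizes (430 × 20,000 cohort, B = 200, 10,000 selected CpGs)
complete the full default run in about a minute on one CPU.

## Known limitations

- The planted model has homogeneous within-group noise; real cohorts mix
  materials and batches, and the pipeline deliberately contains no batch
  correction (none was described for the motivating analysis).
- The promoter-activity transform is a stated surrogate, not a validated
  expression predictor; the deconvolution results demonstrate solver
  correctness on synthetic mixtures, not biological fidelity of the
  reference.
- The moderated test assumes exchangeable per-probe variances around one
  prior; strongly stratified variance structure (e.g. probe-type mixtures)
  would call for a stratified prior, which is not implemented.
- DMP analysis is two-group only: no covariates, no contrast matrices, no
  region-level (DMR) aggregation.
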