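# Methods

`oncostrat` re-implements, as a tested pipeline, a common tumor-transcriptome
stratification workflow: split a cohort at the median expression of a single
marker gene, characterize the two strata molecularly (differential
signatures, gene-set enrichment, an oncoactivity score), transfer the
stratification to external cohorts by nearest-template prediction, and
relate the strata to outcome. This note records the statistical model behind
each stage, the defaults and why, and what the synthetic test bed does and
does not establish.

## Stratification

Samples are labeled HIGH if the marker's log2 expression strictly exceeds
the cohort median and LOW otherwise. Ties at the median go to LOW, so an
odd-sized cohort with distinct values splits (n+1)/2 LOW vs (n−1)/2 HIGH —
the arithmetic a 371-patient cohort needs to produce a 186/185 split. The
split is invariant under any strictly monotone transform of the marker.

Variable genes are selected by raw median absolute deviation
(median |x − median(x)|) above a threshold (default 0.5 log2 units). The
1.4826 normal-consistency constant is *not* applied by default — the
threshold is conventional, and the raw statistic is the simpler default —
but it can be supplied via the `scale` argument.

Concordance between strata and unsupervised structure: samples are clustered
into k=2 by average-linkage agglomeration on 1 − Pearson correlation over
the variable genes (the most common transcriptome convention; distance and
linkage are not canonical and other choices are defensible). The two
clusters are matched to the two strata bijectively, by the assignment that
maximizes total agreement; per-stratum concordance is reported under that
matching. A "majority cluster per stratum" rule was rejected: with one
dominant cluster it scores ~1 for both strata at zero effect, which makes
the statistic useless as a separation measure.

## Differential expression

Per gene, the observed statistic is the Welch (unequal-variance) t between
strata on log2 values; the unequal-variance form is safer when the median
split is unbalanced after ties. "Fold change" is the difference of group
log2 means (mean HIGH − mean LOW), the only scale on which thresholds like
0.5 or 1.0 are coherent for log expression.

The null is built by relabeling samples with the group sizes fixed.
P-values carry the +1 correction, p = (1 + #{|t₀| ≥ |t|})/(1 + n_null), so
p > 0 and the test is valid at finite permutation counts. Two null modes:

* **gene-wise** (`pooled_null=False`): each gene compared to its own
  relabeled statistics; exact exchangeability, resolution 1/(n_perm+1).
* **pooled** (`pooled_null=True`, default): null statistics pooled across
  genes, n_null = n_perm × n_genes. This reaches the very small p-values a
  stringent signature threshold needs (e.g. 10⁻⁶) at ~10³ permutations, at
  the cost of assuming the null t distribution is exchangeable across genes
  — reasonable for homoscedastic log expression, documented as a knob.

An `exhaustive=True` mode enumerates all C(n, n_high) relabelings for small
cohorts; it is the oracle the sampled test is validated against. Signatures
threshold on p and |fc|: up_in_high = {p < p_max, fc > fc_min}, up_in_low
symmetric. Tightening either threshold can only shrink the sets.

## Enrichment scoring

All enrichment statistics are the classic weighted Kolmogorov–Smirnov
running sum: walking down a ranked gene list, set members increment by
|metric|^w normalized by the total hit weight, non-members decrement by
1/(N − n_hits); the enrichment score (ES) is the signed extremum, so
ES ∈ [−1, 1].

* **Two-group GSEA**: genes ranked by signal-to-noise
  (μ_H − μ_L)/(s_H + s_L), each SD floored at max(0.2·|μ|, 0.2) for
  stability; weight w = 1. Significance by phenotype permutation;
  NES = ES / mean(|null ES| of matching sign) and the nominal p is the
  +1-corrected same-sign tail — the classic normalization, since no formula
  is canonical in print.
* **Per-sample ES**: genes ranked by expression *within the sample*; the
  hit metric is the rank weight (N − rank + 1) raised to w = 0.25 (the
  usual single-sample exponent). Using rank weights rather than raw values
  makes each sample's score a pure function of its ordering: invariant to
  per-sample shifts, scalings, or any monotone transform (exactly invariant
  at w = 0). No cross-sample normalization is applied, so each score is a
  genuinely per-sample statistic.
* **Oncoactivity** = per-sample ES over an oncogene set minus per-sample ES
  over a tumor-suppressor set. Identities that hold exactly: zero when the
  two sets coincide; negation under swapping the sets.

Group comparison of per-sample scores uses the two-sided Wilcoxon rank-sum
test (exact enumeration when both groups ≤ 10 and untied, normal
approximation otherwise).

Ties in any ranking are broken by gene symbol so results are identical
across platforms.

## Nearest-template prediction

The signature defines two mirror templates over its genes: +1 on up-in-A,
−1 on up-in-B, and the negation for class B. Sample profiles over the
template genes are z-scored across samples; the distance to each template is
1 − cosine similarity (∈ [0, 2]) and the nearest template is the candidate
call. Significance: n_null random sign-permutations of the template (same
+/− composition, controlling for signature imbalance) give a null distance
distribution per sample; p is the +1-corrected fraction at least as close.
Benjamini–Hochberg across samples converts p to FDR; samples whose best
match fails the FDR threshold (default 0.05) are reported N.D. The exact
null construction and metric are not canonical in the literature this
follows; the implemented contract (cosine to ±1 templates, composition-
preserving resampled null, BH across samples) is one defensible and fully
specified reading. At least half the signature genes (configurable) must be
present in the target matrix — pooled microarray cohorts lose genes, and a
silent heavy loss would bias calls.

## Survival and association statistics

Kaplan–Meier curves and the 2-group log-rank test are delegated to
lifelines. The Cox proportional-hazards model is fit natively by
Newton–Raphson (with step-halving) on the partial likelihood, because the
package needs Breslow in addition to Efron tie handling and the score test
at β = 0, which off-the-shelf fitters do not expose; coefficients and
standard errors are cross-checked against lifelines in the test suite.
Efron is the default tie correction (more accurate with month-granularity
ties). Convergence is declared at a relative log-likelihood change < 1e-9
(50 iteration cap); non-convergence or |β| > 50 flags a possible monotone
likelihood. Confidence intervals and p-values are Wald (exp(β ± 1.96·SE)),
i.e. the symmetric-on-log-scale intervals clinical tables print. The score
test at β = 0 with a single binary covariate reproduces the log-rank
chi-square to numerical precision when event times are untied — a classical
identity the suite asserts.

Zero survival times (a same-month event under whole-month follow-up) are
bumped to half the smallest positive time, with a warning.

Fisher's exact test reports the sample odds ratio ad/bc and a two-sided p
under either the minimum-likelihood convention (default; the R convention)
or the doubled-one-sided convention — published clinical tables use both,
and the two can differ by more than trivial rounding on moderately sized
tables. Chi-square is the Pearson statistic with optional Yates correction
(2×2 only); the two-sample t-test offers pooled-variance and Welch forms.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: per gene,
expression is Normal(μ_g + effects, σ) on the log2 scale with baselines
μ_g ~ Uniform(2, 12) (spanning realistic log intensities without modeling
counts); a balanced latent subtype; a configurable fraction of DEGs shifted
by δ between subtypes (half up in each); the marker gene shifted by its own
δ; optional additive per-dataset batch shifts; exponential survival with
hazard λ (marker-HIGH) vs λ·HR (marker-LOW) under administrative censoring;
and clinical covariates (age, a vascular-invasion flag, a serum-marker
flag) with subtype-dependent distributions. Oncogene-like/TSG-like sets mix
a configurable fraction of truly-up genes with null genes; their default
sizes are 3.5% and 5.5% of the gene universe, the genome-wide proportions
of the curated oncogene (674/~20k) and tumor-suppressor (1088/~20k) lists.

Defaults — 200 samples, 2000 genes, 8% DEGs at δ = 1.0, σ = 0.5, marker
δ = 1.5, HR = 2.0, baseline hazard 0.02/month, censoring at 120 months —
are a desk-scale rendering of a few-hundred-patient cohort with clear but
imperfect molecular separation; problem sizes in the tests and the
acceptance script are chosen at this scale.

Randomness is organized as named substreams of one global seed, so changing
one component's parameters never perturbs another's draws, and the whole
pipeline is byte-reproducible from (config, seed). A separate
`structure_seed` controls the gene-level structure (baselines, DEG
identities, set membership): two cohorts sharing it but differing in `seed`
model an external validation cohort — same disease biology, new patients.

What the generator does *not* model, and hence what passing tests do not
establish about real data: count noise (no negative-binomial layer),
gene–gene correlation beyond the subtype factor, probe-level artifacts,
non-proportional hazards, informative censoring, and confounding between
batch and subtype. Recovery rates measured here are upper bounds for real
cohorts.

## Numerical and degenerate-input choices

* Constant genes get t = 0 and permutation p = 1 (with a warning), never NaN.
* Zero-variance template genes are dropped before z-scoring; an all-constant
  matrix is an error, not a silent zero.
* Duplicate gene symbols at load keep the row with the highest mean
  (deterministic, the common convention); symbols are uppercased everywhere.
* Batch adjustment is per-dataset median centering behind an `adjust`
  switch — a location-only stand-in for empirical-Bayes batch correction,
  idempotent and exactly testable. It does not adjust scale or covariance.
* All stochastic procedures take explicit seeds; sorts are stable with
  symbol-order tie-breaks.

## Known limitations

Two-class NTP only (multi-class templates are out of scope); no moderated-
variance differential expression; no FDR across gene-set collections
(single-set nominal p only, as reported); no time-varying covariates,
stratified Cox, or proportionality diagnostics; the probe-collapsing rule
for pooling array platforms is unspecified upstream and deliberately not
guessed — inputs are expected to arrive symbol-keyed.
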