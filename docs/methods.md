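# Methods

`lipidmets` implements a consensus workflow for two-group plasma lipidomics
(metabolic syndrome vs. none in a treated-HIV cohort setting), structural
interpretation of the differential signal, and weighted network integration
of the lipidome with a small panel of key polar metabolites and clinical
covariates. This note records the models, the defaults and why, the
numerical choices, and what the synthetic cohort does and does not emulate.

## Nomenclature parsing

Complex-lipid-panel shorthand is parsed into (class, category, total
carbons, total double bonds, annotated fatty acids). Three grammatical forms
are supported: acyl-sum `CLS(c:d)`, enumerated acyls `CLS(a:x/b:y)`, and the
triacylglycerol neutral-loss form `TAG(c:d)-FA(f:g)` where totals come from
the parent ion. Sphingoid long-chain-base prefixes (`d18:1`, `t18:0`, ...)
are stripped and the base chain is summed like any acyl chain, because the
structural maps index sphingolipids by total size and saturation. The class
to category table is data, not code: panels with extra classes parse with
`category="other"` rather than failing. The parser does no chemistry — no
mass computation, no isomer resolution beyond what the shorthand states.

## Preprocessing

Fixed order: per-feature minimum imputation of missing values (zeros are
treated as below-limit-of-detection codes by default, configurable), median
centering (every feature's median becomes 1), near-zero-variance filtering,
then a natural-log transform for the parametric branch only. The rank-based
test runs on the centered (untransformed) data; centering and monotone
transforms do not change its result.

The near-zero-variance rule follows the classical freqRatio/uniqueCut
convention (defaults 19 and 10%): a feature is removed iff its variance is
zero, or its most-common/second-most-common frequency ratio reaches the cut
*and* its percent distinct values falls below the uniqueness cut. Filtering
runs after centering; the fraction removed is data-dependent.

The Kolmogorov-Smirnov normality screen tests each feature against a normal
with estimated mean/sd. With estimated parameters the test is
anticonservative in the Lilliefors sense; it is reported for screening and
never gates any downstream decision.

## Differential abundance

Two univariate arms, both Benjamini-Hochberg adjusted with selection at
FDR < 0.001:

* **Mann-Whitney U**, two-sided. Exact enumeration when the pooled sample
  is ≤ 20 without ties; otherwise the normal approximation with tie and
  continuity corrections.
* **Moderated t.** Per feature, `beta = mean(log MetS) − mean(log no-MetS)`
  with pooled variance `s2` on `d = n−2` df, shrunk toward a prior:
  `s̃² = (d0·s0² + d·s2)/(d0 + d)`, `t = beta/(s̃·√(1/n1+1/n2))` on
  `d0 + d` df. The prior `(d0, s0²)` comes from matching the mean and
  variance of `log s2` to their scaled-F expectations; the trigamma
  equation is solved by a monotone Newton iteration. When the observed
  spread of log-variances does not exceed pure sampling noise the prior df
  is infinite and `s0²` is set to the geometric mean of the `s2`, which
  makes the all-equal-variance case an exact no-op. Setting `d0 = 0`
  recovers the ordinary equal-variance t-test identically. The model is the
  two-group special case only — no covariates, no contrast matrices, no
  trend or robust variants.

## Multivariate selection

**PLS-DA** on standardized log abundances with ±1-coded, centered response
(NIPALS backend). Per-feature importance is
`VIP_j = √(p · Σ_a w_ja² SSY_a / Σ_a SSY_a)`; the mean of squared VIPs is
identically 1, so VIP > 1 marks above-average contribution and can never
select every feature unless all are equal. Model quality is Q2Y =
1 − PRESS/TSS from stratified k-fold (default 7) cross-validation; negative
values mean worse than predicting the mean.

**rdCV random forest.** Repeated double cross-validation: outer folds
(default 6, 5 repetitions) are held out entirely; within each outer
training set an inner CV repeatedly drops the lowest-importance fraction of
features (default keep-ratio 0.75), recording validation misclassification
per feature count. Importance is the forest's Gini importance, refit at
every elimination step — the convention of the rdCV variable-selection
method this follows. From the averaged inner curve three counts are taken:
`min` (fewest features within 5% of the curve minimum), `max` (most
features within that tolerance) and `mid` (rounded geometric mean); final
Min/Mid/Max sets are the top features by average elimination rank. AUROC is
computed exclusively from outer-fold predictions, so reported performance
never touches samples used for selection; a pure-noise input therefore
scores near 0.5 regardless of dimensionality.

**Consensus** intersects the four selected sets (Mann-Whitney q<0.001,
moderated-t q<0.001, VIP>1, and the RF `Max` set) and reports all 2^4−1
exclusive intersection sizes in UpSet form.

## Structural composition

Moderated-model effects are aggregated into per-class cells indexed by
(total carbons, total double bonds): cell effect = mean beta of member
species, cell q = minimum member q, significant iff q < 0.01. The per-class
trend is `increase`/`decrease` when ≥ 2/3 of significant cells share a
sign, `mixed` otherwise; classes with no significant cell are omitted. A
reported joint condition of the published figure ("FDR<0.01 and Pearson's
r>0.7") has no defined referent for the correlation; only the FDR condition
is implemented.

## Network integration

All-pairs Spearman correlation over the combined lipid + metabolite log
matrix, two-sided p from the t approximation, BH across all pairs. Edges
require `q ≤ 1e-07` **and** `rho ≥ 0.38` (both configurable) and are
positive-weighted by rho; negative correlations are never edges. Nodes are
the features incident to at least one retained edge — features with no
passing correlation are not part of the network. Constant features are
excluded with a warning.

The topology is compared against `n_draws` G(n, m) Erdős–Rényi graphs with
matched node and edge counts: degree variance, global clustering, mean
shortest path on the largest component, and degree-distribution
Jensen-Shannon divergence, with a 99% null envelope; the network is flagged
markedly distinct when any observed metric leaves its envelope.

Communities come from the Leiden algorithm on weighted modularity
(configurable resolution, fixed seed recorded in outputs, default 1);
labels are re-indexed by decreasing size. Hubs are the top decile by degree
(weighted degree, then lexicographic id, break ties), so the hub set is
invariant to edge-weight rescaling.

Community-clinical association regresses each clinical variable on a
per-sample community score — the mean of member z-scores by default
(`community_score: pc1` switches to the first principal component, sign
aligned with the mean-z score). Binary variables use logistic regression
with the likelihood-ratio p-value (robust when a score separates the groups
perfectly, where the Wald statistic degenerates); continuous variables use
ordinary least squares. BH runs across all community × variable tests;
the default report cut is FDR < 0.12 for communities and < 0.01 for
feature-level association. The regression direction (clinical ~ score) is
chosen so a positive estimate reads "higher community abundance, higher
odds/value of the clinical variable".

Over-representation of annotation terms in a community uses the upper-tail
hypergeometric test against a user-supplied term → members table, with all
network features as background, BH across terms. No lipid-ontology web
service is called; the annotation table is an input.

## Cohort table

Continuous variables: mean (sd) and Mann-Whitney U. Categorical: n (%) per
level and Pearson chi-square (Yates-corrected iff 2×2, df = k−1); a 2×2
with a zero margin or an expected cell below 1 falls back to Fisher's exact
test — this includes rare-exposure rows like a 0-vs-3 antiretroviral class.
Human-readable p-values print with two decimals and "<0.001" below that;
TSVs keep full precision.

## Synthetic cohort generator

The generator defines the study conditions for every test: 100 + 100
samples, 917 lipids (602 glycerolipids, 228 glycerophospholipids, 61
sphingolipids, 26 steroids; within-category class inventory is a plausible
panel-like split, e.g. ~85% of glycerolipids are TAG neutral-loss species),
11 metabolites, 13 clinical variables.

Concentrations are multiplicative log-normal: `log2 x = base + beta·group +
noise_sd·eps` with per-feature baselines ~N(0, 1.5) and `noise_sd = 0.5`.
The group effect (`effect_log2fc = 1.0`) is planted on a random 5% of
DAG/TAG species — confining truth to those classes makes class-level
recovery an assertable property. A Gaussian-copula block (pairwise
correlation 0.5) ties the planted lipids to a 6-metabolite
glutamate-pathway-like sub-block that carries the same group shift; a
second, unshifted DAG/TAG block of matched size provides a second network
community. Missingness is MNAR at the low end: per feature, a
Binomial(n, 0.02) count of the smallest draws is zeroed, matching
minimum-imputation semantics. The clinical table reproduces the cohort's
marginal composition (90% male, age ~N(54.5, 9), visceral and subcutaneous
adipose tissue up-shifted under MetS, per-group antiretroviral exposure
rates), so the cohort table recovers a significant VAT difference by
construction. Generation is a pure function of (config, seed).

What this does **not** emulate: real panel concentration distributions and
their heavy inter-class correlation (real lipidomes give orders of
magnitude more network edges), batch effects, longitudinal structure, or
realistic effect sizes for the differential species — the planted defaults
are chosen for testability. Passing tests demonstrate correctness of the
machinery and calibration under the generator's assumptions, not field
performance on real cohorts.

## Problem sizes used in the test and acceptance runs

The unit and property suites run on reduced cohorts (e.g. 190 features ×
80 samples, with a lighter rdCV schedule of 1–2 repetitions and 4–5 outer
folds) chosen as the package's own desk-scale defaults for fast, exact
property checks; the acceptance script runs the complete default cohort
(917 × 200) with the orchestrated pipeline's default rdCV schedule of
2 repetitions × 5 outer folds, keep-ratio 0.6 and 50 trees — a schedule
chosen so a full-cohort nested CV stays interactive. All resampling
parameters are config-exposed; the standalone selector's defaults
(5 × 6, keep-ratio 0.75) follow the rdCV method's original conventions.

## Known limitations

* The moderated model supports no covariate adjustment; matching variables
  (age, sex) are not regressed out of the differential tests.
* The KS normality screen is anticonservative with estimated parameters.
* The composition map's significance flag uses the best (minimum) q in a
  cell, which is liberal for many-species cells; the per-species table is
  exported for finer control.
* Whether community "average degree" should count within-community edges
  only is ambiguous; the full-network degree is used.
* Fisher fallback diverges from a published table footnote that marks a
  0-vs-3 row as rank-tested; a sparse 2×2 is not a rank-test problem, so
  the dispatcher uses Fisher and documents the divergence.
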