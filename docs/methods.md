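# Methods

## Data model

The central object is a samples × metabolites table of 24-h urinary
excretion amounts (µmol) with per-sample metadata (subject, study arm,
dose/visit) and per-variable annotations. Eleven conjugated metabolites
are modelled, each mapped to one parent aglycone group — 3′OH-PVL (2
conjugates), 4′OH-PVL (1), 3′4′diOH-PVL (6) and HPP (2) — and one
conjugate class (sulfate, glucuronide, sulfo-glucuronide, free aglycone,
methoxy-sulfate). Summing within aglycone groups produces the 4-variable
table; a missing addend makes the sum missing (`missing_as_zero` exists but
silent zero-imputation would bias cluster means, so it is off by default).

For sulfate/glucuronide ratios, the sulfate side is {3′-sulfate,
mono-sulfate (3′,4′), methoxy-sulfate, PPA-sulfate} and the glucuronide
side the five glucuronides; the sulfo-glucuronide diconjugate and the free
aglycone belong to neither class and are excluded. Whether the
methoxy-sulfate counts as a sulfate is genuinely ambiguous in the field's
reporting conventions; `include_methoxy_sulfate` covers both readings
(default: included). A zero glucuronide sum yields an undefined (NaN)
ratio, never infinity; undefined ratios are excluded pairwise from
correlations and the exclusion count is logged. The sulfate-dominance
threshold is fixed at 1.1.

## Pre-treatment

Transforms: identity, log₁₀(C₁x + C₂) and (C₁x + C₂)^C₃ with defaults
C₁ = 1, C₂ = 0, C₃ = 2. Non-positive log arguments become missing rather
than errors: near-zero excretion of minor metabolites is a real feature of
these data and the missing-tolerant PCA carries the resulting holes.
Scaling: none, mean-centering, centering + unit-variance (divide by SD) and
centering + Pareto (divide by √SD). SDs use the n−1 divisor (the common
chemometrics convention; nothing in the problem fixes the choice, so it is
fixed here and documented). Zero-variance columns are centered but not
divided, and flagged. The full grid is 3 × 4 × 2 datasets = 24 specs in
deterministic dataset-major order.

## PCA

Complete matrices are decomposed exactly by SVD (the sequential-deflation
solution coincides with it). Incomplete matrices are fitted by EM-style
iterative imputation: alternate a rank-A SVD of the completed matrix with
re-imputation of missing cells from the reconstruction, starting from
column means, stopping when the observed-cell residual sum of squares
stops improving (relative tolerance 1e-5, cap 2000 iterations). An
earlier scheme that skipped missing cells inside NIPALS inner products was
abandoned: its scores diverge when a row's observed columns all carry
near-zero loadings, a failure mode the diagonal-deletion cross-validation
below reliably triggers. Component signs follow the
largest-|loading|-positive rule so reports are reproducible. R²X is
computed on observed cells, sequentially per component.

Q² uses element-wise cross-validation with a deterministic diagonal-stripe
pattern: fold f of 7 deletes cells (i + j) mod 7 = f. Deleted cells are
predicted by a one-shot projection: loadings are fitted on the fold's
remaining cells (column-mean-completed SVD) and each row's held-out cells
are predicted from the least-squares projection of its remaining cells
onto those loadings. Fully iterated imputation is deliberately *not* used
for prediction: the observed-cell least-squares problem is ill-posed for
high-leverage rows and its held-out predictions are unbounded (observed
numerically: PRESS two orders of magnitude above the total sum of
squares). Q² = 1 − PRESS/SS may be negative; structure-free matrices
reliably produce Q² ≤ 0 while noiseless low-rank matrices give Q² near 1.

Hotelling T² at α = 0.05 uses the two-component F-based critical value
A(n²−1)/(n(n−A)) · F₁₋α;A,n−A. Flags are informational only — no sample is
ever removed, since no profile of metabolite excretion is "wrong".

## Clustering

All partitioners run on autoscaled data. PAM is a classical build+swap
implementation; fuzzy c-means uses fuzzifier m = 2 and hardens by maximal
membership; hierarchical clustering is Ward on Euclidean distances; EM is
a Gaussian mixture with diagonal covariance by default (83 samples × 11
variables make full covariance fragile; configurable). H-Kmeans, H-PAM and
H-fuzzy initialize k-means centers / medoids / memberships from the Ward
cut; HCPC applies Ward to PCA scores retaining ≥ 80% of variance
(configurable) followed by a k-means consolidation pass. Empty clusters
after hardening trigger seeded retries (cap 5). Labels are canonicalized
by first appearance.

### Number of clusters

Twenty-five internal validity indices vote per algorithm × repeat over
k ∈ [2, 10] (5 repeats, repeat r seeded base+r). Only three panel members
are forced by the workflow's description (Ball–Hall, Banfield–Raftery,
C-index); the remaining 22 are standard indices chosen to span the
sum-of-squares, determinant, pairwise-concordance and density families,
and the panel is config-replaceable — results always record which panel
voted. Each index declares how its curve is read: plain min/max
(e.g. silhouette max, Davies–Bouldin min), first-difference drop/rise,
second-difference elbow (trace(W), Marriot, det-ratio), or the Hartigan
rule ((W_k/W_{k+1} − 1)(n − k − 1), largest drop). Curve rules anchor at
the trivial k = 1 partition so that k = 2 is votable; indices undefined
for a partition (singular within-cluster scatter, zero denominators)
abstain rather than error. The winning k is the plurality over all votes,
ties broken toward smaller k (parsimony); per-repeat winners are recorded
as a stability diagnostic.

The unweighted variant of the SD index (scat + dis, without the
k_max-dependent weight) is used because indices are evaluated per
partition, without knowledge of the search range. S_Dbw uses the average
per-cluster variance-norm radius for its density counts. Cluster-internal
variances use the population (1/n_q) convention throughout the panel.

### Consensus and PC-score groups

Partitions are aligned to a reference by solving the assignment problem on
the k × k contingency table (exact, Hungarian); the final consensus assigns
each observation to its per-observation plurality label over the aligned
partitions of all nine algorithms (one converged run each, configurable to
pool repeats), ties resolved toward the reference partition's label. The
vote table is exported alongside the labels.

PC-score clustering takes the first two score columns of a PCA of
autoscaled data: 2-group mode splits on the sign of PC2; 3-group mode
assigns (PC1 ≥ 0, PC2 ≥ 0) → 1, (PC1 ≥ 0, PC2 < 0) → 2, PC1 < 0 → 3. A
score of exactly zero counts as positive (the convention is documented
because the underlying description speaks only of positive/negative).

## PLS-DA

PLS2 NIPALS of autoscaled X against the centered one-hot class matrix,
deflating X per component; two components by default. VIP_j =
√(p · Σ_a SSY_a (w_aj/‖w_a‖)² / Σ_a SSY_a), so Σ VIP² = p identically;
variables with VIP strictly > 1 form the selected set. Q² is residual-
based (raw dummy prediction error, not classification error) under
stratified row-wise 7-fold cross-validation with autoscaling refit per
training fold; folds that would drop a class from training are
re-stratified. The permutation test refits the model under uniformly
permuted labels and reports the add-one p-value
(1 + #{null Q² ≥ observed})/(1 + n_perm). CV-ANOVA is an F-test on
cross-validated residuals, F = ((SSY − PRESS)/d₁)/(PRESS/d₂) with
d₁ = A·M and d₂ = M(N − A − 1) for M dummy columns; when the model does
not beat the class-mean null (PRESS ≥ SSY) the p-value is 1. The exact
degrees-of-freedom bookkeeping of commercial implementations is not
public, so this variant is validated by its calibration (type-I error ≤
10% at nominal 5% in the acceptance suite) rather than by matching any
particular printed p-value.

## Univariate statistics

Normality is checked per group by the Kolmogorov–Smirnov statistic with
Lilliefors critical values (plain KS with estimated moments is
anti-conservative); groups of fewer than 4 observations cannot be assessed
and default to the parametric branch. Two groups: Welch t when both pass,
Mann–Whitney U otherwise. Three or more: Welch ANOVA with a Dunnett's
T3-style pairwise post hoc when all pass — implemented as pairwise Welch t
with Šidák adjustment on Welch degrees of freedom, a conservative
surrogate for the studentized-maximum-modulus reference distribution,
chosen because the workflow has no control group that a
control-vs-treatment Dunnett would need — otherwise Kruskal–Wallis with
Dunn's z-tests, Bonferroni-adjusted. Compact letter displays come from
insert-and-absorb on the pairwise significance graph: groups sharing a
letter are not significantly different. All tests are two-sided at
α = 0.05 with no correction across metabolites by default
(Benjamini–Hochberg available, off by default, matching the workflow's
raw-p reporting convention).

## Synthetic cohorts

The generator reproduces the pooled two-study design: 10 acute subjects ×
4 doses (716/1131/1396/1741 mg total flavan-3-ols) plus 22 chronic
subjects × 2 visits with one missing visit-1 sample — 83 observations, 32
subjects. Each subject draws a latent metabotype (default two: low
excretors 65/83, high excretors 18/83, matching the reference
cluster-conditional moments; a 3-group preset with sizes 11/15/57 mirrors
the PC-score phenotypes). Log-amounts are

log x_isj = μ_gj + σ_gj (a·u_i + b·δ_j·s_i + c_j·ε_isj)

with u_i ~ N(0,1) the subject profile effect, s_i ~ N(0,1) the subject
sulfation propensity acting with sign δ_j = +1 on sulfate-side columns and
−1 on glucuronides (0 elsewhere, where c_j absorbs the share so every
column's total log-variance is exactly σ²_gj), and ε iid residual noise;
a² + (bδ_j)² + c_j² = 1. (μ_gj, σ_gj) are moment-matched on the natural
scale to the reference per-cluster means and SDs, so simulated
cluster-conditional moments are unbiased for their targets (verified to
max |z| ≈ 2 over 200 seeds). Defaults: a = 0.5 (a quarter of log-variance
is subject-level, enough that a subject's repeated samples sit markedly
closer together than samples of different subjects — the conservation
structure the workflow expects) and b = 0.65, calibrated once so that
about 2 of 32 subjects exceed the 1.1 sulfate-dominance threshold while
the cohort median ratio stays near 0.2 (glucuronide-dominant). Dose/visit
has no systematic effect by default (a dose-slope hook exists) because the
emulated data showed no treatment pattern. Lognormal margins are the
natural choice for non-negative amounts whose SDs are of the order of
their means.

What the generator does *not* emulate: analytical (LC-MS) measurement
error and quantification-standard substitution effects, pharmacokinetic
time-courses within the collection window, covariance between aglycone
groups beyond the shared subject effects, and microbiome covariates.
Passing recovery tests on these cohorts therefore demonstrates that the
workflow recovers subject-level mixture structure of the stated effect
sizes under realistic skewness and repeated-measures correlation — not
that it would recover metabotypes from any particular real cohort.

A known tension, documented rather than hidden: the reference
cluster-conditional moments describe *realized* clusters (output of a
partitioning, hence disjoint regions of sample space), while the generator
necessarily treats them as latent mixture components, which overlap. At
these effect sizes a parameter-aware Bayes classifier recovers the labels
almost perfectly, but unsupervised clustering plateaus around ARI 0.8
median with roughly half of replicates at or above 0.8 — boundary subjects
whose random effect carries them toward the other component are
intrinsically ambiguous. The acceptance suite states the stricter
recovery bound and reports honestly against it.

## Pipeline

`run_full` executes: simulate/read → aggregate → 24-model grid report →
k selection (index voting; or fixed k) → the five carried-forward
clustering methods (final consensus, k-means, EM, PC-score 2- and
3-group) on both datasets → one PLS-DA per method per dataset (10 models)
→ univariate summaries per method → ratio report. Every stochastic stage
derives its seed from the run config; identical config + seed gives
byte-identical CSV outputs. The acceptance script uses 20 seeded
replicates for the recovery and ratio statistics and one cohort for the
structural, k-selection and PLS-DA quantities; problem sizes match the
emulated design (n = 83) throughout.
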