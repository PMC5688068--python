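# Methods

## Scope and data model

The package re-implements, over synthetic data, a two-group urinary-VOC
biomarker analysis: feature tables of SPME GC-MS peak areas (injections x
compounds) with subject, group (NW vs OW/Ob), replicate and pH-condition
metadata. Absent peaks are a true missing mark (NaN), never zero: an absent
peak means the compound was not detected in that injection, and how that
absence is handled (imputation vs feature dropping) is an explicit, tested
policy rather than an accident of encoding.

## Synthetic cohorts

`CohortSpec`/`generate_cohort` draw, per compound j: a log-SD
`sigma_j ~ U[0.3, 1.0]` and a log-mean `mu_j ~ U[-1, 2]` (log-normal
abundances match right-skewed peak-area ratios and make "log then autoscale"
the natural preprocessing); subject-level log abundances
`mu_j + sigma_j z_ij`; for informative compounds a group-2 shift of
`effect_size * sigma_j` with a random sign, applied **before** replicate
noise so the planted difference survives the median-of-triplicates step;
presence per subject x compound with probability `occurrence_prob_j`
(absence removes all replicates of that subject's peak); `n_replicates`
technical replicates with multiplicative log-normal noise of coefficient of
variation `replicate_cv`; and six internal-standard peaks (log-SD 0.1, full
occurrence, no group effect), mirroring the six spiked standards of the
assay. Identical seeds give byte-identical tables.

Defaults are the study conditions: 28 + 21 subjects, triplicates,
`replicate_cv = 0.15` (a typical technical CV for SPME GC-MS peak areas),
and — for `CohortSpec.from_study_tables` — compound counts (110 acid / 83
alkaline) and occurrence probabilities taken from the packaged
identification tables (mean of the two group columns, floored at one
detectable subject). The benchmark scenarios used by the validation
simulations are 50 compounds with 5 informative at effect 2.0 log-SD and
full occurrence; the planted effect size is a free demonstration parameter,
not an estimate from the study, which reports no marker effect sizes on an
interpretable scale.

What the generator does **not** emulate: retention-time structure,
instrument drift, batch effects, correlated compound families, or
non-log-normal heavy tails. Passing recovery tests therefore show the
selection machinery works under the model's assumptions, not that the
original biological findings replicate.

## Preprocessing

Fixed chain: internal-standard ratio (per injection; each compound divided
by its mapped standard, standards dropped) -> median of replicates (cell
missing iff all replicates missing; idempotent) -> imputation
(`half_min` default: half the compound's minimum observed value, the usual
GC-MS detection-floor convention; `drop_feature` available for sensitivity
analysis) -> natural log -> autoscale (sample SD, n−1). Compounds missing
everywhere or constant are dropped with a logged warning, never an
exception. The study does not state which standard normalizes which
compound; the mapping is user-supplied, with a round-robin default for
synthetic data where the standards carry no signal.

Autoscaled log columns are invariant to rescaling raw peak areas by a
positive constant, and every step commutes with subject reordering (both
tested).

## Cohort-table utilities

The two-group p-values of the cohort characteristics table are reproduced
by Welch's t-test computed from the printed mean ± SD and n. Age (0.288)
and HOMA-IR (0.794) reproduce to the printed precision; the Height row
(printed 0.364, Welch and pooled t both ≈ 0.60) does not reproduce under
any standard two-sample t on the printed summaries and is left as a
discrepancy rather than forced. Glucose (0.879 vs 0.865) and protein
intake (0.658 vs 0.696) differ at the third decimal, consistent with
p-values computed from unrounded data. HOMA-IR = insulin (mU/L) x glucose
(mmol/L) / 22.5.

Kovats retention indices support the van den Dool (linear) form as default
— appropriate for the temperature-programmed oven — and the original
isothermal (logarithmic) form, against a C8–C20 alkane ladder.

## Multivariate modeling

PLS-DA is single-response NIPALS PLS on the autoscaled matrix with y
encoded ±1 and centered; for one response the weight iteration converges
in a single step (`w = X'y/‖X'y‖`), with X deflated per component. The
regression vector is `B = W(P'W)⁻¹c`; with A = rank the model reproduces
ordinary least squares (tested). VIP uses the standard Wold formula with
`SSY_a = c_a² t_a't_a`.

Cross-validation is stratified k-fold (default 7) with re-centering and
re-scaling inside each training fold; Q² uses one pooled PRESS over the
concatenated held-out predictions (SIMCA convention), and the held-out
continuous predictions also give a cross-validated AUC. The number of
components, when requested as `"auto"`, is the smallest A maximizing Q²
for A ≤ 5; the shipped analyses fix A = 2. The permutation test re-runs
the full CV pipeline on label-shuffled responses and reports
`p = (1 + #{null ≥ observed})/(1 + n_perm)`; the default statistic is the
cross-validated AUC, with Q² available.

Post-transformation: with `v = T'y`, an orthogonal rotation R whose first
column is `v/‖v‖` is applied to scores, weights and loadings (y-loadings
contravariantly), leaving exactly one component with nonzero covariance
with y. Predictions, B, and the score-space Gramian are unchanged (tested
to 1e-8); this is the predictive/orthogonal decomposition used in the
chemometrics literature, and an O-PLS-style filter satisfying the same
invariants would be interchangeable.

Outlier screening computes Hotelling's T² from PCA scores
(limit `A(n−1)(n+1)/(n(n−A)) F(A, n−A)`) and DModX as the per-observation
residual SD over the pooled residual SD (limit
`sqrt(F(p−A, (n−A−1)(p−A)))`). The exact DModX convention differs between
software lineages; this one is chosen for its testable calibration. The
95% level is interpreted as the **family** level of the combined screen:
each statistic is tested at the Šidák-split level `1 − sqrt(1 − α)`, so
on null data the union flags ≈ 5% (two independent per-test 5% limits
would flag ≈ 9.8%). Calibration is verified by simulation.

## Selection

Stability selection: per subsample (subjects kept independently with
probability 0.70; redrawn if a class has fewer than two members), a PLS-DA
model is fitted on the re-autoscaled subsample and the VIP threshold is
chosen from the grid {0.8, 0.9, 1.0, 1.1, 1.2, 1.5} to maximize Q² under
7-fold CV restricted to surviving compounds (ties prefer the larger
threshold, i.e. fewer compounds; the grid is a design choice — the
protocol states the criterion but not the candidate set). The reduced
model then scores the excluded subjects; an AUC is recorded only when both
classes appear among them (else the subsample contributes no AUC, logged).
The "most frequently selected" rule is made explicit as a frequency cutoff,
default 0.5, with the full frequency vector always reported so any cutoff
can be applied post hoc. The degenerate configuration (one subsample,
inclusion 1.0) reduces to a single full-data fit with an empty AUC
distribution, flagged by a warning.

Univariate battery, per compound on log-scale (pre-autoscaling) values —
the t statistic is invariant to the global autoscaling (tested), log scale
is kept for interpretability: Welch t; q-values by Storey's estimator with
the smoother π₀ (cubic smoothing spline of π₀(λ) over λ = 0.05…0.95
evaluated at 0.95, clipped to [1/m, 1]), BH available; oriented
Mann-Whitney AUC (ties ½) with direction annotation from which group has
higher values; DeLong CI (placement-value variance, normal interval,
clipped; bootstrap fallback when the variance degenerates, e.g. complete
separation); sensitivity/specificity at the Youden-optimal cutpoint with
ties broken toward specificity; post-hoc t power via the noncentral-t
distribution at the observed pooled standardized difference; ROC power via
a two-sided normal test of AUC = 0.5 with the Mann-Whitney null variance
and the Hanley-McNeil alternative variance (agrees with binormal
Monte-Carlo within 0.05 at AUC 0.75, n = 28/21).

Merge rule: markers are the union of the stability-selected set and the
compounds passing p < 0.05 AND q < 0.1 AND oriented AUC > 0.50 (the AUC
gate uses the point estimate; the CI is reported alongside). Applying this
gate to the printed 14-marker table passes exactly 12 rows — the two
failures (p = 0.050; p = 0.076 with q = 0.11) are precisely why the union
with stability selection is needed to obtain all 14.

The pipeline gates the multivariate arm on the permutation test
(α = 0.05): stability-selected compounds are claimed as markers only for a
validated model, mirroring the study's treatment of the acid condition
(model failed permutation; no markers reported). The univariate arm is not
gated, matching the study's independent reporting of per-compound tests.

## Expected null behavior and known limitations

Under a complete null, the probability that at least one of m compounds
passes the q < 0.1 gate is ≈ 0.1 by Simes' equality (larger, ≈ 0.16 at
m = 50, for Storey q, whose π₀ estimate is noisy at this m), and the
permutation gate leaks 5% by construction — so roughly 75–85% of null
cohorts end with an empty marker set, not more. This is a property of the
stated thresholds, not a defect of the implementation; users wanting a
stricter null should lower q_max or raise the frequency cutoff.

Other limitations: PLS-DA is strictly two-class (PLS1); DeLong's interval
undercovers slightly at small n (≈ 0.93–0.94 at n ≈ 100 per class,
simulated); stability frequencies at 100 subsamples (used in the
simulations; the protocol's 300 in the analysis scripts) carry Monte-Carlo
noise of ≈ 0.05; and the synthetic generator's independence across
compounds makes selection easier than on real, correlated GC-MS data.

## Problem sizes of the shipped simulations

Validation simulations use 200 null cohorts x 99 permutations for
permutation-test calibration, 500 subjects for outlier-screen calibration,
and 50 generator seeds for recovery/null rates with 100 subsamples per
stability run; the analysis scripts run the full 300-subsample protocol on
single cohorts. These sizes give binomial standard errors of ~1.5–7
points on the reported rates.
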