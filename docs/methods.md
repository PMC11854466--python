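# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, the synthetic-data model and its limits, and the numerical
conventions that affect results.

## Effect sizes from summary statistics

The replication analysis operates on per-region summary tables (n, mean, SD
per group of eTIV-normalized volume) because subject-level data from
published reference cohorts is typically unavailable. Cohen's d uses the
pooled SD with the (n1+n2−2) denominator; the 95% CI uses the large-sample
normal approximation d ± z₀.₀₂₅·sqrt((n1+n2)/(n1·n2) + d²/(2(n1+n2))). The
sign convention throughout is positive = larger in the control group.

Degenerate inputs: a zero pooled SD with equal means yields d = 0 by
convention; with unequal means it is an error (the standardized effect is
infinite), never a silent clamp.

**Sensitivity to table rounding.** When summary tables are transcribed from
print, the means of the smallest structures (accumbens, corpus-callosum
segments, CSF — means near 3·10⁻⁴ at five printed decimals) carry rounding
of up to ±5·10⁻⁶, which is a fifth of a typical SD and therefore shifts the
per-region d by up to ~0.2 and can flip its sign when the true effect is
near zero. Quantities built from many small-|d| regions — the d-vector
correlation and the direction-agreement fraction — inherit this
sensitivity; the S ranking of the strong-effect regions and the CI-overlap
fraction are stable under it. Conclusions drawn from printed tables should
lean on the latter.

## The reproducibility score

S = σ + ω + ε per feature across two analyses (cohorts, software versions,
or processing streams). σ is direction agreement, ω is closed-interval CI
overlap (touching endpoints count; the convention matters only on a measure-
zero boundary), ε = min(|d_A|, |d_B|) rewards effects that are non-trivial
in *both* analyses. S is exchange-symmetric and scale-free (d is
dimensionless), ranges over [0, 2+ε], and ranks features by how credibly a
group difference replicates.

Zero-sign rule: sign(0) is ambiguous. The default ("conservative") treats a
single exact-zero d as unable to confirm a direction (σ = 0) and two zeros
as trivially agreeing (σ = 1); a "lenient" switch counts any zero as
agreement. The switch exists because rounded printed tables produce exact
zeros that subject-level data would not. Ranking ties break
lexicographically by feature label for determinism.

## Univariate statistics

Cliff's delta is computed as δ = 2U/(n_x·n_y) − 1 with ties counted 0.5 in
U, equivalently signed pairwise counting; this is the standard form that
spans [−1, +1] and attains ±1 exactly under complete separation. Two-sided
Mann–Whitney p-values use exact enumeration for tie-free samples with both
sizes ≤ 20 and the tie-corrected normal approximation otherwise — the
study-sized groups (29/49) sit firmly in the asymptotic regime. Bonferroni
adjustment is min(1, m·p) with a configurable m.

Strength bands for |δ| (negligible/small/medium/large at 0.15, 0.34, 0.48)
and |ρ| (negligible below 0.20, then weak/moderate/strong/very strong at
0.40, 0.60, 0.80) treat the printed endpoints as closed; values in the
unprinted gaps between bands (e.g. 0.145) go to the nearer band.

Spearman matrices are Pearson on ranks via scipy; constant features yield
NaN entries plus a warning, never a silent zero.

## Robust multivariate separation

Normality screening uses Mardia's skewness/kurtosis (Gram-matrix form,
biased covariance, χ² and normal asymptotics) and the Henze–Zirkler
statistic with its lognormal p-value approximation (delegated to pingouin
for p ≥ 2; the univariate reduction of the same formulas is computed
in-module). HZ is numerically fragile on near-collinear panels, so singular
covariance or non-finite intermediates set an `unstable` flag instead of
raising.

The robust Mahalanobis distance: each feature is winsorized at the 10th/90th
percentiles of the *pooled* sample (per-group winsorization is a config
option), group centers are per-group medians of the winsorized data, and Σ
is the pooled within-group covariance (n−2 denominator) of winsorized,
center-subtracted data. With p = 35 features and n = 78 subjects the
covariance is near-singular, so a ridge λ = 10⁻⁶·trace(Σ)/p is added when
the condition number exceeds 10⁸ (the ridge actually applied is reported).
Significance uses the standard two-sample Hotelling mapping
T² = n1·n2/(n1+n2)·D², F = (n1+n2−p−1)/(p(n1+n2−2))·T² on
(p, n1+n2−p−1) degrees of freedom.

Two deliberate properties of this recipe:

* **It is not the classical distance.** Clipping 20% of the mass shrinks
  the denominator SD of clean normal data by roughly 20%, so the robust D
  sits systematically above the classical |Δmean|/SD even without outliers.
  At limits (0, 100) with mean centers it reduces exactly to the classical
  two-sample Mahalanobis distance, which is the tested anchor.
* **Winsorization by interpolated percentiles is not strictly idempotent**:
  the clipped sample's own percentiles move slightly inward, so a second
  pass can nudge the extreme values (e.g. 1..10 clips to 1.9 whose re-clip
  point is 1.99). Percentiles use linear interpolation between order
  statistics, stated explicitly because conventions differ across
  ecosystems. The invariants that do hold — contraction, interior order
  statistics untouched, exact idempotence when the limit percentiles
  coincide with data values — are the ones tested.

The permutation test uses T = Σ_features (mean_HC − mean_IBS)² with label
reshuffling preserving group sizes, p = #{T_perm ≥ T_obs}/n_perm (the ≥
rule avoids p = 0 on degenerate data; (1+#)/(1+n_perm) smoothing is a
flag), default 1000 iterations, deterministic given the seed. Note T is not
scale-invariant across features; it is intended for commensurately scaled
(e.g. normalized or standardized) panels.

## Classification harness

Classifier-agnostic: anything with `fit`/`predict_proba`. Positive class =
patient = 1; threshold 0.5 with probabilities exactly at threshold
classified positive. Stratified 70/30 split (so 78 subjects at 29/49 give a
24-subject test set with 9 controls / 15 patients) and stratified 10-fold
CV with preprocessing fitted inside each fold. CV here is plain stratified
k-fold with leakage-safe preprocessing; no inner hyperparameter search loop
is performed. Metrics with zero denominators are NaN with a warning. AUC is
computed by the rank statistic, which ties it algebraically to Cliff's
delta (AUC = (δ+1)/2) and is cross-checked against it in the tests.
Permutation importance shuffles one column at a time on the held-out set
and reports the mean drop of any named metric from the suite over seeded
repeats.

## Synthetic cohort model

The generator draws all 41 features (35 regional volumes + 6 cognitive
indices) from one multivariate normal per group. Defaults are the study
conditions: 29 controls / 49 patients; per-group region means/SDs taken
from the shipped second-cohort summary table; bilateral correlations 0.8
(hippocampus), 0.7 (amygdala), 0.9 (putamen); all other region pairs at a
mild 0.3; cognitive indices at mean 100 ± 15 with pairwise 0.5
(recall–memory 0.67) and group shifts of 6/4/1/3/3/5 index points chosen to
land the rank effect sizes in the reported small band;
cognitive–morphometric cross-correlations 0, mirroring the finding that
structure–function associations are negligible-to-weak. The assembled
correlation matrix passes through an eigenvalue-clipping nearest-PD repair.
Severity scores are truncated normals per screening band — controls
N(25, 15²) on [0, 74], patients N(264, 71²) on [175, 500], matching the
reported medians/IQRs approximately since only those are published — with
an 8% missingness rate per group. Sex is drawn at 69%/77.6% female
(controls/patients), age near 34 ± 10 on [18, 70]. A per-subject eTIV near
1.5·10⁶ mm³ multiplies the normalized volumes into raw mm³ so that eTIV
normalization recovers the drawn scale exactly. An explicit effect vector
replaces the whole group-difference structure with IBS mean = HC mean −
d·SD per feature, enabling null and injected-effect calibrations.

What it does **not** emulate: segmentation-version measurement error,
non-normal marginals and outliers (the very things the robust distance
guards against in real data), missingness outside the severity score,
age/sex effects on brain volumes, and site effects. Passing calibration
tests on these cohorts therefore validates the statistical machinery, not
the biology; results on real data additionally depend on the robustness
features the generator does not exercise.

Missing severity scores are multiply imputed (default m = 5) by empirical
draws within (group, sex) strata, falling back to the group stratum with a
warning when a stratum has no observed values; because strata never mix
groups, imputed values respect the screening bands whenever the observed
data do.

## Problem sizes in the test suite

The calibration tests run at sizes chosen to give stable Monte-Carlo
verdicts at interactive cost: CI coverage over 2000 two-group draws at
n = 100/group; permutation-test size over 500 null cohorts of 10+10
subjects × 3 features at 200 permutations each; effect recovery over 200
generated cohorts at n = 200/group; importance ranking over 20 constructed
datasets of 120/group. The end-to-end CLI run uses the default 78-subject
cohort and 1000 permutations.

## Known limitations

* Effect sizes from printed tables inherit rounding error (quantified
  above); unrounded subject-level data, when available, should be preferred.
* The T² → F inference assumes multivariate normality that the screening
  step routinely rejects on real morphometry; the permutation test is the
  assumption-free companion and should be preferred for headline claims.
* The Henze–Zirkler lognormal p-value is an approximation whose size at
  α = 0.05 sits slightly below nominal in the tested regime (3–8%).
* Multiple imputation uses within-stratum empirical draws (m = 5 by
  default) rather than a posterior-predictive model; with three missing
  cells per group the choice is immaterial, but heavier missingness would
  warrant a proper imputation model.
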