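# Methods

## Model and procedure

The estimand for a candidate patient with feature vector **x** is the
expected 1-year relative LDL-C reduction under each of four statin decisions
*t* ∈ {none, low, moderate, high}:

    y = 100 · (LDL_baseline − LDL_1yr) / LDL_baseline        [percent]

The estimator is arm-wise K-nearest-neighbor regression under a learned
metric:

1. **Per-arm Lasso.** Among training patients who received arm *t*, fit
   L1-penalized least squares of *y* on the standardized features. The
   penalty λ is selected by internal 5-fold cross-validation over a
   log-spaced grid (100 points, λ_min/λ_max = 1e-3) using the
   one-standard-error rule: the largest λ whose CV error is within one SE of
   the minimum. The 1-SE rule is used instead of CV-min because CV-min
   systematically retains spurious predictors at these sample sizes
   (n ≈ 10²–10³ per arm), and the coefficients' *support* matters here —
   every nonzero coefficient becomes a distance weight. `LassoConfig
   (selection_rule="min")` restores plain CV-min.
2. **Metric.** d_t(x, x′) = sqrt(Σ_j w_tj (x_j − x′_j)²) with
   w_tj = |β_tj|^p. The weight power p defaults to 1 (weights applied to
   squared differences inside the root); p = 2 gives the alternative reading
   (|β_tj| Δ_j)². Features the Lasso zeroes out never influence similarity.
   If an arm's fit is entirely null — plausible for small arms whose outcome
   is mostly noise, e.g. the untreated arm — the metric falls back to the
   unweighted Euclidean distance with a warning rather than collapsing all
   distances to zero.
3. **K selection.** For each arm, training patients of that arm are randomly
   partitioned into 5 folds (seeded). Per fold, the standardizer, imputation
   medians and Lasso are refit on the non-held-out folds only; held-out
   patients are scored for every K in the grid (default 1, 3, 5, 10, 15, 20,
   30, 50, 75, 100, truncated at the smallest fold-complement size). Squared
   errors are *pooled* over all held-out patients before averaging (the
   alternative — averaging per-fold MSEs — differs when fold sizes vary;
   pooling weights every patient equally). Ties select the smaller K.
4. **Final fit and recommendation.** The metric is refit on all of the arm's
   training patients, who form the matching pool. A candidate's estimate
   ŷ_t is the unweighted mean outcome of the K_t nearest pool patients
   (no inverse-distance kernel). The recommendation is argmax_t ŷ_t over all
   four arms including "none"; ties within 1e-9 go to the lower intensity
   (least treatment burden under equal predicted benefit). Distance ties at
   the K-th neighbor break by ascending patient id, so predictions are
   deterministic.

## Cohort construction

Eligibility filters run in a fixed order, each exclusion tallied so that
n_input = n_output + Σ exclusions: (1) ≥ 2 visits spanning ≥ 1 year;
(2) age 40–79 at index; (3) no cardiovascular-disease diagnosis anywhere in
the record (prefix-matched ICD-9/10 families, shipped as editable defaults);
(4) at least one cholesterol result — the index date shifts forward to the
first cholesterol result when none precedes the nominal index; (5) baseline
total cholesterol, HDL-C and systolic blood pressure present on/before index;
(6) no statin on/before index; (7) all follow-up-year statin prescriptions
map to a single intensity category ("stable intensity": the simplest faithful
operationalization — no gap or duration rule is imposed); (8) a follow-up
LDL-C inside the outcome window. The baseline LDL-C is the most recent value
on/before index; the follow-up LDL-C is the one closest to index + 365 days
within ± 183 days, ties to the earlier date. The agent+dose → intensity map
ships with guideline-derived defaults and is fully configurable; an
unmapped statin agent or uncovered dose raises a configuration error naming
it. Train/test split is temporal: train iff index date < 2015-01-01.
Lookback for conditions, medications, labs and visits is 365 days;
prior-statin and prior-CVD checks scan the full record.

## Features and standardization

The default schema has 47 expanded columns: age, sex (one-hot 2), race
(one-hot 6 with an explicit unknown level), smoking, baseline LDL-C, total
cholesterol, HDL-C, four vitals, a diabetes indicator (diagnosis- or
medication-derived), 20 CCS-style binary condition flags, an
antihypertensive indicator, medication / laboratory / visit utilization
counts, and two census-block socioeconomic indicators. Missing continuous
values impute the training median; flags impute zero; a condition flag never
observed in an extract is an all-zero column, not an error. All columns are
standardized (mean 0, SD 1; zero-variance columns map to 0 with scale 1)
with parameters fit on the arm's training rows only and reused verbatim for
candidates — required both for comparable coefficient magnitudes and to keep
the distance from being dominated by large-scale features (income in dollars
vs. age in years). Reductions are over C-contiguous arrays so parameters are
bit-reproducible regardless of the frame's memory layout.

## Synthetic cohort generator

The generator emulates the joint structure the pipeline consumes, not
clinical realism: demographics (age uniform 40–79; sex 55% female; six race
categories at realistic shares), baseline LDL-C ~ Normal(121, 30) truncated
at 40 mg/dL with total cholesterol correlated at ρ = 0.7 (all other
continuous covariates independent — one realistic dependence, otherwise
transparent), vitals, 20 condition flags (flag 0 = diabetes at 10%, flag 1 =
the efficacy-gap subgroup), utilization draws, and long-format tables with
the follow-up LDL-C at index + 365 ± 30 days (jitter exercises the
outcome-window logic). The true response surface is

    mu_t(x) = base_t + c_t · z,   z = [age_std, ldl_std, flags]

with defaults base = (0, 15, 25, 35)% and heterogeneity c_t = 0; the
realized follow-up is baseline × (1 − (mu + ε)/100), ε ~ Normal(0,
noise_sd). The default noise_sd = 10% is a modeling choice on the scale of
between-patient response variability, not an assay estimate. Treatment
assignment tilts log-prevalence logits by a score in standardized age,
baseline LDL-C and diabetes scaled by `confounding_strength`, pushing
older/higher-LDL/diabetic patients toward intense therapy. Default arm
prevalences (0.917, 0.026, 0.05, 0.007) mirror a mostly-untreated
primary-prevention population; the untreated share is 0.917 rather than 0.92
so the four probabilities sum to one. The efficacy-effectiveness gap is a
multiplicative attenuation (default × 0.4) of the high-intensity effect in
the flagged subgroup (prevalence = `gap_fraction`), which places mu_high
below mu_moderate there — the phenomenon the recommender should surface as
moderate-intensity recommendations.

What the generator does *not* emulate: realistic ICD code sequences,
adherence dynamics, informative missingness, measurement drift, or
unmeasured confounding (assignment depends only on observables). Passing
policy-recovery tests therefore demonstrates that the pipeline recovers a
recoverable signal, not that recommendations on real EHR data are unbiased.

## Benchmark scenarios and problem sizes

`policy_recovery_config`: balanced arms (25% each), noise_sd = 5,
heterogeneity on exactly three condition flags — low: +6·cond_04 (prevalence
0.3), moderate: +4·cond_03 (0.3), high: −18·cond_02 (0.5) — so the
ground-truth best arm is high for cond_02 = 0 and moderate for cond_02 = 1.
Validation runs use 7 000 generated patients (≈ 5 000 train / 1 000 scored
test). `gap_config`: arms weighted toward the statin decisions for adequate
pool sizes, noise_sd = 5, tunable gap_fraction; gap runs use 3 000 patients
with 600 scored. Generator-scale checks use 20 000–50 000 patients. These
sizes give stable statistics while keeping a full validation run in the
low minutes on one CPU.

## Numerical choices and degenerate inputs

- Lasso: scikit-learn coordinate descent, tol 1e-6, max_iter 5·10⁴; fits are
  bit-reproducible for identical inputs and seed, and the returned
  coefficients satisfy the KKT stationarity conditions at the chosen λ.
- Empty inputs: an empty extract yields an empty cohort with zero tallies; an
  arm with fewer patients than folds raises with an instruction to lower the
  fold count; a K exceeding the pool size raises.
- Patient ids are zero-padded so lexicographic tie-breaking equals numeric
  order.
- CSV round-trips preserve values exactly (shortest-round-trip float
  formatting); model bundles serialize to JSON/CSV text files and reload to
  bit-identical recommendations.

## Known limitations

- Recommendations are associations in observational data; confounding by
  indication is mitigated only insofar as it is captured by the features.
- "Stable intensity" ignores prescription gaps and durations.
- The CV fold partition is per-arm random (seeded), not stratified on any
  covariate; very small arms (< ~50 patients) can yield noisy K choices and
  occasionally a null metric (handled by the unweighted fallback).
- The feature schema is a configurable stand-in for a full 283-category CCS
  expansion; real extracts will need schema editing, not code changes.
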