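# Methods

## The analysis problem

Spontaneous adverse-event reporting systems collect unsolicited reports
of suspected drug reactions.  They have no denominator of exposed
patients, so risk cannot be estimated directly; instead,
*disproportionality analysis* asks whether an event is reported with a
drug more often than the reporting pattern of the rest of the database
would predict.  This package implements that analysis for ocular adverse
events (OAEs) of the three marketed CDK4/6 inhibitors, end to end: from
raw FAERS-dialect tables to signal tables, onset summaries, a
multivariable reporting-risk model and robustness checks.

## Synthetic-report generator

Because spontaneous-report databases are large external downloads, the
package ships a generator (`ocuvigil.synth`) whose output mimics the
seven linked FAERS tables with a fully known ground truth.  Per report:

* a primary-suspect drug is drawn from marketing shares (defaults:
  palbociclib 21.8%, ribociclib 5.2%, abemaciclib 3.2%, the rest a
  breast-cancer co-medication stream — proportions follow the relative
  report volumes of the drug class within a breast-cancer cohort);
* each Preferred Term occurs independently with probability
  `background × RR(drug, PT)` capped at 1, so a planted pair's
  conditional reporting frequency is exact by construction.  Reports that
  draw no event receive the filler reaction "Drug ineffective" rather
  than a resampled event, which keeps planted conditional frequencies
  undistorted;
* demographics come from categorical profiles with per-field missingness
  applied independently (defaults follow the marginal structure of the
  real-world OAE cohort: ~99% female among known sex but 81% sex
  missingness, age mass above 50, ~63% missing weight, ~12% missing age,
  outcome known for ~72% of reports);
* therapy start dates are uniform over the 2015Q1–2024Q3 window and the
  onset delay is log-normal parameterised by (median, IQR) — default
  median 122 days with IQR (28, 414), i.e. σ ≈ 2.0 on the log scale,
  with per-pair overrides (e.g. a 437.5-day median for
  palbociclib × cataract).  Dates are emitted in FAERS's mixed precision
  (YYYYMMDD / YYYYMM / YYYY) with configurable fractions, so roughly
  two-thirds of reports have no computable onset, matching the real
  cohort's onset missingness;
* a configurable fraction of reports is re-emitted as near-duplicate
  clones perturbed strictly within the duplicate-matching tolerances.
  Source reports are forced complete on the matched fields, so the
  injected pairs form a guaranteed-linkable positive set (this shifts
  the overall missingness marginals by at most the duplicate rate);
* concomitant medications: a negative-binomial count (mean 4.4,
  dispersion 0.8) of distinct co-drugs from a fixed pool, with letrozole
  included with probability 0.35 — letrozole is the aromatase inhibitor
  most commonly co-prescribed with this drug class and is a model
  covariate.

What the generator does **not** emulate: stimulated reporting and
secular reporting trends (Weber effect), correlated event co-occurrence,
free-text narratives, and under-reporting dynamics.  Passing tests
therefore demonstrate that the pipeline recovers known structure from
realistically messy tables, not that FAERS itself satisfies any model.

## Deduplication

Two reports link as duplicates only when **all** core fields match —
identical first-10-character caseid prefix, identical PT set at the
Preferred-Term level, therapy start dates (both full precision) ≤ 7 days
apart — **and** all auxiliary fields match: same sex, age gap ≤ 5 years,
same country.  Design choices where the procedure was under-specified:

* a comparison with a missing required field on either side never links —
  simultaneous matching is required, and missingness is not evidence of
  identity;
* the PT criterion uses the report's full PT multiset (the stricter
  reading of "the adverse event term");
* partial-precision start dates are non-comparable rather than
  midpoint-imputed, to avoid fabricating day-level gaps.

Clusters are connected components of the link relation; the retained
report is the one with the latest FDA receipt date (ties: largest
`primaryid`).  The production matcher blocks on the caseid prefix; tests
verify exact equality with an unblocked O(n²) matcher.

## Disproportionality statistics

The four-fold table for (drug, PT) counts deduplicated reports once per
cell; the default comparator is every report whose primary-suspect drug
is not a target drug (so the three inhibitors never contaminate each
other's background), and a pseudo-drug aggregating the whole class is
analysed alongside the three drugs.

* **ROR** `ad/bc` with the Woolf log-scale interval.
* **PRR** `[a/(a+b)]/[c/(c+d)]`; the accompanying test is the
  1-df χ² with Yates continuity correction (configurable).
* **Zero cells**: when any cell is 0 (and a > 0), ROR/PRR point estimates
  and intervals use the Haldane–Anscombe +0.5 correction and the row is
  flagged; a = 0 yields an undefined-result marker (NaN), never an
  exception.
* **BCPNN**: closed-form posterior expectation and variance of the
  information component with the standard priors (α₁ = β₁ = γ₁₁ = 1,
  α = β = 2, γ tied to the margins so the prior IC is centred on 0);
  IC₀₂₅ = E[IC] − 1.96·√V[IC].  A Monte-Carlo route samples independent
  Beta posteriors for the joint cell and the two margins and takes the
  2.5th percentile of log₂(p₁₁/(p₁·p·₁)); it mirrors the closed form's
  moment structure and serves as its in-package cross-check.
* **Multiplicity**: the χ² p-values (the only frequentist p-values in the
  method set) are Benjamini–Hochberg adjusted within each drug's family
  of tested PTs, because signals are reported per drug; a global family
  is available.  Flags: `suspicious` = ROR-positive ∧ PRR-positive;
  `positive_signal` = IC₀₂₅ > 0 ∧ adjusted p < 0.05.  Both are exported
  since either convention appears in practice.

## Time to onset and severity

Onset is the day difference between the earliest full-precision start
date of the target drug on the report and the event date; month- or
year-precision dates censor the record, and negative differences are
excluded and counted.  Quantiles use linear interpolation (numpy
default) everywhere, including the Q1/Q3 in reported medians.  Severity
percentages put death inside the serious class and use reports with a
known outcome as the denominator; denominators are always exported so
the choice is auditable.

## Reporting-risk regression

Within the drug cohort the outcome is binary per report: does it carry
any PT in the ocular system-organ class?  Covariates and reference
levels are fixed: age ≥ 65 (ref < 65), drug (ref abemaciclib),
concomitant-medication count 0 / 1–5 / >5 (ref 0), letrozole use (ref
no).  The fit is a maximum-likelihood logit (statsmodels) with Wald
intervals on the OR scale and complete-case handling (excluded-row
counts are reported; imputation is out of scope).  Optional backward
selection removes the covariate group with the largest likelihood-ratio
p-value until all groups are below `alpha_stay`, never removing the drug
term; the default is the fixed four-covariate model, which is what the
reported estimates describe.  Diagnostics: VIF by auxiliary regressions
(1/(1−R²); infinite under perfect collinearity) and the Hosmer–Lemeshow
χ² over deciles of predicted risk (ties kept together, g − 2 degrees of
freedom).  Non-convergence or separation yields a flagged result rather
than an exception.

## Sensitivity analyses

Each re-analysis is a pure function of the baseline pipeline state.

1. **High-missingness exclusion**: reports missing at least half of the
   three information fields (age, weight, concomitant medications) are
   excluded and incidence/signals recomputed.  Two readings of the rule
   were possible; excluding only event-reports would mechanically shrink
   every indicator by the excluded fraction, so the exclusion applies to
   the whole analysis set (cohort and comparator), which is unbiased
   under outcome-independent missingness and is the only reading under
   which a <5% consistency rule is attainable.  A report's
   concomitant-medication information counts as missing when it carries
   no co-medication rows, since spontaneous reports cannot distinguish
   "none taken" from "not recorded".
2. **Period stratification**: the window is split at a report year
   (default 2020) and each period analysed independently, including the
   ribociclib-vs-abemaciclib odds-ratio contrast.
3. **Co-medication exclusion**: reports carrying a configurable list of
   ocular-toxic co-drugs (illustrative fixture: tamoxifen,
   hydroxychloroquine, chloroquine, amiodarone, ethambutol, isotretinoin,
   digoxin) are excluded — by default only ocular-event reports, per the
   scenario's definition — and the regression refitted.

An indicator is judged *Consistent* when it moved by less than 5%
(relative), configurable per run.

## Problem sizes and numerical choices

The test suite exercises the generator at 300–10,000 reports for unit
properties, 50,000 reports for signal recovery (rate ratio 4 on a 1%
background, 20 seeds) and for the sensitivity null-drift checks, and the
regression simulations at n = 20,000 (coverage, 100 seeds) and n = 4,000
(null calibration, 400 seeds) — sizes at which the asymptotics the Wald
and χ² procedures rely on are comfortably valid while a full run stays
in the minutes range on one core.  The null-drift harness uses larger
event backgrounds (3–5%) than the study defaults so that a <5% drift
bound is a statement about bias rather than about Poisson noise in small
cells, and a period-homogeneous onset model, since a per-pair onset
difference otherwise couples event rates to calendar period by
construction.  Closed-form statistics are validated to 1e-9 against
scalar re-implementations; Monte-Carlo checks use 10⁵ draws.  All
randomness flows from a single integer seed per run.

## Limitations

Signal detection on spontaneous reports measures reporting, not
incidence; confounding by indication and co-medication is only partially
addressed by the regression.  The bundled term map covers the ocular PTs
analysed here, not the full MedDRA hierarchy (no HLT/HLGT traversal).
Probabilistic record linkage (Fellegi–Sunter) and empirical-Bayes
shrinkage (MGPS/EBGM) are deliberately out of scope.
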