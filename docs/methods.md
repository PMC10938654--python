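# Methods

This note records the models the package implements, the assumptions and
parameter choices behind them, what the synthetic-data generator does and
does not emulate, and the numerical conventions.

## Data model and cleaning

A spontaneous-report database in the JADER dialect is four relational CSV
tables keyed by a case id: demographics (sex, age as decade strings,
reporting year), drugs (name, role code, daily dose string, administration
start date), adverse events (MedDRA PT code/name, onset date) and primary
illness. Integration produces one report per case id; when a case appears
several times in the demographics table the **last occurrence in file order
wins**, standing in for the regulator's practice of superseding earlier
report versions (the original workflow does not state its collapse rule;
this is an assumption, exposed as such). Orphan child rows (drug/event/
history rows whose case id never appears in demographics) are dropped with
a logged count. Dose cells strip a trailing unit token ("g", "ｇ") before
parsing; anything else non-numeric becomes missing and is counted, never
silently dropped. Partial dates (year or year–month) carry no day
resolution and are treated as missing for duration analyses.

Only "suspected" drug records enter exposure definitions; reports left with
no suspected drug stay in the analysis set because the 2×2 background is
the whole database. The age sentinels "unknown" and "aged" both map to
missing, and demographic subsets (for sex/age stratification and modeling)
exclude reports missing a required field, with counts returned.

## Exposure groups and daily intake

Products are classified by which of SR/BR/PT they contain, giving 2³ = 8
groups of which 7 are analyzable (the eighth is "contains none"). A report
whose suspected Kampo all share one group belongs to that group; Kampo
spanning groups make the report MIXED. **MIXED reports are excluded from
group-level contingency counts** (not multi-counted), following the
worked examples in the source workflow ("was not counted as one case");
whether the original analysis excluded or multi-counted them is not
decidable from its text, so the choice is isolated in `classify_group`
callers. Per-product counts use simple membership, independent of grouping.

Daily intake of a crude drug is linear in dose:
`crude_content_g × (daily_dose_g / full_daily_dose_g)`, summed across the
report's Kampo products. Compositions vary by manufacturer, so the registry
is a data file. The packaged example registry carries placeholder
compositions (plausible magnitudes, correct SR/BR/PT membership for every
product named in the analyses); only Shosaikoto's SR:BR:PT ratio
(1.5 : 3.5 : 2.5) is anchored to a published composition. The published
ingredient list for Shosaikoto names seven crude drugs against six
proportion numbers — an apparent omission in the source; the registry uses
the standard recipe and the tests rely only on the SR/BR/PT ratios.

## Reporting odds ratio

For exposure E and event D over an analysis set of reports, the 2×2 cells
are a = |E∩D|, b = |E∩¬D|, with c, d by subtraction from the set margins.
The default ("subtracted") ROR is the cross-product ratio a·d/(b·c); the
Woolf 95% CI is exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)). A "marginal"
variant, ROR = (a/C)/(b/D) with C, D the database event/non-event margins,
reproduces the worked arithmetic "(103/36745)/(307/793334)" that appears in
published JADER analyses; for Bofutsushosan it evaluates to 7.24 where the
subtracted form gives 7.26, and only the latter rounds to the printed 7.3.
The subtracted form also reproduces the printed sex-stratum ROR (Male 10.2
vs 10.0 marginal), so it is the default.

Zero cells leave the ROR undefined (tables print a dash); no Haldane 0.5
correction is applied by default. The signal criterion is lower CI bound
> 1 with n ≥ `min_cases`; the source text requires "> 2" reports while its
tables suppress only n < 2, so `min_cases` defaults to 3 and results below
2 cases report "not evaluated".

Of the 52 complete printed rows in the reference tables, all 52 ROR point
estimates and 45 rows' CI bounds reproduce exactly at one-decimal rounding
under this Woolf interval; seven printed bounds differ by one unit in the
last digit (each computed bound sits within ~0.006 of a 0.05 rounding
boundary, except one that no standard interval variant reproduces — the
source software's own arithmetic). The acceptance suite asserts the
reproducible set and keeps a deliberately failing full-table assertion to
document the residual discrepancy.

## Multivariate model, stepwise selection, adjusted RORs

The DIILD log-odds are modeled on reporting year Y, SR intake D1 (g/day),
PT intake D2 (g/day), male sex S, age-≥60 indicator A, and the
interactions D1·A and D1·D2. Age enters dichotomized from decade strings
("60s" and older → 1); the original dichotomizes at 60 without stating the
decade map, so this is documented as the natural choice. Fits are
maximum-likelihood (statsmodels Newton/IRLS; covariance = inverse observed
information; Wald 95% CIs). Stepwise selection is forward–backward with
**likelihood-ratio** p-values at entry/stay threshold 0.05 (the source
names only "stepwise, significance level 0.05, forward and backward");
hierarchy is enforced (interactions enter only while both components are
in, main effects cannot leave under their interactions), and ties break by
smaller p then candidate order, so selection is deterministic.

A single term's adjusted ROR is exp(coefficient). For an interaction row
the reported quantity is the **combined effect**
exp(β_component1 + β_component2 + β_interaction), with the CI from the
delta method on the summed linear combination. This rule is
reverse-engineered from the published table: exp(0.38 + 0.65 + 0.17)
= 3.32 matches the printed 3.35 at coefficient-rounding precision, whereas
exp(0.17) = 1.19 alone cannot.

The per-crude-drug dose–response model is log(odds) = β₀ + β₁·D; exp(β₁)
is the crude ROR per gram. The ROC analysis is empirical over all distinct
thresholds; AUC is the trapezoid integral (= Mann–Whitney concordance);
the cutoff maximizes Youden's J = sensitivity + specificity − 1 (ties
toward the smaller threshold), operationalizing "highest sensitivity while
maintaining high specificity"; a closest-to-(0,1) criterion is available
by flag.

## Propensity-score matching

PS = fitted probability of exposure to one crude drug given sex, the age
indicator and the other two crude-drug intakes. Matching is 1:1 without
replacement, greedy nearest-neighbor on the logit PS, exposed visited in
descending logit-PS order, within a caliper of 0.2·SD(logit PS) over all
subjects; the RNG breaks exact distance ties only, so results are
deterministic given a seed. The source states nearest-neighbor + caliper
but not ratio, replacement or order; these are the common conventions and
all are arguments. SMDs use the pooled-variance forms (continuous:
|m₁−m₂|/√((s₁²+s₂²)/2); binary with p(1−p) variances); the balance table's
p-values are two-sample Welch t (continuous) and χ² (binary) — the source
prints p-values without naming tests. The matched ROR is an unpaired 2×2
over matched subjects, as published post-match RORs are plain RORs.

Greedy within-caliper matching removes most but not all confounding; the
acceptance study (null direct effect, moderate confounding, n = 8,000 per
replicate, 50 replicates) shows the matched CI covering the null in 46/50
replicates with all covariate SMDs < 0.1 in every replicate.

## Time-to-onset and Weibull shape

Durations are onset date minus administration start date in whole days,
per distinct (drug, start date) pair, complete dates only. Same-day or
negative durations are excluded as inconsistent (the convention is
configurable; the source does not state one), and durations beyond the
365-day window are truncated away. All observations are events — a report
exists only because the event occurred — so there is no censoring model
and the Kaplan–Meier product-limit estimator equals the empirical survival
function; the window is a truncation filter.

The two-parameter Weibull is fit by MLE: Newton iteration on the profile
score equation for the shape β (tolerance 1e−10, Menon moment start),
scale α in closed form given β. CIs are Wald on the log-parameter scale
from the analytic observed information; this is deterministic and standard
in Weibull-shape pharmacovigilance reporting (a profile-likelihood option
would be a natural extension). Classification: wear-out iff β > 1 with CI
excluding 1; initial failure iff β < 1 with CI excluding 1; otherwise
random failure. Fits refuse n < 10 (CIs meaningless) and flag degenerate
samples (zero spread, β → ∞) as non-converged. Point estimates agree with
`scipy.stats.weibull_min.fit(floc=0)` to four significant digits in tests,
and curves cross-check against lifelines.

Drug-level reporting is restricted to labels with more than 10 onset
cases, the usual convention for these summaries.

## Synthetic-data generator

`SimConfig`/`generate_tables` emit the four tables with: per-drug Bernoulli
exposures; a logistic event model whose log-odds are
logit(background_rate) + Σ log(odds multiplier)·exposure, so realized RORs
converge to the configured multipliers; onset dates = index-drug start +
Weibull(α, β) days (rounded, min 1); ISO dates with a configurable rate of
partial (year or year–month) strings; decade-string ages with "unknown"/
"aged" sentinels; duplicate case emission; one RNG stream per table, all
derived from one seed, with byte-identical output under a fixed config.

Defaults are the package's study conditions, chosen once: 50,000 reports;
background event rate 0.044 (the DIILD margin of the public extract,
36,745/830,079); a six-product catalog planting RORs 8, 5, 4, 2, 1.5 and 1
at 1–2% exposure; missing sex/age rates 0.1; partial-date rate 0.2 (the
source gives no partial-date frequency — a free parameter); duplicate rate
0.02; onset Weibull (40 days, 1.36) by default with per-drug overrides.
Two compact cohort simulators provide ground truth for the statistical
studies: `simulate_covariate_outcome` (the multivariate design with known
coefficients) and `simulate_confounded_cohort` (exposure and event sharing
demographic/dose confounders with a controllable direct effect).

What the generator does **not** emulate: Japanese free-text drug-name
variants, the regulator's correction/update cycle beyond simple duplicate
emission, correlated multi-event reports, dose-dependent event odds at the
table level (dose matters only through which products are taken), and
realistic underlying-disease structure (histories are uniform draws).
Passing tests therefore demonstrate that the statistical machinery is
correct under the stated models, not that real JADER estimates would be
unbiased — the published adjusted RORs, matched cohorts, AUCs, cutoffs,
medians and Weibull parameters for the real extract require the raw
download and are validated here only as machinery, by parameter-recovery
and coverage studies at stated problem sizes (100 × 50,000 for the
multivariate model, 100 × 1,000 for the Weibull, 50 × 8,000 for matching),
chosen to give stable verdicts at interactive runtimes.

## Numerical conventions

- 95% multiplier fixed at 1.96 everywhere (not the exact normal quantile).
- Printed-value comparisons round half-up, as tabulation software prints.
- Logistic convergence: statsmodels Newton, tol 1e−10, max 100 iterations;
  separation or singular covariance flags the fit rather than raising.
- The analysis-set argument of the modeling stage is explicit: the source
  does not state which subset its multivariate model used, so the pipeline
  fits on the dose- and demographics-complete herbal subset and any other
  subset can be passed directly.

## Known limitations

- Spontaneous-report data carry no denominator; RORs quantify reporting
  disproportionality, not incidence risk.
- Compositions in the example registry are placeholders except where noted;
  real analyses must supply a manufacturer-accurate registry.
- Greedy 1:1 matching is not optimal matching; a small residual bias
  remains under strong confounding (measured in the acceptance study).
- The Weibull Wald CI is symmetric on the log scale and can undercover for
  small n; fits refuse n < 10 for this reason.
- Smoking and other covariates absent from the JADER dialect cannot be
  adjusted for.
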