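# Methods

## Scope and model

`exitcost` implements a static microsimulation of the economic cost of
illness-related early exit from the labour force, configured by default for
diabetes among Australians aged 45–64 in 2010. The causal attribution is
taken from the data definition, not estimated: a person is "out of the
labour force due to diabetes" when the survey says so (left the labour force
because of illness, diabetes nominated as the main chronic condition).
Costing follows the human-capital approach over a 12-month horizon: every
hour not worked is an hour lost. Absenteeism, presenteeism, premature
mortality, carer time and friction-cost accounting are out of scope.

## Synthetic study conditions

The original base population (pooled national disability-survey unit
records) and donor snapshot (a dynamic microsimulation's annual output) are
confidential, so the generator reproduces their statistical structure. Its
defaults are the study conditions, not tuning knobs.

**Groups and sizes.** Five reported groups with the published sampled and
weighted sizes — full-time / part-time with no chronic condition (6,606 /
2,373 records; 1,413,511 / 467,796 persons), full-time / part-time with
diabetes (345 / 105; 88,889 / 25,329), out of the labour force due to
diabetes (46; 11,310) — plus two groups the published tables omit but the
counterfactual needs for a complete labour-force denominator: unemployed
(300; 60,000) and not in the labour force for other reasons (2,500;
500,000), chosen so the no-condition population has roughly 58% full-time,
19% part-time and 23% non-employed (~77% participation, realistic for these
ages in 2010).

**Income.** Log-normal within group with a shared log-linear mean:
log y = μ₀ + β_group + γ·(age, sex, education) + σ_group ε. The group
contrasts β are the published adjusted percent differences (−56.3, −6.5,
−52.4, −88.3 for the four reported non-reference groups), μ₀ anchors the
reference-group median at AU$54,795, and σ_group comes from each group's
published mean/median ratio under log-normality (σ = √(2 ln(mean/median)),
0.52–0.79). A single additive model cannot also match every group's
published *raw* median (the raw reference/NILF median ratio is 0.215 while
the adjusted contrast is 0.117, a gap too large for plausible covariate-mix
offsets); we prioritise the adjusted contrasts because they are the
regression stage's estimand, and document that group medians are therefore
implied rather than anchored. Covariate effects (university +0.35, female
−0.25, ages 60–64 −0.20, all on the log scale) are part of the generating
truth the regression must adjust away.

**Welfare.** Zero-inflated log-normal per group: receipt probability
p, and positive-part parameters solved so the mixture mean (and, where the
mixture median is positive, the median) hit the published anchors — employed
groups have median 0 with means AU$305–2,377; the diabetes-NILF group has
p = 0.8, mean AU$6,048, median AU$986.

**Tax.** Deterministic piecewise-linear marginal schedule applied to income,
2010-era Australian brackets with the Medicare levy folded in and an
effective tax-free threshold of AU$16,000 (so the diabetes-NILF median
income of AU$11,784 attracts zero tax, matching the published median). The
true schedule, never printed alongside the estimates, is config-replaceable.

**Matching variables.** Ten categoricals (4·4·5·2·2·2·4·5·2·2 = 51,200
cells): labour force status, income-unit type, income quintile, age-pension
and disability-support-pension receipt, sex, age group, weekly hours band,
education, home ownership. Hours bands partition 1–15 / 16–24 / 25–34 /
35–40 / 41+ (one published band label is treated as a typographical error to
preserve the partition); non-employed records carry a "none" sentinel.
Quintiles band each record's income at fixed edges (16k / 30k / 45k / 65k
AU$), since the source bands are unpublished. Covariates are independent
within group; design weights carry ±15% uniform jitter around
(group persons)/(group records) so calibration has genuine work.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: survey design effects (clustering,
stratification, non-response), correlation between covariates within group,
measurement error in self-reported conditions, and any relationship between
welfare and income beyond group membership. Donor records, like the real
snapshot, carry no condition label: the diabetes signal survives matching
only through the ten matching variables, so pipeline estimates of the group
contrast are attenuated relative to the generating −88.3% (typically to the
−82 to −87% range) exactly as data fusion attenuates in practice. The
parameter-recovery study therefore evaluates the regression stage on
directly generated economics, while the pipeline's end-to-end totals are
indicative.

## Calibration

Chi-squared-distance GREG with box bounds — the standard choice of
production reweighting software. The unbounded optimum is the closed form
w = d + DX(X′DX)⁺(T − X′d), solved with `lstsq` so overlapping margins
(consistent but redundant constraints) are handled. Bounds default to
(0.3, 3.0) times the design weight, tolerance 1e-6 relative, 50 iterations;
binding weights are fixed at their bound and the regression re-solved on the
remainder against residual targets. Records in no benchmark cell pass
through unchanged with a warning; an empty benchmark cell is an error naming
the cell; non-convergence returns a flagged result with the violation.
Tests verify the implementation against an independent KKT block-system
solve of the generic equality-constrained quadratic program.

## Matching

Maximal-prefix fallback: a recipient is matched on the longest prefix of the
priority list (default: the conventional listing order, so labour force
status is never dropped) that yields a non-empty donor pool; ties are broken
uniformly with a stated seed; donors are reused with replacement. Whether
the original study relaxed within labour-force strata only is unknown; the
priority list makes that choice explicit and configurable. A recipient
unmatched even on the first variable alone is a hard error.

## Regression and descriptives

OLS on log(y + δ) with categorical main effects only (group, age group,
sex, education), reference full-time/no-condition. Offsets δ: 0 for income
(the generator guarantees positive income), 1 AU$ for welfare and tax, which
have legitimate zeros; how the original analysis handled zeros is unstated.
The regression is unweighted on person records by default (weights serve
descriptives and national totals); a WLS switch exists because the original
weighting treatment is also unstated. CIs use 1.96 (normal approximation,
appropriate at these sample sizes). Weighted median: smallest observed value
whose cumulative weight reaches half the total — one convention had to be
picked; it is documented and enumeration-tested. Residual diagnostics
(D'Agostino normality, Breusch–Pagan) are advisory; at full scale the
log-income residuals are detectably non-normal because groups have distinct
σ — the fit's contrast estimates remain unbiased under that
heteroscedasticity.

## Counterfactual and national totals

Counterfactual economics for each diabetes-NILF person: mixture over
full-time, part-time (model-predicted for that person's covariates in the
no-condition group, median-scale back-transform exp(Xβ̂) without smearing,
consistent with the percent-difference interpretation) and non-employed (the
person's actual values), with the no-condition population's shares. A
group-mean alternative (reference-group weighted means instead of
per-covariate predictions) sits behind `method="group_mean"`. Losses:
income and tax (counterfactual − actual) floored at zero; the welfare
difference is sign-flipped into "extra welfare". National totals are
Σ wᵢ·lossᵢ in AU$ million. Extra welfare is the most model-sensitive total:
it is the small difference between two welfare levels, and the synthetic
donor pool mixes NILF subgroups, so its pipeline value is materially larger
than the published AU$3.5M.

**GDP.** Marginal form ΔGDP = (GDP/H)·(H/EMP)·n. When a worker leaves both
employment and the labour force with GDP/H and H/EMP held fixed, the full
identity's before/after difference equals the marginal form exactly (tested
to 1e-12); the participation-rate feedback is second-order only for other
exit patterns. Default parameters (GDP/H = 71 AU$/h, H/EMP = 1,700 h/yr,
EMP/LF = 0.943, LF/Pop15⁺ = 0.655, Pop15⁺ = 17.8M) are *assumptions* —
illustrative 2010 values implying total GDP ≈ AU$1.33 trillion — because the
source levels are not published; the published AU$1,324M GDP loss is
therefore not independently recomputable.

**Rounding.** Money to 0.1 AU$M and persons to integers at reporting only.
The preventable scenario multiplies unrounded internals by the fraction
(default 0.89, the Type 2 share at ages 40–59) and then rounds: from the
published rounded base this gives 11,310 → 10,066 persons, 383.9 → 341.7,
56.4 → 50.2, 3.5 → 3.1 AU$M exactly, and 1,324 → 1,178.4 AU$M for GDP —
0.6 below the published 1,179, which implies an unrounded base slightly
above 1,324.

## Problem sizes and numerical choices

The parameter-recovery study uses 100 replicates of 10,000 records (the
five published group proportions plus the two auxiliary groups, scaled by
largest-remainder rounding), which bounds the Monte-Carlo error of the mean
recovered contrast near 0.1 percentage points while keeping the whole suite
fast. Unit and pipeline tests run on 1,000–2,000-record populations with
4,000–8,000 donors. Calibration oracle checks use ≤ 20 records and ≤ 6
constraints with wide (non-binding) bounds. Seeds are explicit everywhere;
identical spec + seed is byte-identical by contract.

## Known limitations

- Pooling of survey years is treated as a single frame; no year-specific
  adjustment before calibration, and no small-area or variance estimation
  for calibrated estimators (replicate weights, jackknife).
- Matching is categorical-cell only; no nearest-neighbour or constrained
  variants.
- The counterfactual assumes the published "same participation and
  employment structure" rule; whether the original base totals came from
  the regression-adjusted route or a direct group-mean comparison is
  ambiguous, so both routes are exposed and the regression route is the
  default.
- All monetary quantities are treated as annual AU$ (one published table
  caption says weekly; the surrounding text and magnitudes are annual).
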