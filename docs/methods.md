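# Methods

This note documents the models, conventions and numerical choices behind
obesipath, in the order data flows through the pipeline.

## Anthropometrics and body image

BMI is weight (kg) / height (m) squared. Category boundaries are half-open
and lower-inclusive — [18.5, 25) normal, [25, 30) overweight, ≥ 30 obese —
the standard WHO reading; a value of exactly 25 is overweight. The Stunkard
nine-silhouette scale maps to the same four categories as {1,2}, {3,4},
{5–7}, {8,9}. Body-image dissatisfaction is reported both signed
(current − preferred; positive = desires thinner) and as a magnitude
(`bid_degree`), because descriptive tables conventionally report the
degree. Weight perception is compared at category level: the score is the
silhouette-category rank minus the measured-BMI-category rank (range −3..3,
0 = correct perception). A finer figure-to-BMI regression would demand
anthropometric calibration data the silhouette instrument does not provide.

## Psychometric scales

ATOP (20 items) and BAOP (8 items) share one scoring rule: reverse-keyed
items are multiplied by −1, all items are summed, and an offset (60 / 24)
is added. Responses use the 6-point set {−3, −2, −1, +1, +2, +3}; this is
the only symmetric integer range under which the documented score ranges
0–120 and 0–48 are exactly attainable, which is why it is the default. A
neutral 0 can be admitted per instrument (`ScaleDefinition.with_zero()`);
it affects only attainable score parity. Item wording is deliberately not
shipped — scoring depends only on item count and reversal sets, which are
configurable.

## Prospect-theory elicitation

Value function: v(z) = z^σ for z ≥ 0 and −λ(−z)^σ for z < 0; decision
weights follow Prelec, w(p) = exp(−(−ln p)^γ). For binary prospects whose
outcomes share a sign, w(p) applies to the stated probability of the first
(larger-magnitude) outcome and 1 − w(p) to the other. For mixed gain/loss
prospects the gain carries w(p) and the loss w(1 − p), the cumulative
sign-rank convention. The mixed rule matters: every series-3 row offers
50/50 odds in both plans, so the common factor w(0.5) cancels from the
comparison and λ inference is exactly independent of γ — the design
property the third series exists for. Both conventions reduce to expected
value at σ = λ = γ = 1.

The bundled design follows the canonical three-series multiple-price-list
structure (14 + 14 + 7 rows) with euro-scale payoffs: series 1 offers
Plan A (4.00 with p = .30, else 1.00) against an escalating Plan B
(high payoff 6.80 → 170.00 at p = .10, else 0.50); series 2 uses high
probabilities (A: 4.00 at .90 else 3.00; B: 4.20 → 11.00 at .70 else
0.50) so that the two switch rows jointly pin down σ and γ; series 3 mixes
gains and losses. Payoff tables are fully overridable (YAML/JSON); the
inversion is design-agnostic.

Inversion works on the preference pattern, not on utilities: a (σ, γ) grid
spanning [0.05, 2]² at step 0.01 is mapped once per design (and cached) to
implied series-1/2 switch rows using exactly the same tie-to-Plan-A rule
as the choice simulator. The interval estimate for (σ, γ) is the bounding
box of grid cells reproducing the observed rows, padded by one grid step
because the continuous cell boundary can overhang the outermost matching
grid point. The point estimate solves the two switch-row indifference
equations (`scipy.optimize.fsolve`, started from the box centre) and is
clipped into the box; censored patterns (always/never switch) fall back to
the box centre. λ bounds are the closed-form adjacent-row inequalities of
series 3, evaluated across the whole σ interval so the reported λ interval
is valid wherever the true σ lies; the point is the midpoint at the σ
point estimate. Never-switch λ patterns report the last finite boundary
plus half the final cell width, clipped to [0, 12] (comfortably covering
observed population ranges); the analogous σ clip is [0.05, 2].

Point categorisation uses thresholds exactly at 1 (σ: averse/neutral/
loving; λ ≥ 1 loss averse). Because no point estimator can land on 1
exactly, the estimate object also carries an interval-aware risk category:
an interval straddling 1 reports risk-neutral. Non-monotone choice vectors
(switching back from B to A) cannot be bracketed; they raise a
`MultipleSwitchError` and the pipeline excludes the subject with a logged
warning rather than silently repairing the pattern.

## Warped path analysis

All model variables are standardized (mean 0, sd 1, denominator n − 1).
For each structural equation, each incoming predictor x is warped against
the raw criterion y: a polynomial of degree 1 (linear), 2 (quadratic) or
3 (s_curve) is fitted by least squares, x is replaced by the fitted
function of itself, restandardized, and oriented. Orientation multiplies
the warped column by the sign of its correlation with raw x when that
correlation is at least 0.1 in magnitude, otherwise (symmetric warps, e.g.
a pure U) by the sign of its correlation with y; without orientation the
coefficient of a sole warped predictor would be non-negative by
construction and two-sided null inference impossible. Columns with at most
two distinct values (binary indicators) are always warped linearly — a
higher-degree polynomial through two support points is degenerate.
Predictors are warped against the raw criterion, not residualized against
co-predictors; this is the simplest defensible choice and is isolated in
one routine so alternatives can be swapped.

All warped predictors of an equation enter one OLS fit (no intercept —
columns are mean-zero); betas are standardized path coefficients, R² and
adjusted R² come from the same fit, and the per-edge effect size is
|β · r| with r the Pearson correlation of the warped predictor with the
criterion (Cohen bands 0.02 / 0.15 / 0.35). A warped block with condition
number above 1e8 raises a collinearity error.

Bootstrap inference resamples rows with replacement B times (default
5000, so the reference distribution is t with 4999 df), refits the whole
model per resample, takes the bootstrap sd as the standard error, and
refers β/se to t(B−1), two-tailed. Resamples that collapse a variable's
variance are redrawn (at most 10 times). Significance stars follow the
three-level scheme *** p < 0.01, ** p < 0.05, * p < 0.1.

### Fit and quality indices

APC = mean |β|; ARS / AARS = mean (adjusted) R² over endogenous variables,
with p-values from the bootstrap distributions of the same averages.
AVIF averages the block VIFs of equations with at least two predictors
(single-predictor blocks are identically 1 and excluded); AFVIF averages
full-collinearity VIFs of every model variable regressed on all others;
VIF computations are plain 1/(1 − R²). GoF = √(mean communality × ARS);
every variable here is a single indicator with communality 1, so GoF =
√ARS exactly. The causality-quality ratios are declared, versioned
formulas: SPR is the fraction of edges whose β sign matches the warped
bivariate correlation sign; RSCR is the positive share of β·r
contributions (Σ positive / Σ |contribution|); SSR is the fraction of
edges with |β| ≤ |r|; NLBCDR compares the warped bivariate R² in the
hypothesized direction against the reverse and credits 1 when forward ≥
reverse, 0.5 on ties. Linear-mode edges always tie on NLBCDR (forward and
reverse linear R² are both r²), so an all-linear model scores 0.5 — a
known property of this definition, not a defect.

Relationship curves export the fitted warp polynomial over the observed
predictor range. Shape classification counts interior stationary points:
two → S / inverted-S by leading-coefficient sign; one → U / inverted-U by
curvature (J when the dip sits in the left third of the range); monotone
curves are linear, exponential-like (convex increasing, or monotone with
dominant — ≥ 70% of the range — convex growth), or the half-S of their
leading coefficient.

### Default model

The bundled model has 15 directed edges over 13 observed variables (five
equations: BMI, ATOP, BID, diet, loss aversion). Binary predictors are
linear; age, attitudes and beliefs default to s_curve; risk aversion → BMI
is quadratic (U-family); dissatisfaction → diet quadratic. Expected signs
and benchmark estimates ride along as metadata only — they never influence
estimation; the benchmark numbers exist so the index formulas can be
regression-tested (e.g. APC must equal the mean absolute benchmark β to
rounding) and so synthetic output has recognisable target magnitudes.

## Synthetic cohorts

`simulate_paths` generates standardized variables from a declared edge
list. Parent transforms are linear z, quadratic z², s-curve z³ − 1.5z, or
exponential exp(0.9z), each sample-standardized. The residual of every
equation is sample-orthogonalized against the transformed parents and
scaled so the equation's variance is exactly one; the configured
coefficients are therefore exact standardized path coefficients, making
recovery tests sharp rather than statistical. With noise_scale 0 the
deterministic part is rescaled to unit variance and the implied
coefficients (configured / sd) are reported in the exported truth.

`generate_cohort` wraps this in a full survey: demographics are Bernoulli
/ truncated-normal draws matching the target marginals (70% female, 69%
married, 36% university, 32% low income, age 20–70 with mean 45.8 and sd
11.22); BMI is built structurally from the drivers above (S-shaped age,
linear binary effects, S-shaped attitude/belief effects, U-family risk
effect) with noise topping variance to one, then mapped to kg/m² via
mean 25.17 and sd 4.21 and realised as weight/height with instrument-level
rounding; body-image dissatisfaction grows convexly with BMI (target
degree mean 1.19, sd 1.07); silhouettes are chosen category-consistent
with measured BMI shifted by a three-point misperception draw (default
30% incorrect; at rate 0 every perception score is exactly 0 by
construction); dieting is Bernoulli with a logit link on dissatisfaction
around a 24% base rate; ATOP/BAOP item vectors are produced by quantizing
the latent score per item with uniform jitter onto the admissible 6-point
set, so scored totals track the latent levels approximately and always
respect instrument bounds; per-subject (σ, λ, γ) are truncated-normal /
log-normal draws centred on population values (σ 0.58 ± 0.37 on
[0.05, 1.5]; λ log-normal capped at 11.79 and negatively coupled to σ;
γ 0.70 ± 0.15 on [0.35, 1]) and the 35 lottery choices are simulated from
them, noiselessly by default so every subject's choices are exactly
invertible. Everything derives from one `numpy` Generator seeded by the
config, so identical configs produce byte-identical CSVs.

What the generator does *not* emulate: real item-level response styles
(acquiescence, straightlining), measurement error in weight and height
beyond rounding, the joint distribution of demographics (draws are
independent), feedback loops (BMI → dissatisfaction → dieting → BMI is
generated acyclically even though the analysis model estimates the diet →
BMI edge), and noisy lottery behaviour unless a choice temperature is set.
Passing recovery tests therefore demonstrates correctness of the
estimators under the declared generating process, not robustness to
real-data pathologies.

## Problem sizes and numerical conventions

Recovery experiments use n = 1000 with 40 seeded replicates (coefficients
within ±0.05; shape labels ≥ 95% agreement); prospect-theory round trips
cover 54 interior (σ, λ, γ) triples with 100% interval coverage required;
bootstrap calibration uses 500 replications of B = 500 at n = 300 per
replication. Oracle-equivalence checks (linear betas vs normal equations,
VIF vs the precision-matrix diagonal) demand agreement to 1e−10 and 1e−8
relative, respectively.

## Known limitations

- The bootstrap-t standard error of a correlation is biased low in small
  samples: at n ≈ 100–200 the null t-statistic has sd ≈ 1.05–1.08 and the
  nominal 5% test rejects at 8–9%. Calibration holds from n ≈ 300. P-values
  on cohorts of survey size (n ≈ 172) are therefore mildly anti-
  conservative; a studentized or BCa bootstrap would be the next step.
- Interval inversion of lottery choices is exact only for noiseless,
  monotone responders; noisy subjects are excluded, not modelled (no
  maximum-likelihood layer).
- λ point estimates for never-switch patterns depend on the declared
  boundary-plus-half-cell convention and the [0, 12] clip.
- The path model estimates each equation separately over a declared edge
  list; acyclicity is enforced per equation only, so jointly cyclic edge
  sets (BMI → BID → diet → BMI) are estimated as separate directed
  regressions, and no feedback/simultaneity correction is applied.
- Latent variables with multiple indicators, missing-data handling and
  plot rendering (beyond curve CSVs) are out of scope.
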