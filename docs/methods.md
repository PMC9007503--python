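# Methods

This note documents the models implemented in `streamtox`, the synthetic
data they are exercised on, and the numerical and design choices made
where more than one defensible option existed.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Concentration–response models

The fitted curve is the log-logistic

    f(x) = c + (d − c) / (1 + exp(b (ln x − ln e)))

with `f(0) = d`: controls (dose 0) are included as observations on the
upper asymptote rather than dropped, because they anchor `d` and the
EC-gating rule is defined at the intercept.  The sign convention is
`b > 0` ⇒ response decreasing with dose, matching standard dose–response
software.  LL3 fixes `c = 0`; LL4 frees it.  The error model is
homoscedastic Gaussian on the response, optionally on the ln(1 + y) scale
(`transform="log1p"`), with the Gaussian log-likelihood computed from the
residual sum of squares and AIC = 2k − 2·loglik where k counts the free
curve parameters plus the error variance.  Model selection takes the
lower AIC; an exact tie goes to LL3 (parsimony).

Optimisation is deterministic multi-start: `e` starts at three log-scale
quantiles of the positive doses, `b` at {0.5, 1.5, 4}, `d` at the control
mean, each start polished by a bounded trust-region least-squares solve
(`e` is optimised as ln e to keep it positive).  A test verifies on noisy
fixtures that the optimum beats a dense 50³ brute-force grid.

Effect concentrations are *relative* (defined against the span d − c):
EC_p = e (p/(100−p))^(1/b), so EC50 = e exactly.  Standard errors come
from the delta method using the Jacobian-based parameter covariance; the
gradient involves only b and ln e.  An EC is *gated* (reported as NaN)
when d − 1.96·se(d) ≤ 0, i.e. when the 95% CI of the fitted response at
dose zero includes zero — with a decreasing curve there is then no
resolvable effect size to scale against.

Two response scales serve two purposes.  EC estimation uses the identity
scale (the default): at the experiment's design (5 duplicated levels plus
3 controls) this delivers ~14% median relative EC50 error and ~88%
delta-method CI coverage in the recovery simulations.  The mixture
pipeline instead fits its unary curves on the log1p scale, because
identity-scale least squares leaves the upper tail of the curve
unidentified — near-zero counts at the top doses contribute almost
nothing to the RSS, so the fitted response at high dose can wander far
from zero.  On the log scale those observations are informative, the
top-dose predictions concentrate near the truth, and the zero-limit rule
(below) engages where it should.  The log-scale `e` is *not* the
response-scale EC50, so log-scale fits are never used for EC reporting.

## Mixture analysis

Response addition (independent action) predicts the mixture response as
control × (f_A(x_A)/f_A(0)) × (f_B(x_B)/f_B(0)), fractions taken on the
original response scale (back-transformed if the fit was log1p).  The
model deviation ratio, MDR = predicted/observed, is computed per mixture
replicate on the response scale — deliberately not the classical
EC50-ratio MDR — and classed synergistic when MDR > 2 (the boundary
itself is additive), antagonistic below 0.5 (a symmetric choice; only the
synergism threshold is standard).

Zero-limit handling: when the additive prediction falls below a floor ε
the replicate is indeterminate — an additive model that predicts
(essentially) no organisms cannot be distinguished from a synergistic
one.  ε defaults to half the smallest observed nonzero response, capped
at 0.5 individuals for counts.  An observed zero with a prediction above
the floor is substituted by ε and flagged; these substitutions produce
large MDRs by construction and are the main reason the floor and the
log-scale unary fits matter for calibration.  Under data generated with
exact response addition, the calibration suite (200 datasets) checks that
the geometric-mean MDR is within e^±0.1 of 1, the arithmetic mean within
[0.8, 1.25], and at most 5% of determinate replicates are classed
synergistic; with a 4× synergy multiplier the majority of determinate
high-dose replicates must be flagged.

## Species sensitivity distributions

Dataset assembly keeps chronic records (duration ≥ `min_duration_days`,
default 10; 17 is a supported override because both cutoffs are in
circulation for these data) from insect/crustacean groups and retains the
minimum effect value per (taxon, compound).  Four families are fitted by
maximum likelihood on the concentration scale: log-normal (closed form),
log-Gumbel (ln X ~ Gumbel, fixed-point iteration for the scale),
gamma (Newton on the digamma equation), and Weibull (Newton on the
profile shape equation).  Gamma and Weibull are deliberately *not*
log-transformed — the four-family set is the convention of the reference
SSD tooling.  All fitters are vectorised across an arbitrary leading
axis, which is what makes the bootstrap (500 refits × 4 families) take
milliseconds rather than minutes; a test checks each solver's
log-likelihood against scipy's iterative MLE on a fixture.

Families are combined by small-sample Akaike weights,
AICc = AIC + 2k(k+1)/(n−k−1) with k = 2 per family (a plain-AIC fallback
guards the n − k − 1 ≤ 0 edge, unreachable at the enforced minimum of
five values), and HC_p = Σ wᵢ Qᵢ(p).

Bootstrap: per replicate one dataset of n values is drawn from the fitted
model-averaged mixture (each observation picks a family with probability
wᵢ), *all* families are refitted to that same dataset, and the weighted
HC is recomputed with the original weights held fixed.  Refitting to a
shared dataset preserves the strong positive correlation between the
families' quantile estimates; resampling each family independently would
shrink the spread of the weighted average by roughly Σwᵢ² and produce
badly over-narrow intervals (we measured ~0.73 coverage for the
independent scheme vs ~0.97 for the shared scheme at n = 16).  Holding
weights fixed is a documented simplification — model-selection
uncertainty is not propagated.  SE is the bootstrap standard deviation;
the CI is the 2.5/97.5 percentile interval.

## Field screening

Detection frequencies and concentration percentiles are computed over the
last k (default 4) samples per site, with below-reporting-level values
censored to zero.  The CIBQ for a sample is Σ concentration/benchmark
over detected in-scope compounds; a site's CIBQ is the maximum over its
last k samples.  Censored values contribute zero to quotient sums (an
upper-bound variant substituting the reporting level exists but is off by
default).  Benchmarks printed as open bounds (">") are used at face
value, which makes the resulting quotients conservative upper bounds on
"<x" quantities.  HC5-substituted variants replace the IMI and CLO
benchmarks with mesocosm-derived HC5 values; because quotients are linear
in 1/benchmark, substitution rescales per-compound contributions exactly.

## Path models

Each endogenous variable is regressed by OLS on its parents (Gaussian
errors; counts or biomass may be log-transformed upstream), and
standardised coefficients are slope × sd(x)/sd(y).  Indirect/total
effects along a path are products of standardised coefficients.  Global
fit uses d-separation: for every non-adjacent ordered pair the partial
slope of the earlier variable in the regression of the later on both
parent sets gives an independence p-value, and Fisher's
C = −2 Σ ln pᵢ ~ χ²(2k).  Saturated graphs (the predator–prey spec) carry
no global test.  A model p-value above 0.05 is read as good agreement —
the standard convention for d-sep tests; the literature this implements
contains one statement of the opposite direction, which we treat as an
erratum.  Calibration is verified by simulation: under the true DAG the
rejection rate at α = 0.05 is statistically indistinguishable from 5%
over 500 datasets, and d-sep p-values are approximately uniform.

## Field model comparison

Sites are screened for multivariate outliers in the ten natural
covariates by Mahalanobis D² against the χ²(p) 0.999 quantile.  The
response is log10(total mayfly abundance + 1); zero-abundance sites are
retained.  Each covariate enters as a fixed-knot natural cubic regression
spline with df ∈ {1, 2, 3} chosen per term by AIC (df = 1 is linear;
knots at quantiles) — a deliberate, documented simplification of
penalised-GAM smoothing that keeps fits deterministic and fast.  Backward
elimination drops the least significant term (term-level F-test) while
its p-value exceeds 0.05; if nothing survives, the intercept-only model
is returned with a warning.

Eight pesticide predictors are then added one at a time: site CIBQs
(total, neonicotinoids, IMI, CLO), maximum IMI and CLO concentrations,
and two interaction models (CIBQ_IMI × CIBQ_CLO and maxIMI × maxCLO —
both main smooths plus the product of the transformed metrics).  Metrics
are transformed log10(X + half the lowest reported value); for IMI and
CLO concentrations the half-lowest constants are 0.005 and 0.0004 µg/L,
and for dimensionless quotients half the smallest positive observed value
is used.  A metric "improves" the model when its term is significant
(P ≤ 0.05) and the AIC beats the covariate-only model; models are ranked
by AIC.

## Synthetic data: what it emulates, and what it does not

`gen_mesocosm` reproduces the experimental layout: series IMI, CLO and a
1:1-by-mass binary mixture, five duplicated levels (0.001–10 µg/L unary;
0.0005–5 µg/L per compound in the mixture), three undosed controls, and
water samples on days 3/7/10/17/24 with lognormal jitter (CV 0.2) around
nominal and censoring below a 0.001 µg/L reporting level (the order of
magnitude of typical instrument detection levels for these compounds).
Count endpoints are negative-binomial around log-logistic means — the
error model is our choice (overdispersed counts are the field norm), with
dispersion 16 (between-duplicate CV ≈ 25%) reflecting the close agreement
of duplicate mesocosms in this kind of controlled colonised-tray system.
True EC50s default to 1.05 (IMI) and 1.35 (CLO) µg/L for total mayfly
abundance with slope 2.3 — steep enough that community abundance is
near zero at the top doses and the additive mixture prediction at the
5 + 5 µg/L treatment falls below the zero-limit floor, as observed in
such experiments.  Mixture means follow exact response addition divided
by a synergy multiplier γ (γ = 1 ⇒ additive truth).  Emergence is
binomial out of a 200-larva pool with a triangular daily pulse.  Not
emulated: taxonomic composition, temporal population dynamics,
water-chemistry covariates, or hormetic stimulation of emergence — so
passing tests say nothing about those aspects of real data.

`gen_field` draws an 85-site × 4-week screen: per compound, site-level
occurrence (Bernoulli), a per-week presence probability (0.75–0.8, which
creates the realistic gap between per-sample and per-site detection
frequencies), and lognormal concentrations censored at the reporting
level.  Mayfly abundance is negative-binomial around a mean set on the
log10(X + 1) scale by three active standardised covariates, main IMI/CLO
exposure terms, and an IMI × CLO interaction acting on
"detection lift" u = t(max) − t(0) (zero for undetected sites).  The
default effect spec has a modest interaction; the
`FIELD_EFFECT_STRONG_INTERACTION` spec is calibrated so natural
covariates explain roughly half the response variance and the interaction
adds substantially more, emulating the variance split reported for field
datasets of this kind.  Real field data additionally carry spatial
autocorrelation, covariate collinearity and many co-occurring stressors,
none of which are generated.

`gen_path_data` simulates standardised linear recursive systems: unit
population variances, residual variances solved from the implied
covariance (a configuration forcing negative residual variance raises),
so the population standardised coefficients equal the inputs exactly.

`gen_ssd_taxa` draws effect values from a named family and records the
true 5th percentile; groups cycle over mayfly/caddisfly/midge/crustacean
purely as labels.

## Degenerate inputs and tie-breaks

- `fit_logistic` requires ≥ 5 distinct dose levels; flat responses
  either fail to converge or produce gated ECs.
- TWA of a single measurement is that value; measurements are averaged
  from first to last sampling day (not day 0–30) by trapezoid.
- `select_model` ties go to LL3; backward elimination drops the largest
  p-value first.
- Zero observed mixture responses are floored and flagged rather than
  dropped.
- SSD fitting drops a family whose likelihood is non-finite and
  renormalises weights; > 20% bootstrap replicate failures is an error.
- The Mahalanobis screen refuses singular covariate covariance matrices
  rather than pseudo-inverting them.

## Problem sizes used in the verification suites

Recovery and calibration suites use 200 replicate datasets (dose–response
recovery, mixture null, SSD bootstrap coverage), 500 simulations for the
Fisher's C type-I rate, 100 datasets for the field interaction ranking,
and n = 10⁵–2×10⁵ observations for consistency-type checks (path
coefficient recovery, large-sample Akaike weights).  These sizes put
Monte Carlo error comfortably inside the asserted bands while keeping the
full suite and the acceptance script each within a few minutes on one
core.

## Known limitations

- Bootstrap weights are fixed at the original fit: HC5 intervals ignore
  model-selection uncertainty.
- The delta-method EC intervals are symmetric on the concentration scale
  and can under-cover for very shallow fitted slopes.
- No censored-data SSD fitting, no acute-to-chronic extrapolation, no
  hormesis models, no concentration-addition (Loewe) analysis — response
  addition is the only mixture null.
- The spline-based field models approximate penalised GAMs; exact
  equivalence with mgcv-style fits is not attempted.
- No spatial autocorrelation modelling in the field workflow.
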