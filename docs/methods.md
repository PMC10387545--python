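# Methods

## The model

The partial credit model (PCM) gives the probability of a person at latent
location θ (logits) responding in category k of item i with thresholds
τ_i1..τ_im:

    P(X_i = k | θ) = exp(kθ − Σ_{j≤k} τ_ij) / Σ_h exp(hθ − Σ_{j≤h} τ_ih)

A threshold is the latent location where adjacent categories are
equiprobable. The rating scale model (RSM) constrains the threshold
*spacings* to be equal across items (τ_ik = δ_i + κ_k); the dichotomous
model is the m=1 case. The item location δ_i is the arithmetic mean of the
thresholds. Probabilities are evaluated in log space (log-sum-exp), so no
θ magnitude can overflow the math; only I/O applies a ±10-logit cap.
Threshold *disorder* is representable on purpose — diagnosing it is a
feature, so the type does not enforce ordering.

## Estimation

**Items.** Because the raw score is sufficient for θ, the likelihood of a
response pattern conditional on each person's total over their observed
items contains no person parameters. We maximise this conditional
likelihood directly: the normalising constants γ_r (sums over all patterns
with total r) and their single-item-deleted versions are computed by
elementary-symmetric-function dynamic programming (polynomial convolution
with per-step rescaling), one pass per distinct missing-data pattern, with
analytic gradients (observed minus conditionally expected cumulative
category indicators). L-BFGS with a small quadratic gauge penalty pins the
one flat direction (a uniform shift of all thresholds); estimates are then
re-centred exactly so the mean item location is 0. Standard errors come
from the observed information projected onto the complement of the gauge
direction. Convergence: gradient norm < 1e-6 (warning carried into reports
otherwise). Degenerate items (fewer than two observed categories) are
excluded with a warning; a disconnected person-item design raises an error
naming the item components.

For two dichotomous items this reproduces the closed form
δ̂2 − δ̂1 = ln(n10/n01) exactly, and on small instruments it agrees with
naive brute-force maximisation of the enumerated conditional likelihood to
1e-4 logits (tested).

**Persons.** Weighted likelihood (bias-corrected ML): solve
r − ΣE_i(θ) + Σμ3_i(θ)/(2ΣW_i(θ)) = 0 by bracketed root finding, where E,
W, μ3 are the model mean, variance and third central moment of each item
score. The correction keeps estimates finite at zero/maximum raw scores
(flagged `extreme`); SE = 1/√(test information). Estimates are cached by
(observed-item pattern, raw score), which also guarantees the sufficiency
property: equal raw scores on complete data give identical measures. When
degenerate thresholds (e.g. unobserved super-item categories) leave the
score equation without a clean bracket, a grid fallback locates the sign
change or the minimising point.

**RSM vs PCM.** Both models are fitted by the same conditional machinery;
−2(logL_RSM − logL_PCM) is referred to χ² with (I−1)(m−1) degrees of
freedom. Unequal category counts (or a single item) skip the test and
force PCM.

## Residuals and fit

Standardized residuals are z = (x − E(θ̂))/√W̃. Because θ̂ is estimated
from the same responses, the raw model variance W overstates the variance
of the realised residual; by default we use the first-order leverage
correction W̃ = W(1 − W/Σ_j W_j). Without it, the mean of z² is ≈ (I−1)/I
(≈0.91 for 11 items) and the mean-square fit statistics would be biased
low by construction; with it, mean INFIT calibrates at ≈1.0 (measured
1.01 over 100 conforming replicates). The uncorrected form is available
(`leverage_adjust=False`). Persons with extreme scores, or a single
observed item (whose corrected variance is zero), are excluded from all
fit statistics.

Per item: OUTFIT = mean z², INFIT = Σ W̃ z²/Σ W̃, a Wilson–Hilferty
standardized fit residual of Σz² (the ±2.5 convention), a class-interval
chi-square (equal-count ability intervals, G = min(10, max(2, ⌊n/50⌋)),
which gives G=3 at n=188; interval score-residual sums squared over summed
variances, df = G−1; the pooled item-trait statistic sums over items), and
a one-way ANOVA of z across intervals. Chi-square and ANOVA flags are
Bonferroni-adjusted across items. Person fit uses the same Wilson–Hilferty
summary per row.

**The Smith interval.** The sample-size-corrected 5% INFIT band is
1 ± 2/√n (reported to two decimals; at n=45 it coincides with the familiar
0.7–1.3, at n=200 it is 0.86–1.14, and on the exact scale n=45 is the
smallest sample whose band sits inside 0.7–1.3). A caveat the package
measures honestly: the band implies SD(INFIT) ≈ 1/√n, which is accurate
for dichotomous items (residual kurtosis − 1 ≈ 1) but not for five-category
items, where kurtosis − 1 ≈ 2 makes the intrinsic SD(INFIT) ≈ √(2/n).
Consequently the corrected band's empirical Type-I rate on conforming
five-category data at n=500 is ~8–13% (design-dependent), not 5% — true
even when fit is computed with the generating parameters, so it is a
property of the band, not of estimation. The acceptance script reports the
measured rate; treat the Smith flag as the best available rule of thumb,
not an exact test, for polytomous items.

## Local dependency and dimensionality

Residual correlations are computed pairwise over co-observed persons
(pairs with <10 co-observations carry a low-n flag). A pair is locally
dependent when its correlation exceeds the average off-diagonal
correlation by 0.2 — short scales have mechanically negative averages
(≈ −1/(I−1)), so even small positive correlations can flag. Grouped items
are summed into testlets (a priori) or super items (post hoc); totals are
conserved exactly for complete data, and testlet thresholds are reported
as "not interpretable" for ordering purposes.

ECV (explained common variance) uses a method-of-moments bi-factor
decomposition: anchored single-testlet person estimates θ̂_t = g + u_t +
noise give Var(g) as the average between-testlet covariance and specific
variances as Var(θ̂_t) − mean SE_t² − Var(g); ECV = Var_g/(Var_g + mean s_t),
banded at 0.7 (multidimensional) / 0.9 (unidimensional). This is an
approximation, flagged as such in reports: it is well behaved for clearly
unidimensional or clearly orthogonal structures (tested at both ends) but
noisy for two large correlated testlets, where single-testlet estimates
are coarse.

The unidimensionality t-test splits items by loading sign on the first
principal component of the residual correlation matrix (ties join the
larger-|loading| subset), estimates each person from both subsets on the
anchored metric, and refers t = (θ̂_A − θ̂_B)/√(SE_A² + SE_B²) to ±1.96.
The verdict is unidimensional when the percent significant, or the lower
bound of its Clopper–Pearson 95% interval, is ≤5%.

## DIF

Screening: per item, a two-way ANOVA of standardized residuals on group ×
ability class interval; the group main effect is uniform DIF, the
interaction non-uniform DIF; Bonferroni over items × factors. The
substantive test splits the flagged item into deviating-group vs rest
columns (deviating group = largest |mean residual|), estimates the split
solution freely, anchors the unsplit solution through the non-DIF items,
and compares person estimates with a paired t-test; effect size =
|mean difference| / SD of the unsplit estimates, substantive at ≥0.1
(0.015 reported as the non-negligible bound). The comparison is made over
the deviating group's persons when one is named: the pooled item location
is close to the information-weighted mean of the group-specific locations,
so a whole-sample mean difference cancels by construction and would mask
exactly the bias being tested. Factors declared causal in the
configuration are screened and reported but never resolved by splitting
(group differences on a causal pathway are signal, not bias). One external
inconsistency is noted for the record: published guidance states the
substantive effect-size bound both as ≥0.1 and as >1.0 in different
places; the 0.1 rule is implemented.

## Reliability, targeting, transformation, equating

PSI = (Var(θ̂) − mean SE²)/Var(θ̂) over non-extreme persons; Cronbach's
alpha on complete cases (all persons, including extremes); separation
√(PSI/(1−PSI)); strata (4·separation + 1)/3; individual-use flag at 0.9.
Zero person variance reports PSI as undefined with a homogeneous-sample
note. Targeting summarises both distributions, emits Wright-map bin data
(0.25-logit bins), and warns beyond a 1-logit person−item offset.

The transformation table computes the weighted-likelihood estimate at
every raw score of the complete instrument and rescales linearly so raw 0
and raw max hit the reporting range ends exactly (0–100 by default;
one-decimal rendering in reports). Extreme raw scores use the finite
weighted-likelihood estimates rather than extrapolation constants.
Equating fits scale totals as polytomous items on one metric and emits a
cross-walk per scale; it refuses when a fitted scale-item has disordered
thresholds. Equating a scale against a literal copy of itself is
degenerate under conditional estimation (no discordant pairs), so
self-equating is meaningful only across independent administrations.

## The analysis protocol

`run_protocol` runs: (1) model choice (LR test) and baseline estimation
with item/person fit, reliability and targeting; (2) person-fit review
(report only); (3) threshold-ordering report, with remediation deferred
until dependency and dimensionality are settled; (4) LID rounds — on first
detection the configured a priori domain map is applied; thereafter each
round merges only the *strongest* flagged pair, except when the flagged
pairs partition every current column into ≥2 multi-column groups, which is
treated as component coalescence and merged at once (greedy union-merging
chains unrelated columns through noisy edges; the one-pair rule mirrors how
an analyst absorbs one dependency and re-tests); round limit 5, then a
merge-exhausted verdict; (5) if the t-test still says multidimensional,
the two residual-PCA components are grouped as testlets and re-analysed;
(6) DIF screening, then the substantive decision, with at most one split
resolution per run (a re-screen after splitting is the analyst's call);
(7) final reliability and the transformation table (omitted for retained
split solutions, which need per-group tables). Sample-size advisories:
warning below 100, a note outside 250–500, and a caution above 500 where
unconditional fit statistics inflate Type-I error. Reports are written as
JSON (every number in the human-readable summary is also in the JSON) and
are byte-identical for identical inputs, configuration and seed.

## The simulator and what the checks show

`simulate_responses` draws PCM responses at each person's
dimension-specific location, then applies dependency links (with
probability d the dependent item's response is replaced by the source
item's, the simplest mechanism giving tunable positive residual
correlation), then MCAR missingness. Uniform DIF is an additive location
shift for the group (implemented as a trait shift for that item);
non-uniform DIF multiplies the trait for that item. Multidimensionality is
multivariate-normal θ across dimensions with correlation r.

`whodas_like_fixture` emulates the structure of an 11-item, five-category
disability schedule in a stroke inpatient sample (n=188): six domains with
within-domain dependency d=0.5 plus a household→self-care link (d=0.4),
two components (physical vs cognitive/social) at r=0.7 — correlated but
separable, so that component-level dependency surfaces once domains are
testletized, as it does in such data — item locations spanning roughly
−1.1 to +0.9 logits, a well-targeted trait (θ~N(0,1)), and a 0.4-logit
education shift on the two concentration/learning items for the
illiterate group (modest enough that Bonferroni screening at n=188 only
sometimes detects it, which is realistic).

What passing these simulation checks shows: the estimators recover the
generating parameters at their nominal uncertainty; the detectors flag
injected violations and stay near their nominal false-alarm rates; the
protocol reproduces the qualitative decision sequence of a
domain-structured instrument. What they do not show: behaviour under
informative missingness, response styles, longitudinal carry-over beyond
person re-use, or guessing/discrimination phenomena outside the Rasch
family — none of which the generator emulates. MCAR is the only
missingness mechanism; structural missingness is represented by omitting
an item entirely.

## Known limitations

* Item-level fit statistics are unconditional; conditional (bias-free)
  item fit is limited to the pooled machinery and is the main reason for
  the n>500 advisory.
* The ECV estimator is a moment approximation, unstable for two large
  correlated testlets (reported with its band, never used as a gate by
  itself).
* The Smith INFIT band under-covers for polytomous items (see above).
* RSM standard errors are not reported (the RSM fit exists for the
  likelihood-ratio choice; PCM is the reporting parameterisation).
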