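# Methods

## Model

Responses are binary indicators of nine sexual-risk behaviors.  The
dichotomous Rasch model places respondents (θ_n, "risk severity") and
behaviors (δ_i, "difficulty of endorsement") on one logit scale:

    P(X_ni = 1 | θ_n, δ_i) = exp(θ_n − δ_i) / (1 + exp(θ_n − δ_i)).

Assumptions: a single latent dimension; conditional (local)
independence of items given θ; equal item discrimination.  The
dimensionality and local-dependence diagnostics test the first two;
the third is untested (no 2PL comparison is in scope).

## Scoring the survey

Condom-use frequency answers are dichotomized: `every_time` → 0, any
lesser frequency → 1.  Respondents who did not practice a behavior
score 0 on that item rather than missing — a behavior never performed
cannot have been performed unsafely, and this keeps the full-sample
denominator for every item, matching the published frequency table.
Concurrency (item 9) is 1 when any two partnership intervals
(first-to-last intercourse dates) overlap under closed-interval
comparison; a shared boundary day counts as overlap, since intercourse
with both partners on one day is concurrency in substance.  Input dates
are ISO-8601; records are assumed already restricted to the six-month
recall window.

## Estimation

Joint maximum likelihood with PROX starting values (marginal log-odds
expanded by √(1 + var/2.89), items centered).  Each cycle applies one
damped Newton step per parameter set —

    δ_i ← δ_i − (s_i − Σ_n P_ni)/Σ_n W_ni,   W = P(1−P)
    θ_n ← θ_n + (r_n − Σ_i P_ni)/Σ_i W_ni

(sums over observed cells only; steps capped at 1 logit; non-extreme
difficulties recentered to mean 0) — until the largest parameter change
is below 0.001 logits and the largest observed-minus-expected marginal
score below 0.01, with a 200-iteration cap; non-convergence is flagged
in the result, not raised.  Standard errors are 1/√ΣW at convergence.

Zero and perfect marginal scores carry no likelihood information.
Extreme persons and items are pruned iteratively (removing one can
expose the other), excluded from estimation, and measured afterwards by
solving the score equation at a fractional adjustment of 0.3 score
units inside the boundary (score 0 → 0.3, score L → L − 0.3).  The 0.3
default reproduces the published boundary measures −5.71 and 5.03 of
the conversion table.

**Known bias.**  JMLE difficulty estimates are inconsistent at fixed
test length.  For this 9-item scale with a 7.4-logit difficulty range
and a poorly targeted population, the expansion is substantial: on
synthetic cohorts of N=2000 the recovered difficulties correlate
> 0.999 with the generating values but are expanded enough to give an
RMSE near 0.7 logits, and the classical (L−1)/L shrinkage
(`EstimationConfig(bias_correction=True)`, off by default to match
common practice) removes only about half of it.  A marginal-likelihood
oracle on the same data attains RMSE < 0.13, so this is estimator bias,
not an information limit.  Rank order, fit diagnostics and the
score-conversion table (a function of a *given* calibration) are
unaffected; absolute difficulty values at this design should be read
with that caveat.

## Score conversion

For each raw score r, Σ_i P(θ, δ_i) = r is solved by safeguarded
Newton iteration (stopping at |Δθ| < 1e-8, bracket fallback), with the
boundary adjustment above; SE(θ) = 1/√(Σ_i W_i(θ)).  A bisection
oracle agrees to 1e-6 in the test suite.  Measures are strictly
increasing in r and SEs are U-shaped in r.

## Fit statistics

Per item or person u over its observed estimation cells:
outfit = mean z², infit = Σ(x−P)²/ΣW, z = (x−P)/√W.  Mean squares map
to approximate t deviates by the Wilson–Hilferty transform
t = (ms^⅓ − 1)(3/q) + q/3 with q² the variance of the mean square
(infit: Σ(C − W²)/(ΣW)²; outfit: Σ(C/W²)/n² − 1/n; C = W(1−3W)).
Flags are two-sided at |t| > 2, review at |t| > 3, with infit ranked
first in reports.

**Caveat.**  For off-target respondents on a 9-item test, outfit cells
can have W ≈ 10⁻⁴, making q large (3–14); the cube-root transform then
degenerates toward q/3 and the person-level outfit ZSTD flags
respondents regardless of their data.  Item-level statistics (hundreds
of cells, moderate q) are unaffected.  Person misfit should be read
from infit — which the field conventionally scrutinizes first anyway —
and the analysis drivers report it that way.

## Reliability

Separation reliability = (observed − mean error variance)/observed
variance, clipped to [0, 1], with population (÷n) variance for the
spread and mean se² for the error term; separation = √(rel/(1−rel)).
Both n and n−1 spread conventions round the published item calibration
to the same 0.99, so the choice is documented rather than consequential.
Extreme persons/items are excluded.

## Dimensionality and local dependence

PCA is performed on the item × item Pearson correlation matrix of
standardized-residual columns (pairwise-complete over estimation
cells), so each item contributes one eigen-unit and the eigenvalues sum
to the number of items; the "first contrast" is the leading eigenvalue
and its loadings.  Constant residual columns are excluded with a
warning.  The variance explained by the Rasch measures is approximated
as V_m = L·var(E_ni)/mean(W_ni) over cells, split into person and item
shares in proportion to the variance of row versus column means of the
expected-score matrix.  This convention is monotone in the simulated
ability spread (unit-tested) and is used for guideline verdicts
(measures > 50%; items > 4× first contrast; first contrast < 3.0), not
for numeric comparison with any vendor's variance table, whose
arithmetic is unpublished.

Local dependence is screened by all pairwise residual correlations at
|r| ≥ 0.30.  Two facts matter for interpretation.  First, after a
common dimension is fitted, residual correlations have a negative
baseline of order −1/(L−1) ≈ −0.13, so mildly negative pairs are
expected, not evidence of dependence.  Second, with only nine items the
fitted θ absorbs roughly half of a genuine pairwise shock: a
shared-draw dependence that produces a residual correlation of 0.3–0.7
at the generating parameters attenuates to roughly 0.1–0.35 through
the fitted pipeline.  Detection power checks therefore use the
generator's retained abilities (`SimulatedResponses.generating_fit`)
for the clean statistic, and treat fitted-pipeline correlations as a
conservative screen.

## Invariance (DIF)

The cohort splits at raw score ≤ 2 (Low) versus ≥ 3 (High); score 3
goes to High so the groups are exhaustive.  Each group is calibrated
independently; because each group may have different extreme items,
both difficulty sets are recentered to mean 0 over the items estimable
in *both* groups before comparison.  Item i is invariant when
|d_high − d_low| ≤ 1.96·√(se_low² + se_high²); the module also emits
identity-line and band-curve coordinates for a scatter plot.

This split design has limited resolution at N≈351: the Low calibration
rests on raw scores 1–2 only, giving wide bands and residual
differential JMLE bias of up to ≈1 logit on individual items.  In
synthetic null cohorts roughly one item per run falls outside its 95%
band — most often "Had unsafe anal sex with MSM", the same item the
original administration reported as its single non-invariant item,
which suggests that finding may be a split-plus-JMLE artifact rather
than substantive DIF.  Power simulations here show uniform 1-logit DIF
is usually *not* detectable at this design (it can even be cancelled by
the item's null offset), while ≥2.5-logit DIF is flagged reliably.

## Synthetic cohorts

The generator emulates the study conditions: N=351, the published
difficulty vector, and abilities Normal(μ=−2.52, σ=1.83) — calibrated
once by Gauss–Hermite quadrature + Nelder–Mead so model-implied
margins match the published endorsement percentages (achieved within
±1.3 points).  A normal ability law is a convention; nothing in the
published material identifies the ability distribution, and the
published person reliability (0.35) depends on the unavailable
raw-score distribution, so it is not a reproduction target (the
synthetic cohort gives ≈0.67).  Optional injections: DIF (difficulty
shift for the above-median-ability group, defined on the latent θ so
the effect exists pre-response), local dependence (with probability ρ a
person's two paired outcomes are replaced by one shared Bernoulli draw
at the mean cell probability; induced correlation is monotone in ρ),
and a second latent factor (independent N(0,1) score per person added
with a chosen loading to a subset of items).  All draws come from a
seeded generator in a fixed order, so identical specs give
bit-identical matrices, and generating abilities are retained for
oracle checks.  Survey-record dressing (frequency categories,
partnership dates in a 182-day window) uses an independent substream,
so scoring the records reproduces the response matrix exactly.

What the generator does **not** emulate: respondent-driven-sampling
network structure, interviewer effects or underreporting, missing
data, and the true cohort's raw-score distribution.  Green tests
therefore certify the measurement machinery on Rasch-consistent data
with realistic margins, not the behavior of the original sample.

## Problem sizes and tolerances

Simulation-based tests use N=351 (study scale) to N=2000, chosen so
each check's Monte-Carlo error is small relative to its assertion
margin; the full suite runs in seconds.  Numerical tolerances:
JMLE 1e-3 logits, score-equation Newton 1e-8, centering checks 1e-6,
published-table comparisons ±0.02 logits (the rounding radius of
2-decimal printed difficulties).
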