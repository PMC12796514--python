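# Methods

This note documents the models implemented in `koalapop`, the defaults
and why, the numerical choices, and what the synthetic-data tests do and
do not demonstrate about real data.

## Observation model and debiased density

Presence-only sighting records collected opportunistically are treated
as a realisation of an inhomogeneous Poisson process whose intensity is
the product of a spatially constant mean animal density λ (animals
km⁻²) and a detection probability p(x) ∈ (0, 1]. The detection model
captures three biases seen in volunteer-collected koala data: observers
cluster around a well-known hotspot (exponential decay e^(−a·d(x,h)),
d in km), detect more readily inside protected areas (multiplier b ∈
(0, 1] outside parks), and search near roads (e^(−c·d_r(x)), d_r in m).
The unit conventions are deliberate: decay coefficients of order 0.26
per km (hotspot) and 7×10⁻⁴ per m (roads) are only interpretable on
those scales, and both units are explicit in the configuration and file
names.

Assumptions: animals are counted at most once; their locations are
independent (no social clustering or territorial inhibition at the
analysis scale); detection of one animal does not affect detection of
another. Counts in disjoint regions are then independent Poisson
variables and the likelihood factorises into n·log λ + Σ log p(xᵢ) −
log n! − λ∫_C p dx.

Numerical choices:

* ∫_C p dx uses cell-midpoint quadrature at the 1-km analysis
  resolution. The detection field is defined on the same grid
  (piecewise constant within cells), which keeps simulation, point
  evaluation and quadrature mutually consistent — the fitted model is
  then exactly the data-generating model in simulation studies.
* λ is profiled analytically: at fixed (a, b, c) the score equation
  gives λ̂ = n/∫p dx, removing a likelihood ridge; only (a, b, c) are
  optimised, by bounded L-BFGS-B from three fixed starting points.
* Box bounds a, c ∈ [0, 100], b ∈ [10⁻⁶, 1] keep the log-likelihood
  finite; degenerate parameter regions return a large finite penalty
  rather than ±inf so line searches stay well behaved.
* Parametric bootstrap: each replicate re-simulates a pattern at the
  fitted parameters by thinning (exact for an inhomogeneous Poisson
  process) and refits; CIs are the 0.025/0.975 sample quantiles.
  Replicates whose refit fails are dropped; more than 10% failures is
  an error.

The recovery experiments show per-parameter 95% CI coverage of
92%–98%. The joint event "all four parameters inside their marginal
95% intervals simultaneously" has an irreducible ceiling near
0.95⁴ ≈ 0.81–0.86 and is reported but not a calibration criterion.

## Suitability ensemble

The ensemble machinery is learner-agnostic: any classifier exposing
`fit`/`predict_proba` can be registered. Two defaults ship — a
standardised logistic regression and a random forest — because the
workflow (pseudo-absences, repeated splits, TSS weighting, permutation
importance), not the individual learners, is the object of interest.
Defaults: 2000 pseudo-absences sampled uniformly from presence-free
cells (one point per cell, without replacement), 20 stratified 80/20
train/validation repetitions, TSS-weighted averaging with learners at
TSS ≤ 0 excluded, threshold at the exact TSS maximiser over all unique
predicted values (cells below it are treated as absent downstream).
Permutation importance is 1 − Spearman ρ between the benchmark
prediction and the prediction after permuting one covariate, averaged
over 10 permutations per learner and TSS-weighted across learners;
constant predictions make ρ undefined and contribute 0 with a warning.
The VIF screen flags covariates at VIF ≥ 10.

## Suitability-to-density mapping

Three shapes are available: quadratic-unimodal d ∝ s(1−s) (density
peaks at intermediate suitability — the default, matching the stated
ecological assumption of the source analysis), proportional d ∝ s, and
monotone-quadratic d ∝ s². The default is genuinely debatable: observed
density maps often peak where suitability is highest, which the
monotone shapes capture better, so the choice is a config switch and
all three are tested. Whatever the shape, the scale factor is chosen so
the area-weighted mean density over modelled-present cells equals λ̂
exactly (enforced to 10⁻⁶ relative); totals are therefore linear in λ̂
and CIs follow by rescaling at the λ CI endpoints. Density targets in
animals ha⁻¹ convert as ×100 to km⁻².

## Demographic projection

A 13-age (0–12 y) female-only Leslie matrix, pre-breeding census,
fertility in daughters female⁻¹ year⁻¹ under a 1:1 sex ratio (totals
are reported as 2× females; a source table in total offspring is halved
on ingest via a config flag).

**Vital-rate inputs.** Multi-study tables of age-specific medians with
upper/lower limits (±1.96 SE). Survival synthesis: per resampling
iteration a study's median/SD is drawn per age class (cells missing
from the drawn study take the mean of the values available for that age
class; ages absent from every study are linearly interpolated), 13
survival probabilities are beta-sampled, and the exponential
association s(x) = a·e^(−e^(b−c·x)) is fitted by bounded least squares.
The mean fitted constants define the smoothed schedule; the 2.5/97.5
percentiles summarise its uncertainty. Iterations whose fit fails are
dropped (error beyond 20%).

**Reference schedule.** The package ships a synthetic reference
vital-rate schedule — survival constants (a, b, c) = (0.98, −0.60,
1.20), flat fertility of 0.45 daughters female⁻¹ year⁻¹ at ages 2–12 —
standing in for the multi-study compilation used in the source
analysis, whose table is not redistributable here. It was calibrated
once against published anchors for the modelled population: generation
length 6.75 years (ours: 6.753), an unmanaged 25-year increase of
~18% under the density feedback, and a 5%–8% annual sterilisation
effort roughly holding abundance constant. Implied deterministic growth
rate: 1.099 y⁻¹. Adult survival of 0.98 and annual breeding are at the
optimistic end of published koala demography, consistent with a
predator-free, food-rich range.

**Stochasticity.** Fertility is resampled yearly as Gaussian with 3%
SD and survival as beta with 5% SD (both relative to the mean by
default; an absolute-SD switch exists because the convention is
ambiguous). Beta moments are feasibility-clamped (SD capped at 95% of
the maximum for the given mean).

**Density feedback.** Survival is multiplied by
S_mod(N) = 1 − (1 − m_K)·(N/K)^θ with θ = 8 and m_K solved (Brent) so
the modified matrix has dominant eigenvalue exactly 1 at N = K;
K = 1.2 × initial total abundance, on the both-sex scale. This form
satisfies S_mod > 0.999 below K/2, declines monotonically, and — since
it keeps declining beyond K — gives a stable deterministic equilibrium
at K (verified to 10⁻⁷). A logistic alternative centred at 0.9K is
retained as an option but saturates before K and stalls the trajectory
~5% below it; a clipped literal reading of a published three-constant
form is also retained for reference only, as those constants do not
yield a multiplier in (0, 1] on any population scale tried.

**Catastrophes.** Events occur with probability 0.14 per generation,
converted to an annual probability by dividing by the generation length
(the standard convention in the catastrophe literature; made explicit
here because it is often left implicit). Each event multiplies every
age class by 1 − m with m ~ Normal(0.5, 0.05) clipped to [0, 1].
Expected events over 25 years: 25 × 0.14/6.75 ≈ 0.52.

**State and projection.** Three real-valued pools per age class —
breeding, disease-infertile, sterilised — advance together; births come
from breeders only, newborns split 4% to the infertile pool. Treatment
and feedback use expected-value (proportional) updates rather than
integer draws, appropriate at abundances of 10³–10⁴ and verified
against an individual-based oracle for the treatment step. The annual
order is: sample rates → sterilise → apply feedback (from current
both-sex N) → advance/birth → catastrophe. Extinction is absorbing.

## Management

Scenario (i) treats a proportion p of all non-sterilised adult females
(the ~4% chlamydia-infertile cannot be distinguished and waste
implants); scenario (ii) treats p of breeding females only — carrying a
back young proves fertility — plus each treated mother's female joey
(expected joeys per treated mother equal the current age-0 breeders per
breeding female, so the treated count is p·(mothers + age-0 breeders)).
Sterilisation is permanent; treated animals stay in the population and
are never re-treated. Adult ages are defined at runtime by the first
nonzero fertility age of the ingested schedule.

The chlamydia infertile fraction is prevalence × progression × share of
inactive females infected = 0.47 × 0.11 × 0.85 ≈ 0.044, with the
progression term derivable from survey counts through a conjugate
beta-binomial posterior (3 diseased of 75 with a uniform prior gives
mean 5.2%, CI 1.45%–11.11%, the cautious upper bound being 11%).

Costs are exactly unit cost × treated animals, unit cost
0.83 h × 30 AU$ h⁻¹ + 27 AU$ = 51.9 AU$; joeys treated at capture are
costed like adults. The minimum-effort search sweeps p (default 1%
steps), decides on the median final total (CI envelopes are reported
but do not drive the decision), and flags unreachable targets. Treated
counts accumulate monotonically in time and — up to the effort level
where the population crashes — in p; beyond the crash point higher
effort treats fewer animals in total, so cost orderings across density
targets are only guaranteed on the minimal effort, not on the treated
counts.

Both-sex sterilised counts are reported as 2× the female count
alongside the female-only count, since treatment targets females but
totals are conventionally quoted for both sexes.

## What the synthetic tests do and do not show

The generators emulate the *structure* of the real inputs — a bounded
planar study region with disc parks and straight roads (closed-form
distances, easy oracles), smooth Gaussian-bump covariate fields with a
known logistic suitability truth, detection-thinned sightings, and
jittered multi-study rate tables. Passing tests therefore demonstrate
that the estimators are calibrated and the pipeline is self-consistent
when its assumptions hold. They do not show robustness to what real
data add: spatial dependence between animals, detection decay within
surveys, covariate measurement error, non-stationary effort, or
geographic complexity of real park/road networks. Scaled-down problem
sizes are used throughout the test suite (e.g. 30×30 km grids, 50–100
bootstrap/recovery replicates, 500–3000 projection iterations); the
acceptance script uses 100 recovery replicates × 100 bootstrap
replicates and 10,000 projection iterations.

## Known limitations

* No spatial interaction models (clustering/inhibition); independence
  is assumed, so real-data CIs are likely anti-conservative.
* No dispersal, male demography, disease dynamics or genetics; the
  projection is closed and spatially unstructured.
* The suitability-to-density shape is an assumption, not an estimate;
  all three shapes are one-parameter rescalings of the suitability map.
* Implants are modelled as permanent over the horizon (no expiry or
  re-treatment dynamics).
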