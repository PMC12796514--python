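# koalapop

Tools for planning fertility-control management of locally overabundant
koala (*Phascolarctos cinereus*) populations from presence-only
citizen-science records. The package chains five stages:

1. **Debiased density.** Sightings are modelled as an inhomogeneous
   Poisson point process with intensity λ·p(x), where the detection
   probability

   p(x) = p_o(x) · e^(−a·d(x,h)) · e^(−c·d_r(x)),  p_o(x) = 1 inside a
   park, b outside

   combines three documented observation biases: proximity to a
   detection hotspot (d(x,h), km), park membership, and distance to the
   nearest road (d_r(x), m). Maximising the Poisson likelihood

   L = λⁿ ∏ᵢ p(xᵢ) / n! · exp(−λ∫_C p(x) dx)

   gives a debiased mean density λ̂ (λ profiled analytically as
   n/∫p dx); a parametric bootstrap (simulate at the fit, refit, take
   2.5/97.5 percentiles) gives confidence intervals.
2. **Habitat suitability.** A TSS-weighted ensemble of pluggable
   learners fitted on presences plus 2000 random pseudo-absences over
   20 stratified 80/20 train/validation splits, with permutation
   variable importance (1 − Spearman ρ), response curves, and a VIF
   multicollinearity screen.
3. **Abundance.** The suitability map is converted to a density map
   (quadratic-unimodal d ∝ s(1−s) by default, proportional and s²
   alternatives) rescaled so the mean density over modelled-present
   cells equals λ̂ exactly; totals, CIs and the area beyond a density
   target (0.7 animals ha⁻¹ by default) follow.
4. **Projection.** A 13-age female-only Leslie model (1:1 sex ratio)
   with beta/Gaussian vital-rate stochasticity, survival smoothed by
   s(x) = a·e^(−e^(b−c·x)) fitted to resampled multi-study tables,
   compensatory density feedback calibrated so growth stops exactly at
   K = 1.2·N₀, and catastrophic mortality at 0.14 per generation
   (50% ± 5% magnitude), run 10,000 iterations × 25 years.
5. **Management.** Two sterilisation scenarios (adult females only;
   mothers with back young plus their female joeys), a chlamydia
   infertility adjustment (0.47 × 0.11 × 0.85 ≈ 4% of females already
   infertile), per-animal treatment cost 0.83 h × 30 $/h + 27 $ =
   51.9 AU$, and a sweep-based search for the minimum annual effort
   meeting a population target.

Synthetic generators (`koalapop.synthetic`, `koalapop.landscape`)
produce every input — landscape with parks/roads/hotspot, covariate
fields with a known suitability relationship, sightings thinned by a
known detection model, multi-study vital-rate tables — with recorded
ground truth, so the full pipeline is testable offline.

## Worked example

```python
import numpy as np
from koalapop import (
    make_landscape, simulate_sightings, fit_mle,
    suitability_to_density, total_population, area_beyond_target,
)

land = make_landscape(extent=(30, 30), n_parks=2, n_roads=3, seed=1)
sightings = simulate_sightings(land, 106.0, (0.26, 0.18, 7e-4), seed=2)
fit = fit_mle(sightings, land).bootstrap(land, n_boot=200, seed=3)
print(f"n = {len(sightings)}  lambda = {fit.lambda_:.1f} km^-2  "
      f"CI = {fit.ci_['lambda'][0]:.0f}-{fit.ci_['lambda'][1]:.0f}")
print(f"a = {fit.a_:.2f}  b = {fit.b_:.2f}  c = {fit.c_:.1e}")
```

prints

```
n = 1059  lambda = 106.2 km^-2  CI = 98-117
a = 0.25  b = 0.18  c = 7.0e-04
```

— 1059 retained sightings debiased to a mean density of ~106 animals
km⁻² (truth 106 inside the CI), with the hotspot decay (a), outside-park
multiplier (b) and road decay (c) all recovered near their generating
values. Feeding λ̂ into a suitability map then yields a calibrated
density map whose `total_population` and `area_beyond_target` quantify
how much of the modelled range already exceeds the 0.7 ha⁻¹ cap.

The same stages run from the shell:

```sh
koalapop simulate --out demo --extent 30 30 --density 106 --seed 1
koalapop fit-ipp --sightings demo/sightings.csv --landscape demo/landscape --boot 200 --seed 2
koalapop run-all --out demo_run --seed 7
```

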