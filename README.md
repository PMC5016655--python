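# dungsight

Indirect distance sampling for ungulate dung surveys: joint estimation of
a detection function and a covariate-driven density model, AICc model
selection and averaging, dung-to-animal conversion, and habitat-selection
analysis.

## The problem

Low-density desert ungulates are rarely seen but leave durable sign.
Strip-transect surveys of fecal pellet groups turn that sign into density:
each *pellet event* (a group of ≥ 10 pellets) is recorded with its
perpendicular distance from the transect line, territorial dung piles
(middens) are excluded because their placement marks territory rather than
resource use, and declining detectability with distance is corrected by a
detection function. Because pellet groups persist for hundreds of days in
arid climates, one survey integrates habitat use over a long window.

`dungsight` is written for ecologists running such surveys — in the
motivating design, paired wadi/plain transects for scimitar-horned oryx
and dorcas gazelle in a fenced arid reserve — and for methodologists who
want the whole chain testable against a generator with known truth.

## The model

For transect *i* (length L, half-width w, covariates x_i) in wadi system
*s*, counts in distance interval *k* are Poisson with

    λ_ik(b_s) = 2L · exp(β₀ + x_iᵀβ + b_s) · ∫_bin_k g(y; σ) dy,
    g(y; σ) = exp(−y² / 2σ²),        b_s ~ N(0, σ_b²),

and one likelihood estimates β, σ_b and the detection scale σ jointly,
integrating the system random effect by adaptive Gauss–Hermite
quadrature. Candidate covariate models are ranked by AICc, summarized by
Akaike weights, a 95% confidence set and model-averaged coefficients;
pellet-group density converts to animal density through
D_animal = D_dung / (r·T) with defecation rate r and mean decay time T;
habitat use is summarized by Manly standardized selection ratios
(B_i ≥ 0.5 marks a key resource area) and Shannon–Wiener diversity H′.

## Worked example

```python
from dungsight import (SimulationScenario, simulate_survey, filter_middens,
                       bin_distances, ModelSpec, build_model_data, fit,
                       ConversionRates, dung_to_animal, predict_density)

scenario = SimulationScenario(seed=42)        # 18 wadi/plain pairs, 8 systems
survey = simulate_survey(scenario)
retained, bookkeeping = filter_middens(survey.events)
print(bookkeeping)

binned = bin_distances(retained, survey.transects, survey.cutpoints)
spec = ModelSpec(species="oryx", terms=("rock_cover", "richness"))
data = build_model_data(binned, survey.transects, survey.covariates, spec,
                        survey.cutpoints)
model = fit(data, spec, seed=0)
print(model.coef_table().round(4))
print(f"sigma_det = {model.sigma_det:.2f} m   AICc = {model.aicc:.2f}")

rates = ConversionRates(defecation_rate=20.0, decay_days=505.0)
d_dung = predict_density(model, survey.covariates)["density_per_m2"].mean() * 1e6
d_animal = dung_to_animal(d_dung, rates)
print(f"dung density  = {d_dung:,.0f} groups/km^2")
print(f"animal density = {d_animal:.2f} animals/km^2  "
      f"(~{d_animal * 38:.0f} animals on a 38 km^2 plain)")
```

Output:

```
          recorded  middens  retained
oryx           713       13       700
gazelle        192       60       132
combined       905       73       832
            term  estimate      se
0      intercept   -5.1329  0.3225
1     rock_cover   -0.0233  0.0068
2       richness    0.2437  0.0266
3    log_sigma_b   -1.2097  0.3213
4  log_sigma_det    0.3929  0.0332
sigma_det = 1.48 m   AICc = 417.87
dung density  = 24,882 groups/km^2
animal density = 2.46 animals/km^2  (~94 animals on a 38 km^2 plain)
```

The bookkeeping table audits the midden filter (recorded − middens =
retained, per species). The fit recovers the generator's truth (rock
cover −0.031, richness +0.208, σ = 1.5 m) within its standard errors:
oryx dung density falls with rock cover and rises with plant species
richness, and a pellet group on the line is detected with certainty while
one at the 4 m strip edge is detected with probability
exp(−4²/(2·1.48²)) ≈ 0.026. Dividing the fitted pellet-group density by
r·T = 20 × 505 gives about 2.5 animals/km².

The same chain is available from the shell:

    dungsight simulate --seed 42 --out survey/
    dungsight select --events survey/events.csv --transects survey/transects.csv \
        --quadrats survey/quadrats.csv --species oryx
    dungsight run --seed 42 --out report/      # full pipeline bundle

## Layout

- `dungsight.survey_data` — schemas, CSV readers, midden filter, distance
  binning, quadrat→transect covariate aggregation
- `dungsight.synthetic` — the survey generator (study design + generative
  laws), steady-state dung density
- `dungsight.detection` — half-normal / hazard-rate detection functions,
  bin probabilities, effective strip width, design-based density
- `dungsight.integrated` — the joint likelihood, fitting, AICc, density
  prediction
- `dungsight.model_selection` — candidate sets, Δ AICc, Akaike weights,
  confidence sets, importance, model averaging
- `dungsight.abundance` — rate-based conversion and abundance intervals
- `dungsight.habitat` — Ward habitat typing, selection ratios, H′,
  Wilcoxon contrasts
- `dungsight.pipeline` / `dungsight.cli` — end-to-end runner and the
  `dungsight` command

See `docs/methods.md` for model assumptions, defaults and limitations.
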