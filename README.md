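# splicekin

Single-molecule colocalization (CoSMoS) analysis of spliceosome
activation kinetics, as a reusable Python library: simulate
multi-channel fluorophore binding traces from a kinetic model of
tri-snRNP recruitment, detect binding events by threshold rules,
classify tri-snRNP arrival/departure pathways, and fit dwell-time
distributions with censored exponential-mixture and convolution
likelihoods.

## The problem

During spliceosome activation on a pre-mRNA, the U4/U6.U5 tri-snRNP
binds (forming B complex) and then either releases intact (discard) or
irreversibly loses U4 (activation), after which the NTC (Prp19 complex)
joins. In multi-wavelength TIRF recordings each tethered pre-mRNA shows
arrival and departure of labeled U4, U5 and NTC spots; the kinetics are
read out as dwell times censored by the recording window.

A dwell is observable only inside `[t_m, t_max]` (minimum detectable
dwell, one frame spacing; recording length 60 min). Dwell densities are
exponential mixtures renormalized over that window,

    f(t) = [Σᵢ Aᵢ (e^(−t_m/τᵢ) − e^(−t_max/τᵢ))]⁻¹ · Σᵢ (Aᵢ/τᵢ) e^(−t/τᵢ),

or, for two sequential rate-limiting steps, the window-normalized
convolution `f(t) ∝ (e^(−t/τ₁) − e^(−t/τ₂))/(τ₁ − τ₂)`. Fits are
unbinned maximum likelihood with bootstrap standard errors; outcome
routes (U4 lost first / U5 lost first / simultaneous loss / persist)
are tallied from coincident U4+U5 arrivals. See `docs/methods.md` for
the full model description.

The package is for single-molecule kineticists who want a tested,
scriptable reimplementation of this analysis chain, and for method
development where ground truth is needed — the simulator generates the
same data the analysis consumes.

## Worked example

```python
from splicekin import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(preset="2mM", n_molecules=300,
                                     seed=11, fit_cohorts=False))
tally = report["tally"]
print(tally["counts"])
resolved = tally["total"] - tally["counts"]["PERSIST"]
print(round(100 * tally["counts"]["U4_FIRST"] / resolved, 1))
```

prints

```
{'U4_FIRST': 293, 'U5_FIRST': 2, 'SIMULTANEOUS_LOSS': 155, 'PERSIST': 57}
65.1
```

i.e. out of 507 detected coincident U4/U5 arrivals, 65.1% of the
resolved events lost U4 first (activation) — recovering, within
binomial error and a small detection bias from sub-frame discard
events, the 62% activation flux configured in the physiological-ATP
preset. The `examples/` directory holds one short script per
capability (simulation/rendering, detection, pathway classification,
dwell-time fitting, NTC-ordering with a shuffled control, and the
photobleaching power control), each printing the numbers it computes.

## Layout

- `splicekin.simulate` — kinetic schemes, Gillespie simulation, dwell
  sampling, trace and background rendering, ATP-regime presets
- `splicekin.detect` — baseline estimation, hysteresis event detection,
  dwell extraction
- `splicekin.pathways` — coincidence matching, outcome routes,
  multi-binding/rebinding, NTC-vs-U4 ordering with randomized control,
  correlations, background rates
- `splicekin.dwell` — censored densities, MLE fitting, bootstrap,
  probability-density histograms, model selection, photobleaching
  global fit
- `splicekin.pipeline` — end-to-end seeded runs, report bundles,
  worked-example fixtures; `splicekin.io` — CSV/JSON interchange
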