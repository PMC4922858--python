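# Methods

`splicekin` analyzes (and simulates) multi-wavelength colocalization
single-molecule spectroscopy (CoSMoS) recordings of spliceosome
activation on surface-tethered pre-mRNA molecules. The observables are
arrivals and departures of fluorescently labeled U4, U5 and NTC
(Prp19-complex) particles at each pre-mRNA: a simultaneous U4+U5 arrival
marks U4/U6.U5 tri-snRNP binding (B-complex formation), loss of U4 with
U5 retained marks activation, simultaneous U4/U5 loss marks discard of
the intact tri-snRNP.

## Censored dwell-time densities

A dwell is observable only inside the window `[t_m, t_max]`: `t_m` is the
minimum detectable dwell (one frame spacing; 3 s by default, 5 s for the
5-s-spacing acquisition variant) and `t_max` the recording length
(3600 s). All densities are renormalized over this window.

Exponential mixtures with k = 1..3 components:

    f(t) = [ Σ_i A_i (e^{-t_m/τ_i} − e^{-t_max/τ_i}) ]^{-1} Σ_i (A_i/τ_i) e^{-t/τ_i}

with amplitudes on the simplex and time constants τ_i > 0, reported in
ascending order. Processes with two sequential rate-limiting steps use
the convolution of two exponentials,

    f(t) ∝ (e^{-t/τ1} − e^{-t/τ2}) / (τ1 − τ2),

window-normalized analytically, with a continuous Erlang-2 branch
(`t e^{-t/τ}/τ²`) entered when |τ1 − τ2| ≤ 1e-9·max(τ1, τ2). The printed
form of the convolution normalizer admits two readings of its constant
prefactor; since any constant cancels under normalization we use the
analytic window mass and verify unit mass by quadrature at construction
(tolerance 1e-6). Likelihood ranking is invariant to this choice.

### Fitting

Parameters are estimated by unbinned maximum likelihood in transformed
coordinates (log τ, softmax amplitudes) with Nelder–Mead and ≥ 8
multi-starts from stratified quantile-based initial guesses (jittered by
a seeded generator; fits are deterministic given the seed). Convergence
tolerance is 1e-8 on the log-likelihood. Right-censored dwells (signal
persisting at `t_max`) are excluded from fitting, consistent with
densities normalized over the observable window.

Dwells measured by the frame-based detector sit on the frame grid with
an atom exactly at `t_m`; there the truncated-mixture likelihood is
unbounded as a component's τ → 0. Fits on detector output therefore
apply a floor `tau_min = t_m/2`; fits on continuously distributed data
do not need it. The shortest resolvable component is of order the frame
spacing in any case.

Standard errors come from a nonparametric bootstrap (resample dwells
with replacement, refit warm-started from the full-data optimum, sort τ
ascending to resolve label switching, report per-parameter SDs). The
canonical resample count is 1000; the test suite uses 100–200 resamples,
which estimates each SD to ~5–10% relative accuracy — adequate for ±2 SD
coverage checks at far lower cost. Model order is compared by BIC (ties
toward fewer parameters).

Probability-density histograms divide each bin count by (bin width × N);
per-bin errors use the binomial formula `sqrt(p(1−p)/N)/width`.

### Known statistical limitation: the censored convolution near t_max

With τ1 + τ2 comparable to the window length (e.g. τ = 2105 and 417 s in
a 3600 s window), the truncated convolution's likelihood surface has a
long ridge in the τ1/τ2 split, and at a few hundred events the MLE
collapses onto the Erlang corner (τ1 = τ2) in roughly a fifth of
replicates. The collapse is a genuine likelihood maximum, and bootstrap
SDs computed from a collapsed sample are honestly small, so
point-estimate ± 2 SD intervals undercover the generating parameters
(~72–74% instead of ≥ 90% in our replicate study). The sum τ1 + τ2 is
well determined; only the split is weakly identified at this sample
size. Conclusions should rest on the fitted density, not on the
individual split parameters.

## Photobleaching control

The global fit across laser powers shares intrinsic time constants and
amplitudes and models the observed rate of each component at power P as
`1/τ_i(P) = 1/τ_i + b·P` with a single bleaching coefficient b ≥ 0
(units (µW·s)^-1). With a single power b is unidentifiable and the fit
refuses. b is tested against zero by a likelihood ratio versus the
shared-mixture submodel (χ²₁).

## Event detection

The baseline level and noise σ of each trace are estimated robustly
(median and 1.4826×MAD by default; an iterative dark-frame mean/SD
estimator is available). A plain median tolerates bound intervals up to
its quantile shift (≈ 0.32 σ at 20% occupancy) and fails above 50%
occupancy — traces dominated by a stalled complex are the practical
failure mode. Events open at the first frame exceeding baseline + 3.2 σ
and close at the frame before the intensity falls below baseline + 1 σ
(hysteresis applied per channel independently); an event still open at
the last frame is censored. The original workflow confirmed each spot by
manual inspection; here an automatic acceptance rule replaces it
(`min_event_frames`, default 1; set to 2 to suppress the analytic
3.2 σ false-positive rate of ≈ 6.9×10⁻⁴ per frame when unpaired
single-channel events matter).

Dwell convention: (last above-threshold frame time − first
above-threshold frame time) + frame spacing, so a single-frame event
carries exactly `t_m` = one frame spacing. This matches treating
single-frame events as "< 3 s". (An alternative end−start convention
without the added spacing would shorten every dwell by one spacing; the
choice is documented here and applied consistently.)

## Coincidence and pathway analysis

Arrivals on two channels are paired greedily by nearest start time
within ± one frame spacing (per molecule, each interval used at most
once; ties broken by stream order). Simultaneity of departures uses the
same tolerance. Outcome routes: PERSIST (both censored),
SIMULTANEOUS_LOSS (both end uncensored within tolerance), else
U4_FIRST/U5_FIRST by the earlier departure, a censored partner counting
as departing last. Routes are exhaustive and mutually exclusive, so
tallies conserve the event count.

Ordering of activation events uses Δ = t(U4 release) − t(NTC arrival)
per molecule (positive = NTC first). When a molecule has several
candidates the pair with minimal |Δ| is kept. The randomized control
permutes NTC arrival-time lists across molecules while holding U4
release times fixed, recomputes Δ, and averages histograms over seeded
shuffles; this destroys within-molecule coupling while preserving both
marginal time distributions. Frame quantization flips the apparent sign
of Δ when the true NTC delay is under ~1–2 frames, so detector-derived
offsets show ~80% Δ < 0 for a strictly sequential process whose
ground-truth offsets are 100% negative — the same ceiling applies to
real recordings.

Dwell–dwell association (e.g. time-to-U4-loss vs subsequent U5 dwell)
uses Spearman rank correlation with a two-sided permutation p-value
(≥ 1000 seeded permutations). Background binding rates are events /
(AOIs × minutes) with exact Poisson confidence intervals.

## Synthetic-data generator

Molecule histories are sampled from a labeled continuous-time Markov
chain by the Gillespie algorithm, one independent generator per molecule
spawned from the master seed. Each state emits on a set of channels;
a tri-snRNP binding step is a single transition into a U4+U5-emitting
state, so both spots appear at the same instant. Traces are rendered at
the experimental timing (1 s frames every 3 s for 60 min): per frame,
intensity = baseline + amplitude × (bound fluorophores, fractionally
weighted by exposure overlap) + Gaussian noise. Optional photobleaching
converts individual fluorophores to dark states at rate b·P per second
of illumination (duty-cycle corrected); label multiplicity per channel
is configurable (defaults: U4 1, U5 2, NTC 2, matching the tagging
scheme). Background binding at empty locations is a Poisson process
with short exponential dwells.

### Presets

The published model constrains route fractions and dwell-time constants
but not elementary rates; the presets map printed constants onto rates
as follows (all unprinted values are package defaults, not published
claims):

- **2 mM ATP (physiological).** Two-step initial arrival (rates 1/2105
  and 1/417 s⁻¹). B complex is a three-substate mixture with exit time
  constants 4/34/660 s at equal default amplitudes (the printed
  amplitudes live in a source-data file not reproduced in the text).
  62% of B exits commit to activation; commitment is followed by one
  further step (default 60 s) before U4 release, making
  activation-cohort U4 dwells convolution-shaped (multi-step,
  irreversible U4 loss). NTC arrives exp(30 s) after U4 release; U5
  (with NTC) releases after exp(300 s). Rebinding is single-step:
  1/617 s⁻¹ after an activation round, 1/492 s⁻¹ after a discard.
- **50 µM ATP (limiting).** Release mixture 52/780 s (equal
  amplitudes); activation branch reduced to 10% of non-stalled exits;
  9% of bindings enter a long-lived stalled B complex (exit 1/36000
  s⁻¹), realizing the printed 9% persist class, which the 52/780 s
  components alone cannot produce (≈ 1% censoring probability at
  3600 s). NTC recruitment is disabled.

What the generator does **not** emulate: extract depletion and snRNP
recycling pools (rebinding never slows down, so simulated molecules
show more repeat rounds than observed — route fractions are
unaffected), nonspecific binding at occupied locations, spatial image
formation, stage drift, and channel registration. Tests passing on this
generator validate the analysis chain under the stated kinetic
assumptions; they do not certify performance on drifting or
low-signal-to-noise recordings.

## Problem sizes and numerical choices

End-to-end checks run 300–500 molecules per condition (several hundred
coincident events, comparable to the published event counts);
recovery studies use 50 seeded replicates at the published per-figure
event counts (87–197). Route-fraction checks compare against the
configured branch probability with a 3-binomial-SD tolerance among
resolved (non-persist) events, since branch probabilities are defined
conditional on B-complex exit. All randomness flows from explicit
integer seeds; reports are bit-reproducible given config + seed.
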