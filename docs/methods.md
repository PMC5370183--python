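# Methods

## Model and assumptions

The package treats degradation of a ZTL target (PRR5 or TOC1) as a
first-order process whose rate coefficient interpolates between a
light-state value k₁ and a dark-state value k₂ according to the fraction of
ZTL carrying the flavin C4a adduct. The assumptions, in order of
importance:

- **Total ZTL is constant and normalised to 1.** ZTL protein cycling is
  ignored; this matches overexpression conditions and the observation that
  published clock models predict PRR5 decay adequately without a ZTL
  concentration term.
- **Light saturates the adduct.** At typical growth-light irradiances
  photo-activation is fast relative to the hours timescale, so the
  light-state fraction is held at 1 throughout light phases and reset to 1
  instantaneously at dawn. Only dark-phase kinetics carry photocycle
  information.
- **The dusk clock restarts at every light→dark transition**, giving
  c_L(t′) = e^(−k₃ t′) with t′ hours since the most recent dusk.
- **No synthesis.** Only the degradation term is modelled, so trajectories
  are strictly positive and non-increasing. This is appropriate for decay
  windows (after the transcriptional peak); it is *not* a model of full
  diurnal protein profiles.
- **TOC1's extra channel m₈** (ZTL-independent turnover) defaults to 0:
  no measured value exists, and the quantitative analysis is restricted to
  PRR5, with TOC1 handled qualitatively.

The dark-phase ODE has the exact solution
c(t′) = c₀·exp[((k₁−k₂)/k₃)(e^(−k₃ t′) − 1) − (k₂+m₈) t′], which is what
fitting and simulation evaluate. Two limits get explicit branches rather
than the generic expression: k₃ = 0 (adduct never decays; pure k₁
exponential, with a warning) and k₃ = ∞ (instant reversion; pure k₂
exponential).

## Parameters

| symbol | meaning | unit | default | origin |
|---|---|---|---|---|
| k₁ | degradation rate, light-state ZTL | hr⁻¹ | 0.14 | LL protein decay (0.13–0.14 across genotypes) |
| k₂ | degradation rate, dark-state ZTL | hr⁻¹ | 0.8 | dark-mimic variant decay; agrees with published-model maxima (0.78–0.8) |
| k₃ | adduct-decay (dark-reversion) rate | hr⁻¹ | per variant | reciprocal of the spectroscopic time constant |
| m₈ | ZTL-independent TOC1 turnover | hr⁻¹ | 0 | unmeasured |
| c₀ | level at the fit's time origin | rel. | nuisance | estimated (see below) |

`MODEL_LIGHT_STATE_RATE = 0.2 hr⁻¹` is also exposed: the light-state bound
taken from published model fits, used for prediction-style simulations made
before LL data refined k₁ to 0.14.

Variant presets (k₃/τ): WT 0.7/1.4, G80R 0.15/6.6, V48I 0.09/10.7,
G46S:G80R 0.05/21, V48I:G80R 0.02 with τ censored at >65 hr. The k₃·τ ≈ 1
consistency check exempts the censored variant: its printed rate (0.02
hr⁻¹ = 1/50 hr) is not the reciprocal of its printed bound, and both values
are kept verbatim with a `tau_is_lower_bound` flag rather than reconciled.
V48I-containing variants are allosteric dark-state mimics; this is encoded
as k₁ = k₂ = 0.8 (full activity regardless of illumination), deliberately
kept separate from their (slow but intact) photocycle k₃.

## Photocycle fitting

Recovery traces are fit in linear absorbance space, unweighted, with
y = y₀ + A·e^(−k t). Seeding is derivative-free: y₀ from the mean of the
last 10% of points, A from first-minus-plateau, k from the slope of
log|y − y₀| (fallback: reciprocal of the window). The 450 and 478 nm
channels are fit independently and combined as the mean rate, with the
propagated uncertainty the larger of the half-range and the pooled standard
error; a joint shared-k fit was considered and rejected as the default
because independent fits expose channel disagreement instead of averaging
it away. When the fitted τ exceeds ~3× the observation window the result is
flagged as a lower bound (and any fit whose window is under one half-life
warns). Base-catalysed (imidazole) traces use the same model; the flag is
metadata only.

## Degradation-parameter inference

Bounded (0–10 hr⁻¹) nonlinear least squares on **log levels** by default:
densitometry noise is multiplicative, so log residuals are approximately
homoscedastic and the fit is near maximum likelihood; a linear-space option
is retained. Replicates are pooled by concatenation (duplicating every
replicate leaves point estimates unchanged). Five multi-start runs with
multiplicative jitter guard against local minima; objective ties are broken
toward the smallest k₃. LD fits re-clock observations from dusk and use
only dark-phase points.

**c₀ handling.** The fit's time origin is dusk, and c₀ is estimated jointly
as a nuisance scale (initialised at, but not pinned to, the first
dark-phase observation). Pinning c₀ to the observed initial level is
available (`c0="anchor"`) but not the default: it injects that one
observation's noise into every residual.

**Identifiability.** Under continuous light the model reduces to
c₀·e^(−k₁ t): k₂ and k₃ do not appear, and requesting them raises an
`IdentifiabilityError` rather than returning a silently arbitrary number.
Likewise k₁ = k₂ removes k₃ from the model entirely; such fits are flagged
non-identifiable. `profile_objective` provides the corresponding
diagnostic (a flat profile) for marginal cases. The recommended protocol
mirrors the estimation narrative the defaults come from: fix k₁ from LL
data, fix k₂ from a constitutively dark-active series, then free k₃ on LD
dark-phase data.

**Apparent rates.** `effective_rate_constant` fits a single exponential by
ordinary least squares on log levels (exact ML under the lognormal noise
model; two points give the exact log-ratio slope). For LD data this
averages a time-varying coefficient, so the value lies between k₁ and k₂
and is meaningful only for comparing variants.

**Uncertainty.** Percentile bootstrap (95% default), either case
(replicate) resampling or residual resampling of pooled log residuals,
refit warm-started at the base estimates, deterministic under a seed. With
the default three replicates the case bootstrap materially undercovers
(~70–75% observed at nominal 95% in simulation) — a generic small-sample
property of the replicate bootstrap; the residual bootstrap achieves
~90–95% coverage under the generator's noise model and is the better choice
at n = 3.

## Synthetic data

The generator emulates the two assay types the fitters consume:

- **Absorbance traces**: y₀ + A·e^(−k t) plus additive Gaussian noise,
  default sd 0.005 AU. Defaults y₀ = 0.35, A = −0.30 correspond to the
  450 nm dark-state band of a ~30 µM LOV sample (ε ≈ 12,500 M⁻¹cm⁻¹)
  bleached by illumination. The noise sd is a declared assumption chosen so
  recovered-τ scatter matches the printed replicate standard deviations;
  true instrument noise is unpublished.
- **Protein time courses**: the model trajectory times mean-one lognormal
  noise, LogNormal(−σ²/2, σ) with σ = √ln(1+CV²), default CV 10%, three
  replicates. Lognormal because western-blot densitometry is ratio-scaled
  and strictly positive; the published data report only mean ± SEM of three
  replicates, so the CV is likewise a declared assumption.

Identical seeds give bit-identical output. What passing recovery tests
show: the estimation machinery is unbiased and precise *under this noise
model and sampling design*. What they do not show: robustness to features
real densitometry data have and the generator lacks — synthesis/transport
dynamics, non-stationary ZTL levels, loading-control error correlated
across lanes, saturation nonlinearity, and day-to-day batch effects.

## Numerical choices

- ODE oracle: DOP853, rtol 1e−8 / atol 1e−12, integrating the log level so
  accuracy stays *relative* even after the level falls through many orders
  of magnitude; agreement with the closed form is asserted at rtol ≤ 1e−6.
- CSV round-trips write floats at 17 significant digits and parse with
  round-trip precision, so write→read is bit-exact.
- Sampling cadence guidance for traces follows the spectroscopic practice
  of 10–20 points per half-life; the recovery tests use 0.15 hr steps over
  0–7 hr (wild type) and hourly over 0–105 hr (slow variants).
- Simulation study sizes (25 seeds for recovery medians, 30 outer
  repetitions for bootstrap-coverage checks at 200 resamples) were chosen
  as the smallest designs whose pass/fail verdicts are stable across
  reruns.

## Known limitations

- No synthesis terms: the package cannot reproduce full diurnal
  abundance rhythms, only decay windows.
- TOC1 is modelled structurally (m₈ channel present) but never fit
  quantitatively; its mRNA regulation is out of scope.
- GI competition/stabilisation of ZTL is not modelled.
- The censored variant's photocycle (τ > 65 hr) cannot be recovered
  accurately from windows much shorter than τ; fits there report bounds.
- In vivo apparent k_deg values depend on densitometry that was never
  published as numbers; the package implements the procedure, not the
  printed table.
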