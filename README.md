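# ztlkinetics

Kinetic analysis of how the ZEITLUPE (ZTL) LOV-domain photocycle shapes
targeted degradation of the *Arabidopsis* clock proteins PRR5 and TOC1.

ZTL is an F-box photoreceptor: blue light drives a cysteinyl–flavin C4a
adduct (the "light state"), which decays thermally in the dark with rate
constant k₃ (time constant τ = 1/k₃). The dark state is the more
degradation-active conformation, so k₃ sets how fast ZTL's E3-ligase
activity ramps up after dusk — and thereby how fast PRR5 and TOC1 are
cleared at night. This package is for photobiologists and circadian
modelers who want to simulate that coupling, fit photocycle kinetics from
absorbance recovery data, and infer degradation rate constants from protein
time courses.

## Model

Normalising the total ZTL pool to 1, the light-state fraction during the
dark phase (t measured from dusk) is

    c_ZTL-L(t) = e^(−k₃ t),     c_ZTL-D = 1 − c_ZTL-L

and a ZTL target degrades with the time-dependent first-order coefficient

    dc/dt = −[(k₁ − k₂) e^(−k₃ t) + k₂] c        (PRR5)
    dc/dt = −[(k₁ − k₂) e^(−k₃ t) + k₂] c − m₈ c (TOC1)

where k₁ and k₂ are the degradation rates under fully light- and
dark-state ZTL and m₈ is a ZTL-independent channel (TOC1 only). This
integrates exactly to

    c(t) = c₀ · exp[ ((k₁ − k₂)/k₃)(e^(−k₃ t) − 1) − (k₂ + m₈) t ],

the closed form used throughout (an adaptive ODE integrator is kept as an
independent oracle). Under light the adduct is saturated and the target
decays as a pure exponential at k₁. Photocycle recovery traces are fit with
the monoexponential y = y₀ + A·e^(−k t) at 450/478 nm.

Built-in variant presets carry the measured adduct-decay constants
(k₃ in hr⁻¹ / τ in hr): WT 0.7/1.4, G80R 0.15/6.6, V48I 0.09/10.7,
G46S:G80R 0.05/21, V48I:G80R 0.02/τ>65 (censored). V48I-containing variants
are allosteric dark-state mimics, encoded as k₁ = k₂.

## Worked example

Generate synthetic recovery traces for the slow-photocycle variant G80R and
fit them:

```sh
$ ztlkin generate --kind trace --preset G80R --seed 11 --t-max 33 --t-step 0.7 --out g80r_traces.csv
$ ztlkin fit-photocycle --input g80r_traces.csv
 replicate channel  k_per_hr   tau_hr       y0  amplitude  k_stderr  converged
         0    a450  0.149668 6.681465 0.348607  -0.295687  0.002880       True
         1    a450  0.148089 6.752691 0.351378  -0.298543  0.003301       True
         2    a450  0.152321 6.565072 0.349567  -0.301959  0.003238       True
summary: mean tau = 6.67 hr, sd = 0.095 hr, n = 3
```

The fitted τ ≈ 6.7 hr recovers the preset's 6.6 hr adduct-decay time
constant from noisy traces. Now infer k₃ from a simulated protein time
course (hourly dark-phase samples, three replicates, 10% multiplicative
noise), holding k₁ = 0.14 hr⁻¹ and k₂ = 0.8 hr⁻¹ fixed:

```sh
$ ztlkin generate --kind timecourse --preset G80R --seed 11 --out g80r_tc.csv
$ ztlkin fit-degradation --input g80r_tc.csv --free k3 --k3 0.3
{
  "estimates": { "k3": 0.15066924325017017 },
  "stderr":    { "k3": 0.0026386245688465306, "c0": 0.004293237907568823 },
  "fixed":     { "k1": 0.14, "k2": 0.8, "m8": 0.0 },
  ...
}
```

The estimate k̂₃ ≈ 0.151 hr⁻¹ matches the generating value 0.15 hr⁻¹. A
full simulate-and-refit study over 25 independent data sets:

```sh
$ ztlkin recover --preset G80R --seeds 25 --seed 1
           truth    median      mean      bias  rel_rmse   n
parameter
k3          0.15  0.150181  0.150027  0.000027  0.021736  25
```

i.e. the dark-phase design identifies k₃ with ~2% relative RMSE at this
noise level. The same machinery is available from Python
(`fit_monoexponential`, `fit_degradation`, `recovery_experiment`, or the
sklearn-style `MonoexponentialDecay` / `PhotocycleDegradationModel`
estimators).

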