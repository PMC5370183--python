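"""Synthetic absorbance traces and protein time courses.

Emulates the two data types the pipeline consumes:

* absorbance dark-recovery traces — monoexponential recovery
  y = y0 + A*exp(-k t) with additive Gaussian instrument noise;
* protein time courses — trajectories of the photocycle-coupled degradation
  model under a light schedule, with mean-one multiplicative lognormal
  biological noise over replicates (densitometry is ratio-scaled and strictly
  positive).

Named presets carry the adduct-decay rate constants of the characterised ZTL
LOV-domain variants; V48I-containing variants additionally act as allosteric
dark-state mimics (encoded as k1 = k2: full degradation activity regardless
of illumination), independent of their slowed photocycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AbsorbanceTrace, ProteinTimecourse
from .model import LightSchedule, evaluate_schedule
from .params import DegradationParams

__all__ = [
    "NoiseSpec",
    "VariantPreset",
    "PRESETS",
    "preset_params",
    "gen_absorbance_trace",
    "gen_protein_timecourse",
    "gen_ld_schedule",
    "LIGHT_STATE_RATE",
    "DARK_STATE_RATE",
    "MODEL_LIGHT_STATE_RATE",
]

#: light-state degradation rate (hr^-1) estimated from LL time courses
LIGHT_STATE_RATE = 0.14
#: dark-state maximum degradation rate (hr^-1), shared by published clock models
DARK_STATE_RATE = 0.8
#: light-state rate bound taken from published-model fits (used for the
#: prediction-only simulations, before LL data refined it to 0.14)
MODEL_LIGHT_STATE_RATE = 0.2


@dataclass(frozen=True)
class NoiseSpec:
    """Noise and replication structure of the generated data.

    ``absorbance_sd`` — additive Gaussian sd in AU; ``protein_cv`` —
    coefficient of variation of the mean-one multiplicative lognormal noise;
    three biological replicates by default.  ``seed`` fully determines the
    output.
    """

    absorbance_sd: float = 0.005
    protein_cv: float = 0.10
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.absorbance_sd < 0 or self.protein_cv < 0:
            raise ValueError("noise magnitudes must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class VariantPreset:
    """A characterised ZTL LOV variant: photocycle rate and allosteric class."""

    name: str
    k3: float  # hr^-1
    tau: float  # hr, printed time constant
    allosteric: bool = False  # dark-state mimic (constitutive k2)
    tau_is_lower_bound: bool = False


PRESETS: dict[str, VariantPreset] = {
    "WT": VariantPreset("WT", k3=0.7, tau=1.4),
    "G80R": VariantPreset("G80R", k3=0.15, tau=6.6),
    "V48I": VariantPreset("V48I", k3=0.09, tau=10.7, allosteric=True),
    "G46S:G80R": VariantPreset("G46S:G80R", k3=0.05, tau=21.0),
    "V48I:G80R": VariantPreset(
        "V48I:G80R", k3=0.02, tau=65.0, allosteric=True, tau_is_lower_bound=True
    ),
}


def preset_params(
    name: str, k1: float = LIGHT_STATE_RATE, k2: float = DARK_STATE_RATE
) -> tuple[DegradationParams, VariantPreset]:
    """Degradation parameters for a named ZTL variant.

    Allosteric (V48I-containing) variants return k1 = k2: the dark-mimic
    conformation keeps full degradation activity in the light, separately
    from their slowed adduct decay.
    """
    if name not in PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    preset = PRESETS[name]
    if preset.allosteric:
        params = DegradationParams(k1=k2, k2=k2, k3=preset.k3)
    else:
        params = DegradationParams(k1=k1, k2=k2, k3=preset.k3)
    return params, preset


def gen_absorbance_trace(
    k: float,
    t_grid,
    noise: NoiseSpec,
    y0: float = 0.35,
    amplitude: float = -0.30,
    channels: tuple = ("a450",),
) -> list[AbsorbanceTrace]:
    """Replicated monoexponential recovery traces with Gaussian noise.

    Defaults mimic the dark-state 450 nm band of a ~30 uM LOV sample (plateau
    ~0.35 AU) bleached to ~0.05 AU by illumination.  Returns one trace per
    replicate; identical seeds give bit-identical output.
    """
    if not k > 0:
        raise ValueError("k must be > 0")
    t = np.asarray(t_grid, dtype=float)
    if t.size == 0:
        raise ValueError("t_grid must be non-empty")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    for c in channels:
        if c not in ("a450", "a478"):
            raise ValueError(f"unknown channel {c!r}")
    rng = np.random.default_rng(noise.seed)
    clean = y0 + amplitude * np.exp(-k * t)
    traces = []
    for rep in range(noise.n_replicates):
        kwargs = {}
        for c in channels:
            kwargs[c] = clean + rng.normal(0.0, noise.absorbance_sd, size=t.shape)
        traces.append(AbsorbanceTrace(times=t, replicate=rep, **kwargs))
    return traces


def gen_protein_timecourse(
    truth: DegradationParams,
    schedule: LightSchedule,
    c0: float,
    times,
    noise: NoiseSpec,
    species: str = "PRR5",
    condition: str = "LD",
) -> ProteinTimecourse:
    """Protein time course from the degradation model plus lognormal noise.

    ``times`` are hours since lights-on and must lie within the schedule
    span.  Each replicate observation is the model level multiplied by
    LogNormal(mu = -sigma^2/2, sigma) with sigma chosen so the noise has mean
    one and coefficient of variation ``noise.protein_cv``; the replicate mean
    therefore converges to the model trajectory.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("times must be non-empty")
    if condition == "LL":
        schedule = LightSchedule.ll(max(float(t.max()), 1e-6))
    level, _, _ = evaluate_schedule(t, species, c0, truth, schedule)
    rng = np.random.default_rng(noise.seed)
    sigma = float(np.sqrt(np.log1p(noise.protein_cv**2)))
    all_t, all_y, all_r = [], [], []
    for rep in range(noise.n_replicates):
        if sigma > 0:
            factor = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=t.shape)
        else:
            factor = np.ones_like(t)
        all_t.append(t)
        all_y.append(level * factor)
        all_r.append(np.full(t.shape, rep, dtype=int))
    return ProteinTimecourse(
        species=species,
        condition=condition,
        times=np.concatenate(all_t),
        levels=np.concatenate(all_y),
        replicates=np.concatenate(all_r),
    )


def gen_ld_schedule(
    light_hours: float = 12.0, dark_hours: float = 12.0, n_cycles: int = 1
) -> LightSchedule:
    """Alternating light/dark schedule starting with LIGHT at ZT0."""
    return LightSchedule.ld(light_hours, dark_hours, n_cycles)
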