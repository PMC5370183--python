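"""Closed-form and numerical solutions of the photocycle-coupled degradation model.

During the dark phase the light-state (adduct-bearing) fraction of ZTL decays
as ``c_L(t) = exp(-k3 t)`` with t measured from dusk, and the target protein
obeys

    dc/dt = -[(k1 - k2) exp(-k3 t) + k2] c          (PRR5)
    dc/dt = -[(k1 - k2) exp(-k3 t) + k2] c - m8 c   (TOC1)

which integrates exactly to

    c(t) = c0 * exp[ ((k1 - k2)/k3) (exp(-k3 t) - 1) - (k2 + m8) t ].

Under light the adduct is taken as saturated (c_L = 1) so the target decays
as a pure exponential at rate k1 (+ m8).  ``simulate_schedule`` stitches these
pieces across an arbitrary light/dark schedule; ``integrate_numeric`` is an
independent adaptive-ODE oracle for the closed forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import solve_ivp

from .data import ProteinTimecourse
from .params import SPECIES, DegradationParams

__all__ = [
    "PhaseKind",
    "Phase",
    "LightSchedule",
    "SimulationResult",
    "light_state_fraction",
    "effective_degradation_coefficient",
    "prr5_analytic",
    "toc1_analytic",
    "dark_phase_level",
    "integrate_numeric",
    "evaluate_schedule",
    "simulate_schedule",
    "effective_rate_constant",
    "RateEstimate",
]


class PhaseKind(str, Enum):
    LIGHT = "LIGHT"
    DARK = "DARK"


@dataclass(frozen=True)
class Phase:
    kind: PhaseKind
    duration: float  # hours

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("phase duration must be > 0")


@dataclass(frozen=True)
class LightSchedule:
    """Ordered light/dark phases; time origin is lights-on (ZT0)."""

    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        if len(self.phases) == 0:
            raise ValueError("schedule must contain at least one phase")

    @classmethod
    def ld(
        cls, light_hours: float = 12.0, dark_hours: float = 12.0, n_cycles: int = 1
    ) -> "LightSchedule":
        """Alternating light/dark cycles starting with LIGHT at ZT0."""
        if n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        phases = []
        for _ in range(n_cycles):
            phases.append(Phase(PhaseKind.LIGHT, light_hours))
            phases.append(Phase(PhaseKind.DARK, dark_hours))
        return cls(tuple(phases))

    @classmethod
    def ll(cls, duration: float = 24.0) -> "LightSchedule":
        """Continuous light for ``duration`` hours."""
        return cls((Phase(PhaseKind.LIGHT, duration),))

    @property
    def total_hours(self) -> float:
        return float(sum(p.duration for p in self.phases))

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative phase start times, plus the final end time."""
        return np.concatenate([[0.0], np.cumsum([p.duration for p in self.phases])])


@dataclass
class SimulationResult:
    """Trajectory of one species under a light schedule.

    ``ztl_light_fraction`` is c_ZTL-L at each time (dark fraction is its
    complement, the total ZTL pool being normalised to 1).
    """

    times: np.ndarray
    species: str
    level: np.ndarray
    ztl_light_fraction: np.ndarray
    phase: np.ndarray  # "LIGHT"/"DARK" per time point

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_hr": self.times,
                "species": self.species,
                "level": self.level,
                "ztl_light_fraction": self.ztl_light_fraction,
                "phase": self.phase,
            }
        )


def _check_species(species: str) -> None:
    if species not in SPECIES:
        raise ValueError(f"species must be one of {SPECIES}, got {species!r}")


def light_state_fraction(t_since_dusk, k3: float):
    """Light-state (adduct) fraction of ZTL, exp(-k3 t), t from dusk."""
    t = np.asarray(t_since_dusk, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_dusk must be >= 0")
    if k3 < 0:
        raise ValueError("k3 must be >= 0")
    out = np.exp(-k3 * t)
    return out if out.ndim else float(out)


def effective_degradation_coefficient(t_since_dusk, params: DegradationParams):
    """Instantaneous first-order coefficient (k1-k2)exp(-k3 t) + k2 (hr^-1)."""
    frac = light_state_fraction(t_since_dusk, params.k3)
    return (params.k1 - params.k2) * frac + params.k2


def _log_dark_decay(t: np.ndarray, params: DegradationParams, m8: float) -> np.ndarray:
    k1, k2, k3 = params.k1, params.k2, params.k3
    if np.isinf(k3):
        return -(k2 + m8) * t
    if k3 == 0.0:
        warnings.warn(
            "k3 = 0: adduct never decays; using the pure light-state limit "
            "c0*exp(-k1*t)",
            RuntimeWarning,
            stacklevel=3,
        )
        return -(k1 + m8) * t
    return ((k1 - k2) / k3) * (np.expm1(-k3 * t)) - (k2 + m8) * t


def dark_phase_level(
    t_since_dusk, c0: float, params: DegradationParams, species: str = "PRR5"
):
    """Closed-form level during a dark phase for either species."""
    _check_species(species)
    if not c0 > 0:
        raise ValueError("c0 must be > 0")
    t = np.asarray(t_since_dusk, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_dusk must be >= 0")
    m8 = params.m8 if species == "TOC1" else 0.0
    out = c0 * np.exp(_log_dark_decay(t, params, m8))
    return out if out.ndim else float(out)


def prr5_analytic(t_since_dusk, c0: float, params: DegradationParams):
    """Exact PRR5 dark-phase solution c0*exp[((k1-k2)/k3)(e^{-k3 t}-1) - k2 t]."""
    return dark_phase_level(t_since_dusk, c0, params, "PRR5")


def toc1_analytic(t_since_dusk, c0: float, params: DegradationParams):
    """Exact TOC1 dark-phase solution; m8 adds a constant first-order channel."""
    return dark_phase_level(t_since_dusk, c0, params, "TOC1")


def integrate_numeric(
    species: str,
    c0: float,
    params: DegradationParams,
    time_grid,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> SimulationResult:
    """Adaptive numerical integration of the dark-phase ODE on a time grid.

    Serves as the independent oracle for the closed-form solutions; the
    contract is accuracy (agreement to <= 1e-6 relative), not scheme identity.
    The integration is performed on the log level (du/dt = -coefficient(t)),
    which keeps the error relative even when the level decays through many
    orders of magnitude.
    """
    _check_species(species)
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("time_grid must be a non-empty 1-D array")
    if t[0] != 0.0 or np.any(np.diff(t) <= 0):
        raise ValueError("time_grid must be strictly increasing and start at 0")
    if not c0 > 0:
        raise ValueError("c0 must be > 0")
    m8 = params.m8 if species == "TOC1" else 0.0

    def rhs(ti, u):
        return -(effective_degradation_coefficient(ti, params) + m8) * np.ones_like(u)

    if t.size == 1:  # zero-length grid beyond t=0
        level = np.array([c0])
    else:
        sol = solve_ivp(
            rhs,
            (t[0], t[-1]),
            [np.log(c0)],
            t_eval=t,
            method="DOP853",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        level = np.exp(sol.y[0])
    return SimulationResult(
        times=t,
        species=species,
        level=level,
        ztl_light_fraction=light_state_fraction(t, params.k3),
        phase=np.full(t.shape, PhaseKind.DARK.value),
    )


def _phase_starts(
    c0: float, params: DegradationParams, schedule: LightSchedule, m8: float
) -> list[float]:
    """Level at the start of each phase, propagated analytically."""
    starts = [c0]
    c = c0
    for ph in schedule.phases[:-1]:
        if ph.kind is PhaseKind.LIGHT:
            c = c * np.exp(-(params.k1 + m8) * ph.duration)
        else:
            c = c * np.exp(_log_dark_decay(np.asarray(ph.duration), params, m8))
        starts.append(float(c))
    return starts


def evaluate_schedule(
    times,
    species: str,
    c0: float,
    params: DegradationParams,
    schedule: LightSchedule,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Level, light fraction and phase label at arbitrary ZT times.

    The dusk clock restarts at every LIGHT->DARK boundary; at dawn the adduct
    is instantaneously re-saturated (c_ZTL-L resets to 1).  Phase boundaries
    belong to the phase they end (the trajectory is continuous in level).
    """
    _check_species(species)
    if not c0 > 0:
        raise ValueError("c0 must be > 0")
    t = np.asarray(times, dtype=float)
    bounds = schedule.boundaries
    if np.any(t < 0) or np.any(t > bounds[-1] + 1e-9):
        raise ValueError("times must lie within the schedule span")
    m8 = params.m8 if species == "TOC1" else 0.0
    starts = _phase_starts(c0, params, schedule, m8)

    level = np.empty(t.shape)
    frac = np.empty(t.shape)
    label = np.empty(t.shape, dtype=object)
    # boundary points assigned to the earlier phase via side="left"
    idx = np.clip(np.searchsorted(bounds[1:], t, side="left"), 0, len(schedule.phases) - 1)
    for i, ph in enumerate(schedule.phases):
        mask = idx == i
        if not np.any(mask):
            continue
        local = t[mask] - bounds[i]
        if ph.kind is PhaseKind.LIGHT:
            level[mask] = starts[i] * np.exp(-(params.k1 + m8) * local)
            frac[mask] = 1.0
        else:
            level[mask] = starts[i] * np.exp(_log_dark_decay(local, params, m8))
            frac[mask] = light_state_fraction(local, params.k3)
        label[mask] = ph.kind.value
    return level, frac, label


def simulate_schedule(
    species: str,
    c0: float,
    params: DegradationParams,
    schedule: LightSchedule,
    step: float = 0.1,
) -> SimulationResult:
    """Simulate a full light/dark schedule on a regular grid (plus boundaries)."""
    if not step > 0:
        raise ValueError("step must be > 0")
    total = schedule.total_hours
    grid = np.arange(0.0, total + step / 2, step)
    grid = np.unique(np.concatenate([grid, schedule.boundaries, [total]]))
    grid = grid[grid <= total + 1e-12]
    level, frac, label = evaluate_schedule(grid, species, c0, params, schedule)
    return SimulationResult(
        times=grid,
        species=species,
        level=level,
        ztl_light_fraction=frac,
        phase=label.astype(str),
    )


@dataclass(frozen=True)
class RateEstimate:
    """Apparent single-exponential rate constant with its standard error."""

    k: float
    stderr: float | None
    c0: float
    n: int


def effective_rate_constant(tc: ProteinTimecourse) -> RateEstimate:
    """Apparent first-order rate from a single-exponential fit c(t)=c0*e^{-kt}.

    Treats the system as containing only one kinetic state, so for LD data the
    value is a time-averaged coefficient — accurate as a comparative term
    between variants only.  The fit is ordinary least squares on log levels
    (exact maximum likelihood under multiplicative lognormal noise); with two
    points it reduces to the exact log-ratio slope.
    """
    t, y = tc.times, np.log(tc.levels)
    if np.unique(t).size < 2:
        raise ValueError("need >= 2 distinct time points")
    res = stats.linregress(t, y)
    k = -res.slope
    if k <= 0:
        warnings.warn(
            "time course does not decay; apparent rate constant is <= 0",
            RuntimeWarning,
            stacklevel=2,
        )
    stderr = float(res.stderr) if t.size > 2 else None
    return RateEstimate(k=float(k), stderr=stderr, c0=float(np.exp(res.intercept)), n=t.size)
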