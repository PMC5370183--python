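"""Observation containers: absorbance recovery traces and protein time courses."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import SPECIES

__all__ = ["AbsorbanceTrace", "ProteinTimecourse", "CONDITIONS"]

CONDITIONS = ("LD", "LL")

MIN_TRACE_POINTS = 5


@dataclass
class AbsorbanceTrace:
    """Dual-wavelength dark-recovery absorbance trace.

    ``times`` are hours from the start of dark recovery (strictly increasing
    from 0).  Either channel may be absent (``None``).  ``temperature`` (K)
    and ``base_catalyzed`` (imidazole-catalysed recovery) are metadata only.
    """

    times: np.ndarray
    a450: np.ndarray | None = None
    a478: np.ndarray | None = None
    temperature: float = 296.0
    base_catalyzed: bool = False
    replicate: int | str = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("times must be a non-empty 1-D array")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.a450 is None and self.a478 is None:
            raise ValueError("at least one of a450/a478 must be present")
        for name in ("a450", "a478"):
            values = getattr(self, name)
            if values is None:
                continue
            values = np.asarray(values, dtype=float)
            if values.shape != self.times.shape:
                raise ValueError(f"{name} must match times in shape")
            if not np.all(np.isfinite(values)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, values)

    def channel(self, name: str) -> np.ndarray:
        if name not in ("a450", "a478"):
            raise ValueError(f"unknown channel {name!r}; expected 'a450' or 'a478'")
        values = getattr(self, name)
        if values is None:
            raise ValueError(f"channel {name!r} absent from trace")
        return values

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(c for c in ("a450", "a478") if getattr(self, c) is not None)


@dataclass
class ProteinTimecourse:
    """Replicated, loading-control-normalised protein levels over time.

    ``times`` are hours since lights-on (ZT); ``levels`` are strictly positive
    relative amounts; ``replicates`` labels the biological replicate of each
    observation.  All arrays are flat and aligned (one row per observation).
    """

    species: str
    condition: str
    times: np.ndarray
    levels: np.ndarray
    replicates: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}, got {self.species!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        self.times = np.asarray(self.times, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.times.shape != self.levels.shape or self.times.ndim != 1:
            raise ValueError("times and levels must be aligned 1-D arrays")
        if self.replicates is None:
            self.replicates = np.zeros(self.times.shape, dtype=int)
        else:
            self.replicates = np.asarray(self.replicates)
            if self.replicates.shape != self.times.shape:
                raise ValueError("replicates must be aligned with times")
        if np.any(self.levels <= 0):
            bad = int(np.flatnonzero(self.levels <= 0)[0])
            raise ValueError(
                f"levels must be strictly positive (first offending index {bad})"
            )
        if self.times.size == 0:
            raise ValueError("time course is empty")

    @property
    def replicate_ids(self) -> np.ndarray:
        return np.unique(self.replicates)

    def for_replicate(self, rep: int | str) -> "ProteinTimecourse":
        mask = self.replicates == rep
        return ProteinTimecourse(
            species=self.species,
            condition=self.condition,
            times=self.times[mask],
            levels=self.levels[mask],
            replicates=self.replicates[mask],
        )
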