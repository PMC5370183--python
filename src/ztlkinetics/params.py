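"""Kinetic parameter containers for the ZTL photocycle-coupled degradation model.

The model describes first-order degradation of a ZTL target protein (PRR5 or
TOC1) whose instantaneous rate interpolates between a light-state constant
``k1`` and a more active dark-state constant ``k2`` according to the fraction
of ZTL carrying the cysteinyl-flavin adduct.  The adduct decays thermally in
the dark with rate constant ``k3`` (time constant tau = 1/k3).  TOC1 carries
an additional ZTL-independent first-order channel ``m8``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["DegradationParams", "PokhilkoRates", "convert_pokhilko_params", "SPECIES"]

SPECIES = ("PRR5", "TOC1")


@dataclass(frozen=True)
class DegradationParams:
    """Rate constants (hr^-1) of the photocycle-coupled degradation model.

    Parameters
    ----------
    k1 : float
        Degradation rate of the target when ZTL is fully light-state.
    k2 : float
        Degradation rate when ZTL is fully dark-state (k2 >= k1 in vivo,
        not enforced).
    k3 : float
        Adduct-decay (dark-reversion) rate of the ZTL LOV domain.
    m8 : float, default 0
        ZTL-independent degradation rate; only meaningful for TOC1.
    """

    k1: float
    k2: float
    k3: float
    m8: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "m8"):
            value = getattr(self, name)
            if not value >= 0.0:
                raise ValueError(f"{name} must be >= 0, got {value!r}")

    @property
    def tau(self) -> float:
        """Adduct-decay time constant 1/k3 (hr)."""
        return 1.0 / self.k3

    def with_updates(self, **kwargs: float) -> "DegradationParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PokhilkoRates:
    """Degradation rate constants (hr^-1) of the published clock models.

    PRR5 degrades at m17 (light) rising to m17 + m24 in the dark; TOC1 at m6
    rising to m6 + m7, plus a ZTL-independent channel m8.
    """

    m17: float = 0.0
    m24: float = 0.0
    m6: float = 0.0
    m7: float = 0.0
    m8: float = 0.0

    def __post_init__(self) -> None:
        for name in ("m17", "m24", "m6", "m7", "m8"):
            if not getattr(self, name) >= 0.0:
                raise ValueError(f"{name} must be >= 0")


def convert_pokhilko_params(
    rates: PokhilkoRates, species: str, k3: float = 0.0
) -> DegradationParams:
    """Map published-model degradation constants onto (k1, k2).

    The dark indicator D of the published models adds m24 (PRR5) or m7 (TOC1)
    on top of the basal light rate, so k1 = m17, k2 = m17 + m24 for PRR5 and
    k1 = m6, k2 = m6 + m7 (with m8 passed through) for TOC1.  ``k3`` is not
    part of the published models and must be supplied separately.
    """
    if species == "PRR5":
        return DegradationParams(k1=rates.m17, k2=rates.m17 + rates.m24, k3=k3)
    if species == "TOC1":
        return DegradationParams(
            k1=rates.m6, k2=rates.m6 + rates.m7, k3=k3, m8=rates.m8
        )
    raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
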