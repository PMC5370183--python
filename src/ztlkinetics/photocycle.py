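"""Monoexponential fitting of LOV-domain dark-recovery absorbance traces.

Dark recovery of the flavin C4a adduct restores the dark-state absorbance
bands at 450 and 478 nm.  Each kinetic trace is fit with

    y(t) = y0 + A * exp(-k t)

where ``y0`` is the recovered plateau, ``A`` the (negative, for recovery
toward higher absorbance) amplitude and ``k`` the adduct-decay rate constant;
the time constant tau = 1/k is the quantity compared across variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .data import MIN_TRACE_POINTS, AbsorbanceTrace

__all__ = [
    "MonoexponentialDecay",
    "ExpFitResult",
    "fit_monoexponential",
    "combine_channel_fits",
    "summarize_replicates",
]


@dataclass
class ExpFitResult:
    """Result of a monoexponential fit y = y0 + A*exp(-k t)."""

    y0: float
    amplitude: float
    k: float
    stderr: dict = field(default_factory=dict)
    rss: float = np.nan
    converged: bool = False
    channel: str | None = None
    n_points: int = 0
    note: str | None = None

    @property
    def tau(self) -> float:
        """Time constant 1/k (hr); tau * k == 1 by construction."""
        return 1.0 / self.k


def _as_time_vector(X) -> np.ndarray:
    t = np.asarray(X, dtype=float)
    if t.ndim == 2 and t.shape[1] == 1:  # sklearn-style column matrix
        t = t[:, 0]
    if t.ndim != 1:
        raise ValueError("expected a 1-D time vector or a single-column matrix")
    return t


class MonoexponentialDecay(RegressorMixin, BaseEstimator):
    """Least-squares estimator for y = y0 + A*exp(-k t).

    Initial guesses (unless supplied): ``y0`` from the mean of the last 10% of
    points, ``A`` from first-minus-plateau, ``k`` from the slope of
    log|y - y0_guess| — a derivative-free seeding that is robust for both
    decaying and recovering traces.  The fit is unweighted in linear
    absorbance space.

    Fitted attributes: ``y0_``, ``amplitude_``, ``k_``, ``tau_``, ``stderr_``
    (dict per parameter, NaN when unavailable), ``rss_``, ``converged_``.
    """

    def __init__(
        self,
        y0_init: float | None = None,
        amplitude_init: float | None = None,
        k_init: float | None = None,
        min_points: int = MIN_TRACE_POINTS,
    ):
        self.y0_init = y0_init
        self.amplitude_init = amplitude_init
        self.k_init = k_init
        self.min_points = min_points

    def _guesses(self, t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
        tail = max(1, t.size // 10)
        y0 = self.y0_init if self.y0_init is not None else float(np.mean(y[-tail:]))
        amp = self.amplitude_init if self.amplitude_init is not None else float(y[0] - y0)
        k = self.k_init
        if k is None:
            resid = np.abs(y - y0)
            floor = max(1e-12, 1e-3 * max(abs(amp), 1e-12))
            ok = resid > floor
            if ok.sum() >= 2:
                slope = np.polyfit(t[ok], np.log(resid[ok]), 1)[0]
                k = float(-slope)
            if k is None or not np.isfinite(k) or k <= 0:
                k = 1.0 / max(t[-1] - t[0], 1e-6)
        return y0, amp, k

    def fit(self, X, y):
        t = _as_time_vector(X)
        y = np.asarray(y, dtype=float)
        if y.shape != t.shape:
            raise ValueError("X and y must be aligned")
        if t.size < self.min_points:
            raise ValueError(
                f"need at least {self.min_points} points to fit, got {t.size}"
            )
        y0g, ag, kg = self._guesses(t, y)
        pars = lmfit.Parameters()
        pars.add("y0", value=y0g)
        pars.add("amplitude", value=ag)
        pars.add("k", value=max(kg, 1e-9), min=1e-9)

        def residual(p):
            return p["y0"] + p["amplitude"] * np.exp(-p["k"] * t) - y

        out = lmfit.minimize(residual, pars, method="leastsq")
        self.y0_ = float(out.params["y0"].value)
        self.amplitude_ = float(out.params["amplitude"].value)
        self.k_ = float(out.params["k"].value)
        self.tau_ = 1.0 / self.k_
        self.stderr_ = {
            name: (float(out.params[name].stderr) if out.params[name].stderr else np.nan)
            for name in ("y0", "amplitude", "k")
        }
        self.rss_ = float(np.sum(out.residual**2))
        self.converged_ = bool(out.success) and np.isfinite(self.k_) and self.k_ > 0
        span = t[-1] - t[0]
        self.tau_is_lower_bound_ = self.tau_ > 3.0 * span
        if self.converged_ and span < np.log(2) / self.k_:
            warnings.warn(
                "observation window shorter than one fitted half-life; the "
                "time constant may only be bounded, not determined",
                RuntimeWarning,
                stacklevel=2,
            )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "k_")
        t = _as_time_vector(X)
        return self.y0_ + self.amplitude_ * np.exp(-self.k_ * t)

    def result_(self, channel: str | None = None, n_points: int = 0) -> ExpFitResult:
        check_is_fitted(self, "k_")
        return ExpFitResult(
            y0=self.y0_,
            amplitude=self.amplitude_,
            k=self.k_,
            stderr=dict(self.stderr_),
            rss=self.rss_,
            converged=self.converged_,
            channel=channel,
            n_points=n_points,
            note=(
                "tau exceeds ~3x the observation window; report as a lower bound"
                if self.tau_is_lower_bound_
                else None
            ),
        )


def fit_monoexponential(trace: AbsorbanceTrace, channel: str = "a450") -> ExpFitResult:
    """Fit one channel of an absorbance trace with a monoexponential decay."""
    y = trace.channel(channel)
    est = MonoexponentialDecay().fit(trace.times, y)
    return est.result_(channel=channel, n_points=trace.times.size)


def combine_channel_fits(
    fit450: ExpFitResult | None, fit478: ExpFitResult | None
) -> ExpFitResult:
    """Combine the 450 and 478 nm channel fits into one rate constant.

    Both converged: k is the arithmetic mean of the channel rates, with the
    propagated uncertainty taken as the larger of the half-range and the
    pooled standard error.  If one channel failed (or is absent) the other is
    returned, flagged single-channel.
    """
    ok450 = fit450 is not None and fit450.converged
    ok478 = fit478 is not None and fit478.converged
    if not ok450 and not ok478:
        raise ValueError("no converged channel fit to combine")
    if ok450 != ok478:
        survivor = fit450 if ok450 else fit478
        assert survivor is not None
        out = ExpFitResult(**{**survivor.__dict__})
        out.channel = "combined"
        out.note = f"single-channel ({survivor.channel}); other channel unavailable"
        return out
    assert fit450 is not None and fit478 is not None
    k = 0.5 * (fit450.k + fit478.k)
    half_range = 0.5 * abs(fit450.k - fit478.k)
    se450 = fit450.stderr.get("k", np.nan)
    se478 = fit478.stderr.get("k", np.nan)
    pooled = float(np.sqrt(np.nansum([se450**2, se478**2]) / 2.0))
    return ExpFitResult(
        y0=0.5 * (fit450.y0 + fit478.y0),
        amplitude=0.5 * (fit450.amplitude + fit478.amplitude),
        k=k,
        stderr={"k": max(half_range, pooled)},
        rss=fit450.rss + fit478.rss,
        converged=True,
        channel="combined",
        n_points=fit450.n_points + fit478.n_points,
    )


def summarize_replicates(fits: list[ExpFitResult]) -> pd.Series:
    """Mean and sample sd of tau across replicate fits (sd NaN for n < 2)."""
    if not fits:
        raise ValueError("no fits to summarize")
    taus = np.array([f.tau for f in fits])
    sd = float(np.std(taus, ddof=1)) if taus.size >= 2 else np.nan
    return pd.Series(
        {"mean_tau_hr": float(np.mean(taus)), "sd_tau_hr": sd, "n": taus.size}
    )
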