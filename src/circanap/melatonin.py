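"""Melatonin secretion-curve fitting and dim-light melatonin onset.

The secretion profile is modelled as a skewed baseline cosine: a flat
baseline ``B`` plus an exponentiated half-cosine pulse of amplitude
``H`` peaking at the acrophase ``phi``, with independent rising and
falling half-durations (the skewness) and a shape exponent ``nu``.  The
model is extended 24-h periodically so that one parameter set accounts
for both evening rises inside a 40-h recording.

Circadian phase markers are threshold crossings of the fitted curve:
DLMOn is the earliest time on the rising limb at which the modelled
level reaches 25% of the fitted peak-to-baseline amplitude; DLMOff is
the corresponding falling-limb crossing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "PERIOD_MIN",
    "PhaseUndefinedError",
    "SBCFParams",
    "MelatoninSeries",
    "SBCFFit",
    "PhaseEstimate",
    "sbcf",
    "fit_sbcf",
    "extract_dlmo",
    "DLMO_FRACTION",
]

PERIOD_MIN = 1440.0
#: DLMO threshold as a fraction of fitted peak-to-baseline amplitude.
DLMO_FRACTION = 0.25


class PhaseUndefinedError(ValueError):
    """Raised when a phase marker is requested from a pulseless fit."""


@dataclass(frozen=True)
class SBCFParams:
    """Parameters of the skewed baseline cosine secretion model.

    B       baseline concentration (pg/mL)
    H       peak-to-baseline amplitude (pg/mL)
    phi     acrophase, minutes since baseline wake-up
    w_rise  rising half-duration (minutes): curve leaves baseline at phi - w_rise
    w_fall  falling half-duration (minutes): curve regains baseline at phi + w_fall
    nu      shape exponent (>= 1); larger values sharpen the pulse
    """

    B: float
    H: float
    phi: float
    w_rise: float
    w_fall: float
    nu: float

    def __post_init__(self) -> None:
        if self.H < 0:
            raise ValueError("amplitude H must be non-negative")
        if self.w_rise <= 0 or self.w_fall <= 0:
            raise ValueError("half-durations must be positive")
        if self.nu < 1:
            raise ValueError("shape exponent nu must be >= 1")


@dataclass(frozen=True)
class MelatoninSeries:
    """Sampled melatonin concentrations on the protocol time axis."""

    times_min: np.ndarray     # minutes since baseline wake-up
    conc: np.ndarray          # pg/mL

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and concentrations must be 1-D and equal length")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "conc", c)

    @property
    def n(self) -> int:
        return self.times_min.size

    @property
    def span_min(self) -> float:
        return float(np.ptp(self.times_min))


@dataclass(frozen=True)
class SBCFFit:
    params: SBCFParams
    rss: float
    converged: bool


@dataclass(frozen=True)
class PhaseEstimate:
    """DLMOn/DLMOff (minutes since baseline wake-up) and their source fit."""

    dlmon: float
    dlmoff: float
    fit: SBCFParams
    rss: float
    converged: bool

    def __post_init__(self) -> None:
        if not self.dlmon < self.dlmoff:
            raise ValueError("dlmon must precede dlmoff")


def sbcf(t, params: SBCFParams):
    """Evaluate the skewed baseline cosine model at time ``t`` (minutes).

    Within one circadian period the value is
    ``B + H * max(0, cos(pi*(t-phi)/(2*w)))**nu`` with ``w = w_rise``
    before the acrophase and ``w_fall`` after it; the time offset is
    wrapped to the nearest period, so the pulse recurs every 24 h.
    Total function: defined for every real ``t``.
    """
    t = np.asarray(t, dtype=float)
    dt = (t - params.phi + PERIOD_MIN / 2.0) % PERIOD_MIN - PERIOD_MIN / 2.0
    w = np.where(dt < 0, params.w_rise, params.w_fall)
    inside = np.abs(dt) < w
    c = np.where(inside, np.cos(np.pi * dt / (2.0 * w)), 0.0)
    c = np.clip(c, 0.0, None)
    out = params.B + params.H * np.power(c, params.nu)
    return out if out.shape else float(out)


def _residuals(theta: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    p = SBCFParams(*theta)
    return sbcf(t, p) - y


def fit_sbcf(
    series: MelatoninSeries,
    phi_grid_min: float = 120.0,
    n_refine: int = 4,
    extra_starts: list[SBCFParams] | None = None,
) -> SBCFFit:
    """Least-squares fit of the secretion model to a melatonin series.

    Requires at least 8 samples spanning at least 24 h.  Candidate
    acrophases are laid out every ``phi_grid_min`` minutes across the
    first circadian period of the recording; the ``n_refine`` most
    promising starts (lowest raw residual) are polished with bounded
    least squares and the best solution returned.  A constant series is
    returned as a converged zero-amplitude fit.
    """
    t, y = series.times_min, series.conc
    if series.n < 8:
        raise ValueError(f"need >= 8 samples, got {series.n}")
    if series.span_min < PERIOD_MIN:
        raise ValueError(
            f"samples must span >= 24 h, got {series.span_min / 60.0:.1f} h"
        )
    if np.ptp(y) < 1e-12:
        params = SBCFParams(float(y[0]), 0.0, float(t[0]) + 600.0, 180.0, 240.0, 2.0)
        return SBCFFit(params, 0.0, True)

    t0, t1 = float(t.min()), float(t.max())
    phi_hi = min(t1, t0 + PERIOD_MIN)
    b0 = float(np.percentile(y, 10))
    h0 = float(np.ptp(y))
    lb = np.array([0.0, 0.0, t0, 30.0, 30.0, 1.0])
    ub = np.array([float(y.max()), 3.0 * h0 + 1e-9, phi_hi, 600.0, 600.0, 5.0])

    starts: list[np.ndarray] = []
    for phi0 in np.arange(t0, phi_hi + 1e-9, phi_grid_min):
        starts.append(np.array([b0, h0, phi0, 180.0, 240.0, 2.0]))
    for p in extra_starts or []:
        theta = np.array([p.B, p.H, p.phi, p.w_rise, p.w_fall, p.nu])
        starts.append(np.clip(theta, lb, ub))

    # cheap triage: rank starts by raw rss, polish only the best few
    scored = sorted(
        starts, key=lambda th: float(np.sum(_residuals(th, t, y) ** 2))
    )
    n_polish = max(n_refine, len(extra_starts or []) + 1)

    best = None
    for theta0 in scored[:n_polish]:
        try:
            sol = least_squares(
                _residuals, theta0, bounds=(lb, ub), args=(t, y), method="trf"
            )
        except Exception:  # pragma: no cover - solver failure on a start
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        params = SBCFParams(b0, h0, 0.5 * (t0 + phi_hi), 180.0, 240.0, 2.0)
        return SBCFFit(params, float(np.sum(_residuals(
            np.array([b0, h0, 0.5 * (t0 + phi_hi), 180.0, 240.0, 2.0]), t, y) ** 2)),
            False)
    rss, sol = best
    return SBCFFit(SBCFParams(*sol.x), rss, bool(sol.success))


def extract_dlmo(fit: SBCFFit | SBCFParams, xtol_min: float = 1e-4) -> PhaseEstimate:
    """Locate DLMOn/DLMOff as 25%-amplitude crossings of the fitted pulse.

    DLMOn is the rising-limb crossing (between ``phi - w_rise`` and the
    acrophase), DLMOff the falling-limb crossing; both are root-found to
    ``xtol_min`` minutes.  Raises :class:`PhaseUndefinedError` for a
    zero-amplitude fit.
    """
    if isinstance(fit, SBCFParams):
        fit = SBCFFit(fit, float("nan"), True)
    p = fit.params
    if p.H <= 0:
        raise PhaseUndefinedError("phase markers undefined for a flat (H=0) fit")
    level = p.B + DLMO_FRACTION * p.H

    def f(t: float) -> float:
        return sbcf(t, p) - level

    eps = 1e-9
    dlmon = brentq(f, p.phi - p.w_rise + eps, p.phi, xtol=xtol_min)
    dlmoff = brentq(f, p.phi, p.phi + p.w_fall - eps, xtol=xtol_min)
    return PhaseEstimate(float(dlmon), float(dlmoff), p, fit.rss, fit.converged)
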