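"""Reduction of raw NMR decay curves to R1, R2 and D.

Three acquisition modes are supported, matching a standard variable
temperature relaxation/diffusion protocol on a high-field spectrometer:

* inversion recovery -> longitudinal rate R1, model
  ``S(t) = S_inf (1 - 2 f exp(-R1 t))`` with an inversion-efficiency factor
  ``f`` in (0.5, 1] fitted rather than fixed at perfect inversion;
* CPMG echo trains -> transverse rate R2, monoexponential
  ``S(t) = S0 exp(-R2 t)`` with t = echo count x echo time;
* PGSTE gradient ramps -> translational diffusion D via the
  Stejskal-Tanner attenuation ``S = S0 exp(-D gamma^2 g^2 delta^2 (Delta - delta/3))``.

All fits are unweighted nonlinear least squares (scipy) unless per-point
uncertainties are supplied; initialization is a deterministic log-linear
pre-fit on the decaying part of the signal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .relaxation_core import NucleusContext

__all__ = [
    "CurveKind",
    "DecayCurve",
    "DecayFit",
    "DecayFitError",
    "UnderAttenuatedWarning",
    "fit_inversion_recovery",
    "fit_cpmg",
    "fit_pgste",
    "fit_decay",
    "stejskal_tanner_b",
    "read_decay_csv",
    "write_decay_csv",
]


class CurveKind(str, Enum):
    INVERSION_RECOVERY = "inversion_recovery"
    CPMG = "cpmg"
    PGSTE = "pgste"


class DecayFitError(RuntimeError):
    """Raised when a decay fit is degenerate or does not converge."""


class UnderAttenuatedWarning(UserWarning):
    """PGSTE ramp attenuates the signal by less than 20%."""


@dataclass
class DecayCurve:
    """A raw decay curve.

    For inversion recovery and CPMG, ``abscissa`` holds the recovery time or
    the total echo time (echo count x echo spacing) in seconds, strictly
    increasing.  For PGSTE, ``gradients`` holds the gradient strengths (T/m,
    non-negative increasing) together with the gradient-pulse length
    ``delta`` and the diffusion delay ``Delta`` (both s); ``abscissa`` is
    unused.  ``signal`` is in arbitrary units; optional per-point ``sigma``
    enables weighted fits.
    """

    kind: CurveKind
    signal: np.ndarray
    abscissa: Optional[np.ndarray] = None
    gradients: Optional[np.ndarray] = None
    delta: Optional[float] = None
    Delta: Optional[float] = None
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.kind = CurveKind(self.kind)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.size < 4:
            raise ValueError("a decay curve needs at least 4 points")
        if self.kind is CurveKind.PGSTE:
            if self.gradients is None or self.delta is None or self.Delta is None:
                raise ValueError("PGSTE curves need gradients, delta and Delta")
            self.gradients = np.asarray(self.gradients, dtype=float)
            if self.gradients.size != self.signal.size:
                raise ValueError("gradients and signal lengths differ")
            if np.any(self.gradients < 0) or np.any(np.diff(self.gradients) < 0):
                raise ValueError("gradients must be non-negative and non-decreasing")
        else:
            if self.abscissa is None:
                raise ValueError(f"{self.kind.value} curves need an abscissa")
            self.abscissa = np.asarray(self.abscissa, dtype=float)
            if self.abscissa.size != self.signal.size:
                raise ValueError("abscissa and signal lengths differ")
            if np.any(np.diff(self.abscissa) <= 0):
                raise ValueError("abscissa must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class DecayFit:
    """Result of a decay-curve fit.

    ``rate_or_D`` is R1 or R2 in s^-1, or D in m^2/s for PGSTE.
    """

    kind: CurveKind
    rate_or_D: float
    amplitude: float
    standard_error: float
    residual_rms: float
    offset: float = 0.0  # inversion-efficiency factor f for inversion recovery
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rate_or_D <= 0:
            raise ValueError("fitted rate/diffusion must be positive")


def _loglinear_rate(t: np.ndarray, y: np.ndarray) -> float:
    """Deterministic initial rate guess from a log-linear fit of |y|.

    Uses the points where the decaying quantity is positive; falls back to
    the inverse time span when the decay is too shallow to resolve.
    """
    mask = y > 0
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], np.log(y[mask]), 1)[0]
        if slope < 0:
            return -slope
    return 1.0 / (t[-1] - t[0])


def fit_inversion_recovery(curve: DecayCurve) -> DecayFit:
    """Fit S(t) = S_inf (1 - 2 f exp(-R1 t)) and return R1.

    The inversion-efficiency factor f is constrained to (0.5, 1]; f = 1 is a
    perfect 180-degree inversion.  Raises :class:`DecayFitError` when the
    curve shows no resolvable recovery over the sampled window.
    """
    if curve.kind is not CurveKind.INVERSION_RECOVERY:
        raise ValueError("curve kind must be inversion_recovery")
    t, y = curve.abscissa, curve.signal
    s_inf = y[-1]
    if s_inf == 0 or np.allclose(y, y[0], rtol=1e-12, atol=0.0):
        raise DecayFitError("no decay over the sampled window (ill-conditioned)")
    # recovery amplitude S_inf - S(t) decays exponentially
    r0 = _loglinear_rate(t, (s_inf - y) / abs(s_inf))

    def model(t, s_inf, f, r1):
        return s_inf * (1.0 - 2.0 * f * np.exp(-r1 * t))

    try:
        popt, pcov = curve_fit(
            model, t, y, p0=[s_inf, 1.0, r0], sigma=curve.sigma,
            bounds=([-np.inf, 0.5, 0.0], [np.inf, 1.0, np.inf]), maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise DecayFitError(f"inversion-recovery fit failed: {exc}") from exc
    resid = y - model(t, *popt)
    err = math.sqrt(max(pcov[2, 2], 0.0))
    if popt[2] <= 0 or not np.isfinite(err):
        raise DecayFitError("inversion-recovery fit degenerate (R1 <= 0)")
    return DecayFit(kind=curve.kind, rate_or_D=popt[2], amplitude=popt[0],
                    offset=popt[1], standard_error=err,
                    residual_rms=float(np.sqrt(np.mean(resid**2))))


def fit_cpmg(curve: DecayCurve) -> DecayFit:
    """Fit the monoexponential echo decay S(t) = S0 exp(-R2 t) and return R2."""
    if curve.kind is not CurveKind.CPMG:
        raise ValueError("curve kind must be cpmg")
    t, y = curve.abscissa, curve.signal
    if np.allclose(y, y[0], rtol=1e-12, atol=0.0):
        raise DecayFitError("no decay over the echo train (ill-conditioned)")
    r0 = _loglinear_rate(t, y / abs(y[0]))

    def model(t, s0, r2):
        return s0 * np.exp(-r2 * t)

    try:
        popt, pcov = curve_fit(model, t, y, p0=[y[0], r0], sigma=curve.sigma,
                               maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise DecayFitError(f"CPMG fit failed: {exc}") from exc
    resid = y - model(t, *popt)
    err = math.sqrt(max(pcov[1, 1], 0.0))
    if popt[1] <= 0:
        raise DecayFitError("CPMG fit degenerate (R2 <= 0)")
    return DecayFit(kind=curve.kind, rate_or_D=popt[1], amplitude=popt[0],
                    standard_error=err,
                    residual_rms=float(np.sqrt(np.mean(resid**2))))


def stejskal_tanner_b(gradients: np.ndarray, delta: float, Delta: float,
                      gamma: float) -> np.ndarray:
    """Diffusion-weighting factor b = gamma^2 g^2 delta^2 (Delta - delta/3)."""
    g = np.asarray(gradients, dtype=float)
    return (gamma * g * delta) ** 2 * (Delta - delta / 3.0)


def fit_pgste(curve: DecayCurve, ctx: NucleusContext) -> DecayFit:
    """Fit the Stejskal-Tanner attenuation and return D in m^2/s.

    Warns (:class:`UnderAttenuatedWarning`) when the gradient ramp attenuates
    the echo by less than 20%, where the fitted D is poorly conditioned.
    """
    if curve.kind is not CurveKind.PGSTE:
        raise ValueError("curve kind must be pgste")
    b = stejskal_tanner_b(curve.gradients, curve.delta, curve.Delta,
                          ctx.gyromagnetic_ratio)
    y = curve.signal
    if np.all(b == 0):
        raise DecayFitError("all gradient strengths are zero (degenerate)")
    attenuation = 1.0 - y[-1] / y[0]
    if attenuation < 0.2:
        warnings.warn(
            f"echo attenuated by only {100 * attenuation:.1f}% over the ramp",
            UnderAttenuatedWarning, stacklevel=2)
    d0 = _loglinear_rate(b, y / abs(y[0]))

    def model(b, s0, d):
        return s0 * np.exp(-d * b)

    try:
        popt, pcov = curve_fit(model, b, y, p0=[y[0], d0], sigma=curve.sigma,
                               maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise DecayFitError(f"PGSTE fit failed: {exc}") from exc
    resid = y - model(b, *popt)
    err = math.sqrt(max(pcov[1, 1], 0.0))
    if popt[1] <= 0:
        raise DecayFitError("PGSTE fit degenerate (D <= 0)")
    return DecayFit(kind=curve.kind, rate_or_D=popt[1], amplitude=popt[0],
                    standard_error=err,
                    residual_rms=float(np.sqrt(np.mean(resid**2))))


def fit_decay(curve: DecayCurve, ctx: Optional[NucleusContext] = None) -> DecayFit:
    """Dispatch to the fitter matching ``curve.kind``."""
    if curve.kind is CurveKind.INVERSION_RECOVERY:
        return fit_inversion_recovery(curve)
    if curve.kind is CurveKind.CPMG:
        return fit_cpmg(curve)
    return fit_pgste(curve, ctx or NucleusContext())


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------
# Column conventions (units in the header names): time_s / gradient_T_per_m,
# signal, optional sigma.  PGSTE pulse timings travel in extra columns
# delta_s and Delta_s (constant over the curve).

def write_decay_csv(curve: DecayCurve, path: str | Path,
                    header_comment: str | None = None) -> None:
    cols: dict[str, np.ndarray] = {}
    if curve.kind is CurveKind.PGSTE:
        cols["gradient_T_per_m"] = curve.gradients
        cols["delta_s"] = np.full(curve.signal.size, curve.delta)
        cols["Delta_s"] = np.full(curve.signal.size, curve.Delta)
    else:
        cols["time_s"] = curve.abscissa
    cols["signal"] = curve.signal
    if curve.sigma is not None:
        cols["sigma"] = curve.sigma
    df = pd.DataFrame(cols)
    df.insert(0, "kind", curve.kind.value)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_decay_csv(path: str | Path) -> DecayCurve:
    df = pd.read_csv(path, comment="#")
    kind = CurveKind(df["kind"].iloc[0])
    sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
    if kind is CurveKind.PGSTE:
        return DecayCurve(kind=kind, signal=df["signal"].to_numpy(),
                          gradients=df["gradient_T_per_m"].to_numpy(),
                          delta=float(df["delta_s"].iloc[0]),
                          Delta=float(df["Delta_s"].iloc[0]), sigma=sigma)
    return DecayCurve(kind=kind, signal=df["signal"].to_numpy(),
                      abscissa=df["time_s"].to_numpy(), sigma=sigma)
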