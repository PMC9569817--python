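"""Two-state thermal-unfolding model and melting-curve fits.

The observed signal (fixed-wavelength CD or a secondary-structure fraction)
is a population-weighted mix of linear native and unfolded baselines:

    K(T)   = exp[ -(dH/R) (1/T - 1/Tm) ]        (van't Hoff, dCp = 0)
    f_U(T) = K / (1 + K)
    y(T)   = (1 - f_U)(a_N + b_N T) + f_U (a_U + b_U T)

Six parameters are fitted: Tm, dH, and the two baseline (intercept, slope)
pairs.  An optional heat-capacity change dCp extends K(T) with the
Gibbs-Helmholtz terms but is off (0) by default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import optimize

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .datatypes import MeltingCurve

CELSIUS_OFFSET = 273.15


@dataclass
class UnfoldFit:
    """Two-state melting-fit result.

    Tm is in kelvin (``Tm_celsius`` converts); dH_unfold is the van't Hoff
    unfolding enthalpy in kcal/mol; baselines are (intercept, slope) in
    signal units (per kelvin for the slope).
    """

    Tm: float
    dH_unfold: float
    native_baseline: Tuple[float, float]
    unfolded_baseline: Tuple[float, float]
    chisq: float
    dCp: float = 0.0
    at_boundary: bool = False

    @property
    def Tm_celsius(self) -> float:
        return self.Tm - CELSIUS_OFFSET


def fraction_unfolded(
    T,
    Tm: float,
    dH: float,
    dCp: float = 0.0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Unfolded fraction f_U(T) of the two-state equilibrium.

    f_U(Tm) = 0.5 exactly; strictly increasing in T for dH > 0.
    """
    t = np.asarray(T, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive kelvin")
    r = constants.R_gas
    dg = dH * (1.0 - t / Tm)
    if dCp != 0.0:
        dg = dg + dCp * (t - Tm - t * np.log(t / Tm))
    k_eq = np.exp(-dg / (r * t))
    f_u = k_eq / (1.0 + k_eq)
    return float(f_u) if np.isscalar(T) else f_u


def two_state_signal(
    T,
    fit: UnfoldFit,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Model signal at temperature(s) ``T`` (kelvin) for a given fit."""
    t = np.asarray(T, dtype=float)
    f_u = fraction_unfolded(t, fit.Tm, fit.dH_unfold, fit.dCp, constants)
    a_n, b_n = fit.native_baseline
    a_u, b_u = fit.unfolded_baseline
    y = (1.0 - f_u) * (a_n + b_n * t) + f_u * (a_u + b_u * t)
    return float(y) if np.isscalar(T) else y


def _initial_guess(curve: MeltingCurve) -> Tuple[float, float, np.ndarray]:
    t, y = curve.temperature, curve.signal
    n = len(t)
    edge = max(3, n // 6)
    b_n, a_n = np.polyfit(t[:edge], y[:edge], 1)
    b_u, a_u = np.polyfit(t[-edge:], y[-edge:], 1)
    # Tm guess: steepest point of a lightly smoothed derivative
    kernel = np.ones(3) / 3.0
    smoothed = np.convolve(y, kernel, mode="same")
    grad = np.abs(np.gradient(smoothed, t))
    interior = slice(edge, n - edge) if n > 2 * edge + 2 else slice(None)
    tm0 = float(t[interior][np.argmax(grad[interior])])
    return tm0, 85.0, np.array([a_n, b_n, a_u, b_u])


def fit_melting(
    curve: MeltingCurve,
    errors: Optional[np.ndarray] = None,
    dCp: float = 0.0,
    min_transition_snr: float = 5.0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> UnfoldFit:
    """Fit the two-state model to a melting curve.

    Parameters
    ----------
    curve : MeltingCurve
        Temperatures (kelvin, increasing) and signal.
    errors : array, optional
        Per-point signal errors; uniform weights when omitted.
    dCp : float
        Heat-capacity change in kcal mol^-1 K^-1, held fixed (not fitted).
    min_transition_snr : float
        The signal change across the curve must exceed this multiple of the
        point-to-point noise, otherwise no transition is detectable.

    Notes
    -----
    A fit whose Tm lands at the edge of the data range is flagged via
    ``at_boundary`` -- the transition is then not bracketed and Tm/dH are
    extrapolations.
    """
    t, y = curve.temperature, curve.signal
    noise = float(np.median(np.abs(np.diff(y)))) or 1e-12
    span = float(np.ptp(y))
    if span < min_transition_snr * noise:
        raise ValueError(
            "no unfolding transition detected: signal change "
            f"({span:.3g}) is below {min_transition_snr} x point noise ({noise:.3g})"
        )
    weights = np.ones_like(y) if errors is None else 1.0 / np.asarray(errors)

    tm0, dh0, base0 = _initial_guess(curve)

    def residuals(x: np.ndarray) -> np.ndarray:
        fit = UnfoldFit(
            Tm=x[0],
            dH_unfold=x[1],
            native_baseline=(x[2], x[3]),
            unfolded_baseline=(x[4], x[5]),
            chisq=0.0,
            dCp=dCp,
        )
        return (two_state_signal(t, fit, constants) - y) * weights

    lo = [t[0], 1.0, -np.inf, -np.inf, -np.inf, -np.inf]
    hi = [t[-1], 500.0, np.inf, np.inf, np.inf, np.inf]
    best = None
    for tm_start in (tm0, 0.5 * (t[0] + t[-1])):
        x0 = np.clip(
            np.concatenate([[tm_start, dh0], base0]),
            lo, hi,
        )
        result = optimize.least_squares(
            residuals, x0=x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12
        )
        if best is None or result.cost < best.cost:
            best = result
    tm, dh = best.x[0], best.x[1]
    at_boundary = bool(
        tm - t[0] < 1e-6 * (t[-1] - t[0]) or t[-1] - tm < 1e-6 * (t[-1] - t[0])
    )
    if at_boundary:
        warnings.warn(
            "fitted Tm lies at the temperature-range boundary; the transition "
            "is not bracketed by the data",
            RuntimeWarning,
            stacklevel=2,
        )
    return UnfoldFit(
        Tm=float(tm),
        dH_unfold=float(dh),
        native_baseline=(float(best.x[2]), float(best.x[3])),
        unfolded_baseline=(float(best.x[4]), float(best.x[5])),
        chisq=float(2.0 * best.cost),
        dCp=dCp,
        at_boundary=at_boundary,
    )
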