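"""Two-state CPMG relaxation dispersion: Carver-Richards modelling and fits.

A ground state A exchanges with a sparsely populated excited state B
(k_ex = k_AB + k_BA, population p_B < 0.5, 15N shift difference |dw| in
ppm).  The closed-form Carver-Richards expression gives the effective
transverse relaxation rate R2eff as a function of the CPMG refocusing
frequency nu_CPMG; it is valid on all exchange timescales and is the fit
engine here.  A numerically exact two-state Bloch-McConnell propagator over
the pulse train is provided as an independent cross-check.

Only single-quantum 15N dispersions are modelled: the multiple-quantum
formulation degenerates to Carver-Richards when the 1H shift difference is
zero, which is the exposed default (nonzero 1H dw is out of scope).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize
from scipy.linalg import expm

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .datatypes import DispersionDataset, DispersionProfile, ResidueId

#: The 19-point CPMG frequency grid of the study acquisition scheme (Hz).
NU_CPMG_GRID = np.array(
    [25.0, 50.0, 74.0, 99.0, 123.0, 147.0, 172.0, 195.0, 219.0, 242.0,
     289.0, 335.0, 380.0, 425.0, 469.0, 556.0, 641.0, 764.0, 883.0]
)

#: Constant-time CPMG relaxation delay (s).
DEFAULT_T_CP = 0.040

REX_FLAG_THRESHOLD = 15.0  # Hz; profiles above this are flagged as strong exchange


@dataclass
class ExchangeParams:
    """Two-state exchange parameters for one residue (or shared cluster)."""

    kex: float  # s^-1, k_AB + k_BA
    pB: float  # excited-state fraction, in (0, 0.5)
    dw: float  # ppm, |15N shift difference| between states
    R20: float  # s^-1, intrinsic transverse rate

    def __post_init__(self) -> None:
        if self.kex <= 0:
            raise ValueError("kex must be positive")
        if not (0.0 < self.pB < 0.5):
            raise ValueError("pB must lie in (0, 0.5)")
        if self.dw < 0:
            raise ValueError("dw must be non-negative")
        if self.R20 <= 0:
            raise ValueError("R20 must be positive")

    @property
    def kAB(self) -> float:
        return self.pB * self.kex

    @property
    def kBA(self) -> float:
        return (1.0 - self.pB) * self.kex


@dataclass
class ExchangeFit:
    """Result of an individual-profile two-state fit."""

    params: ExchangeParams
    errors: Dict[str, float]
    chisq: float
    dof: int
    rex: float
    degenerate: bool = False


@dataclass
class GlobalFitResult:
    """Global cluster fit: shared kinetics per temperature, shared dw per residue."""

    kex: Dict[float, float]  # temperature -> s^-1
    pB: Dict[float, float]  # temperature -> fraction
    dw: Dict[ResidueId, float]  # ppm, shared across temperatures
    R20: Dict[Tuple[ResidueId, float], float]
    chisq: float
    dof: int
    errors: Dict[str, Dict] = field(default_factory=dict)


@dataclass
class ThermoParams:
    """Van't Hoff thermodynamics of the exchange equilibrium."""

    dH: float  # kcal/mol
    dS: float  # cal mol^-1 K^-1
    dG_at: Dict[float, float]  # temperature -> kcal/mol
    kAB: Dict[float, float]
    kBA: Dict[float, float]


def ppm_to_rad(dw_ppm: float, field_B0: float,
               constants: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Convert a 15N shift difference from ppm to rad/s at the given field."""
    return dw_ppm * 1e-6 * abs(constants.omega_N(field_B0))


def r2eff_two_state(
    nu_cpmg,
    p: ExchangeParams,
    field_B0: float = 14.1,
    dw_H: float = 0.0,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Carver-Richards closed-form R2eff at the given CPMG frequencies.

    ``nu_cpmg`` (Hz, > 0) may be scalar or array.  ``dw_H`` is accepted for
    interface compatibility with multiple-quantum treatments but must be 0
    (single-quantum 15N only).  Evaluation is overflow-safe: the acosh of
    the large-argument branch is taken in the log domain.
    """
    if dw_H != 0.0:
        raise NotImplementedError(
            "nonzero 1H shift difference (multiple-quantum dispersion) is not supported"
        )
    nu = np.asarray(nu_cpmg, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("nu_cpmg must be strictly positive")
    dw = ppm_to_rad(p.dw, field_B0, constants)
    pA = 1.0 - p.pB
    k_ab, k_ba = p.kAB, p.kBA
    # equal intrinsic rates in the two states
    psi = (k_ba - k_ab) ** 2 - dw**2 + 4.0 * k_ab * k_ba
    zeta = 2.0 * dw * (k_ba - k_ab)
    root = math.hypot(psi, zeta)
    d_plus = 0.5 * (1.0 + (psi + 2.0 * dw**2) / root)
    d_minus = 0.5 * (-1.0 + (psi + 2.0 * dw**2) / root)
    eta_plus = np.sqrt(max(root + psi, 0.0) / 2.0) / (2.0 * nu)
    eta_minus = np.sqrt(max(root - psi, 0.0) / 2.0) / (2.0 * nu)
    # acosh(D+ cosh(eta+) - D- cos(eta-)), stable for large eta+
    small = eta_plus < 30.0
    arg = np.where(
        small,
        d_plus * np.cosh(np.where(small, eta_plus, 0.0)) - d_minus * np.cos(eta_minus),
        1.0,
    )
    acosh_term = np.empty_like(arg)
    acosh_term[small] = np.arccosh(np.maximum(arg[small], 1.0))
    if np.any(~small):
        big = ~small
        # cosh(x) ~ e^x / 2; acosh(y) ~ ln(2y)
        log2y = (
            np.log(
                d_plus * (1.0 + np.exp(-2.0 * eta_plus[big]))
                - 2.0 * d_minus * np.cos(eta_minus[big]) * np.exp(-eta_plus[big])
            )
            + eta_plus[big]
        )
        acosh_term[big] = log2y
    r2 = p.R20 + 0.5 * (p.kex - 2.0 * nu * acosh_term)
    return float(r2) if np.isscalar(nu_cpmg) else r2


def _real_rep(mat: np.ndarray) -> np.ndarray:
    """Real 4x4 representation of a complex 2x2 linear map."""
    return np.block([[mat.real, -mat.imag], [mat.imag, mat.real]])


_CONJ = np.diag([1.0, 1.0, -1.0, -1.0])  # ideal 180 pulse: complex conjugation


def bloch_mcconnell_r2eff(
    nu_cpmg,
    p: ExchangeParams,
    field_B0: float = 14.1,
    T_CP: float = DEFAULT_T_CP,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    method: str = "eigenvalue",
):
    """Numerically exact two-state R2eff from the Bloch-McConnell equations
    propagated over the CPMG pulse train.

    The pulse train is tau-180-tau echo units with nu_cpmg = 1/(4 tau); 180
    pulses are ideal and instantaneous (complex conjugation of the
    transverse magnetization); free precession uses the matrix exponential
    of the two-site evolution matrix.

    ``method='eigenvalue'`` (default) reports the decay rate of the
    slowest-decaying mode of the echo propagator, i.e. the asymptotic
    per-unit-time attenuation of the pulse train -- the quantity the
    closed-form expression describes.  ``method='intensity'`` instead
    propagates equilibrium magnetization through the finite constant-time
    train and returns -(1/T_CP) ln(|M_A(T_CP)|/p_A); this includes
    transient amplitude effects of order a few percent at low nu_cpmg and
    requires 2*T_CP*nu_cpmg to be a whole number of echoes.
    """
    if method not in ("eigenvalue", "intensity"):
        raise ValueError(f"unknown method {method!r}")
    nus = np.atleast_1d(np.asarray(nu_cpmg, dtype=float))
    if np.any(nus <= 0):
        raise ValueError("nu_cpmg must be strictly positive")
    dw = ppm_to_rad(p.dw, field_B0, constants)
    liouville = np.array(
        [
            [-p.R20 - p.kAB, p.kBA],
            [p.kAB, -p.R20 - p.kBA + 1j * dw],
        ],
        dtype=complex,
    )
    out = np.empty_like(nus)
    pA = 1.0 - p.pB
    for i, nu in enumerate(nus):
        tau = 1.0 / (4.0 * nu)
        prop = expm(liouville * tau)
        if method == "eigenvalue":
            echo = _real_rep(prop) @ _CONJ @ _real_rep(prop)
            lam = np.max(np.abs(np.linalg.eigvals(echo)))
            out[i] = -math.log(lam) / (2.0 * tau)
        else:
            n_echo = int(round(2.0 * T_CP * nu))
            if n_echo < 1 or abs(n_echo - 2.0 * T_CP * nu) > 1e-6:
                raise ValueError(
                    f"nu_cpmg={nu} does not give a whole number of echoes in "
                    f"T_CP={T_CP}"
                )
            m = np.array([pA, p.pB], dtype=complex)
            for _ in range(n_echo):
                m = prop @ np.conj(prop @ m)
            out[i] = -math.log(abs(m[0]) / pA) / T_CP
    return float(out[0]) if np.isscalar(nu_cpmg) else out


def rex_from_profile(profile: DispersionProfile) -> float:
    """Exchange contribution estimated as R2eff at the lowest minus at the
    highest CPMG frequency.  May be negative on noisy flat profiles."""
    if len(profile.nu_cpmg) < 2:
        raise ValueError("need at least 2 nu_CPMG points")
    order = np.argsort(profile.nu_cpmg)
    return float(profile.r2eff[order[0]] - profile.r2eff[order[-1]])


def flag_strong_exchange(
    data: DispersionDataset, threshold: float = REX_FLAG_THRESHOLD
) -> List[Tuple[ResidueId, float]]:
    """Profiles whose apparent Rex exceeds ``threshold`` Hz (flagged sites)."""
    return [
        (rid, temp)
        for (rid, temp), prof in data.profiles.items()
        if rex_from_profile(prof) > threshold
    ]


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_KEX_STARTS = (1e2, 1e3, 1e4)
_PB_STARTS = (0.01, 0.05)


def _is_flat(profile: DispersionProfile) -> bool:
    span = float(profile.r2eff.max() - profile.r2eff.min())
    return span < 2.0 * float(np.median(profile.error))


def fit_individual(
    profile: DispersionProfile,
    field_B0: float = 14.1,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    dw_max: float = 15.0,
) -> ExchangeFit:
    """Two-state fit of one dispersion profile.

    Weighted least squares over (kex, pB, dw, R20) with a multistart grid
    over kex decades and pB values.  Flat profiles leave pB*dw
    unidentifiable; these are reported with ``degenerate=True`` rather than
    spurious parameter precision.  Parameter errors come from the Jacobian
    covariance scaled by the reduced chi-square.
    """
    if len(profile.nu_cpmg) < 6:
        raise ValueError("need >= 6 nu_CPMG points for an individual fit")
    if np.any(profile.error <= 0):
        raise ValueError("profile errors must be strictly positive")
    nu = profile.nu_cpmg
    obs = profile.r2eff
    err = profile.error

    def residuals(x: np.ndarray) -> np.ndarray:
        kex, pb, dw, r20 = np.exp(x[0]), x[1], x[2], x[3]
        pred = r2eff_two_state(
            nu, ExchangeParams(kex, pb, dw, r20), field_B0, constants=constants
        )
        return (pred - obs) / err

    r20_guess = max(float(obs.min()), 0.1)
    lo = [math.log(1.0), 1e-4, 0.0, 0.01]
    hi = [math.log(1e6), 0.499, dw_max, 200.0]
    best = None
    for kex0 in _KEX_STARTS:
        for pb0 in _PB_STARTS:
            rex0 = max(float(obs.max() - obs.min()), 0.1)
            # fast-exchange guess: Rex ~ pA pB dw^2 / kex
            dw0 = math.sqrt(rex0 * kex0 / (pb0 * (1 - pb0))) / ppm_to_rad(
                1.0, field_B0, constants
            )
            x0 = np.clip(
                [math.log(kex0), pb0, min(dw0, dw_max * 0.9), r20_guess], lo, hi
            )
            result = optimize.least_squares(
                residuals, x0=x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12
            )
            if best is None or result.cost < best.cost:
                best = result
    kex, pb, dw, r20 = math.exp(best.x[0]), best.x[1], max(best.x[2], 1e-9), best.x[3]
    params = ExchangeParams(kex=kex, pB=min(pb, 0.499), dw=dw, R20=r20)
    chisq = float(2.0 * best.cost)
    dof = len(nu) - 4
    fitted = r2eff_two_state(np.array([nu.min(), nu.max()]), params, field_B0,
                             constants=constants)
    rex = float(fitted[0] - fitted[1])
    degenerate = _is_flat(profile) or rex < 2.0 * float(np.median(err))
    errors = _covariance_errors(best, ("log_kex", "pB", "dw", "R20"), chisq, dof)
    if "log_kex" in errors:
        errors["kex"] = errors.pop("log_kex") * kex
    if degenerate:
        warnings.warn(
            "flat dispersion profile: pB and dw are unidentifiable (only their "
            "combination is constrained)",
            RuntimeWarning,
            stacklevel=2,
        )
    return ExchangeFit(
        params=params, errors=errors, chisq=chisq, dof=dof, rex=rex,
        degenerate=degenerate,
    )


def _covariance_errors(result, names: Sequence[str], chisq: float, dof: int) -> Dict[str, float]:
    try:
        jac = result.jac
        cov = np.linalg.inv(jac.T @ jac)
        scale = chisq / dof if dof > 0 else 1.0
        sd = np.sqrt(np.clip(np.diag(cov) * scale, 0.0, np.inf))
        return {n: float(s) for n, s in zip(names, sd)}
    except np.linalg.LinAlgError:
        return {}


def fit_global(
    data: DispersionDataset,
    cluster: Sequence[ResidueId],
    temperatures: Optional[Sequence[float]] = None,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    dw_max: float = 15.0,
) -> GlobalFitResult:
    """Global two-state fit of a residue cluster across temperatures.

    Shared parameters: (kex, pB) per temperature; per-residue dw shared
    across temperatures; intrinsic R20 free per (residue, temperature)
    profile.  The R20 values are profiled out in closed form at each
    iteration (they enter additively), so the optimizer only sees the
    kinetic and shift parameters.
    """
    cluster = list(cluster)
    if temperatures is None:
        temperatures = data.temperatures
    temperatures = sorted(temperatures)
    for rid in cluster:
        for temp in temperatures:
            if (rid, temp) not in data.profiles:
                raise ValueError(f"cluster residue {rid} has no profile at {temp} K")

    profiles = {
        (rid, temp): data.profiles[(rid, temp)]
        for rid in cluster
        for temp in temperatures
    }
    n_t = len(temperatures)
    n_r = len(cluster)

    def unpack(x: np.ndarray):
        kex = np.exp(x[:n_t])
        pb = x[n_t: 2 * n_t]
        dw = x[2 * n_t:]
        return kex, pb, dw

    def residuals(x: np.ndarray) -> np.ndarray:
        kex, pb, dw = unpack(x)
        out = []
        for i, rid in enumerate(cluster):
            for j, temp in enumerate(temperatures):
                prof = profiles[(rid, temp)]
                params = ExchangeParams(
                    kex=kex[j], pB=pb[j], dw=max(dw[i], 1e-9), R20=1.0
                )
                shape = r2eff_two_state(
                    prof.nu_cpmg, params, data.field_B0, constants=constants
                ) - 1.0  # exchange contribution on top of R20
                w = 1.0 / prof.error**2
                r20 = np.sum(w * (prof.r2eff - shape)) / np.sum(w)
                out.append((shape + r20 - prof.r2eff) / prof.error)
        return np.concatenate(out)

    dw_init = np.array(
        [
            max(
                math.sqrt(
                    max(rex_from_profile(profiles[(rid, temperatures[0])]), 0.05)
                ),
                0.2,
            )
            for rid in cluster
        ]
    )
    lo = np.concatenate([[math.log(1.0)] * n_t, [1e-4] * n_t, [0.0] * n_r])
    hi = np.concatenate([[math.log(1e6)] * n_t, [0.499] * n_t, [dw_max] * n_r])
    best = None
    for kex0 in _KEX_STARTS:
        for pb0 in _PB_STARTS:
            x0 = np.clip(
                np.concatenate([[math.log(kex0)] * n_t, [pb0] * n_t, dw_init]),
                lo, hi,
            )
            result = optimize.least_squares(
                residuals, x0=x0, bounds=(lo, hi), xtol=1e-10, ftol=1e-10
            )
            if best is None or result.cost < best.cost:
                best = result
    if not best.success:
        warnings.warn(
            f"global fit did not report convergence: {best.message}", RuntimeWarning,
            stacklevel=2,
        )
    kex, pb, dw = unpack(best.x)
    # recover the profiled R20 values at the optimum
    r20_map: Dict[Tuple[ResidueId, float], float] = {}
    for i, rid in enumerate(cluster):
        for j, temp in enumerate(temperatures):
            prof = profiles[(rid, temp)]
            params = ExchangeParams(
                kex=kex[j], pB=pb[j], dw=max(dw[i], 1e-9), R20=1.0
            )
            shape = r2eff_two_state(
                prof.nu_cpmg, params, data.field_B0, constants=constants
            ) - 1.0
            w = 1.0 / prof.error**2
            r20_map[(rid, temp)] = float(
                np.sum(w * (prof.r2eff - shape)) / np.sum(w)
            )
    n_points = sum(len(p.nu_cpmg) for p in profiles.values())
    n_params = 2 * n_t + n_r + len(profiles)
    return GlobalFitResult(
        kex={t: float(k) for t, k in zip(temperatures, kex)},
        pB={t: float(p_) for t, p_ in zip(temperatures, pb)},
        dw={rid: float(d) for rid, d in zip(cluster, dw)},
        R20=r20_map,
        chisq=float(2.0 * best.cost),
        dof=n_points - n_params,
    )


# ---------------------------------------------------------------------------
# Thermodynamics
# ---------------------------------------------------------------------------

def exchange_thermo(
    kex: Dict[float, float],
    pB: Dict[float, float],
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> ThermoParams:
    """Van't Hoff analysis of the A<->B equilibrium across temperatures.

    K(T) = pB/(1-pB) = kAB/kBA; a least-squares line of ln K against 1/T
    gives dH = -R * slope and dS = R * intercept.  Forward/reverse rates are
    kAB = pB*kex and kBA = (1-pB)*kex; dG(T) = -R*T*ln(kAB/kBA) is computed
    at every input temperature even when fewer than the three temperatures
    needed for the regression are available (dH/dS then raise).
    """
    temps = sorted(kex)
    if sorted(pB) != temps:
        raise ValueError("kex and pB must cover the same temperatures")
    k_ab = {t: pB[t] * kex[t] for t in temps}
    k_ba = {t: (1.0 - pB[t]) * kex[t] for t in temps}
    r_kcal = constants.R_gas
    dg = {t: -r_kcal * t * math.log(k_ab[t] / k_ba[t]) for t in temps}
    if len(temps) < 3:
        raise ValueError("need >= 3 temperatures for the van't Hoff regression")
    inv_t = np.array([1.0 / t for t in temps])
    ln_k = np.array([math.log(pB[t] / (1.0 - pB[t])) for t in temps])
    slope, intercept = np.polyfit(inv_t, ln_k, 1)
    dh = -r_kcal * slope  # kcal/mol
    ds = r_kcal * intercept * 1e3  # cal/mol/K
    return ThermoParams(dH=float(dh), dS=float(ds), dG_at=dg, kAB=k_ab, kBA=k_ba)


def thermo_from_global(fit: GlobalFitResult,
                       constants: PhysicalConstants = DEFAULT_CONSTANTS) -> ThermoParams:
    """Van't Hoff thermodynamics straight from a global cluster fit."""
    return exchange_thermo(fit.kex, fit.pB, constants)
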