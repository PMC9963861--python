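"""Spectral densities and elementary relaxation-rate kernels.

Five ingredient families are provided:

* Lorentzian dipolar relaxation, ``C [J(w) + 4 J(2w)]`` with
  ``J(w) = tau / (1 + (w tau)^2)`` — exponential correlation functions;
* the force-free-hard-sphere (FFHS) spectral density for unrestricted 3D
  relative translational diffusion of spin-bearing spheres, evaluated by
  adaptive quadrature of the Hwang–Freed integral;
* the two-dimensional (surface-diffusion) spectral density, logarithmic in
  frequency, with or without a finite adsorption residence lifetime;
* the 1H-14N quadrupole relaxation enhancement (QRE) rate — six Lorentzians
  centred at the 14N quadrupole transition frequencies;
* conversion helpers between translational correlation times and diffusion
  coefficients, and between inter-spin distance and dipolar constant.

All public functions take the Larmor frequency as *angular* frequency
``omega`` in rad/s; the Hz -> rad/s conversion happens once, in
:mod:`nmrdfit.models`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import quad

from .constants import CONSTANTS, PhysicalConstants

__all__ = [
    "LorentzianComponent",
    "FFHSParams",
    "SurfaceDiffusionParams",
    "QREParams",
    "lorentzian_r1",
    "j3d_ffhs",
    "r1_translational_3d",
    "j2d",
    "j2d_long_residence",
    "r1_qre_hn",
    "qre_peak_frequencies",
    "d_from_tau",
    "tau_from_d",
    "cdd_hn_from_distance",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LorentzianComponent:
    """One dipolar relaxation contribution with an exponential correlation
    function: amplitude ``C`` (s^-2) and correlation time ``tau`` (s)."""

    C: float
    tau: float

    def __post_init__(self) -> None:
        if self.C < 0:
            raise ValueError("relaxation constant C must be non-negative")
        if self.tau <= 0:
            raise ValueError("correlation time tau must be strictly positive")


@dataclass(frozen=True)
class FFHSParams:
    """Parameters of the force-free-hard-sphere translational model.

    ``N_H`` is the hydrogen number density of the diffusing fraction (m^-3),
    ``d`` the distance of closest approach (m) and ``tau_trans`` the
    translational correlation time ``d^2 / (2 D)`` (s).
    """

    N_H: float
    d: float
    tau_trans: float

    def __post_init__(self) -> None:
        if self.N_H < 0:
            raise ValueError("N_H must be non-negative")
        if self.d <= 0:
            raise ValueError("distance of closest approach d must be positive")
        if self.tau_trans <= 0:
            raise ValueError("tau_trans must be strictly positive")


#: Sentinel accepted by :class:`SurfaceDiffusionParams` for an unbounded
#: residence lifetime (reduces the 2D spectral density to its long-residence
#: limit).
INFINITE = math.inf


@dataclass(frozen=True)
class SurfaceDiffusionParams:
    """Two-dimensional (surface) diffusion parameters.

    ``tau_res`` is the mean time a water molecule stays adsorbed on the
    macromolecular surface; ``math.inf`` selects the long-residence limit.
    A finite ``tau_res`` must exceed ``tau_trans`` — adsorption truncates the
    surface-diffusion correlation function on a slower time scale than the
    diffusion itself decorrelates it.
    """

    C_trans: float
    tau_trans: float
    tau_res: float = INFINITE

    def __post_init__(self) -> None:
        if self.C_trans < 0:
            raise ValueError("C_trans must be non-negative")
        if self.tau_trans <= 0:
            raise ValueError("tau_trans must be strictly positive")
        if not math.isinf(self.tau_res) and self.tau_res <= self.tau_trans:
            raise ValueError("finite tau_res must exceed tau_trans")


@dataclass(frozen=True)
class QREParams:
    """1H-14N quadrupole relaxation enhancement parameters.

    ``a_Q`` is the 14N quadrupole coupling constant (Hz), ``eta`` the
    asymmetry parameter of the electric-field-gradient (EFG) tensor,
    ``tau_Q`` the correlation time of the 1H-14N dipolar coupling and
    ``theta``/``phi`` the EFG orientation angles relative to the H-N axis,
    in degrees.  ``r_HN``, when given, records the inter-spin distance from
    which ``C_DD_HN`` may be derived.
    """

    C_DD_HN: float
    a_Q: float
    eta: float
    tau_Q: float
    theta: float
    phi: float
    r_HN: float | None = None

    def __post_init__(self) -> None:
        if self.C_DD_HN < 0:
            raise ValueError("C_DD_HN must be non-negative")
        if self.a_Q <= 0:
            raise ValueError("quadrupole coupling a_Q must be positive")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("asymmetry parameter eta must lie in [0, 1]")
        if self.tau_Q <= 0:
            raise ValueError("tau_Q must be strictly positive")
        if not (0.0 <= self.theta <= 90.0 and 0.0 <= self.phi <= 90.0):
            raise ValueError("theta and phi must lie in [0, 90] degrees")
        if self.r_HN is not None and self.r_HN <= 0:
            raise ValueError("r_HN must be positive when given")


# ---------------------------------------------------------------------------
# Lorentzian kernel
# ---------------------------------------------------------------------------

def lorentzian_r1(C: float, tau: float, omega):
    """Dipolar relaxation rate for an exponential correlation function.

    ``R1 = C [ tau/(1+(w tau)^2) + 4 tau/(1+(2 w tau)^2) ]`` — even in
    ``omega`` and monotonically non-increasing on ``omega >= 0``; the
    zero-frequency plateau is exactly ``5 C tau``.
    """
    if tau <= 0:
        raise ValueError("correlation time tau must be strictly positive")
    if C < 0:
        raise ValueError("relaxation constant C must be non-negative")
    omega = np.asarray(omega, dtype=float)
    wt = omega * tau
    return C * (tau / (1.0 + wt**2) + 4.0 * tau / (1.0 + (2.0 * wt) ** 2))


# ---------------------------------------------------------------------------
# FFHS (3D translational diffusion)
# ---------------------------------------------------------------------------

def _ffhs_integrand(u: float, x: float) -> float:
    return u**4 / (81.0 + 9.0 * u**2 - 2.0 * u**4 + u**6) / (u**4 + x * x)


#: beyond this the integrand is < u^-6 and the tail contributes < 1e-10 rel.
_FFHS_UMAX = 2.0e3
_FFHS_RTOL = 1.0e-8


@lru_cache(maxsize=65536)
def _ffhs_reduced(x: float) -> float:
    """Reduced FFHS integral I(x) = int_0^inf u^4/(81+9u^2-2u^4+u^6)/(u^4+x^2) du.

    The full spectral density depends on (omega, tau) only through
    x = omega*tau, so results are memoized on x.
    """
    val, err = quad(
        _ffhs_integrand, 0.0, _FFHS_UMAX, args=(x,),
        epsabs=0.0, epsrel=_FFHS_RTOL, limit=500,
    )
    if not np.isfinite(val) or (val > 0 and err / val > 100 * _FFHS_RTOL):
        raise ArithmeticError(
            f"FFHS quadrature did not converge at x={x!r} (value={val!r}, err={err!r})"
        )
    return val


#: normalization of the Hwang-Freed spectral density
_FFHS_NORM = 72.0 / 5.0

# The reduced integral I(x) is one-dimensional and smooth; model fitting
# evaluates it at thousands of continuously varying x, where per-point
# adaptive quadrature would dominate the runtime.  A cubic log-log spline
# through quadrature values at 2500 knots covers the x range any profile
# fit can reach (nu in [1 kHz, 1 GHz] x tau in [1e-12, 1e-4] s); below the
# table I(x) follows its sqrt(x) leading correction, above it the code
# falls back to direct quadrature.
_SPL_LO, _SPL_HI = 1e-7, 1e6
_interp_state: tuple | None = None


def _ffhs_interp_state():
    global _interp_state
    if _interp_state is None:
        from scipy.interpolate import CubicSpline

        xs = np.geomspace(_SPL_LO, _SPL_HI, 2500)
        ys = np.array([_ffhs_reduced(float(x)) for x in xs])
        spline = CubicSpline(np.log(xs), np.log(ys))
        i0 = _ffhs_reduced(0.0)
        sqrt_coeff = (i0 - ys[0]) / math.sqrt(_SPL_LO)
        _interp_state = (spline, i0, sqrt_coeff)
    return _interp_state


def _ffhs_reduced_vec(x: np.ndarray) -> np.ndarray:
    """Vectorized reduced FFHS integral (spline-accelerated, validated
    against the adaptive quadrature to ~1e-7 relative)."""
    spline, i0, c = _ffhs_interp_state()
    x = np.abs(np.asarray(x, dtype=float))
    out = np.empty_like(x)
    small = x < _SPL_LO
    big = x > _SPL_HI
    mid = ~(small | big)
    out[small] = i0 - c * np.sqrt(x[small])
    if mid.any():
        out[mid] = np.exp(spline(np.log(x[mid])))
    for i in np.flatnonzero(big):
        out[i] = _ffhs_reduced(float(x[i]))
    return out


def j3d_ffhs(omega, tau_trans: float):
    """Force-free-hard-sphere spectral density (Hwang–Freed kernel).

    Returns ``(72/5) tau_trans * I(omega*tau_trans)`` with
    ``I(x) = int_0^inf u^4/(81+9u^2-2u^4+u^6) / (u^4+x^2) du``; positive,
    even in ``omega`` and non-increasing on ``omega >= 0``.  Dimensional
    prefactors live in :func:`r1_translational_3d`.
    """
    if tau_trans <= 0:
        raise ValueError("tau_trans must be strictly positive")
    omega = np.asarray(omega, dtype=float)
    out = _FFHS_NORM * tau_trans * _ffhs_reduced_vec(
        np.atleast_1d(omega) * tau_trans)
    return out.reshape(omega.shape) if omega.shape else float(out[0])


def r1_translational_3d(params: FFHSParams, omega,
                        constants: PhysicalConstants = CONSTANTS):
    """Relaxation rate from 3D translational diffusion (FFHS model).

    ``R1 = (3/2) (mu0/(4 pi) gamma_H^2 hbar)^2 N_H/d^3
    [J(omega) + 4 J(2 omega)]`` with the reduced FFHS density of
    :func:`j3d_ffhs`; linear in ``N_H``.
    """
    if params.d <= 0:
        raise ValueError("distance of closest approach d must be positive")
    pref = (1.5 * (constants.mu0 / (4 * math.pi) * constants.gamma_H**2
                   * constants.hbar) ** 2 * params.N_H / params.d**3)
    omega = np.asarray(omega, dtype=float)
    return pref * (j3d_ffhs(omega, params.tau_trans)
                   + 4.0 * j3d_ffhs(2.0 * omega, params.tau_trans))


# ---------------------------------------------------------------------------
# 2D surface diffusion
# ---------------------------------------------------------------------------

def j2d(omega, tau_trans: float, tau_res: float = INFINITE):
    """Spectral density of two-dimensional (surface) translational diffusion.

    ``J2D(w) = tau_trans * ln[(1+(w tau)^2) / ((tau/tau_res)^2 + (w tau)^2)]``.
    A finite residence lifetime ``tau_res`` caps the logarithmic divergence
    at zero frequency; with ``tau_res = inf`` the expression reduces to the
    long-residence form ``tau * ln(1 + (w tau)^-2)``, which diverges at
    ``omega = 0`` (raised as a domain error).
    """
    if tau_trans <= 0:
        raise ValueError("tau_trans must be strictly positive")
    if tau_res <= 0:
        raise ValueError("tau_res must be strictly positive (or math.inf)")
    omega = np.asarray(omega, dtype=float)
    wt2 = (omega * tau_trans) ** 2
    if math.isinf(tau_res):
        if np.any(wt2 == 0.0):
            raise ValueError(
                "J2D diverges logarithmically at omega=0 for an infinite "
                "residence lifetime"
            )
        return tau_trans * np.log1p(1.0 / wt2)
    r2 = (tau_trans / tau_res) ** 2
    return tau_trans * np.log((1.0 + wt2) / (r2 + wt2))


def j2d_long_residence(omega, tau_trans: float):
    """Long-residence (tau_res -> inf) limit of :func:`j2d`."""
    return j2d(omega, tau_trans, INFINITE)


# ---------------------------------------------------------------------------
# 1H-14N quadrupole relaxation enhancement
# ---------------------------------------------------------------------------

def qre_peak_frequencies(a_Q: float, eta: float) -> tuple[float, float, float]:
    """14N quadrupole transition frequencies (Hz) for coupling ``a_Q`` and
    asymmetry ``eta``: ``nu_- = a_Q (1 - eta/3)``, ``nu_+ = a_Q (1 + eta/3)``,
    ``nu_0 = nu_+ - nu_-``."""
    if a_Q <= 0:
        raise ValueError("a_Q must be positive")
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    nu_minus = a_Q * (1.0 - eta / 3.0)
    nu_plus = a_Q * (1.0 + eta / 3.0)
    return nu_minus, nu_plus, nu_plus - nu_minus


def r1_qre_hn(params: QREParams, omega):
    """1H-14N quadrupole relaxation enhancement rate.

    Sum of six Lorentzians of width ``1/tau_Q`` centred at ``±omega_-``,
    ``±omega_+`` and ``±omega_0`` (the 14N quadrupole transition
    frequencies), with weights set by the EFG orientation angles:
    ``(1/3 + sin^2(theta) cos^2(phi))``, ``(1/3 + sin^2(theta) sin^2(phi))``
    and ``(1/3 + cos^2(theta))``; the three weights always sum to 2.
    """
    omega = np.asarray(omega, dtype=float)
    nu_m, nu_p, nu_0 = qre_peak_frequencies(params.a_Q, params.eta)
    w_m, w_p, w_0 = 2 * math.pi * nu_m, 2 * math.pi * nu_p, 2 * math.pi * nu_0
    th = math.radians(params.theta)
    ph = math.radians(params.phi)
    weights = (
        (1.0 / 3.0 + math.sin(th) ** 2 * math.cos(ph) ** 2, w_m),
        (1.0 / 3.0 + math.sin(th) ** 2 * math.sin(ph) ** 2, w_p),
        (1.0 / 3.0 + math.cos(th) ** 2, w_0),
    )
    tq = params.tau_Q
    out = np.zeros_like(omega)
    for wgt, w_c in weights:
        out = out + wgt * (tq / (1.0 + (omega - w_c) ** 2 * tq**2)
                           + tq / (1.0 + (omega + w_c) ** 2 * tq**2))
    return params.C_DD_HN * out


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------

def d_from_tau(tau_trans: float, d: float) -> float:
    """Translational diffusion coefficient from the correlation time:
    ``D = d^2 / (2 tau_trans)`` (m^2/s)."""
    if tau_trans <= 0 or d <= 0:
        raise ValueError("tau_trans and d must be strictly positive")
    return d * d / (2.0 * tau_trans)


def tau_from_d(D_trans: float, d: float) -> float:
    """Translational correlation time from the diffusion coefficient:
    ``tau = d^2 / (2 D)`` (s); exact inverse of :func:`d_from_tau`."""
    if D_trans <= 0 or d <= 0:
        raise ValueError("D_trans and d must be strictly positive")
    return d * d / (2.0 * D_trans)


def cdd_hn_from_distance(r_HN: float,
                         constants: PhysicalConstants = CONSTANTS) -> float:
    """1H-14N dipolar relaxation constant from the inter-spin distance:
    ``C = (2/3) (mu0/(4 pi) gamma_H gamma_N hbar / r^3)^2`` (s^-2)."""
    if r_HN <= 0:
        raise ValueError("r_HN must be strictly positive")
    return (2.0 / 3.0) * (constants.mu0 / (4 * math.pi) * constants.gamma_H
                          * constants.gamma_N * constants.hbar / r_HN**3) ** 2
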