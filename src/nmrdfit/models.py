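"""Full R1(nu) relaxation models assembled from the spectral-density kernels.

A model family is one of:

``lorentzian_sum``
    Decomposition into 1-3 Lorentzian dipolar contributions (slow /
    intermediate / fast) plus a frequency-independent offset ``A``.
``ffhs_plus_lorentzian``
    3D translational diffusion (force-free hard sphere) plus Lorentzian
    term(s) plus ``A``.
``surface2d_long_res``
    2D surface diffusion in the long-residence limit plus Lorentzian
    term(s) plus ``A``.
``surface2d_res``
    2D surface diffusion truncated by a finite adsorption residence
    lifetime plus Lorentzian term(s) plus ``A``.
``lorentzian_sum_plus_qre``
    Lorentzian decomposition plus the 1H-14N quadrupole relaxation
    enhancement term.

Public interfaces take the Larmor frequency ``nu`` in Hz; the conversion
``omega = 2 pi nu`` happens here, once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import spectral
from .spectral import (
    FFHSParams,
    LorentzianComponent,
    QREParams,
    SurfaceDiffusionParams,
)

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "ModelParams",
    "ContributionCurve",
    "evaluate_model",
    "decompose",
    "dominant_range",
]

FAMILIES = (
    "lorentzian_sum",
    "ffhs_plus_lorentzian",
    "surface2d_long_res",
    "surface2d_res",
    "lorentzian_sum_plus_qre",
)

#: which parameter blocks are legal per family
_BLOCKS = {
    "lorentzian_sum": frozenset(),
    "ffhs_plus_lorentzian": frozenset({"ffhs"}),
    "surface2d_long_res": frozenset({"surface"}),
    "surface2d_res": frozenset({"surface"}),
    "lorentzian_sum_plus_qre": frozenset({"qre"}),
}


class ModelSpecificationError(ValueError):
    """Raised when parameters and model specification disagree."""


@dataclass(frozen=True)
class ModelSpec:
    """Which model family to evaluate and how many Lorentzian terms it has."""

    family: str
    n_lorentzians: int = 1
    include_offset: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ModelSpecificationError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.n_lorentzians not in (1, 2, 3):
            raise ModelSpecificationError("n_lorentzians must be 1, 2 or 3")


@dataclass(frozen=True)
class ModelParams:
    """Parameter blocks for one model evaluation.

    Only the blocks legal for the chosen family may be present; ``A`` is the
    frequency-independent offset accounting for motion fast enough that
    ``omega * tau << 1`` over the whole frequency window (e.g. bulk-like
    water).
    """

    lorentzians: tuple[LorentzianComponent, ...] = field(default_factory=tuple)
    ffhs: FFHSParams | None = None
    surface: SurfaceDiffusionParams | None = None
    qre: QREParams | None = None
    A: float = 0.0

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("offset A must be non-negative")
        object.__setattr__(self, "lorentzians", tuple(self.lorentzians))

    def validate_for(self, spec: ModelSpec) -> None:
        """Check that exactly the blocks the family requires are present."""
        present = {
            name for name in ("ffhs", "surface", "qre")
            if getattr(self, name) is not None
        }
        required = _BLOCKS[spec.family]
        if present != required:
            raise ModelSpecificationError(
                f"family {spec.family!r} requires blocks {sorted(required)}, "
                f"got {sorted(present)}"
            )
        if len(self.lorentzians) != spec.n_lorentzians:
            raise ModelSpecificationError(
                f"expected {spec.n_lorentzians} Lorentzian component(s), "
                f"got {len(self.lorentzians)}"
            )
        if spec.family == "surface2d_res" and math.isinf(self.surface.tau_res):
            raise ModelSpecificationError(
                "surface2d_res requires a finite residence lifetime; use "
                "surface2d_long_res for tau_res = inf"
            )
        if spec.family == "surface2d_long_res" and not math.isinf(
            self.surface.tau_res
        ):
            raise ModelSpecificationError(
                "surface2d_long_res requires tau_res = inf"
            )


@dataclass(frozen=True)
class ContributionCurve:
    """One labelled relaxation contribution on a frequency grid."""

    label: str
    nu: np.ndarray
    r1: np.ndarray

    def __post_init__(self) -> None:
        nu = np.asarray(self.nu, dtype=float)
        r1 = np.asarray(self.r1, dtype=float)
        if nu.shape != r1.shape:
            raise ValueError("nu and r1 must have the same length")
        if np.any(r1 < 0):
            raise ValueError("relaxation contributions must be non-negative")
        object.__setattr__(self, "nu", nu)
        object.__setattr__(self, "r1", r1)


def _lorentzian_labels(spec: ModelSpec) -> list[str]:
    """Labels for the Lorentzian components, longest correlation time first.

    The sum over Lorentzians is permutation-symmetric, so components are
    named by their rank in tau: slow / intermediate / fast for three terms,
    intermediate / fast for two (matching how a two-term decomposition lines
    up against a neighbouring three-term one), plain 'lorentzian' for one.
    """
    if spec.n_lorentzians == 1:
        return ["lorentzian"]
    names = ("slow", "intermediate", "fast")
    return list(names[3 - spec.n_lorentzians:])


def decompose(spec: ModelSpec, params: ModelParams, nu) -> list[ContributionCurve]:
    """Evaluate the model and return its labelled per-contribution curves.

    The element-wise sum of the returned curves is exactly (same floating
    point operations) the value of :func:`evaluate_model`.
    """
    params.validate_for(spec)
    nu = np.asarray(nu, dtype=float)
    if np.any(nu < 0):
        raise ValueError("frequencies must be non-negative")
    omega = 2.0 * math.pi * nu

    curves: list[ContributionCurve] = []
    labels = _lorentzian_labels(spec)
    order = sorted(
        range(len(params.lorentzians)),
        key=lambda i: -params.lorentzians[i].tau,
    )
    for label, i in zip(labels, order):
        comp = params.lorentzians[i]
        curves.append(ContributionCurve(
            label, nu, spectral.lorentzian_r1(comp.C, comp.tau, omega)))

    if params.ffhs is not None:
        curves.append(ContributionCurve(
            "translational_3d", nu,
            spectral.r1_translational_3d(params.ffhs, omega)))
    if params.surface is not None:
        s = params.surface
        r1_2d = s.C_trans * (
            spectral.j2d(omega, s.tau_trans, s.tau_res)
            + 4.0 * spectral.j2d(2.0 * omega, s.tau_trans, s.tau_res)
        )
        curves.append(ContributionCurve("translational_2d", nu, r1_2d))
    if params.qre is not None:
        curves.append(ContributionCurve(
            "qre_hn", nu, spectral.r1_qre_hn(params.qre, omega)))
    if spec.include_offset:
        curves.append(ContributionCurve(
            "offset", nu, np.full_like(nu, params.A)))
    return curves


def evaluate_model(spec: ModelSpec, params: ModelParams, nu) -> np.ndarray:
    """Total relaxation rate R1(nu) of the model, s^-1, on the given grid."""
    curves = decompose(spec, params, nu)
    total = np.zeros(np.asarray(nu, dtype=float).shape)
    for c in curves:
        total = total + c.r1
    return total


def dominant_range(curves: list[ContributionCurve]) -> dict[str, dict]:
    """Where each contribution is strictly the largest one.

    For every label, finds the maximal contiguous grid interval on which
    that contribution strictly exceeds all others (ties count as "none
    dominant") and reports the frequency bounds and the interval width in
    decades.  Labels that are nowhere dominant map to ``None``.
    """
    if not curves:
        raise ModelSpecificationError("need at least one contribution curve")
    nu = curves[0].nu
    for c in curves[1:]:
        if c.nu.shape != nu.shape or not np.array_equal(c.nu, nu):
            raise ModelSpecificationError(
                "all contribution curves must share one frequency grid")

    stack = np.vstack([c.r1 for c in curves])
    top = np.max(stack, axis=0)
    # strict winner per grid point, -1 on ties
    winner = np.full(nu.shape, -1, dtype=int)
    for i in range(stack.shape[0]):
        others = np.delete(stack, i, axis=0)
        strictly = stack[i] > (others.max(axis=0) if others.size else
                               np.full_like(top, -np.inf))
        winner[strictly] = i

    out: dict[str, dict] = {}
    for i, c in enumerate(curves):
        mask = winner == i
        if not mask.any():
            out[c.label] = None
            continue
        # maximal contiguous run of True
        best = (0, 0)
        run_start = None
        for j, m in enumerate(np.append(mask, False)):
            if m and run_start is None:
                run_start = j
            elif not m and run_start is not None:
                if j - run_start > best[1] - best[0]:
                    best = (run_start, j)
                run_start = None
        lo, hi = nu[best[0]], nu[best[1] - 1]
        width = math.log10(hi / lo) if lo > 0 else math.inf
        out[c.label] = {
            "nu_lo": float(lo),
            "nu_hi": float(hi),
            "decades": float(width),
            "n_points": int(best[1] - best[0]),
        }
    return out
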