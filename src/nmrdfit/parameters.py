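"""Parameter layout, bounds and transforms for the fitting engine.

Every model family maps to a flat, named parameter registry.  Scale
parameters (relaxation constants, correlation times, hydrogen density, the
offset) span many decades across the study conditions, so they are
optimized as log10 values inside box bounds; angles and the asymmetry
parameter stay linear.  The finite residence lifetime is parametrized as
the ratio ``tau_res / tau_trans`` (log10, lower bound > 1) so that every
optimizer iterate honours the ``tau_res > tau_trans`` invariant; the
reported parameter is ``tau_res`` itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import WATER_DIAMETER
from .models import ModelParams, ModelSpec
from .spectral import (
    FFHSParams,
    LorentzianComponent,
    QREParams,
    SurfaceDiffusionParams,
)

__all__ = ["ParamDef", "param_registry", "params_to_natural",
           "natural_to_params", "transform", "back_transform"]


@dataclass(frozen=True)
class ParamDef:
    """One fit parameter: name, optimization scale and box bounds
    (bounds in natural units)."""

    name: str
    scale: str  # "log" or "lin"
    lo: float
    hi: float
    unit: str = ""


_TAU = (1e-12, 1e-4)
_C = (1e4, 1e10)


def param_registry(spec: ModelSpec) -> list[ParamDef]:
    """Ordered parameter definitions for one model family."""
    defs: list[ParamDef] = []
    for k in range(1, spec.n_lorentzians + 1):
        defs.append(ParamDef(f"C{k}", "log", *_C, "s^-2"))
        defs.append(ParamDef(f"tau{k}", "log", *_TAU, "s"))
    if spec.family == "ffhs_plus_lorentzian":
        defs.append(ParamDef("N_H", "log", 1e24, 1e30, "m^-3"))
        defs.append(ParamDef("tau_trans", "log", *_TAU, "s"))
    elif spec.family == "surface2d_long_res":
        defs.append(ParamDef("C_trans", "log", *_C, "s^-2"))
        defs.append(ParamDef("tau_trans", "log", *_TAU, "s"))
    elif spec.family == "surface2d_res":
        defs.append(ParamDef("C_trans", "log", *_C, "s^-2"))
        defs.append(ParamDef("tau_trans", "log", *_TAU, "s"))
        defs.append(ParamDef("tau_res_ratio", "log", 1.05, 1e5, ""))
    elif spec.family == "lorentzian_sum_plus_qre":
        defs.append(ParamDef("C_DD_HN", "log", *_C, "s^-2"))
        defs.append(ParamDef("a_Q", "log", 1e5, 1e8, "Hz"))
        defs.append(ParamDef("eta", "lin", 0.0, 1.0, ""))
        defs.append(ParamDef("tau_Q", "log", *_TAU, "s"))
        defs.append(ParamDef("theta", "lin", 0.0, 90.0, "deg"))
        defs.append(ParamDef("phi", "lin", 0.0, 90.0, "deg"))
    if spec.include_offset:
        defs.append(ParamDef("A", "log", 1e-3, 1e3, "s^-1"))
    return defs


def params_to_natural(spec: ModelSpec, params: ModelParams) -> dict[str, float]:
    """Flatten a ModelParams into the named natural-unit dictionary."""
    params.validate_for(spec)
    vals: dict[str, float] = {}
    for k, comp in enumerate(params.lorentzians, start=1):
        vals[f"C{k}"] = comp.C
        vals[f"tau{k}"] = comp.tau
    if params.ffhs is not None:
        vals["N_H"] = params.ffhs.N_H
        vals["tau_trans"] = params.ffhs.tau_trans
    if params.surface is not None:
        vals["C_trans"] = params.surface.C_trans
        vals["tau_trans"] = params.surface.tau_trans
        if spec.family == "surface2d_res":
            vals["tau_res_ratio"] = (params.surface.tau_res
                                     / params.surface.tau_trans)
    if params.qre is not None:
        q = params.qre
        vals.update(C_DD_HN=q.C_DD_HN, a_Q=q.a_Q, eta=q.eta,
                    tau_Q=q.tau_Q, theta=q.theta, phi=q.phi)
    if spec.include_offset:
        vals["A"] = params.A
    return vals


def natural_to_params(spec: ModelSpec, vals: dict[str, float],
                      d: float = WATER_DIAMETER) -> ModelParams:
    """Rebuild a ModelParams from the named natural-unit dictionary."""
    lor = tuple(
        LorentzianComponent(vals[f"C{k}"], vals[f"tau{k}"])
        for k in range(1, spec.n_lorentzians + 1)
    )
    kwargs: dict = {"lorentzians": lor,
                    "A": vals.get("A", 0.0) if spec.include_offset else 0.0}
    if spec.family == "ffhs_plus_lorentzian":
        kwargs["ffhs"] = FFHSParams(vals["N_H"], d, vals["tau_trans"])
    elif spec.family == "surface2d_long_res":
        kwargs["surface"] = SurfaceDiffusionParams(
            vals["C_trans"], vals["tau_trans"], math.inf)
    elif spec.family == "surface2d_res":
        kwargs["surface"] = SurfaceDiffusionParams(
            vals["C_trans"], vals["tau_trans"],
            vals["tau_trans"] * vals["tau_res_ratio"])
    elif spec.family == "lorentzian_sum_plus_qre":
        kwargs["qre"] = QREParams(
            C_DD_HN=vals["C_DD_HN"], a_Q=vals["a_Q"], eta=vals["eta"],
            tau_Q=vals["tau_Q"], theta=vals["theta"], phi=vals["phi"])
    return ModelParams(**kwargs)


def transform(defs: list[ParamDef], vals: dict[str, float]) -> np.ndarray:
    """Natural values -> optimizer vector (log10 for log-scale params)."""
    out = np.empty(len(defs))
    for i, pd in enumerate(defs):
        v = vals[pd.name]
        out[i] = math.log10(v) if pd.scale == "log" else v
    return out


def back_transform(defs: list[ParamDef], x: np.ndarray) -> dict[str, float]:
    """Optimizer vector -> natural values."""
    return {
        pd.name: (10.0 ** x[i] if pd.scale == "log" else float(x[i]))
        for i, pd in enumerate(defs)
    }


def transformed_bounds(defs: list[ParamDef]) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([math.log10(pd.lo) if pd.scale == "log" else pd.lo
                   for pd in defs])
    hi = np.array([math.log10(pd.hi) if pd.scale == "log" else pd.hi
                   for pd in defs])
    return lo, hi
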