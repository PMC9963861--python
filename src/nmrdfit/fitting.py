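"""Weighted nonlinear least-squares estimation of relaxation-model parameters.

The module is organised around two model classes in the statsmodels style:

* :class:`ProfileFit` — one dispersion profile, one model family; ``fit()``
  runs a seeded multi-start bounded least-squares minimization and returns
  a :class:`FitResults` carrying estimates, curvature-based uncertainties,
  residual diagnostics and a ``summary()`` table.
* :class:`SeriesFit` — a multi-temperature series with a per-parameter
  sharing layout (shared across temperatures / free per temperature /
  fixed); ``fit()`` warm-starts from per-profile fits and refines a single
  joint objective, returning :class:`SeriesFitResults`.

Scale parameters are optimized in log10 space inside box bounds (they span
many decades) from a seeded Latin-hypercube of start points — the single
objective is multi-modal for the richer families.  Weights are
``1/sigma`` where per-point uncertainties are recorded and ``1/R1``
(relative weighting) otherwise.

Free functions cover the remaining analyses: model ranking by AICc with
the dominance-width diagnostic, Arrhenius analysis of correlation times,
profile ratios, and mono-exponential magnetization-decay fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import qmc

from . import models as _models
from .constants import GAS_CONSTANT, WATER_DIAMETER
from .models import ModelParams, ModelSpec, decompose, dominant_range, evaluate_model
from .parameters import (
    ParamDef,
    back_transform,
    natural_to_params,
    param_registry,
    params_to_natural,
    transform,
    transformed_bounds,
)
from .profiles import NMRDProfile

__all__ = [
    "ProfileFit",
    "SeriesFit",
    "FitResults",
    "SeriesFitResults",
    "ArrheniusResult",
    "RatioCurve",
    "DecayFitResult",
    "UnderdeterminedError",
    "fit_profile",
    "fit_series_global",
    "fit_qre_staged",
    "compare_models",
    "arrhenius_fit",
    "profile_ratio",
    "fit_monoexponential_decay",
]

DEFAULT_SEED = 1234
DEFAULT_N_STARTS = 16

#: off-peak region used by the staged quadrupole fit: outside this window
#: the 14N peaks contribute negligibly and the 1H-1H background dominates.
QRE_PEAK_WINDOW = (1.8e6, 4.2e6)


class UnderdeterminedError(ValueError):
    """Raised when a fit has fewer than twice as many points as free
    parameters."""


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

def _aicc(n: int, k: int, wss: float) -> float:
    if n - k - 1 <= 0 or wss <= 0:
        return math.inf
    return n * math.log(wss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _derive_extras(spec: ModelSpec, est: dict, cov: np.ndarray | None,
                   defs: list[ParamDef], free: list[str], d: float) -> tuple[dict, dict]:
    """Derived quantities (tau_res, D_trans) with delta-method errors."""
    extras: dict[str, float] = {}
    extras_err: dict[str, float] = {}
    if spec.family == "surface2d_res":
        tau_res = est["tau_trans"] * est["tau_res_ratio"]
        extras["tau_res"] = tau_res
        if cov is not None:
            # log10(tau_res) = log10(tau_trans) + log10(ratio)
            g = np.zeros(len(free))
            for nm in ("tau_trans", "tau_res_ratio"):
                if nm in free:
                    g[free.index(nm)] = 1.0
            var = float(g @ cov @ g)
            if var >= 0:
                extras_err["tau_res"] = tau_res * math.log(10) * math.sqrt(var)
    if spec.family in ("surface2d_res", "surface2d_long_res",
                       "ffhs_plus_lorentzian") and "tau_trans" in est:
        extras["D_trans"] = d * d / (2.0 * est["tau_trans"])
    return extras, extras_err


@dataclass
class FitResults:
    """Estimates and diagnostics of a single-profile fit.

    ``estimates``/``stderr`` are keyed by parameter name in natural units
    (derived quantities ``tau_res`` and ``D_trans`` included where they
    apply); ``residuals`` are weighted; ``wss`` is the weighted sum of
    squares, ``redchi`` the reduced chi-square and ``aicc`` the small-sample
    corrected Akaike criterion used for model ranking.
    """

    spec: ModelSpec
    profile: NMRDProfile
    params: ModelParams
    estimates: dict[str, float]
    stderr: dict[str, float]
    residuals: np.ndarray
    wss: float
    redchi: float
    aicc: float
    nfev: int
    optimality: float
    seed: int
    n_starts: int
    best_start: int
    fixed: dict[str, float]
    d: float = WATER_DIAMETER

    @property
    def n_free(self) -> int:
        return len([k for k in self.estimates
                    if k not in ("tau_res", "D_trans")])

    def model_curve(self, nu=None) -> np.ndarray:
        nu = self.profile.nu if nu is None else nu
        return evaluate_model(self.spec, self.params, nu)

    def decompose(self, nu=None):
        nu = self.profile.nu if nu is None else nu
        return decompose(self.spec, self.params, nu)

    def summary(self) -> str:
        lines = [
            f"Model family: {self.spec.family} "
            f"({self.spec.n_lorentzians} Lorentzian term(s))",
            f"Sample: {self.profile.sample}  T = {self.profile.temperature:g} K"
            f"  n = {len(self.profile)} points",
            f"Weighted SS = {self.wss:.6g}   reduced chi2 = {self.redchi:.6g}"
            f"   AICc = {self.aicc:.6g}",
            f"nfev = {self.nfev}   gradient optimality = {self.optimality:.3g}"
            f"   seed = {self.seed}, best start #{self.best_start}"
            f"/{self.n_starts}",
            "-" * 58,
            f"{'parameter':<14}{'estimate':>16}{'std. error':>16}",
            "-" * 58,
        ]
        for name, val in self.estimates.items():
            err = self.stderr.get(name)
            errs = f"{err:>16.4g}" if err is not None else f"{'--':>16}"
            lines.append(f"{name:<14}{val:>16.5g}{errs}")
        for name, val in self.fixed.items():
            lines.append(f"{name:<14}{val:>16.5g}{'(fixed)':>16}")
        lines.append("-" * 58)
        return "\n".join(lines)


@dataclass
class SeriesFitResults:
    """Estimates and diagnostics of a joint multi-temperature fit."""

    spec: ModelSpec
    profiles: list[NMRDProfile]
    layout: dict[str, object]
    shared_estimates: dict[str, float]
    shared_stderr: dict[str, float]
    per_temperature: list[dict[str, float]]
    per_temperature_stderr: list[dict[str, float]]
    params: list[ModelParams]
    residuals: np.ndarray
    wss: float
    redchi: float
    aicc: float
    nfev: int
    optimality: float
    seed: int
    fixed: dict[str, float]
    d: float = WATER_DIAMETER

    def summary(self) -> str:
        lines = [
            f"Joint fit, family {self.spec.family}, "
            f"{len(self.profiles)} temperatures, sample "
            f"{self.profiles[0].sample}",
            f"Weighted SS = {self.wss:.6g}   reduced chi2 = {self.redchi:.6g}"
            f"   AICc = {self.aicc:.6g}",
        ]
        if self.shared_estimates:
            lines.append("Shared constants:")
            for k, v in self.shared_estimates.items():
                err = self.shared_stderr.get(k)
                tail = f" +/- {err:.3g}" if err is not None else ""
                lines.append(f"  {k} = {v:.5g}{tail}")
        if self.fixed:
            lines.append("Fixed: " + ", ".join(
                f"{k}={v:.5g}" for k, v in self.fixed.items()))
        free_names = list(self.per_temperature[0]) if self.per_temperature else []
        header = f"{'T [K]':>8}" + "".join(f"{n:>14}" for n in free_names)
        lines += ["-" * len(header), header, "-" * len(header)]
        for prof, est in zip(self.profiles, self.per_temperature):
            row = f"{prof.temperature:>8g}" + "".join(
                f"{est[n]:>14.4g}" for n in free_names)
            lines.append(row)
        lines.append("-" * len(header))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# single-profile fitting
# ---------------------------------------------------------------------------

def _lhs_starts(lo: np.ndarray, hi: np.ndarray, n: int, seed: int,
                margin: float = 0.02) -> np.ndarray:
    """Seeded Latin-hypercube start points in the transformed box."""
    sampler = qmc.LatinHypercube(d=lo.size, seed=seed)
    u = sampler.random(n)
    span = hi - lo
    return lo + span * (margin + (1 - 2 * margin) * u)


class ProfileFit:
    """Weighted least-squares model for one NMRD profile.

    Parameters
    ----------
    profile : NMRDProfile
        The measured (or simulated) dispersion curve.
    spec : ModelSpec
        Which relaxation model family to fit.
    fixed : dict, optional
        Parameters held at given natural-unit values (not estimated).
    init : dict, optional
        Natural-unit starting values for free parameters; used as an extra
        start point alongside the Latin-hypercube draws.
    d : float
        Distance of closest approach (m), held fixed (default: water
        diameter 2.7 Angstrom).
    """

    def __init__(self, profile: NMRDProfile, spec: ModelSpec, *,
                 fixed: dict[str, float] | None = None,
                 init: dict[str, float] | None = None,
                 d: float = WATER_DIAMETER):
        self.profile = profile
        self.spec = spec
        self.d = d
        self.fixed = dict(fixed or {})
        self.init = dict(init or {})
        self.defs = param_registry(spec)
        names = [p.name for p in self.defs]
        for key in list(self.fixed) + list(self.init):
            if key not in names:
                raise KeyError(f"unknown parameter {key!r} for family "
                               f"{spec.family!r}")
        self.free_defs = [p for p in self.defs if p.name not in self.fixed]
        if not self.free_defs:
            raise ValueError("no free parameters to fit")
        n, k = len(profile), len(self.free_defs)
        if n < 2 * k:
            raise UnderdeterminedError(
                f"{n} data points cannot constrain {k} free parameters "
                f"(need at least {2 * k})")
        self._w = profile.weights

    # -- residuals ---------------------------------------------------------
    def _values_from_x(self, x: np.ndarray) -> dict[str, float]:
        vals = back_transform(self.free_defs, x)
        vals.update(self.fixed)
        return vals

    def _residual(self, x: np.ndarray) -> np.ndarray:
        params = natural_to_params(self.spec, self._values_from_x(x), self.d)
        model = evaluate_model(self.spec, params, self.profile.nu)
        return (model - self.profile.r1) * self._w

    # -- fitting -----------------------------------------------------------
    def fit(self, *, n_starts: int = DEFAULT_N_STARTS,
            seed: int = DEFAULT_SEED, max_nfev: int | None = None
            ) -> FitResults:
        """Run the multi-start bounded minimization; return the best fit."""
        lo, hi = transformed_bounds(self.free_defs)
        starts = [0.5 * (lo + hi)]
        if self.init:
            full = dict(self.init)
            for p in self.free_defs:
                full.setdefault(p.name, math.sqrt(p.lo * p.hi)
                                if p.scale == "log" else 0.5 * (p.lo + p.hi))
            x0 = np.clip(transform(self.free_defs, full), lo, hi)
            starts.insert(0, x0)
        if n_starts > 0:
            starts.extend(_lhs_starts(lo, hi, n_starts, seed))

        best = None
        best_idx = -1
        nfev_total = 0
        for i, x0 in enumerate(starts):
            try:
                sol = optimize.least_squares(
                    self._residual, x0, bounds=(lo, hi), method="trf",
                    x_scale="jac", max_nfev=max_nfev)
            except (ValueError, ArithmeticError):
                continue
            nfev_total += sol.nfev
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
                best_idx = i
        if best is None:
            raise RuntimeError(
                "no start point converged; widen bounds or supply init")
        return self._package(best, nfev_total, seed, len(starts), best_idx)

    # -- packaging ---------------------------------------------------------
    def _package(self, sol, nfev_total: int, seed: int, n_starts: int,
                 best_idx: int) -> FitResults:
        free = [p.name for p in self.free_defs]
        est = self._values_from_x(sol.x)
        params = natural_to_params(self.spec, est, self.d)
        n, k = len(self.profile), len(free)
        wss = float(2.0 * sol.cost)
        redchi = wss / (n - k) if n > k else math.inf

        cov = None
        stderr: dict[str, float] = {}
        try:
            J = sol.jac
            cov = np.linalg.pinv(J.T @ J) * redchi
            sig = np.sqrt(np.clip(np.diag(cov), 0, None))
            for i, p in enumerate(self.free_defs):
                v = est[p.name]
                stderr[p.name] = (v * math.log(10) * sig[i]
                                  if p.scale == "log" else float(sig[i]))
        except np.linalg.LinAlgError:
            cov = None

        estimates = {p.name: est[p.name] for p in self.free_defs}
        extras, extras_err = _derive_extras(
            self.spec, est, cov, self.free_defs, free, self.d)
        estimates.update(extras)
        stderr.update(extras_err)
        return FitResults(
            spec=self.spec, profile=self.profile, params=params,
            estimates=estimates, stderr=stderr, residuals=sol.fun,
            wss=wss, redchi=redchi, aicc=_aicc(n, k, wss),
            nfev=nfev_total, optimality=float(sol.optimality),
            seed=seed, n_starts=n_starts, best_start=best_idx,
            fixed=dict(self.fixed), d=self.d)


def fit_profile(profile: NMRDProfile, spec: ModelSpec, *,
                fixed: dict[str, float] | None = None,
                init: dict[str, float] | None = None,
                d: float = WATER_DIAMETER,
                n_starts: int = DEFAULT_N_STARTS,
                seed: int = DEFAULT_SEED,
                max_nfev: int | None = None) -> FitResults:
    """Fit one model family to one profile (multi-start engine)."""
    return ProfileFit(profile, spec, fixed=fixed, init=init, d=d).fit(
        n_starts=n_starts, seed=seed, max_nfev=max_nfev)


def _mask_profile(profile: NMRDProfile, mask: np.ndarray) -> NMRDProfile:
    return NMRDProfile(
        nu=profile.nu[mask], r1=profile.r1[mask],
        sigma=None if profile.sigma is None else profile.sigma[mask],
        temperature=profile.temperature, sample=profile.sample)


def fit_qre_staged(profile: NMRDProfile, spec: ModelSpec, *,
                   n_starts: int = DEFAULT_N_STARTS,
                   seed: int = DEFAULT_SEED) -> FitResults:
    """Staged quadrupole fit: 1H-1H background first on off-peak points,
    then the 14N quadrupole block with the background held fixed.

    Off-peak means outside the 1.8-4.2 MHz region where the quadrupole
    peaks sit.  Returns the stage-two results (full grid, quadrupole
    parameters free, background fixed at the stage-one estimates).
    """
    if spec.family != "lorentzian_sum_plus_qre":
        raise _models.ModelSpecificationError(
            "staged fitting applies to the lorentzian_sum_plus_qre family")
    lo, hi = QRE_PEAK_WINDOW
    off_peak = (profile.nu < lo) | (profile.nu > hi)
    bg_spec = ModelSpec("lorentzian_sum", spec.n_lorentzians,
                        spec.include_offset)
    bg = fit_profile(_mask_profile(profile, off_peak), bg_spec,
                     n_starts=n_starts, seed=seed)
    fixed = dict(bg.estimates)
    return fit_profile(profile, spec, fixed=fixed,
                       n_starts=n_starts, seed=seed)


def bootstrap_uncertainties(results: FitResults, n_boot: int = 50,
                            seed: int = 0,
                            n_starts: int = 0) -> dict[str, float]:
    """Seeded parametric bootstrap of a single-profile fit.

    Resamples the data as model + noise (scale from the recorded sigma, or
    relative to the fitted curve under the default weighting), refits each
    replicate starting from the original optimum, and returns the standard
    deviation of each estimate.  Complements the default curvature-based
    errors on strongly non-quadratic ridges.
    """
    prof = results.profile
    model = results.model_curve()
    scale = prof.sigma if prof.sigma is not None \
        else model * float(np.median(np.abs(results.residuals)))
    rng = np.random.default_rng(seed)
    init = {k: v for k, v in results.estimates.items()
            if k not in ("tau_res", "D_trans")}
    draws: dict[str, list[float]] = {k: [] for k in results.estimates}
    for _ in range(n_boot):
        r1_star = np.clip(model + scale * rng.standard_normal(model.shape),
                          1e-12, None)
        star = NMRDProfile(nu=prof.nu, r1=r1_star, sigma=prof.sigma,
                           temperature=prof.temperature, sample=prof.sample)
        try:
            res = ProfileFit(star, results.spec, fixed=results.fixed,
                             init=init, d=results.d).fit(
                n_starts=n_starts, seed=seed)
        except RuntimeError:
            continue
        for k in draws:
            draws[k].append(res.estimates[k])
    return {k: float(np.std(v, ddof=1)) for k, v in draws.items()
            if len(v) > 1}


# ---------------------------------------------------------------------------
# global (multi-temperature) fitting
# ---------------------------------------------------------------------------

class SeriesFit:
    """Joint weighted least squares across a temperature series.

    ``layout`` assigns each parameter name one of ``"shared"`` (one value
    across all temperatures), ``"free"`` (one value per temperature) or
    ``("fixed", value)``.  Unlisted parameters default to ``"free"``.
    This mirrors how the published tables report one amplitude constant per
    concentration but per-temperature correlation times and offsets.
    """

    def __init__(self, profiles: list[NMRDProfile], spec: ModelSpec,
                 layout: dict[str, object] | None = None, *,
                 d: float = WATER_DIAMETER):
        if len(profiles) < 2:
            raise ValueError("a series fit needs at least two profiles")
        labels = {p.sample for p in profiles}
        if len(labels) != 1:
            raise ValueError(
                f"profiles must share one sample label, got {sorted(labels)}")
        self.profiles = list(profiles)
        self.spec = spec
        self.d = d
        self.defs = param_registry(spec)
        names = [p.name for p in self.defs]
        layout = dict(layout or {})
        for key in layout:
            if key not in names:
                raise KeyError(f"unknown parameter {key!r} in layout")
        self.layout = {n: layout.get(n, "free") for n in names}
        self.fixed = {n: v[1] for n, v in self.layout.items()
                      if isinstance(v, tuple) and v[0] == "fixed"}
        self.shared_defs = [p for p in self.defs
                            if self.layout[p.name] == "shared"]
        self.free_defs = [p for p in self.defs
                          if self.layout[p.name] == "free"]
        for n, v in self.layout.items():
            if n not in self.fixed and v not in ("shared", "free"):
                raise ValueError(f"layout entry for {n!r} must be 'shared', "
                                 f"'free' or ('fixed', value)")
        k = len(self.shared_defs) + len(self.free_defs) * len(profiles)
        n_pts = sum(len(p) for p in profiles)
        if n_pts < 2 * k:
            raise UnderdeterminedError(
                f"{n_pts} points cannot constrain {k} parameters")
        self._k = k
        self._npts = n_pts

    def _split(self, x: np.ndarray):
        ns = len(self.shared_defs)
        nf = len(self.free_defs)
        shared = back_transform(self.shared_defs, x[:ns])
        per = [back_transform(self.free_defs, x[ns + i * nf: ns + (i + 1) * nf])
               for i in range(len(self.profiles))]
        return shared, per

    def _residual(self, x: np.ndarray) -> np.ndarray:
        shared, per = self._split(x)
        out = []
        for prof, vals in zip(self.profiles, per):
            full = {**vals, **shared, **self.fixed}
            params = natural_to_params(self.spec, full, self.d)
            model = evaluate_model(self.spec, params, prof.nu)
            out.append((model - prof.r1) * prof.weights)
        return np.concatenate(out)

    def fit(self, *, n_starts: int = DEFAULT_N_STARTS,
            seed: int = DEFAULT_SEED,
            n_joint_starts: int = 4) -> SeriesFitResults:
        """Warm-start from independent per-profile fits, then refine the
        joint objective from several assembled start points.

        The richer families have swapped-component local minima, and a
        single profile stuck in the wrong mode can poison a joint start
        assembled naively.  Each single-profile result therefore acts in
        turn as a *donor* of the shared constants: the other profiles are
        re-fitted with those constants held fixed (which pulls them into
        the donor's mode), the aligned assembly is refined jointly, and
        the best-cost refinement wins.  An across-profile log-mean
        assembly is included as well; ``n_joint_starts`` caps the number
        of donors tried.
        """
        ss = np.random.SeedSequence(seed)
        child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                       for s in ss.spawn(len(self.profiles) + 1)]
        cond_seed = child_seeds[-1]
        singles = [
            ProfileFit(prof, self.spec, fixed=self.fixed, d=self.d).fit(
                n_starts=n_starts, seed=cs)
            for prof, cs in zip(self.profiles, child_seeds[:-1])
        ]
        free_of = [{p.name: s.estimates[p.name] for p in self.free_defs}
                   for s in singles]

        def _assemble(shared_vals: dict[str, float],
                      free_vals: list[dict[str, float]]) -> np.ndarray:
            x = (list(transform(self.shared_defs, shared_vals))
                 if self.shared_defs else [])
            for fv in free_vals:
                x.extend(transform(self.free_defs, fv))
            return np.asarray(x)

        starts = []
        if self.shared_defs:
            mean_shared = {}
            for p in self.shared_defs:
                vals = np.array([s.estimates[p.name] for s in singles])
                mean_shared[p.name] = (10 ** float(np.mean(np.log10(vals)))
                                       if p.scale == "log"
                                       else float(np.mean(vals)))
            starts.append(_assemble(mean_shared, free_of))
            n_cond = max(1, n_starts // 4)
            donors = singles if n_joint_starts <= 0 \
                else singles[:n_joint_starts]
            for donor in donors:
                shared_vals = {p.name: donor.estimates[p.name]
                               for p in self.shared_defs}
                if not self.free_defs:
                    starts.append(_assemble(shared_vals, []))
                    continue
                fixed_cond = {**self.fixed, **shared_vals}
                aligned = []
                for j, prof in enumerate(self.profiles):
                    cond = ProfileFit(
                        prof, self.spec, fixed=fixed_cond, d=self.d,
                    ).fit(n_starts=n_cond, seed=cond_seed + j)
                    aligned.append({p.name: cond.estimates[p.name]
                                    for p in self.free_defs})
                starts.append(_assemble(shared_vals, aligned))
        else:
            starts.append(_assemble({}, free_of))

        lo_s, hi_s = transformed_bounds(self.shared_defs)
        lo_f, hi_f = transformed_bounds(self.free_defs)
        lo = np.concatenate([lo_s] + [lo_f] * len(self.profiles))
        hi = np.concatenate([hi_s] + [hi_f] * len(self.profiles))

        best = None
        nfev = sum(s.nfev for s in singles)
        for x0 in starts:
            try:
                sol = optimize.least_squares(
                    self._residual, np.clip(x0, lo, hi), bounds=(lo, hi),
                    method="trf", x_scale="jac")
            except (ValueError, ArithmeticError):
                continue
            nfev += sol.nfev
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise RuntimeError("joint refinement did not converge")
        return self._package(best, nfev, seed)

    def _package(self, sol, nfev: int, seed: int) -> SeriesFitResults:
        shared, per = self._split(sol.x)
        n, k = self._npts, self._k
        wss = float(2.0 * sol.cost)
        redchi = wss / (n - k) if n > k else math.inf

        sig = None
        try:
            cov = np.linalg.pinv(sol.jac.T @ sol.jac) * redchi
            sig = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            cov = None

        def _err(defs, offset, vals):
            out = {}
            if sig is None:
                return out
            for i, p in enumerate(defs):
                v = vals[p.name]
                s = sig[offset + i]
                out[p.name] = (v * math.log(10) * s if p.scale == "log"
                               else float(s))
            return out

        ns, nf = len(self.shared_defs), len(self.free_defs)
        shared_err = _err(self.shared_defs, 0, shared)
        per_err = [_err(self.free_defs, ns + i * nf, vals)
                   for i, vals in enumerate(per)]

        params_list = []
        per_out = []
        for vals in per:
            full = {**vals, **shared, **self.fixed}
            params_list.append(natural_to_params(self.spec, full, self.d))
            est = dict(vals)
            if self.spec.family == "surface2d_res" and {
                    "tau_trans", "tau_res_ratio"} <= set(full):
                est["tau_res"] = full["tau_trans"] * full["tau_res_ratio"]
            per_out.append(est)
        return SeriesFitResults(
            spec=self.spec, profiles=self.profiles, layout=dict(self.layout),
            shared_estimates=shared, shared_stderr=shared_err,
            per_temperature=per_out, per_temperature_stderr=per_err,
            params=params_list, residuals=sol.fun, wss=wss, redchi=redchi,
            aicc=_aicc(n, k, wss), nfev=nfev,
            optimality=float(sol.optimality), seed=seed,
            fixed=dict(self.fixed), d=self.d)


def fit_series_global(profiles: list[NMRDProfile], spec: ModelSpec,
                      layout: dict[str, object] | None = None, *,
                      d: float = WATER_DIAMETER,
                      n_starts: int = DEFAULT_N_STARTS,
                      seed: int = DEFAULT_SEED) -> SeriesFitResults:
    """Joint fit over a temperature series with a sharing layout."""
    return SeriesFit(profiles, spec, layout, d=d).fit(
        n_starts=n_starts, seed=seed)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def compare_models(results: list[FitResults]):
    """Rank candidate fits of the *same* profile by AICc.

    Alongside the information criterion, reports each model's reduced
    chi-square and the width (decades) of the frequency interval over which
    its non-Lorentzian contribution dominates the total rate — a
    model-discrimination diagnostic: a mechanism is only identifiable when
    its contribution dominates over a broad frequency range.  Ties keep the
    input order (stable sort).
    """
    import pandas as pd

    if not results:
        raise ValueError("need at least one fit result")
    ref = results[0].profile
    for r in results[1:]:
        if (not np.array_equal(r.profile.nu, ref.nu)
                or not np.array_equal(r.profile.r1, ref.r1)):
            raise ValueError("all results must be fits of the same profile")

    rows = []
    for i, r in enumerate(results):
        dom = dominant_range(r.decompose())
        width = max(
            (d["decades"] for label, d in dom.items()
             if d is not None and label in ("translational_2d",
                                            "translational_3d", "qre_hn")),
            default=0.0)
        rows.append({
            "index": i,
            "family": r.spec.family,
            "n_free": r.n_free,
            "wss": r.wss,
            "redchi": r.redchi,
            "aicc": r.aicc,
            "dominance_decades": width,
        })
    df = pd.DataFrame(rows)
    order = np.argsort(df["aicc"].to_numpy(), kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    df["delta_aicc"] = df["aicc"] - df["aicc"].iloc[0]
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# Arrhenius analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArrheniusResult:
    """Arrhenius parameters of a correlation time: tau(T) = tau0 exp(Ea/RT)."""

    E_a: float        # activation energy, J/mol
    tau0: float       # pre-exponential time, s
    r_squared: float  # goodness of the ln tau vs 1/T regression

    def tau(self, T) -> np.ndarray:
        return self.tau0 * np.exp(self.E_a / (GAS_CONSTANT
                                              * np.asarray(T, dtype=float)))


def arrhenius_fit(taus: list[tuple[float, float]]) -> ArrheniusResult:
    """Least squares of ln(tau) on 1/T; slope x R gives the activation
    energy.  Needs at least two distinct temperatures and positive taus."""
    T = np.array([t for t, _ in taus], dtype=float)
    tau = np.array([x for _, x in taus], dtype=float)
    if np.unique(T).size < 2:
        raise ValueError("need at least two distinct temperatures")
    if np.any(tau <= 0) or np.any(T <= 0):
        raise ValueError("temperatures and correlation times must be positive")
    x = 1.0 / T
    y = np.log(tau)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ArrheniusResult(E_a=float(slope * GAS_CONSTANT),
                           tau0=float(math.exp(intercept)), r_squared=r2)


# ---------------------------------------------------------------------------
# profile ratio
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatioCurve:
    """Pointwise ratio of two profiles on the overlap of their grids."""

    nu: np.ndarray
    ratio: np.ndarray
    scale: float


def profile_ratio(p1: NMRDProfile, p2: NMRDProfile,
                  scale: float = 1.0) -> RatioCurve:
    """scale * R1^(1)/R1^(2) with p2 log-log interpolated onto p1's grid
    over the overlapping frequency range."""
    lo = max(p1.nu[0], p2.nu[0])
    hi = min(p1.nu[-1], p2.nu[-1])
    if lo >= hi:
        raise ValueError("profiles have disjoint frequency ranges")
    mask = (p1.nu >= lo) & (p1.nu <= hi)
    nu = p1.nu[mask]
    r2 = np.exp(np.interp(np.log(nu), np.log(p2.nu), np.log(p2.r1)))
    return RatioCurve(nu=nu, ratio=scale * p1.r1[mask] / r2, scale=scale)


# ---------------------------------------------------------------------------
# mono-exponential decay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecayFitResult:
    """Single-exponential magnetization fit M(t) = Minf + (M0-Minf) e^{-R1 t}."""

    R1: float
    R1_stderr: float
    M0: float
    M_inf: float
    flagged: bool  # True when the data are flat within noise


def fit_monoexponential_decay(times, magnetizations) -> DecayFitResult:
    """Least-squares fit of a single-exponential recovery/decay.

    Works for either recovery direction (the amplitude may carry either
    sign).  Data that do not decay within noise yield a flagged estimate.
    """
    t = np.asarray(times, dtype=float)
    m = np.asarray(magnetizations, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    minf0 = float(m[-1])
    amp0 = float(m[0] - minf0)
    scatter = float(np.std(np.diff(m))) / math.sqrt(2) if m.size > 1 else 0.0
    if abs(amp0) <= 3 * scatter or amp0 == 0.0:
        # flat within noise: no decay to fit
        return DecayFitResult(R1=0.0, R1_stderr=math.inf, M0=float(m[0]),
                              M_inf=minf0, flagged=True)

    # initial rate from the log-linear regime of |M - Minf|
    dev = (m - minf0) / amp0
    sel = dev > 0.05
    if sel.sum() >= 2:
        slope = np.polyfit(t[sel], np.log(dev[sel]), 1)[0]
        r1_0 = max(-slope, 1e-3 / (t[-1] - t[0]))
    else:
        r1_0 = 1.0 / max(t[t.size // 2], t[1])

    def f(tt, minf, amp, r1):
        return minf + amp * np.exp(-r1 * tt)

    popt, pcov = optimize.curve_fit(
        f, t, m, p0=[minf0, amp0, r1_0],
        bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
        maxfev=10000)
    perr = np.sqrt(np.diag(pcov))
    resid = m - f(t, *popt)
    flagged = abs(popt[1]) < 3 * float(np.std(resid))
    return DecayFitResult(
        R1=float(popt[2]), R1_stderr=float(perr[2]),
        M0=float(popt[0] + popt[1]), M_inf=float(popt[0]), flagged=flagged)
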