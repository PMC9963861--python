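"""File formats: the profile CSV dialect and the JSON fit report.

Profiles travel as UTF-8 CSV with a mandatory header and columns
``frequency_hz, r1_per_s, sigma_per_s (optional), temperature_k, sample``;
one profile per ``(sample, temperature_k)`` group, rows sorted by
frequency within a group.  All numbers are SI (frequencies in Hz — MHz
rendering is display-only).

Fit reports are JSON documents holding the model specification, sharing
layout, estimates with uncertainties and units, the goodness-of-fit block,
the fitted curve, software version, seed and an input digest.  Reloading a
report and re-evaluating the model reproduces the stored curve.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fitting import FitResults, SeriesFitResults
from .models import ModelParams, ModelSpec, evaluate_model
from .parameters import natural_to_params, params_to_natural
from .profiles import NMRDProfile

__all__ = [
    "read_profiles",
    "write_profiles",
    "ProfileCSVError",
    "report_from_results",
    "save_report",
    "load_report",
    "params_from_report",
    "report_table",
]

_REQUIRED = ["frequency_hz", "r1_per_s", "temperature_k", "sample"]
_OPTIONAL = ["sigma_per_s"]


class ProfileCSVError(ValueError):
    """Malformed profile CSV; the message names the offending row."""


def read_profiles(path) -> list[NMRDProfile]:
    """Read and validate a profile CSV; one NMRDProfile per
    (sample, temperature) group, ordered by sample then temperature."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"sample": str})
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ProfileCSVError(f"missing required column(s): {missing}")
    numeric_cols = _REQUIRED[:-1] + (
        ["sigma_per_s"] if "sigma_per_s" in df.columns else [])
    for col in numeric_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        nan_rows = np.flatnonzero(numeric.isna().to_numpy())
        if nan_rows.size and col != "sigma_per_s":
            # +2: header line and 1-based numbering
            raise ProfileCSVError(
                f"non-numeric or empty value in column {col!r} at row "
                f"{int(nan_rows[0]) + 2}")
        df[col] = numeric

    profiles = []
    for (sample, temp), grp in df.groupby(["sample", "temperature_k"],
                                          sort=True):
        grp_sorted = grp  # rows must already be sorted within the group
        freq = grp_sorted["frequency_hz"].to_numpy()
        diffs = np.diff(freq)
        if np.any(diffs <= 0):
            j = int(np.flatnonzero(diffs <= 0)[0])
            row = int(grp_sorted.index[j + 1]) + 2
            kind = "duplicate" if diffs[j] == 0 else "unsorted"
            raise ProfileCSVError(
                f"{kind} frequency within group ({sample!r}, {temp:g} K) "
                f"at row {row}")
        sigma = (grp_sorted["sigma_per_s"].to_numpy()
                 if "sigma_per_s" in grp_sorted.columns
                 and grp_sorted["sigma_per_s"].notna().all() else None)
        try:
            profiles.append(NMRDProfile(
                nu=freq, r1=grp_sorted["r1_per_s"].to_numpy(),
                sigma=sigma, temperature=float(temp), sample=str(sample)))
        except ValueError as exc:
            raise ProfileCSVError(
                f"invalid group ({sample!r}, {temp:g} K): {exc}") from exc
    return profiles


def write_profiles(profiles: list[NMRDProfile], path) -> None:
    """Write profiles to the CSV dialect (lossless round trip with
    :func:`read_profiles`)."""
    frames = []
    any_sigma = any(p.sigma is not None for p in profiles)
    for p in profiles:
        data = {
            "frequency_hz": p.nu,
            "r1_per_s": p.r1,
            "temperature_k": np.full(len(p), p.temperature),
            "sample": [p.sample] * len(p),
        }
        if any_sigma:
            data["sigma_per_s"] = (p.sigma if p.sigma is not None
                                   else np.full(len(p), np.nan))
        frames.append(pd.DataFrame(data))
    cols = ["frequency_hz", "r1_per_s"]
    if any_sigma:
        cols.append("sigma_per_s")
    cols += ["temperature_k", "sample"]
    pd.concat(frames)[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fit reports
# ---------------------------------------------------------------------------

def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True).encode()).hexdigest()


def _spec_dict(spec: ModelSpec) -> dict:
    return {"family": spec.family, "n_lorentzians": spec.n_lorentzians,
            "include_offset": spec.include_offset}


def spec_from_dict(d: dict) -> ModelSpec:
    return ModelSpec(d["family"], d.get("n_lorentzians", 1),
                     d.get("include_offset", True))


def report_from_results(results: FitResults | SeriesFitResults) -> dict:
    """Serialize fit results to the JSON report structure."""
    if isinstance(results, FitResults):
        profiles = [results.profile]
        blocks = [{
            "temperature_k": results.profile.temperature,
            "estimates": results.estimates,
            "stderr": results.stderr,
            "params": params_to_natural(results.spec, results.params),
        }]
        layout = None
        shared = {}
        shared_err = {}
    else:
        profiles = results.profiles
        blocks = [{
            "temperature_k": prof.temperature,
            "estimates": est,
            "stderr": err,
            "params": params_to_natural(results.spec, par),
        } for prof, est, err, par in zip(
            results.profiles, results.per_temperature,
            results.per_temperature_stderr, results.params)]
        layout = {k: (list(v) if isinstance(v, tuple) else v)
                  for k, v in results.layout.items()}
        shared = results.shared_estimates
        shared_err = results.shared_stderr

    input_digest = _digest([
        {"nu": p.nu.tolist(), "r1": p.r1.tolist(),
         "temperature": p.temperature, "sample": p.sample}
        for p in profiles])
    fitted = [{
        "temperature_k": prof.temperature,
        "nu_hz": prof.nu.tolist(),
        "r1_fit_per_s": evaluate_model(
            results.spec,
            natural_to_params(results.spec, blk["params"], results.d),
            prof.nu).tolist(),
    } for prof, blk in zip(profiles, blocks)]

    return {
        "software": {"name": "nmrdfit", "version": __version__},
        "spec": _spec_dict(results.spec),
        "d_m": results.d,
        "layout": layout,
        "seed": results.seed,
        "sample": profiles[0].sample,
        "shared_estimates": shared,
        "shared_stderr": shared_err,
        "per_temperature": blocks,
        "goodness_of_fit": {
            "wss": results.wss,
            "redchi": results.redchi,
            "aicc": None if math.isinf(results.aicc) else results.aicc,
            "nfev": results.nfev,
            "optimality": results.optimality,
        },
        "input_digest": input_digest,
        "fitted_curves": fitted,
    }


def save_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True),
                          encoding="utf-8")


def load_report(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def params_from_report(report: dict, index: int = 0
                       ) -> tuple[ModelSpec, ModelParams]:
    """Model spec and parameters of one temperature block of a report."""
    spec = spec_from_dict(report["spec"])
    vals = report["per_temperature"][index]["params"]
    return spec, natural_to_params(spec, vals, report.get("d_m", 2.7e-10))


def report_table(report: dict) -> str:
    """Human-readable rendering of a report: shared constants on top, one
    row per temperature (mirrors how multi-temperature results tables are
    usually printed)."""
    lines = [f"nmrdfit {report['software']['version']} — "
             f"family {report['spec']['family']}, sample {report['sample']}"]
    if report["shared_estimates"]:
        for k, v in report["shared_estimates"].items():
            err = report["shared_stderr"].get(k)
            tail = f" +/- {err:.3g}" if err is not None else ""
            lines.append(f"  shared {k} = {v:.5g}{tail}")
    names = sorted({k for blk in report["per_temperature"]
                    for k in blk["estimates"]})
    header = f"{'T [K]':>8}" + "".join(f"{n:>14}" for n in names)
    lines += [header, "-" * len(header)]
    for blk in report["per_temperature"]:
        lines.append(f"{blk['temperature_k']:>8g}" + "".join(
            f"{blk['estimates'].get(n, float('nan')):>14.4g}" for n in names))
    gof = report["goodness_of_fit"]
    lines.append(f"redchi = {gof['redchi']:.4g}   wss = {gof['wss']:.4g}")
    return "\n".join(lines)
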