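"""Named parameter presets for the BSA-water study conditions.

The fitted parameter sets published for 20%wt and 40%wt BSA-water mixtures
(four model families at 266-298 K, plus the 263 K quadrupole-enhanced fit)
are transcribed verbatim in ``data/table_presets.json`` and exposed here as
``(ModelSpec, ModelParams)`` pairs under keys such as ``table4_20wt_268K``.

The transcription for the 3D-diffusion family stores the printed
``(tau_trans, D_trans)`` pairs even though they satisfy ``D = d^2/tau``
rather than the caption relation ``D = d^2/(2 tau)``; the flag
``tau_d_consistent`` records this, and all conversions in this package use
``D = d^2/(2 tau)``.
"""

from __future__ import annotations

import json
from importlib import resources

from .models import ModelParams, ModelSpec
from .spectral import (
    FFHSParams,
    LorentzianComponent,
    QREParams,
    SurfaceDiffusionParams,
)

__all__ = [
    "load_transcription",
    "list_presets",
    "list_series",
    "get_preset",
    "get_series",
    "PresetNotFoundError",
]

_FAMILY_TO_TABLE = {
    "table1": "lorentzian_sum",
    "table2": "ffhs_plus_lorentzian",
    "table3": "surface2d_long_res",
    "table4": "surface2d_res",
    "qre": "lorentzian_sum_plus_qre",
}


class PresetNotFoundError(KeyError):
    """Raised when a preset key does not resolve to a table row."""


def load_transcription() -> dict:
    """Load the frozen transcription of the published parameter tables."""
    with resources.files("nmrdfit.data").joinpath(
        "table_presets.json"
    ).open("r", encoding="utf-8") as fh:
        return json.load(fh)


_CACHE: dict | None = None


def _tables() -> dict:
    global _CACHE
    if _CACHE is None:
        _CACHE = load_transcription()
    return _CACHE


def _build(family: str, sample: str, temp: str):
    data = _tables()
    block = data[family][sample]
    row = block["rows"][temp]
    d = data["d"]

    if family == "lorentzian_sum":
        if sample == "20wt":
            lor = (
                LorentzianComponent(block["C_i"], row["tau_i"]),
                LorentzianComponent(block["C_f"], row["tau_f"]),
            )
        else:
            lor = (
                LorentzianComponent(block["C_s"], row["tau_s"]),
                LorentzianComponent(block["C_i"], row["tau_i"]),
                LorentzianComponent(block["C_f"], row["tau_f"]),
            )
        spec = ModelSpec("lorentzian_sum", n_lorentzians=len(lor))
        params = ModelParams(lorentzians=lor, A=row["A"])
    elif family == "ffhs_plus_lorentzian":
        spec = ModelSpec("ffhs_plus_lorentzian", n_lorentzians=1)
        params = ModelParams(
            lorentzians=(LorentzianComponent(block["C_DD"], row["tau_c"]),),
            ffhs=FFHSParams(N_H=block["N_H"], d=d, tau_trans=row["tau_trans"]),
            A=row["A"],
        )
    elif family in ("surface2d_long_res", "surface2d_res"):
        tau_res = row.get("tau_res", float("inf"))
        spec = ModelSpec(family, n_lorentzians=1)
        params = ModelParams(
            lorentzians=(LorentzianComponent(block["C_DD"], row["tau_c"]),),
            surface=SurfaceDiffusionParams(
                C_trans=block["C_trans"],
                tau_trans=row["tau_trans"],
                tau_res=tau_res,
            ),
            A=row["A"],
        )
    elif family == "lorentzian_sum_plus_qre":
        lor = (
            LorentzianComponent(row["C_s"], row["tau_s"]),
            LorentzianComponent(row["C_i"], row["tau_i"]),
            LorentzianComponent(row["C_f"], row["tau_f"]),
        )
        spec = ModelSpec("lorentzian_sum_plus_qre", n_lorentzians=3)
        params = ModelParams(
            lorentzians=lor,
            qre=QREParams(
                C_DD_HN=row["C_DD_HN"], a_Q=row["a_Q"], eta=row["eta"],
                tau_Q=row["tau_Q"], theta=row["theta"], phi=row["phi"],
            ),
            A=row["A"],
        )
    else:  # pragma: no cover - guarded by _FAMILY_TO_TABLE
        raise PresetNotFoundError(family)
    return spec, params


def _parse_key(key: str) -> tuple[str, str, str]:
    parts = key.split("_")
    if len(parts) != 3 or parts[0] not in _FAMILY_TO_TABLE:
        raise PresetNotFoundError(
            f"unknown preset {key!r}; expected e.g. 'table4_20wt_268K'"
        )
    family = _FAMILY_TO_TABLE[parts[0]]
    sample, temp = parts[1], parts[2]
    if not temp.endswith("K"):
        raise PresetNotFoundError(f"temperature field of {key!r} must end in 'K'")
    return family, sample, temp[:-1]


def get_preset(key: str):
    """Resolve a preset key to ``(spec, params, temperature_K, sample)``.

    Keys follow ``<table1|table2|table3|table4|qre>_<20wt|40wt>_<T>K``.
    """
    family, sample, temp = _parse_key(key)
    try:
        spec, params = _build(family, sample, temp)
    except KeyError as exc:
        raise PresetNotFoundError(f"no table row for preset {key!r}") from exc
    return spec, params, float(temp), f"BSA_{sample}"


def list_presets() -> list[str]:
    """All available preset keys, sorted."""
    data = _tables()
    inv = {v: k for k, v in _FAMILY_TO_TABLE.items()}
    keys = []
    for family, short in ((f, inv[f]) for f in inv):
        for sample, block in data[family].items():
            if sample in ("tau_d_consistent",):
                continue
            for temp in block["rows"]:
                keys.append(f"{short}_{sample}_{temp}K")
    return sorted(keys)


def list_series() -> list[str]:
    """Series keys (one per table x sample), e.g. ``table4_20wt``."""
    return sorted({k.rsplit("_", 1)[0] for k in list_presets()})


def get_series(series_key: str) -> list[str]:
    """Preset keys of one temperature series, ordered by temperature."""
    keys = [k for k in list_presets() if k.rsplit("_", 1)[0] == series_key]
    if not keys:
        raise PresetNotFoundError(f"unknown series {series_key!r}")
    return sorted(keys, key=lambda k: float(k.rsplit("_", 1)[1][:-1]))
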