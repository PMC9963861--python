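"""Optional decomposition figures (matplotlib required only here)."""

from __future__ import annotations

import numpy as np

from .models import ModelParams, ModelSpec, decompose


def plot_decomposition(spec: ModelSpec, params: ModelParams, nu,
                       profile=None, ax=None):
    """Log-log plot of the total R1(nu) and its labelled contributions.

    Returns the matplotlib axes.  ``profile``, when given, is drawn as
    points over the model curves.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    nu = np.asarray(nu, dtype=float)
    curves = decompose(spec, params, nu)
    total = sum(c.r1 for c in curves)
    if profile is not None:
        ax.plot(profile.nu * 1e-6, profile.r1, "o", ms=4, color="0.4",
                label="data")
    ax.plot(nu * 1e-6, total, "k-", lw=1.6, label="total")
    for c in curves:
        ax.plot(nu * 1e-6, c.r1, "--", lw=1.0, label=c.label)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"$^1$H frequency $\nu$ [MHz]")
    ax.set_ylabel(r"$R_1$ [s$^{-1}$]")
    ax.legend(fontsize=8)
    return ax
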