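"""The NMRD profile container: one temperature's R1(nu) dispersion curve."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class NMRDProfile:
    """One relaxation-dispersion profile.

    Frequencies ``nu`` (Hz, strictly increasing), rates ``r1`` (s^-1),
    optional per-point uncertainties ``sigma`` (s^-1), the sample
    temperature (K) and a sample label (e.g. the protein mass fraction).
    """

    nu: np.ndarray
    r1: np.ndarray
    temperature: float
    sample: str = ""
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        nu = np.asarray(self.nu, dtype=float)
        r1 = np.asarray(self.r1, dtype=float)
        if nu.ndim != 1 or nu.shape != r1.shape:
            raise ValueError("nu and r1 must be 1-D arrays of equal length")
        if np.any(nu <= 0):
            raise ValueError("frequencies must be strictly positive")
        if np.any(np.diff(nu) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(r1 <= 0):
            raise ValueError("relaxation rates must be strictly positive")
        object.__setattr__(self, "nu", nu)
        object.__setattr__(self, "r1", r1)
        if self.sigma is not None:
            sigma = np.asarray(self.sigma, dtype=float)
            if sigma.shape != nu.shape:
                raise ValueError("sigma must match nu in length")
            if np.any(sigma <= 0):
                raise ValueError("sigma must be strictly positive")
            object.__setattr__(self, "sigma", sigma)
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    def __len__(self) -> int:
        return self.nu.size

    @property
    def weights(self) -> np.ndarray:
        """Least-squares weights: 1/sigma when uncertainties are recorded,
        else 1/R1 (relative weighting)."""
        if self.sigma is not None:
            return 1.0 / self.sigma
        return 1.0 / self.r1
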