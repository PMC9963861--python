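"""Physical constants used by the dipolar relaxation prefactors.

Values are CODATA 2018/2022 recommended values; they are frozen on the
:class:`PhysicalConstants` dataclass so every prefactor in the package is
computed from one immutable source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable container of the constants entering dipolar couplings.

    Attributes
    ----------
    gamma_H : float
        1H gyromagnetic ratio, rad s^-1 T^-1.
    gamma_N : float
        14N gyromagnetic ratio, rad s^-1 T^-1.
    mu0 : float
        Vacuum permeability, T^2 m^3 J^-1.
    hbar : float
        Reduced Planck constant, J s.
    """

    gamma_H: float = 2.6752218708e8
    gamma_N: float = 1.9337792e7
    mu0: float = 4e-7 * math.pi
    hbar: float = 1.054571817e-34

    def __post_init__(self) -> None:
        for name in ("gamma_H", "gamma_N", "mu0", "hbar"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


#: Default constant set shared across the package.
CONSTANTS = PhysicalConstants()

#: Molar gas constant, J mol^-1 K^-1 (used by the Arrhenius analysis).
GAS_CONSTANT = 8.31446261815324

#: Distance of closest approach default: the diameter of a water molecule, m.
WATER_DIAMETER = 2.7e-10
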