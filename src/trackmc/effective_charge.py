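"""Booth effective charge and the Z^2 scaling of proton cross-sections to ions.

A slow ion picks up electrons from the medium and carries a reduced apparent
charge Zeff < Z.  The empirical Booth model expresses the reduction through a
scaling variable y proportional to the ion velocity:

    Zeff = Z * (1 - exp(-1.316 y + 0.112 y^2 - 0.065 y^3)),   y = 100 beta Z^(-2/3)

with beta the ion velocity in units of c.  Cross-sections for an ion of mass
number A and energy Ek are the proton cross-sections at the proton-equivalent
energy Ek/A scaled by Zeff^2.

The velocity (beta) form of y is the default; the beta^2 variant that a
literal reading of some typographies suggests is available behind a flag but
does not reproduce the published 5%-correction anchor energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import CONSTANTS, PhysicalConstants
from .cross_sections import CrossSectionTable

__all__ = [
    "IonSpec",
    "booth_polynomial",
    "effective_charge",
    "charge_correction_threshold",
    "ion_channel_xs",
]

_BOOTH_C1, _BOOTH_C2, _BOOTH_C3 = 1.316, 0.112, 0.065


def booth_polynomial(y: float | np.ndarray) -> float | np.ndarray:
    """Exponent polynomial -1.316 y + 0.112 y^2 - 0.065 y^3 of the Booth model."""
    y = np.asarray(y, dtype=float)
    out = -_BOOTH_C1 * y + _BOOTH_C2 * y**2 - _BOOTH_C3 * y**3
    return float(out) if out.ndim == 0 else out


def _beta(Ek: float, A: int, constants: PhysicalConstants) -> float:
    """Ion velocity in units of c from relativistic kinematics (rest energy A*Mc^2)."""
    gamma = 1.0 + Ek / (A * constants.proton_rest_energy_eV)
    return math.sqrt(1.0 - 1.0 / gamma**2)


def _scaling_variable(Z: int, A: int, Ek: float,
                      constants: PhysicalConstants, use_beta_squared: bool) -> float:
    beta = _beta(Ek, A, constants)
    v = beta**2 if use_beta_squared else beta
    return 100.0 * v * Z ** (-2.0 / 3.0)


def effective_charge(Z: int, A: int, Ek: float,
                     constants: PhysicalConstants = CONSTANTS,
                     use_beta_squared: bool = False) -> float:
    """Booth effective charge Zeff for an ion (Z, A) of kinetic energy Ek (eV)."""
    if Z < 1 or A < 1 or Ek <= 0:
        raise ValueError("require Z >= 1, A >= 1 and Ek > 0")
    y = _scaling_variable(Z, A, Ek, constants, use_beta_squared)
    return Z * (1.0 - math.exp(booth_polynomial(y)))


def charge_correction_threshold(Z: int, A: int,
                                constants: PhysicalConstants = CONSTANTS,
                                correction: float = 0.05) -> tuple[float, float]:
    """(y*, Ek*) at which the effective-charge correction equals `correction`.

    y* solves exp(booth_polynomial(y)) = correction by bracketed root-finding
    on y in [0, 10]; Ek* is the ion kinetic energy (eV) at which the scaling
    variable equals y*.
    """
    if Z < 1 or A < 1 or not (0.0 < correction < 1.0):
        raise ValueError("invalid ion or correction level")
    target = math.log(correction)
    y_star = brentq(lambda y: booth_polynomial(y) - target, 1e-9, 10.0, xtol=1e-12)
    # invert y(Ek): y = 100 beta Z^(-2/3)  =>  beta, then Ek from gamma
    beta = y_star * Z ** (2.0 / 3.0) / 100.0
    if beta >= 1.0:
        raise ValueError("correction threshold would require a superluminal ion")
    gamma = 1.0 / math.sqrt(1.0 - beta**2)
    Ek_star = (gamma - 1.0) * A * constants.proton_rest_energy_eV
    return y_star, Ek_star


@dataclass
class IonSpec:
    """An ion species/energy with its derived effective-charge quantities."""

    Z: int
    A: int
    Ek_eV: float
    constants: PhysicalConstants = field(default=CONSTANTS, repr=False)

    def __post_init__(self) -> None:
        if self.Z < 1 or self.A < 1 or self.Ek_eV <= 0:
            raise ValueError("require Z >= 1, A >= 1 and Ek > 0")

    @property
    def proton_equivalent_energy_eV(self) -> float:
        """Energy Ep = Ek/A of a proton with the same velocity."""
        return self.Ek_eV / self.A

    @property
    def scaling_variable(self) -> float:
        return _scaling_variable(self.Z, self.A, self.Ek_eV, self.constants, False)

    @property
    def effective_charge(self) -> float:
        return effective_charge(self.Z, self.A, self.Ek_eV, self.constants)


def ion_channel_xs(Z: int, A: int, Ek: float, table: CrossSectionTable,
                   constants: PhysicalConstants = CONSTANTS) -> np.ndarray:
    """Per-channel cross-sections for an ion: Zeff^2 x proton values at Ek/A."""
    zeff = effective_charge(Z, A, Ek, constants)
    return zeff**2 * table.lookup(Ek / A)
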