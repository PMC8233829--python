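"""Physical constants for track-structure transport in liquid water.

All energies are in eV unless noted; lengths in metres. The constants are
grouped in a frozen dataclass so a simulation run carries one immutable,
hashable set of values end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass(frozen=True)
class PhysicalConstants:
    """Immutable bundle of the physical constants the transport models use.

    Attributes
    ----------
    electron_rest_energy_eV : electron rest energy m*c^2.
    proton_rest_energy_eV : proton (nucleon) rest energy M*c^2.
    bohr_radius_m : Bohr radius a0.
    rydberg_eV : Rydberg energy E_R.
    avogadro : Avogadro constant N_A (1/mol).
    water_density_kg_m3 : liquid water mass density rho.
    water_molar_mass_kg_mol : molar mass of water M_w.
    """

    electron_rest_energy_eV: float = 0.511e6
    proton_rest_energy_eV: float = 938.272e6
    bohr_radius_m: float = 5.3e-11
    rydberg_eV: float = 13.6
    avogadro: float = 6.02214076e23
    water_density_kg_m3: float = 1000.0
    water_molar_mass_kg_mol: float = 18.015e-3

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"constant {f.name} must be strictly positive")

    @property
    def mass_ratio(self) -> float:
        """Electron-to-proton mass ratio m/M."""
        return self.electron_rest_energy_eV / self.proton_rest_energy_eV

    @property
    def water_number_density_m3(self) -> float:
        """Molecular number density of liquid water, rho*N_A/M_w (~3.34e28 m^-3)."""
        return self.water_density_kg_m3 * self.avogadro / self.water_molar_mass_kg_mol


#: Default constants shared by the whole package.
CONSTANTS = PhysicalConstants()

#: 1 eV in joules, used when converting deposited energy to dose.
EV_TO_JOULE = 1.602176634e-19
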