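"""Physical constants and unit conversions.

The internal energy unit throughout the package is the wavenumber (cm^-1);
eV appears only at presentation time.  Time is measured in femtoseconds and
distances in angstroms.  The frequency <-> timescale convention is

    gamma(cm^-1) = 1 / (2 pi c tau),   tau in fs, c in cm/fs,

i.e. a correlation time of 16.065 fs corresponds to a cutoff of 330.4 cm^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class UnitConstants:
    """Immutable bundle of the conversion constants the pipeline uses.

    Attributes
    ----------
    wavenumber_per_ev : cm^-1 per eV.
    boltzmann_wavenumber : Boltzmann constant in cm^-1 per K.
    speed_of_light : speed of light in cm per fs.
    dipole_coupling_prefactor : electrostatic conversion for dipole-dipole
        couplings with dipoles in Debye, distances in angstrom and energies
        in cm^-1.
    """

    wavenumber_per_ev: float = 8065.544
    boltzmann_wavenumber: float = 0.6950348
    speed_of_light: float = 2.99792458e-5
    dipole_coupling_prefactor: float = 5.034

    def __post_init__(self) -> None:
        for name in (
            "wavenumber_per_ev",
            "boltzmann_wavenumber",
            "speed_of_light",
            "dipole_coupling_prefactor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


CONSTANTS = UnitConstants()

#: hbar expressed in cm^-1 * fs, i.e. 1 / (2 pi c).
HBAR_WAVENUMBER_FS = 1.0 / (2.0 * math.pi * CONSTANTS.speed_of_light)


def ev_to_wavenumber(energy_ev: float) -> float:
    """Convert an energy from eV to cm^-1."""
    return energy_ev * CONSTANTS.wavenumber_per_ev


def wavenumber_to_ev(energy_cm: float) -> float:
    """Convert an energy from cm^-1 to eV."""
    return energy_cm / CONSTANTS.wavenumber_per_ev


def thermal_energy(temperature: float) -> float:
    """k_B * T in cm^-1 (208.51 cm^-1 at 300 K)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return CONSTANTS.boltzmann_wavenumber * temperature


def timescale_to_wavenumber(tau_fs: float) -> float:
    """Convert a correlation time tau (fs) to a frequency gamma (cm^-1)."""
    if tau_fs <= 0:
        raise ValueError("timescale must be positive")
    return 1.0 / (2.0 * math.pi * CONSTANTS.speed_of_light * tau_fs)


def wavenumber_to_timescale(gamma_cm: float) -> float:
    """Convert a frequency gamma (cm^-1) to a correlation time tau (fs)."""
    if gamma_cm <= 0:
        raise ValueError("frequency must be positive")
    return 1.0 / (2.0 * math.pi * CONSTANTS.speed_of_light * gamma_cm)


def matsubara_timescale(temperature: float) -> float:
    """Timescale of the first bosonic Matsubara frequency, hbar/(2 pi k_B T).

    This is the temperature-fixed fast bath timescale of the white-noise
    residue ansatz: about 4.05 fs at 300 K, depending only on temperature.
    """
    return HBAR_WAVENUMBER_FS / (2.0 * math.pi * thermal_energy(temperature))
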