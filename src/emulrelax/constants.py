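"""Physical constants and unit helpers.

All values are CODATA 2018. They are kept in one table so that every
module draws on the same numbers; nothing in the package hard-codes a
physical constant elsewhere.
"""

import math

#: Vacuum permeability mu0 (T m / A).
VACUUM_PERMEABILITY = 1.25663706212e-06

#: Proton magnetogyric ratio gamma (rad s^-1 T^-1).
PROTON_GYROMAGNETIC_RATIO = 2.6752218744e8

#: Planck constant h (J s).
PLANCK_CONSTANT = 6.62607015e-34

#: Reduced Planck constant h/2pi (J s).
REDUCED_PLANCK = PLANCK_CONSTANT / (2.0 * math.pi)

#: Molar gas constant R (J mol^-1 K^-1).
GAS_CONSTANT = 8.314462618

#: Offset between the Celsius and kelvin scales.
CELSIUS_OFFSET = 273.15

#: Default intra-molecular proton-proton distance r0 (m), a typical
#: value for a proton pair within a small molecule.  Used only when the
#: correlation time is extracted from R1 alone, which requires the
#: dipolar prefactor; the default ratio-based route never needs it.
DEFAULT_PROTON_DISTANCE = 1.8e-10


def celsius_to_kelvin(temperature_c: float) -> float:
    """Convert a Celsius temperature to kelvin."""
    return temperature_c + CELSIUS_OFFSET


def kelvin_to_celsius(temperature_k: float) -> float:
    """Convert a kelvin temperature to Celsius."""
    return temperature_k - CELSIUS_OFFSET


def dipolar_prefactor(r0: float = DEFAULT_PROTON_DISTANCE) -> float:
    """Lumped dipolar coupling constant K (s^-2) for a like-spin proton pair.

    K = (mu0 / 4 pi)^2 * gamma^4 * hbar^2 / r0^6, the constant that
    multiplies the spectral-density terms of the dipolar relaxation
    rates for two protons separated by ``r0``.

    Parameters
    ----------
    r0 : float
        Internuclear distance in metres.
    """
    if r0 <= 0:
        raise ValueError(f"internuclear distance must be positive, got {r0}")
    return (
        (VACUUM_PERMEABILITY / (4.0 * math.pi)) ** 2
        * PROTON_GYROMAGNETIC_RATIO**4
        * REDUCED_PLANCK**2
        / r0**6
    )
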