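"""Physical constants and unit conventions.

The package works in a single unit system throughout:

* energy        kcal mol^-1
* length        angstrom (A)
* time          femtosecond (fs)
* temperature   kelvin (K)
* mass          atomic mass unit (amu)

Rates are expressed in s^-1 and half-lives in seconds; conversion helpers
live in :mod:`evbkit.kinetics`.
"""

import math

#: Boltzmann constant in kcal mol^-1 K^-1.
BOLTZMANN_KCAL: float = 0.0019872041

#: Conventional rounded thermal energy k_B*T at 37 degC (310.15 K), in
#: kcal mol^-1, as used in experimental kinetics arithmetic.  Note that
#: ``BOLTZMANN_KCAL * 310.15 = 0.61633`` differs from this rounded value in
#: the third decimal; :class:`evbkit.kinetics.KineticContext` records which
#: convention is active.
KT_37C: float = 0.617

#: 37 degC in kelvin.
T_37C: float = 310.15

#: Boltzmann constant, SI (J K^-1).
BOLTZMANN_SI: float = 1.380649e-23

#: Planck constant, SI (J s).
PLANCK_SI: float = 6.62607015e-34

#: Conversion factor for Newton's second law in internal units:
#: force [kcal mol^-1 A^-1] / mass [amu] * ACCEL_UNIT = acceleration [A fs^-2].
ACCEL_UNIT: float = 4.184e-4

LN10: float = math.log(10.0)


def thermal_energy(temperature: float) -> float:
    """Physical thermal energy k_B*T in kcal mol^-1 at `temperature` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return BOLTZMANN_KCAL * temperature


def eyring_prefactor(temperature: float) -> float:
    """Transition-state-theory attempt frequency k_B*T/h in s^-1.

    This is the Eyring--Polanyi prefactor with transmission coefficient 1.
    At 310 K it evaluates to about 6.46e12 s^-1.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return BOLTZMANN_SI * temperature / PLANCK_SI
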