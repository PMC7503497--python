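"""Physical constants and unit conversions.

Internal unit system: energy kcal/mol, length Å, mass amu, time fs,
temperature K, charge e.
"""

from scipy import constants as _sc

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 1.987204e-3

#: Coulomb prefactor, kcal Å mol^-1 e^-2 (q_i q_j * COULOMB_KCAL / r).
COULOMB_KCAL = 332.06371

#: Kinetic-energy conversion: 1 amu (Å/fs)^2 in kcal/mol.
#: 1 amu Å^2 fs^-2 = 1e7 J/mol.
MV2_TO_KCAL = 1.0e7 / _sc.calorie / 1000.0  # = 2390.057...

#: Acceleration conversion: (kcal mol^-1 Å^-1 / amu) -> Å fs^-2.
ACC_FROM_FORCE = 1.0 / MV2_TO_KCAL


def boltzmann_prefactor(temperature_k: float) -> float:
    """Eyring prefactor k_B*T/h in s^-1, from CODATA constants."""
    return _sc.Boltzmann * temperature_k / _sc.Planck
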