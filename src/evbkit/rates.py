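"""Transition-state-theory arithmetic and bundled reference energetics.

Reference data: aqueous-phase activation/reaction free energies and fitted
EVB parameters for the two propargylamine inhibitors, plus their measured
inactivation rate constants.  TST conversions use a transmission
coefficient of 1 and the Eyring prefactor k_B*T/h computed from CODATA
constants at call time.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from .constants import R_KCAL, boltzmann_prefactor
from .errors import UnitError, ValidationError

#: Conventional TST temperature (K) used for barrier/rate arithmetic; the
#: dynamics default of 300 K is deliberately not reused here.
TST_TEMPERATURE = 298.15

_RATE_UNITS = {"1/s": 1.0, "/s": 1.0, "s^-1": 1.0,
               "1/min": 1.0 / 60.0, "/min": 1.0 / 60.0, "min^-1": 1.0 / 60.0}


@dataclass(frozen=True)
class Rate:
    """A first-order rate constant with an explicit unit."""

    value: float
    unit: str = "1/s"

    def __post_init__(self):
        if self.unit not in _RATE_UNITS:
            raise UnitError(f"unknown rate unit {self.unit!r}")
        canonical = "1/min" if _RATE_UNITS[self.unit] != 1.0 else "1/s"
        object.__setattr__(self, "unit", canonical)
        if not self.value > 0:
            raise ValidationError(f"rate must be positive, got {self.value}")

    @property
    def per_second(self) -> float:
        return self.value * _RATE_UNITS[self.unit]


def parse_rate(text) -> Rate:
    """Parse '0.99/min', '1.2 1/s', or a bare number (assumed 1/s)."""
    if isinstance(text, Rate):
        return text
    if isinstance(text, (int, float)):
        return Rate(float(text))
    m = re.fullmatch(r"\s*([0-9.eE+-]+)\s*(.*)", str(text))
    if not m:
        raise UnitError(f"cannot parse rate {text!r}")
    value, unit = float(m.group(1)), m.group(2).strip() or "1/s"
    return Rate(value, unit)


@dataclass(frozen=True)
class ReferenceEnergetics:
    """One inhibitor's reference row plus its experimental k_inact."""

    inhibitor: str
    dg_ts: float  # kcal/mol, transition state vs reactant complex
    dg_intermediate: float  # kcal/mol
    h_ij: float  # kcal/mol, fitted coupling
    alpha0: float  # kcal/mol, fitted solution-phase shift
    k_inact: Rate
    imag_freq_cm: float  # |imaginary frequency| in 1/cm, metadata only


_REFERENCE = (
    ReferenceEnergetics("rasagiline", 30.60, 19.18, 44.34, 106.7,
                        Rate(0.0533, "1/min"), 1351.0),
    ReferenceEnergetics("selegiline", 31.11, 17.29, 43.59, 80.40,
                        Rate(0.99, "1/min"), 1390.0),
)


def load_reference() -> list:
    """Return the two bundled reference records."""
    return list(_REFERENCE)


def lookup(inhibitor: str) -> ReferenceEnergetics:
    for rec in _REFERENCE:
        if rec.inhibitor == inhibitor.lower():
            return rec
    raise KeyError(
        f"unknown inhibitor {inhibitor!r}; expected one of "
        f"{[r.inhibitor for r in _REFERENCE]}"
    )


@dataclass(frozen=True)
class RateEstimate:
    """A mutually consistent (rate, barrier, temperature) triple with unit
    transmission coefficient."""

    k_per_s: float
    temperature: float
    dg_activation: float  # kcal/mol
    transmission: float = 1.0

    def __post_init__(self):
        implied = boltzmann_prefactor(self.temperature) * math.exp(
            -self.dg_activation / (R_KCAL * self.temperature))
        if abs(implied - self.k_per_s) > 1e-12 * abs(self.k_per_s):
            raise ValidationError(
                f"inconsistent RateEstimate: k = {self.k_per_s} but the "
                f"Eyring expression gives {implied}")

    @classmethod
    def from_barrier(cls, dg_activation: float,
                     temperature: float = TST_TEMPERATURE):
        return cls(eyring_rate(dg_activation, temperature), temperature,
                   dg_activation)

    @classmethod
    def from_rate(cls, k, temperature: float = TST_TEMPERATURE):
        k = parse_rate(k)
        return cls(k.per_second, temperature,
                   barrier_from_rate(k, temperature))


def eyring_rate(dg_activation: float, temperature: float = TST_TEMPERATURE) -> float:
    """Rate constant k = (k_B*T/h) * exp(-dG/RT) in 1/s."""
    if not temperature > 0:
        raise ValidationError(f"temperature must be positive, got {temperature}")
    return boltzmann_prefactor(temperature) * math.exp(
        -dg_activation / (R_KCAL * temperature)
    )


def barrier_from_rate(k, temperature: float = TST_TEMPERATURE) -> float:
    """Invert the Eyring expression: dG = RT * ln(k_B*T/h / k), kcal/mol."""
    if not temperature > 0:
        raise ValidationError(f"temperature must be positive, got {temperature}")
    k = parse_rate(k)
    return R_KCAL * temperature * math.log(
        boltzmann_prefactor(temperature) / k.per_second
    )


def ddg_from_rates(k_fast, k_slow, temperature: float = TST_TEMPERATURE) -> float:
    """Activation free-energy difference R*T*ln(k_fast/k_slow), kcal/mol.

    Rates may be floats (1/s), Rate objects, or strings like '0.99/min';
    both rates must carry the same unit since only the ratio enters.
    """
    kf, ks = parse_rate(k_fast), parse_rate(k_slow)
    if kf.unit != ks.unit and {kf.unit, ks.unit} - {"1/s", "/s", "s^-1"}:
        if _RATE_UNITS[kf.unit] != _RATE_UNITS[ks.unit]:
            raise UnitError(
                f"rate units differ ({kf.unit!r} vs {ks.unit!r}); "
                "supply both in the same unit"
            )
    if not temperature > 0:
        raise ValidationError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature * math.log(kf.value / ks.value)


def catalytic_orders(dg_reference: float, dg_catalyzed: float,
                     temperature: float = TST_TEMPERATURE) -> float:
    """Orders of magnitude of rate enhancement from a barrier reduction.

    (dg_reference - dg_catalyzed) / (R*T*ln 10); negative means the
    "catalyzed" barrier is actually higher.
    """
    if not temperature > 0:
        raise ValidationError(f"temperature must be positive, got {temperature}")
    return (dg_reference - dg_catalyzed) / (R_KCAL * temperature * math.log(10.0))
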