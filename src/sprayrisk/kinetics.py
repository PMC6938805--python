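"""Temperature-corrected single-first-order degradation on a daily grid.

Degradation follows single first-order kinetics, k = ln 2 / DT50s, with the
effective half-life obtained from the reference-temperature value by an
Arrhenius correction

    DT50s = DT50soil * F * exp( Ea/R * (1/T - 1/Ts) )

where F is the user's per-application degradation factor, Ea the activation
energy [J/mol], R the molar gas constant, Ts the reference temperature and T
the (monthly mean) soil temperature, both in kelvin.  The sign convention
follows directly from k = A * exp(-Ea/(R T)): colder months slow degradation
and lengthen the half-life.  Concentrations are never floored to zero; the
exponential tail is kept at full floating precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ScenarioError

CELSIUS_OFFSET = 273.15


@dataclass
class KineticParams:
    dt50_soil: float  # [d] half-life at the reference temperature
    degradation_factor: float = 1.0
    activation_energy: float = 54000.0  # Ea [J/mol]
    gas_constant: float = 8.314  # R [J/(mol K)]
    reference_temperature_K: float = 20.0 + CELSIUS_OFFSET  # Ts [K]
    temperature_K: float = 20.0 + CELSIUS_OFFSET  # T [K]

    def __post_init__(self) -> None:
        if not (math.isfinite(self.dt50_soil) and self.dt50_soil > 0):
            raise ScenarioError(f"DT50 must be finite and > 0 d, got {self.dt50_soil}")
        if self.degradation_factor <= 0:
            raise ScenarioError("degradation factor must be > 0")
        if self.temperature_K <= 0 or self.reference_temperature_K <= 0:
            raise ScenarioError("temperatures must be > 0 K")


def corrected_half_life(p: KineticParams) -> float:
    """Effective half-life DT50s [d] at the actual temperature."""
    dt50s = (
        p.dt50_soil
        * p.degradation_factor
        * math.exp(
            p.activation_energy
            / p.gas_constant
            * (1.0 / p.temperature_K - 1.0 / p.reference_temperature_K)
        )
    )
    if not math.isfinite(dt50s) or dt50s <= 0:
        raise ScenarioError(f"temperature correction produced invalid DT50s = {dt50s}")
    return dt50s


def rate_constant(dt50s: float) -> float:
    """First-order disappearance rate constant k [1/d] from a half-life."""
    if not (math.isfinite(dt50s) and dt50s > 0):
        raise ScenarioError(f"DT50s must be finite and > 0 d, got {dt50s}")
    return math.log(2.0) / dt50s


def decay_step(c: float, k: float) -> float:
    """Concentration after one day of first-order decay at rate k [1/d]."""
    if c < 0:
        raise ScenarioError(f"concentration must be >= 0, got {c}")
    if k < 0:
        raise ScenarioError(f"rate constant must be >= 0, got {k}")
    return c * math.exp(-k)
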