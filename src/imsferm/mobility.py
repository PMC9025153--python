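"""Reduced ion mobility arithmetic and drift-time coordinate conversions.

In drift-tube ion mobility spectrometry an ion packet traverses a tube of
length ``L`` (cm) under a field ``E = U / L`` (V cm^-1) against a
counter-flowing drift gas at pressure ``p`` (hPa) and temperature ``T`` (K).
The measured drift time ``t_D`` (s) is converted to the reduced ion mobility

    K0 = L / (E * t_D) * (p / p0) * (T0 / T)    [cm^2 V^-1 s^-1]

normalized to the reference pressure ``p0 = 1013.2`` hPa and reference
temperature ``T0 = 273.2`` K, which makes mobilities comparable across
instruments and ambient conditions (Mason-Schamp relation).

Analyte drift times are additionally expressed relative to the reactant ion
peak (RIP) as the dimensionless ratio ``t_D / t_RIP`` ("RIPrel"), the
instrument-independent drift coordinate used throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "REFERENCE_PRESSURE_HPA",
    "REFERENCE_TEMPERATURE_K",
    "MobilityConditions",
    "MobilityResult",
    "reduced_mobility",
    "drift_time_for_mobility",
    "rip_relative",
    "celsius_to_kelvin",
]

REFERENCE_PRESSURE_HPA = 1013.2
REFERENCE_TEMPERATURE_K = 273.2


def _require_positive(value: float, name: str) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be strictly positive, got {value!r}")


def celsius_to_kelvin(temp_c: float) -> float:
    """Convert a Celsius temperature to Kelvin (+273.15)."""
    return temp_c + 273.15


@dataclass(frozen=True)
class MobilityConditions:
    """Drift-tube operating conditions.

    Parameters
    ----------
    drift_length:
        Drift tube length L in cm.
    drift_voltage:
        Drift voltage U in V. The field strength is derived as E = U / L.
    pressure:
        Drift-gas pressure p in hPa.
    temperature:
        Drift-gas temperature T in K.
    """

    drift_length: float
    drift_voltage: float
    pressure: float
    temperature: float
    reference_pressure: float = field(default=REFERENCE_PRESSURE_HPA)
    reference_temperature: float = field(default=REFERENCE_TEMPERATURE_K)

    def __post_init__(self) -> None:
        for name in (
            "drift_length",
            "drift_voltage",
            "pressure",
            "temperature",
            "reference_pressure",
            "reference_temperature",
        ):
            _require_positive(getattr(self, name), name)

    @property
    def field_strength(self) -> float:
        """Electric field strength E = U / L in V cm^-1."""
        return self.drift_voltage / self.drift_length


@dataclass(frozen=True)
class MobilityResult:
    """A (drift time, reduced mobility) pair.

    ``drift_time`` in seconds, ``reduced_mobility`` K0 in cm^2 V^-1 s^-1.
    """

    drift_time: float
    reduced_mobility: float

    def __post_init__(self) -> None:
        _require_positive(self.drift_time, "drift_time")
        _require_positive(self.reduced_mobility, "reduced_mobility")


def reduced_mobility(cond: MobilityConditions, drift_time: float) -> float:
    """Reduced ion mobility K0 for a drift time in seconds.

    K0 = (L / (E * t_D)) * (p / p0) * (T0 / T).
    """
    _require_positive(drift_time, "drift_time")
    velocity_term = cond.drift_length / (cond.field_strength * drift_time)
    pressure_term = cond.pressure / cond.reference_pressure
    temperature_term = cond.reference_temperature / cond.temperature
    return velocity_term * pressure_term * temperature_term


def drift_time_for_mobility(cond: MobilityConditions, k0: float) -> float:
    """Drift time (s) at which an ion of reduced mobility ``k0`` arrives.

    Algebraic inverse of :func:`reduced_mobility`; the round trip is exact to
    floating-point precision.
    """
    _require_positive(k0, "k0")
    pressure_term = cond.pressure / cond.reference_pressure
    temperature_term = cond.reference_temperature / cond.temperature
    return cond.drift_length * pressure_term * temperature_term / (
        cond.field_strength * k0
    )


def rip_relative(drift_time: float, rip_drift_time: float) -> float:
    """Drift position relative to the reactant ion peak (dimensionless).

    The RIP itself maps to exactly 1.0; analyte ions, being slower, map to
    values above 1.
    """
    _require_positive(rip_drift_time, "rip_drift_time")
    return drift_time / rip_drift_time
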