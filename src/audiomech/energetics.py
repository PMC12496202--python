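"""Equipartition energetics: total fluctuation power, apparent mass, power gain.

The fitted velocity-amplitude model is converted to displacement via
``x(f) = v(f) / (2 pi f)`` and its power integrated over all frequencies:

    <x^2> = integral of the displacement power spectral density.

Because the spectrum bins are power-calibrated on a grid of width ``df``
(``bin^2 / 2`` is the power per bin), the fitted curve's PSD is
``V(f)^2 / (2 df)`` and the closed-form integral of the Lorentzian gives

    <x^2> = A^2 * f0 * Q / (16 * pi * df).

For a passive thermal receiver this equals ``k_B T / k``, which pins the
apparent mass ``m = k_B T / (omega0^2 <x^2>)`` and the active-vs-passive
power gain ``(omega_a^2 <x_a^2>) / (omega_p^2 <x_p^2>) - 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import BOLTZMANN, DEFAULT_TEMPERATURE
from .spectra import OscillatorFit, oscillator_velocity_model

__all__ = [
    "FluctuationPower",
    "ApparentMass",
    "PowerGain",
    "fluctuation_power",
    "apparent_mass",
    "power_gain",
]


@dataclass(frozen=True)
class FluctuationPower:
    """Total displacement fluctuation power <x^2> in m^2."""

    x2_total_m2: float
    method: str  # {"analytic-from-fit", "numeric-band"}
    domain_rad_s: tuple[float, float]

    def __post_init__(self) -> None:
        if not (self.x2_total_m2 > 0 and math.isfinite(self.x2_total_m2)):
            raise ValueError("x2_total must be positive and finite")


@dataclass(frozen=True)
class ApparentMass:
    """Apparent receiver mass from equipartition: m = k_B T / (omega0^2 <x^2>)."""

    mass_kg: float
    temperature_k: float
    boltzmann: float
    source_fit: OscillatorFit
    source_power: FluctuationPower

    @property
    def mass_ng(self) -> float:
        return self.mass_kg * 1e12


@dataclass(frozen=True)
class PowerGain:
    """Active-vs-passive fluctuation-power ratio minus one."""

    gain: float
    active_omega_rad_s: float
    active_x2_m2: float
    passive_omega_rad_s: float
    passive_x2_m2: float


def _require_valid(fit: OscillatorFit) -> None:
    if not fit.valid:
        raise ValueError(f"refusing to use an invalid oscillator fit: {fit.message}")


def fluctuation_power(
    fit: OscillatorFit,
    method: str = "analytic",
    band_hz: tuple[float, float] | None = None,
    n_grid: int = 200_001,
) -> FluctuationPower:
    """Integrate the fitted model's displacement power over frequency.

    ``method="analytic"`` evaluates the closed-form integral of the fitted
    Lorentzian over (0, inf); ``method="numeric"`` integrates
    ``V(f)^2 / ((2 pi f)^2 * 2 df)`` by trapezoid over ``band_hz``.
    """
    _require_valid(fit)
    f0, q, amp, df = (
        fit.best_frequency_hz,
        fit.quality_factor,
        fit.amplitude_scale,
        fit.bin_width_hz,
    )
    if method == "analytic":
        x2 = amp**2 * f0 * q / (16.0 * math.pi * df)
        return FluctuationPower(
            x2_total_m2=x2, method="analytic-from-fit", domain_rad_s=(0.0, math.inf)
        )
    if method == "numeric":
        if band_hz is None:
            band_hz = (f0 / 20.0, 20.0 * f0)
        lo, hi = band_hz
        if not (0 < lo < hi):
            raise ValueError("numeric band must satisfy 0 < lo < hi")
        f = np.linspace(lo, hi, n_grid)
        v = oscillator_velocity_model(f, f0, q, amp)
        psd_x = v**2 / ((2.0 * math.pi * f) ** 2 * 2.0 * df)
        x2 = float(np.trapezoid(psd_x, f))
        return FluctuationPower(
            x2_total_m2=x2,
            method="numeric-band",
            domain_rad_s=(2.0 * math.pi * lo, 2.0 * math.pi * hi),
        )
    raise ValueError(f"unknown method {method!r}")


def apparent_mass(
    fit: OscillatorFit,
    power: FluctuationPower,
    temperature: float = DEFAULT_TEMPERATURE,
) -> ApparentMass:
    """Apparent mass via equipartition (passive-state inputs are the caller's contract)."""
    _require_valid(fit)
    if power.x2_total_m2 <= 0:
        raise ValueError("fluctuation power must be positive")
    omega0 = fit.omega0
    mass = BOLTZMANN * temperature / (omega0**2 * power.x2_total_m2)
    return ApparentMass(
        mass_kg=mass,
        temperature_k=temperature,
        boltzmann=BOLTZMANN,
        source_fit=fit,
        source_power=power,
    )


def power_gain(
    active_fit: OscillatorFit,
    active_power: FluctuationPower,
    passive_fit: OscillatorFit,
    passive_power: FluctuationPower,
) -> PowerGain:
    """Gain = (omega_a^2 <x_a^2>) / (omega_p^2 <x_p^2>) - 1."""
    _require_valid(active_fit)
    _require_valid(passive_fit)
    if passive_power.x2_total_m2 <= 0:
        raise ValueError("passive fluctuation power must be positive")
    omega_a, omega_p = active_fit.omega0, passive_fit.omega0
    gain = (omega_a**2 * active_power.x2_total_m2) / (
        omega_p**2 * passive_power.x2_total_m2
    ) - 1.0
    return PowerGain(
        gain=gain,
        active_omega_rad_s=omega_a,
        active_x2_m2=active_power.x2_total_m2,
        passive_omega_rad_s=omega_p,
        passive_x2_m2=passive_power.x2_total_m2,
    )
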