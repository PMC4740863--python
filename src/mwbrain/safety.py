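"""Analytic radiation-safety calculators: power density and skin heating.

The incident power density on the skin follows the far-field spherical
spreading law S = P_tx G / (4 pi r^2) with G the antenna gain as a linear
factor.  With the system's 1 mW transmit power, gain factor 3.5 and 15 mm
standoff this evaluates to 1.24 W/m^2 (0.124 mW/cm^2), well under the
1 mW/cm^2 radiation limit; a dBi reading of the same gain figure
(10^0.35 = 2.24) would instead give 0.79 W/m^2, so the linear reading is
the one this module adopts and tests.  ``dbi_to_linear`` is provided so
both interpretations can be computed explicitly.

Skin heating uses the classical erfc solution of a semi-infinite skin
slab absorbing the transmitted fraction of the incident power
exponentially over the power penetration depth L::

    dT(t) = (S T_tr L / k) * [ 2 sqrt(x/pi) + exp(x) erfc(sqrt(x)) - 1 ],
    x = t / tau,  tau = L^2 * (rho c / k) = L^2 P_th / k^2,

where T_tr = 1 - |Gamma|^2 is the skin-surface transmission coefficient,
Gamma the air/skin reflection coefficient from the complex skin
permittivity at the operating frequency, P_th = k rho c the thermal
inertia, k the thermal conductivity, and tau the thermal time constant
(the time for the thermal wave to diffuse one skin depth).  dT is linear
in the incident power density and rises faster at higher frequencies,
where the larger skin conductivity shrinks L and concentrates the loss at
the surface.  A frequency sweep exposes each frequency only for its dwell
fraction, so the effective rise is the duty-cycle-weighted superposition
of the per-frequency rises.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.special import erfcx

from .constants import C0_M, EPS0

__all__ = [
    "ThermalParams",
    "SkinFrequencyParams",
    "dbi_to_linear",
    "incident_power_density",
    "temperature_rise",
    "band_sweep_temperature",
]


def dbi_to_linear(gain_dbi: float) -> float:
    """Convert an antenna gain in dBi to a linear power gain factor."""
    return 10.0 ** (gain_dbi / 10.0)


def incident_power_density(p_tx: float, gain_linear: float, r: float) -> float:
    """S = P_tx * G / (4 pi r^2), W/m^2; ``r`` in metres."""
    if p_tx <= 0 or gain_linear <= 0:
        raise ValueError("transmit power and gain must be positive")
    if r <= 0:
        raise ValueError("distance must be positive")
    return p_tx * gain_linear / (4.0 * np.pi * r**2)


@dataclass(frozen=True)
class ThermalParams:
    """Skin thermal/dielectric constants.

    Defaults are standard literature values for human skin (package
    defaults, configurable): thermal conductivity 0.37 W/m/K, thermal
    inertia k*rho*c with rho = 1109 kg/m^3 and c = 3390 J/kg/K, and
    band-edge skin permittivity 50 -> 44 / conductivity 0.9 -> 1.8 S/m over
    0.75--2.55 GHz (linearly interpolated in between).
    """

    thermal_conductivity: float = 0.37  # W/m/K
    thermal_inertia: float = 0.37 * 1109.0 * 3390.0  # W^2 s / m^4 / K^2
    eps_skin_band: Tuple[float, float] = (50.0, 44.0)
    sigma_skin_band: Tuple[float, float] = (0.9, 1.8)  # S/m
    f_band: Tuple[float, float] = (0.75e9, 2.55e9)

    def __post_init__(self) -> None:
        if self.thermal_conductivity <= 0 or self.thermal_inertia <= 0:
            raise ValueError("thermal constants must be positive")

    def at_frequency(self, f: float) -> "SkinFrequencyParams":
        """Derived per-frequency quantities (clamped to the band edges)."""
        lo, hi = self.f_band
        u = np.clip((f - lo) / (hi - lo), 0.0, 1.0)
        eps_r = self.eps_skin_band[0] + u * (self.eps_skin_band[1] - self.eps_skin_band[0])
        sigma = self.sigma_skin_band[0] + u * (self.sigma_skin_band[1] - self.sigma_skin_band[0])
        w = 2.0 * np.pi * f
        eps_c = eps_r - 1j * sigma / (w * EPS0)
        n_c = np.sqrt(eps_c)
        gamma = (1.0 - n_c) / (1.0 + n_c)
        t_tr = 1.0 - abs(gamma) ** 2
        kappa = -n_c.imag if n_c.imag < 0 else n_c.imag
        skin_depth = C0_M / (2.0 * w * kappa)  # power penetration depth, m
        diffusivity = self.thermal_conductivity**2 / self.thermal_inertia  # k/(rho c)
        tau = skin_depth**2 / diffusivity
        return SkinFrequencyParams(
            eps_complex=eps_c,
            reflection_coefficient=gamma,
            transmission_coefficient=t_tr,
            skin_depth=skin_depth,
            thermal_time_constant=tau,
        )


@dataclass(frozen=True)
class SkinFrequencyParams:
    eps_complex: complex
    reflection_coefficient: complex
    transmission_coefficient: float
    skin_depth: float  # m
    thermal_time_constant: float  # s


def temperature_rise(
    s_incident: float, f: float, t, params: ThermalParams = ThermalParams()
):
    """Surface skin temperature rise dT(t) in degrees C; vectorized over t (s)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    if s_incident < 0 or f <= 0:
        raise ValueError("need s_incident >= 0 and f > 0")
    d = params.at_frequency(f)
    x = t / d.thermal_time_constant
    sx = np.sqrt(x)
    # exp(x) * erfc(sqrt(x)) computed stably via the scaled erfc
    shape = 2.0 * sx / np.sqrt(np.pi) + erfcx(sx) - 1.0
    amp = (
        s_incident
        * d.transmission_coefficient
        * d.skin_depth
        / params.thermal_conductivity
    )
    out = amp * shape
    return out if out.ndim else float(out)


def band_sweep_temperature(
    schedule: Sequence[Tuple[float, float]],
    duration: float,
    p_tx: float,
    gain_linear: float = 3.5,
    distance: float = 0.015,
    params: ThermalParams = ThermalParams(),
    n_times: int = 200,
):
    """Duty-cycle-weighted skin temperature rise for a frequency sweep.

    ``schedule`` is a list of (frequency Hz, dwell fraction) pairs whose
    fractions sum to 1; each frequency heats the skin for its share of the
    exposure.  Returns (t, per-frequency dT array, effective dT).
    """
    fr = np.array([s[1] for s in schedule], dtype=float)
    if len(schedule) == 0 or np.any(fr < 0) or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("dwell fractions must be nonnegative and sum to 1")
    if duration <= 0:
        raise ValueError("duration must be positive")
    s_inc = incident_power_density(p_tx, gain_linear, distance)
    t = np.linspace(0.0, duration, n_times)
    per_f = np.stack(
        [temperature_rise(s_inc, f_i, t, params) for f_i, _ in schedule]
    )
    effective = (fr[:, None] * per_f).sum(axis=0)
    return t, per_f, effective
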