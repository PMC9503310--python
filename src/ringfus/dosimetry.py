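"""Frequency-selection analytics: resolution, efficacy scaling, attenuation
and the ophthalmic power budget.

Four small pure functions trade off against each other when picking a
stimulation frequency:

- diffraction-limited focal width  D_l = K * lambda * F#  (shrinks with f);
- the bilayer-sonophore efficacy proxy, maximal areal membrane strain
  eps_max ~ P_A * f^(-beta), so holding efficacy constant requires the
  negative peak pressure to grow like f^beta (beta in 0.8-0.9);
- power-law tissue attenuation a(f) = a0 * f^gamma in dB/cm (gamma 1.0-1.9);
- the ophthalmic intensity ceiling (50 mW/cm^2) times the stimulated area,
  which caps total acoustic power.

All functions are deterministic and side-effect free.  dB per cm, MHz and
mm conventions are stated per function.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DoseParams",
    "fwhm_resolution",
    "required_pressure_ratio",
    "attenuation_db",
    "attenuation_np_per_mm",
    "calibrate_a0_to_lens",
    "safety_power_budget",
]

_NP_PER_DB = np.log(10.0) / 20.0


@dataclass(frozen=True)
class DoseParams:
    """Knobs of the frequency-selection trade-off.

    K is the aperture-shape constant of the diffraction limit (~1),
    f_number the focal depth over aperture, beta the sonophore strain
    exponent, (a0, gamma) the attenuation power law, and intensity_limit
    the regulatory ceiling for the eye in mW/cm^2.
    """

    K: float = 1.0
    f_number: float = 1.0
    beta: float = 0.85
    a0: float = 0.1          # dB/cm at 1 MHz
    gamma: float = 1.2
    intensity_limit: float = 50.0  # mW/cm^2

    def __post_init__(self) -> None:
        if min(self.K, self.f_number, self.intensity_limit) <= 0:
            raise ValueError("K, f_number and intensity_limit must be positive")
        if not (0.8 <= self.beta <= 0.9):
            raise ValueError("beta outside its empirical 0.8-0.9 range")
        if self.a0 < 0:
            raise ValueError("a0 must be >= 0")
        if not (1.0 <= self.gamma <= 1.9):
            raise ValueError("gamma outside the physical 1.0-1.9 range")


def fwhm_resolution(frequency_mhz: float, params: DoseParams, medium) -> float:
    """Diffraction-limited focal width D_l = K * (v/f) * F# in mm."""
    if frequency_mhz <= 0:
        raise ValueError("frequency must be positive")
    wavelength_mm = medium.sound_speed / frequency_mhz / 1000.0
    return params.K * wavelength_mm * params.f_number


def required_pressure_ratio(f1_mhz: float, f2_mhz: float, params: DoseParams) -> float:
    """Factor by which peak pressure must grow from f1 to f2 at equal efficacy.

    Under eps_max ~ P_A * f^(-beta), constant membrane strain requires
    P_A(f2)/P_A(f1) = (f2/f1)^beta.  The exponent convention is a module
    constant here; alternative readings (beta/2, 1/(2 beta)) can be derived
    from the returned ratio by the caller.
    """
    if f1_mhz <= 0 or f2_mhz <= 0:
        raise ValueError("frequencies must be positive")
    return (f2_mhz / f1_mhz) ** params.beta


def attenuation_db(frequency_mhz: float, path_cm: float, params: DoseParams) -> float:
    """Total loss a0 * f^gamma * path in dB over ``path_cm`` of tissue."""
    if frequency_mhz <= 0 or path_cm <= 0:
        raise ValueError("frequency and path must be positive")
    return params.a0 * frequency_mhz**params.gamma * path_cm


def attenuation_np_per_mm(frequency_mhz: float, a0: float, gamma: float) -> float:
    """Amplitude attenuation coefficient in Np/mm for the forward model."""
    db_per_cm = a0 * frequency_mhz**gamma
    return db_per_cm * _NP_PER_DB / 10.0


def calibrate_a0_to_lens(
    gamma: float, path_cm: float, loss_db: float = 7.8, at_mhz: float = 10.0
) -> float:
    """a0 such that the power law reproduces a measured loss.

    The crystalline lens of the human eye absorbs about 7.8 dB at 10 MHz;
    given the lens path length this pins a0 for a chosen gamma.
    """
    if path_cm <= 0:
        raise ValueError("path must be positive")
    return loss_db / (at_mhz**gamma * path_cm)


def safety_power_budget(
    pattern_side_mm: float,
    params: DoseParams,
    stated_budget_mw: float | None = None,
) -> dict:
    """Maximum acoustic power deliverable to a square stimulation pattern.

    area[cm^2] = (side/10)^2 and max power = intensity_limit * area.  When a
    stated budget is supplied, the record carries a pass/fail check against
    it plus the intensity that budget would imply over the same area, so an
    inconsistent stated figure is flagged rather than silently accepted.
    """
    if pattern_side_mm <= 0:
        raise ValueError("pattern side must be positive")
    area_cm2 = (pattern_side_mm / 10.0) ** 2
    max_power_mw = params.intensity_limit * area_cm2
    record = {
        "pattern_side_mm": pattern_side_mm,
        "area_cm2": area_cm2,
        "intensity_limit_mw_per_cm2": params.intensity_limit,
        "max_power_mw": max_power_mw,
    }
    if stated_budget_mw is not None:
        implied = stated_budget_mw / area_cm2
        record.update(
            stated_budget_mw=stated_budget_mw,
            within_stated_budget=bool(max_power_mw <= stated_budget_mw),
            implied_intensity_mw_per_cm2=implied,
            stated_budget_consistent=bool(
                np.isclose(implied, params.intensity_limit, rtol=0.05)
            ),
        )
    return record
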