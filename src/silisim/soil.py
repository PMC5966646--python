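"""Bioavailable Si(OH)4 in the soil solution.

Availability of orthosilicic acid in soil pore water is modelled as the
product of three response factors — a cubic in soil temperature, a
Michaelis-Menten term in organic-matter content, and a cubic in pH —
scaling the gap between the irrigation-water contribution and the
polymerization ceiling:

    SiAv = (SiP - SiWater) * ETem * EOM * EpH + SiWater

The raw cubics go negative outside roughly 8.6-31.5 degC and above pH 9.1,
and the pH cubic slightly exceeds 1 near its optimum (~6.8), so the factors
are clamped to physical ranges; the raw polynomials are available via the
``clamp=False`` escape hatch for inspection.  Per-area availability (mg m^-2)
multiplies the solution concentration by the water volume held in the
managed soil profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class AvailabilityParams:
    """Coefficients of the availability response functions (printed defaults).

    ``temp_coeffs`` and ``ph_coeffs`` are cubic coefficients ordered from
    degree 3 down to the constant term.  ``km`` is the organic-matter
    half-saturation constant (% w/w), ``vmax`` the organic-matter plateau,
    and ``si_max`` the polymerization ceiling in mg L^-1 Si(OH)4.
    """

    temp_coeffs: tuple[float, float, float, float] = (-0.0003, 0.0127, -0.1093, 0.1674)
    ph_coeffs: tuple[float, float, float, float] = (-0.0235, 0.325, -1.1563, 1.2262)
    vmax: float = 1.0
    km: float = 2.5
    si_max: float = 192.18

    def __post_init__(self) -> None:
        if not self.km > 0:
            raise ValidationError(f"km must be > 0, got {self.km}")
        if not self.vmax > 0:
            raise ValidationError(f"vmax must be > 0, got {self.vmax}")
        if not self.si_max > 0:
            raise ValidationError(f"si_max must be > 0, got {self.si_max}")


@dataclass(frozen=True)
class SoilState:
    """Edaphic state governing Si(OH)4 availability.

    Parameters
    ----------
    ph : float
        Soil pore-water pH (meaningful range 2-9).
    om : float
        Organic-matter content, % w/w, >= 0.
    temperature : float
        0-30 cm soil temperature, degC.
    profile_depth : float
        Managed profile depth, m.
    moisture : float
        Gravimetric water content, fraction w/w in (0, 1).
    bulk_density : float
        Dry bulk density, kg m^-3.
    si_water : float
        Si(OH)4 in irrigation water, mg L^-1.
    """

    ph: float
    om: float
    temperature: float
    profile_depth: float = 0.30
    moisture: float = 0.25
    bulk_density: float = 1200.0
    si_water: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.ph):
            raise ValidationError(f"ph must be finite, got {self.ph}")
        if not self.om >= 0:
            raise ValidationError(f"om must be >= 0, got {self.om}")
        if not np.isfinite(self.temperature):
            raise ValidationError(f"temperature must be finite, got {self.temperature}")
        if not self.profile_depth > 0:
            raise ValidationError(
                f"profile_depth must be > 0, got {self.profile_depth}"
            )
        if not 0 <= self.moisture < 1:
            raise ValidationError(f"moisture must be in [0, 1), got {self.moisture}")
        if not self.bulk_density > 0:
            raise ValidationError(
                f"bulk_density must be > 0, got {self.bulk_density}"
            )
        if not self.si_water >= 0:
            raise ValidationError(f"si_water must be >= 0, got {self.si_water}")


def temperature_effect(
    temp: float,
    params: AvailabilityParams = AvailabilityParams(),
    *,
    clamp: bool = True,
) -> float:
    """Temperature response factor, cubic clamped to >= 0."""
    raw = float(np.polyval(params.temp_coeffs, temp))
    return max(raw, 0.0) if clamp else raw


def om_effect(om: float, params: AvailabilityParams = AvailabilityParams()) -> float:
    """Organic-matter response, Michaelis-Menten: vmax * om / (km + om)."""
    if om < 0:
        raise ValidationError(f"om must be >= 0, got {om}")
    return params.vmax * om / (params.km + om)


def ph_effect(
    ph: float,
    params: AvailabilityParams = AvailabilityParams(),
    *,
    clamp: bool = True,
) -> float:
    """pH response factor, cubic clamped to [0, 1]."""
    raw = float(np.polyval(params.ph_coeffs, ph))
    return min(max(raw, 0.0), 1.0) if clamp else raw


def soil_si_contribution(
    soil: SoilState, params: AvailabilityParams = AvailabilityParams()
) -> float:
    """Soil-derived term of the availability equation, mg L^-1 Si(OH)4.

    (si_max - si_water) * ETem * EOM * EpH — the availability excluding the
    additive irrigation-water floor.
    """
    if soil.si_water > params.si_max:
        raise ValidationError(
            f"si_water ({soil.si_water}) exceeds si_max ({params.si_max})"
        )
    return (
        (params.si_max - soil.si_water)
        * temperature_effect(soil.temperature, params)
        * om_effect(soil.om, params)
        * ph_effect(soil.ph, params)
    )


def available_si(
    soil: SoilState, params: AvailabilityParams = AvailabilityParams()
) -> float:
    """Bioavailable Si(OH)4 in the soil solution, mg L^-1.

    Always within [si_water, si_max]; capped at si_max by construction and
    by an explicit guard.
    """
    value = soil_si_contribution(soil, params) + soil.si_water
    return min(value, params.si_max)


def soil_water_volume(soil: SoilState) -> float:
    """Litres of soil water per m^2 of ground in the managed profile.

    profile_depth [m] x bulk_density [kg m^-3] x moisture [w/w]; 1 kg of
    water is taken as 1 L.
    """
    return soil.profile_depth * soil.bulk_density * soil.moisture


def areal_availability(
    soil: SoilState, params: AvailabilityParams = AvailabilityParams()
) -> float:
    """Per-ground-area availability, mg Si(OH)4 per m^2."""
    return available_si(soil, params) * soil_water_volume(soil)


def availability_grid(
    ph_values,
    om_values,
    temperature: float,
    soil_defaults: SoilState | None = None,
    params: AvailabilityParams = AvailabilityParams(),
) -> pd.DataFrame:
    """Areal availability (mg m^-2) on a pH x OM grid at fixed temperature.

    Returns a DataFrame with pH as the row index and OM (% w/w) as columns.
    Non-coordinate soil properties (depth, moisture, bulk density, si_water)
    are taken from *soil_defaults* when given.
    """
    ph_values = np.asarray(ph_values, dtype=float)
    om_values = np.asarray(om_values, dtype=float)
    if ph_values.size == 0 or om_values.size == 0:
        raise ValidationError("availability_grid requires non-empty coordinate axes")
    for name, axis in (("ph", ph_values), ("om", om_values)):
        if axis.size > 1 and not (np.all(np.diff(axis) > 0) or np.all(np.diff(axis) < 0)):
            raise ValidationError(f"{name} axis must be strictly monotone")
    base = soil_defaults or SoilState(ph=7.0, om=0.0, temperature=temperature)
    values = np.empty((ph_values.size, om_values.size))
    for i, ph in enumerate(ph_values):
        for j, om in enumerate(om_values):
            soil = SoilState(
                ph=float(ph),
                om=float(om),
                temperature=temperature,
                profile_depth=base.profile_depth,
                moisture=base.moisture,
                bulk_density=base.bulk_density,
                si_water=base.si_water,
            )
            values[i, j] = areal_availability(soil, params)
    frame = pd.DataFrame(values, index=ph_values, columns=om_values)
    frame.index.name = "ph"
    frame.columns.name = "om_pct"
    return frame
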