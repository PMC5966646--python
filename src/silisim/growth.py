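"""Dry-biomass dynamics and transpiration for a greenhouse tomato crop.

Transpiration is the linear function of standing dry biomass

    rate [L m^-2 s^-1] = biomass [g m^-2] * plm / tcg

with plm = 8.5714 and tcg = 10279801 s (the season length).  Biomass
dynamics sit behind a small ``GrowthDriver`` protocol so the uptake and
simulation machinery never depend on a particular growth formulation; the
default :class:`CanopyGrowthDriver` is a reduced canopy model,

    dB/dt = rue * PAR * f_CO2 * f_T * intercept(B) * (1 - B / Bmax(Tair))

i.e. light-limited potential growth shaped by a saturating CO2 response, a
trapezoidal temperature-suitability window, a canopy-closure light
interception factor B/(B + canopy_half), and a logistic ceiling whose
asymptote shrinks at cool air temperature.  ``rue`` is calibrated so that
the reference scenario (PAR 400 umol m^-2 s^-1 for 12 h/day, CO2 400 ppm,
air 30 degC, density 3 plants m^-2) ends the season near 1370 g dry mass
per plant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol

import numpy as np

from .errors import ValidationError

ORGANS = ("leaf", "stem", "fruit", "root")

#: Organ biomass partition anchors (fractions of total dry mass) at the two
#: air-temperature regimes the model distinguishes; linear interpolation in
#: between, constant outside.
PARTITION_ANCHORS: dict[float, dict[str, float]] = {
    20.0: {"leaf": 0.33, "stem": 0.24, "fruit": 0.33, "root": 0.10},
    30.0: {"leaf": 0.09, "stem": 0.21, "fruit": 0.60, "root": 0.10},
}

#: Ratio of the biomass asymptote at 20 degC to that at 30 degC (2240/3000).
_ASYMPTOTE_ANCHORS = ((20.0, 2240.0 / 3000.0), (30.0, 1.0))

#: Radiation-use coefficient of the default driver, g dry mass per
#: (umol photons m^-2): calibrated against the 1370 g plant^-1 reference
#: season (see scripts in the repository history).
DEFAULT_RUE = 1.397447028077309e-05


@dataclass(frozen=True)
class GrowthParams:
    """Transpiration constants plus default-driver coefficients."""

    plm: float = 8.5714
    tcg: float = 10279801.0
    planting_density: float = 3.0
    # --- default CanopyGrowthDriver coefficients ---
    rue: float = DEFAULT_RUE
    co2_half: float = 300.0  # uL L^-1, CO2 half-saturation
    canopy_half: float = 1200.0  # g m^-2, biomass at half light interception
    bmax_ref: float = 7000.0  # g m^-2, asymptote at >= 30 degC
    initial_biomass: float = 2.0  # g m^-2 at transplant
    temp_window: tuple[float, float, float, float] = (0.0, 10.0, 35.0, 45.0)

    def __post_init__(self) -> None:
        if not self.tcg > 0:
            raise ValidationError(f"tcg must be > 0, got {self.tcg}")
        if not self.planting_density > 0:
            raise ValidationError(
                f"planting_density must be > 0, got {self.planting_density}"
            )
        for name in ("rue", "co2_half", "canopy_half", "bmax_ref"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if not self.initial_biomass >= 0:
            raise ValidationError("initial_biomass must be >= 0")
        lo0, lo1, hi1, hi0 = self.temp_window
        if not (lo0 <= lo1 <= hi1 <= hi0):
            raise ValidationError(f"temp_window must be ordered, got {self.temp_window}")


@dataclass(frozen=True)
class EnvSample:
    """One environment reading: PAR, air temperature, CO2."""

    par: float
    tair: float
    co2: float


@dataclass(frozen=True)
class PlantState:
    """Standing crop state on a per-ground-area basis."""

    biomass_total: float  # g dry m^-2
    organ_biomass: Mapping[str, float]  # g dry m^-2 per organ
    cumulative_transpiration: float = 0.0  # L m^-2

    def __post_init__(self) -> None:
        if self.biomass_total < 0:
            raise ValidationError("biomass_total must be >= 0")
        if set(self.organ_biomass) != set(ORGANS):
            raise ValidationError(f"organ_biomass must have keys {ORGANS}")
        total = sum(self.organ_biomass.values())
        if self.biomass_total > 0 and abs(total - self.biomass_total) > 1e-9 * self.biomass_total:
            raise ValidationError(
                f"organ biomass sums to {total}, expected {self.biomass_total}"
            )


def partition_fractions(
    tair: float, params: GrowthParams = GrowthParams()
) -> dict[str, float]:
    """Organ dry-mass fractions at air temperature *tair* (sum exactly 1).

    Linear interpolation between the 20 and 30 degC anchor regimes,
    constant outside that interval.
    """
    (t_lo, lo), (t_hi, hi) = sorted(PARTITION_ANCHORS.items())
    w = float(np.clip((tair - t_lo) / (t_hi - t_lo), 0.0, 1.0))
    fractions = {organ: (1 - w) * lo[organ] + w * hi[organ] for organ in ORGANS}
    # force exact unit sum; the residual lands on the root fraction
    fractions["root"] = 1.0 - sum(fractions[o] for o in ORGANS if o != "root")
    return fractions


def transpiration_rate(
    biomass_total: float, params: GrowthParams = GrowthParams()
) -> float:
    """Instantaneous water flux, L m^-2 s^-1, linear in standing biomass."""
    if biomass_total < 0:
        raise ValidationError("biomass_total must be >= 0")
    return biomass_total * params.plm / params.tcg


def co2_factor(co2: float, params: GrowthParams = GrowthParams()) -> float:
    """Saturating CO2 response, co2 / (co2_half + co2), in [0, 1)."""
    if co2 <= 0:
        raise ValidationError(f"co2 must be > 0, got {co2}")
    return co2 / (params.co2_half + co2)


def temperature_suitability(tair: float, params: GrowthParams = GrowthParams()) -> float:
    """Trapezoidal growth suitability: 0 outside the window, 1 on its plateau."""
    lo0, lo1, hi1, hi0 = params.temp_window
    if tair <= lo0 or tair >= hi0:
        return 0.0
    if tair < lo1:
        return (tair - lo0) / (lo1 - lo0)
    if tair > hi1:
        return (hi0 - tair) / (hi0 - hi1)
    return 1.0


def biomass_asymptote(tair: float, params: GrowthParams = GrowthParams()) -> float:
    """Season biomass ceiling, g m^-2, reduced at cool air temperature."""
    (t_lo, s_lo), (t_hi, s_hi) = _ASYMPTOTE_ANCHORS
    w = float(np.clip((tair - t_lo) / (t_hi - t_lo), 0.0, 1.0))
    return params.bmax_ref * ((1 - w) * s_lo + w * s_hi)


class GrowthDriver(Protocol):
    """Contract every biomass driver satisfies: state, env sample, dt -> state."""

    def initial_state(self, params: GrowthParams) -> PlantState: ...

    def step(
        self, state: PlantState, env: EnvSample, dt: float, params: GrowthParams
    ) -> PlantState: ...


class CanopyGrowthDriver:
    """Default reduced canopy growth model (see module docstring)."""

    def initial_state(self, params: GrowthParams) -> PlantState:
        b0 = params.initial_biomass
        fractions = partition_fractions(20.0, params)
        return PlantState(
            biomass_total=b0,
            organ_biomass={o: f * b0 for o, f in fractions.items()},
        )

    def step(
        self, state: PlantState, env: EnvSample, dt: float, params: GrowthParams
    ) -> PlantState:
        if dt <= 0:
            raise ValidationError(f"dt must be > 0, got {dt}")
        b = state.biomass_total
        bmax = biomass_asymptote(env.tair, params)
        potential = (
            params.rue
            * env.par
            * co2_factor(env.co2, params)
            * temperature_suitability(env.tair, params)
        )
        interception = b / (b + params.canopy_half)
        headroom = max(0.0, 1.0 - b / bmax)
        b_new = b + potential * interception * headroom * dt
        fractions = partition_fractions(env.tair, params)
        return PlantState(
            biomass_total=b_new,
            organ_biomass={o: f * b_new for o, f in fractions.items()},
            cumulative_transpiration=state.cumulative_transpiration,
        )


class ConstantBiomassDriver:
    """Stub driver holding biomass fixed; for tests of driver-independence."""

    def __init__(self, biomass_total: float, tair: float = 25.0):
        self._biomass = biomass_total
        self._tair = tair

    def initial_state(self, params: GrowthParams) -> PlantState:
        fractions = partition_fractions(self._tair, params)
        return PlantState(
            biomass_total=self._biomass,
            organ_biomass={o: f * self._biomass for o, f in fractions.items()},
        )

    def step(
        self, state: PlantState, env: EnvSample, dt: float, params: GrowthParams
    ) -> PlantState:
        return state


def growth_step(
    state: PlantState,
    env: EnvSample,
    dt: float,
    params: GrowthParams = GrowthParams(),
    driver: GrowthDriver | None = None,
) -> PlantState:
    """Advance the plant one timestep with *driver* (default canopy model)."""
    driver = driver if driver is not None else CanopyGrowthDriver()
    return driver.step(state, env, dt, params)
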