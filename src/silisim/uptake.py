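"""Silicon accumulation bookkeeping.

Per timestep the plant takes up

    increment = concentration [mg L^-1 Si(OH)4] * transpired volume [L m^-2] * SiSi

re-expressed as SiO2 mass (the form silicon is deposited and reported in),
subject to the running capacity 1% of standing dry biomass.  The truncated
increment is split across organs by their share of whole-plant
transpiration (leaf 90%, stem 5%, fruit 2.5%, root 2.5%); deposited silica
is never remobilized, so the account only grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from . import chem
from .errors import ConfigError, ValidationError
from .growth import ORGANS

#: Organ shares of whole-plant transpiration.
DEFAULT_ORGAN_FRACTIONS: Mapping[str, float] = MappingProxyType(
    {"leaf": 0.90, "stem": 0.05, "fruit": 0.025, "root": 0.025}
)


def _default_organ_fractions() -> Mapping[str, float]:
    return DEFAULT_ORGAN_FRACTIONS


@dataclass(frozen=True)
class UptakeParams:
    """Uptake fraction, saturation limit, and organ transpiration shares."""

    si_si: float = 1.0  # fraction of stream Si retained by the plant
    max_si_fraction: float = 0.01  # SiO2 cap as a fraction of dry biomass
    organ_fractions: Mapping[str, float] = field(
        default_factory=_default_organ_fractions
    )
    planting_density: float = 3.0  # plants m^-2

    def __post_init__(self) -> None:
        if not 0 <= self.si_si <= 1:
            raise ValidationError(f"si_si must be in [0, 1], got {self.si_si}")
        if not 0 < self.max_si_fraction <= 1:
            raise ValidationError(
                f"max_si_fraction must be in (0, 1], got {self.max_si_fraction}"
            )
        if not self.planting_density > 0:
            raise ValidationError("planting_density must be > 0")
        if set(self.organ_fractions) != set(ORGANS):
            raise ConfigError(f"organ_fractions must have keys {ORGANS}")
        if any(v < 0 for v in self.organ_fractions.values()):
            raise ConfigError("organ_fractions must be >= 0")
        total = sum(self.organ_fractions.values())
        if total != 1.0:
            raise ConfigError(f"organ_fractions must sum to exactly 1, got {total}")


def _zero_organs() -> Mapping[str, float]:
    return {organ: 0.0 for organ in ORGANS}


@dataclass(frozen=True)
class SiAccount:
    """Accumulated Si as grams of SiO2 per m^2 of ground, total and per organ."""

    total_si: float = 0.0
    organ_si: Mapping[str, float] = field(default_factory=_zero_organs)

    def __post_init__(self) -> None:
        if self.total_si < 0 or any(v < 0 for v in self.organ_si.values()):
            raise ValidationError("Si masses must be >= 0")
        if set(self.organ_si) != set(ORGANS):
            raise ValidationError(f"organ_si must have keys {ORGANS}")
        organ_sum = sum(self.organ_si.values())
        if abs(organ_sum - self.total_si) > 1e-9 * max(self.total_si, 1e-300):
            raise ValidationError(
                f"organ_si sums to {organ_sum}, expected total {self.total_si}"
            )


def max_si_capacity(
    biomass_total: float, params: UptakeParams = UptakeParams()
) -> float:
    """Saturation limit, g SiO2 m^-2: 1% of standing dry biomass.

    Divide by ``params.planting_density`` for the per-plant figure.
    """
    if biomass_total < 0:
        raise ValidationError("biomass_total must be >= 0")
    return params.max_si_fraction * biomass_total


def allocate_organs(
    increment: float, params: UptakeParams = UptakeParams()
) -> dict[str, float]:
    """Split an uptake increment across organs by transpiration share.

    Shares sum to the increment exactly: the root share (the smallest)
    absorbs the floating-point residual, which Sterbenz subtraction makes
    exact under left-to-right summation.
    """
    if increment < 0:
        raise ValidationError(f"increment must be >= 0, got {increment}")
    shares = {o: params.organ_fractions[o] * increment for o in ORGANS if o != "root"}
    partial = 0.0
    for o in ORGANS:
        if o != "root":
            partial += shares[o]
    residual = increment - partial
    shares["root"] = residual if residual > 0.0 else 0.0
    return {o: shares[o] for o in ORGANS}


def uptake_step(
    account: SiAccount,
    si_concentration: float,
    transpired_volume: float,
    cap: float,
    params: UptakeParams = UptakeParams(),
) -> SiAccount:
    """Advance the Si account by one uptake increment, truncated at *cap*.

    Parameters
    ----------
    si_concentration : float
        Source concentration, mg L^-1 Si(OH)4 — soil-solution availability
        in soil mode, irrigation-water content in soilless mode.
    transpired_volume : float
        Water transpired during the step, L m^-2.
    cap : float
        Current saturation limit, g SiO2 m^-2.
    """
    for name, value in (
        ("si_concentration", si_concentration),
        ("transpired_volume", transpired_volume),
        ("cap", cap),
    ):
        if value < 0:
            raise ValidationError(f"{name} must be >= 0, got {value}")
    as_sio2 = chem.convert(
        chem.Concentration(si_concentration, chem.Unit.MG_PER_L, chem.SIOH4),
        chem.Unit.MG_PER_L,
        chem.SIO2,
    ).value
    increment = as_sio2 * transpired_volume * params.si_si / 1000.0  # mg -> g
    headroom = max(0.0, cap - account.total_si)
    actual = min(increment, headroom)
    shares = allocate_organs(actual, params)
    organ_si = {o: account.organ_si[o] + shares[o] for o in ORGANS}
    return SiAccount(total_si=account.total_si + actual, organ_si=organ_si)


def si_concentration_pct(account: SiAccount, biomass_total: float) -> float:
    """Whole-plant Si concentration, % of dry mass as SiO2."""
    if biomass_total <= 0:
        raise ValidationError(
            "Si concentration is undefined for non-positive biomass"
        )
    return 100.0 * account.total_si / biomass_total
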