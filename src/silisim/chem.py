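"""Silicate species, concentration value objects, and unit conversions.

Concentrations of silicon are reported interchangeably in the literature as
elemental Si, orthosilicic acid Si(OH)4, silica SiO2, or a fertilizer salt
such as sodium metasilicate — all on either a molar or a mass basis.  Mixing
these up is a classic source of error, so no bare number crosses a module
boundary: every concentration carries its unit and species, and conversions
conserve moles of Si.

>>> c = Concentration(1.8, Unit.MM, SIOH4)
>>> round(convert(c, Unit.MG_PER_L, SIOH4).value, 1)
173.0
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .errors import UnsupportedSpeciesError, ValidationError

#: Standard atomic masses, g mol^-1.
ATOMIC_MASS = {
    "Si": 28.086,
    "O": 15.999,
    "H": 1.008,
    "Na": 22.990,
}


@dataclass(frozen=True)
class SiSpecies:
    """A silicon-bearing chemical species.

    Parameters
    ----------
    name : str
        Canonical identifier, e.g. ``"SiOH4"``.
    molar_mass : float
        Formula mass in g mol^-1.
    si_atoms : int
        Number of Si atoms per formula unit.
    """

    name: str
    molar_mass: float
    si_atoms: int = 1

    def __post_init__(self) -> None:
        if not self.molar_mass > 0:
            raise ValidationError(f"molar_mass must be > 0, got {self.molar_mass}")
        if self.si_atoms < 1:
            raise ValidationError(f"si_atoms must be >= 1, got {self.si_atoms}")

    @property
    def si_mass_fraction(self) -> float:
        """Mass fraction of elemental Si in the formula, in (0, 1]."""
        return self.si_atoms * ATOMIC_MASS["Si"] / self.molar_mass


def _mass(formula: dict[str, int]) -> float:
    return sum(ATOMIC_MASS[el] * n for el, n in formula.items())


SI = SiSpecies("Si", ATOMIC_MASS["Si"])
SIOH4 = SiSpecies("SiOH4", _mass({"Si": 1, "O": 4, "H": 4}))
SIO2 = SiSpecies("SiO2", _mass({"Si": 1, "O": 2}))
NA2SIO3 = SiSpecies("Na2SiO3", _mass({"Na": 2, "Si": 1, "O": 3}))

#: Supported species by canonical name (case-insensitive lookup via get_species).
SPECIES: dict[str, SiSpecies] = {s.name: s for s in (SI, SIOH4, SIO2, NA2SIO3)}

_ALIASES = {
    "si": "Si",
    "sioh4": "SiOH4",
    "si(oh)4": "SiOH4",
    "sio2": "SiO2",
    "na2sio3": "Na2SiO3",
}

#: Mass ratio SiO2 : Si(OH)4 used when booking uptake of orthosilicic acid
#: as silica (both carry one Si per formula).
SIO2_PER_SIOH4 = SIO2.molar_mass / SIOH4.molar_mass


def get_species(name: str | SiSpecies) -> SiSpecies:
    """Resolve a species by name (aliases like ``"Si(OH)4"`` accepted)."""
    if isinstance(name, SiSpecies):
        return name
    key = _ALIASES.get(str(name).strip().lower())
    if key is None:
        raise UnsupportedSpeciesError(
            f"unsupported species {name!r}; supported: {sorted(SPECIES)}"
        )
    return SPECIES[key]


class Unit(str, enum.Enum):
    """Concentration units: millimolar or mass per litre."""

    MM = "mM"
    MG_PER_L = "mg_per_L"


def get_unit(unit: str | Unit) -> Unit:
    if isinstance(unit, Unit):
        return unit
    key = str(unit).strip().lower().replace("/", "_per_").replace(" ", "")
    for u in Unit:
        if u.value.lower() == key:
            return u
    raise ValidationError(f"unsupported unit {unit!r}; supported: mM, mg_per_L")


@dataclass(frozen=True)
class Concentration:
    """A non-negative concentration bound to its unit and species."""

    value: float
    unit: Unit
    species: SiSpecies

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value < 0:
            raise ValidationError(
                f"concentration must be finite and >= 0, got {self.value}"
            )
        object.__setattr__(self, "unit", get_unit(self.unit))
        object.__setattr__(self, "species", get_species(self.species))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        unit = "mM" if self.unit is Unit.MM else "mg L^-1"
        return f"{self.value:g} {unit} {self.species.name}"


def si_millimolar(conc: Concentration) -> float:
    """Millimoles of elemental Si per litre carried by *conc*."""
    if conc.unit is Unit.MM:
        species_mm = conc.value
    else:
        species_mm = conc.value / conc.species.molar_mass
    return species_mm * conc.species.si_atoms


def convert(
    conc: Concentration,
    target_unit: str | Unit,
    target_species: str | SiSpecies | None = None,
) -> Concentration:
    """Re-express *conc* in another unit and/or as another species.

    The conversion conserves moles of Si: expressing a solution of one
    species "as" another answers the question *what concentration of the
    target species carries the same amount of silicon*.
    """
    target_unit = get_unit(target_unit)
    species = conc.species if target_species is None else get_species(target_species)
    si_mm = si_millimolar(conc)
    species_mm = si_mm / species.si_atoms
    if target_unit is Unit.MM:
        value = species_mm
    else:
        value = species_mm * species.molar_mass
    return Concentration(value, target_unit, species)


class PolymerizationStatus(str, enum.Enum):
    SOLUBLE = "soluble"
    AT_THRESHOLD = "at_threshold"
    POLYMERIZING = "polymerizing"


#: Si(OH)4 stays fully soluble below this molarity (mM).
SOLUBILITY_LIMIT_MM = 1.8
#: At and above this molarity (mM) Si(OH)4 condenses into amorphous silica
#: polymers that plants cannot take up.
POLYMERIZATION_LIMIT_MM = 2.0


def polymerization_status(conc: Concentration) -> PolymerizationStatus:
    """Classify an orthosilicic-acid solution against the solubility limits.

    Raises
    ------
    ValidationError
        If *conc* is not expressed as Si(OH)4.
    """
    if conc.species != SIOH4:
        raise ValidationError(
            f"polymerization_status requires Si(OH)4, got {conc.species.name}"
        )
    mm = convert(conc, Unit.MM).value
    eps = 1e-9  # absorb unit-conversion round-off at the printed thresholds
    if mm < SOLUBILITY_LIMIT_MM * (1 - eps):
        return PolymerizationStatus.SOLUBLE
    if mm < POLYMERIZATION_LIMIT_MM * (1 - eps):
        return PolymerizationStatus.AT_THRESHOLD
    return PolymerizationStatus.POLYMERIZING
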