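"""Season simulation: growth, transpiration, and Si uptake composed.

Each explicit-Euler step (default dt = 1800 s) advances biomass with the
configured growth driver, converts the transpiration rate of the updated
canopy into a water volume, draws Si(OH)4 at the mode's source
concentration — the edaphic availability in soil mode, the irrigation-water
content in soilless mode — and books the uptake against the running 1%
SiO2 cap.  Soil availability is treated as non-depleting: the source
concentration is re-evaluated from the static soil state, never drawn down.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .envgen import Environment, EnvSpec, generate_environment
from .errors import ConfigError, CoverageError, ValidationError
from .growth import (
    ORGANS,
    CanopyGrowthDriver,
    GrowthDriver,
    GrowthParams,
    PlantState,
    transpiration_rate,
)
from .soil import AvailabilityParams, SoilState, areal_availability, available_si
from .uptake import SiAccount, UptakeParams, max_si_capacity, uptake_step

MODES = ("soil", "soilless")

#: Default season: the crop-growth time tcg truncated down to a whole
#: number of 1800 s steps (tcg itself is 10279801 s, not a multiple).
DEFAULT_SEASON_S = 10279800.0
DEFAULT_DT_S = 1800.0

#: Cartesian-size guard for scenario sweeps.
DEFAULT_GRID_LIMIT = 4096


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to run one season (environment supplied separately)."""

    mode: str
    si_water: float = 0.0  # mg L^-1 Si(OH)4 in irrigation water
    soil: SoilState | None = None  # required in soil mode
    season_length: float = DEFAULT_SEASON_S
    dt: float = DEFAULT_DT_S
    mulch_offset: float = 0.0  # degC added to soil temperature
    growth: GrowthParams = GrowthParams()
    uptake: UptakeParams = UptakeParams()
    availability: AvailabilityParams = AvailabilityParams()

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.si_water < 0:
            raise ConfigError(f"si_water must be >= 0, got {self.si_water}")
        if self.dt <= 0:
            raise ConfigError(f"dt must be > 0, got {self.dt}")
        steps = self.season_length / self.dt
        if self.season_length <= 0 or abs(steps - round(steps)) > 1e-9:
            raise ConfigError(
                f"dt={self.dt} must divide season_length={self.season_length}"
            )
        if self.mode == "soil" and self.soil is None:
            raise ConfigError("soil mode requires a soil state")
        if not self.mulch_offset >= 0:
            raise ConfigError("mulch_offset must be >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.season_length / self.dt))

    def effective_soil(self) -> SoilState:
        """Soil state with the mulch temperature offset applied."""
        if self.soil is None:
            raise ConfigError("no soil state in soilless mode")
        soil = replace(
            self.soil,
            temperature=self.soil.temperature + self.mulch_offset,
            si_water=self.si_water,
        )
        return soil

    def source_concentration(self) -> float:
        """Si(OH)4 concentration (mg L^-1) feeding uptake for this mode."""
        if self.mode == "soil":
            return available_si(self.effective_soil(), self.availability)
        return self.si_water

    def to_dict(self) -> dict[str, Any]:
        """JSON-serializable snapshot of the full configuration."""

        def plain(obj: Any) -> Any:
            if hasattr(obj, "__dataclass_fields__"):
                return {
                    k: plain(getattr(obj, k)) for k in obj.__dataclass_fields__
                }
            if isinstance(obj, Mapping):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return plain(self)

    def digest(self) -> str:
        """Stable hash of the configuration snapshot."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass(frozen=True)
class SimulationResult:
    """Time-indexed trajectories of one season (index 0 is the initial state)."""

    time: np.ndarray  # s
    biomass_total: np.ndarray  # g dry m^-2
    organ_biomass: Mapping[str, np.ndarray]  # g dry m^-2
    transpiration: np.ndarray  # L m^-2 s^-1
    cumulative_transpiration: np.ndarray  # L m^-2
    si_available: np.ndarray  # mg L^-1 Si(OH)4 source concentration
    si_total: np.ndarray  # g SiO2 m^-2
    organ_si: Mapping[str, np.ndarray]  # g SiO2 m^-2
    si_concentration_pct: np.ndarray  # % of dry mass as SiO2
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.time.size)

    def summary(self) -> dict[str, float]:
        """Final-state summary with per-plant figures via planting density."""
        pd_ = float(self.metadata.get("planting_density", 1.0))
        out = {
            "final_biomass_total_g_m2": float(self.biomass_total[-1]),
            "final_biomass_per_plant_g": float(self.biomass_total[-1]) / pd_,
            "cumulative_transpiration_l_m2": float(self.cumulative_transpiration[-1]),
            "final_si_total_g_m2": float(self.si_total[-1]),
            "final_si_per_plant_g": float(self.si_total[-1]) / pd_,
            "final_si_concentration_pct": float(self.si_concentration_pct[-1]),
            "max_si_concentration_pct": float(np.max(self.si_concentration_pct)),
            "source_si_mg_l": float(self.si_available[-1]),
        }
        for organ in ORGANS:
            out[f"final_si_{organ}_g_m2"] = float(self.organ_si[organ][-1])
            out[f"final_biomass_{organ}_g_m2"] = float(self.organ_biomass[organ][-1])
        if "areal_availability_mg_m2" in self.metadata:
            out["areal_availability_mg_m2"] = float(
                self.metadata["areal_availability_mg_m2"]
            )
        return out


def run_simulation(
    config: SimulationConfig,
    environment: Environment,
    driver: GrowthDriver | None = None,
) -> SimulationResult:
    """Run one season and record full trajectories.

    Raises
    ------
    CoverageError
        If the environment series is shorter than the season or sampled at
        a different step than ``config.dt``.
    """
    if abs(environment.dt - config.dt) > 1e-9:
        raise CoverageError(
            f"environment dt={environment.dt} differs from config dt={config.dt}"
        )
    n = config.n_steps
    if len(environment) < n:
        raise CoverageError(
            f"environment has {len(environment)} samples, season needs {n}"
        )
    driver = driver if driver is not None else CanopyGrowthDriver()
    source = config.source_concentration()  # static for both modes

    state = driver.initial_state(config.growth)
    account = SiAccount()

    time = np.empty(n + 1)
    biomass = np.empty(n + 1)
    organ_biomass = {o: np.empty(n + 1) for o in ORGANS}
    transp = np.empty(n + 1)
    cum_transp = np.empty(n + 1)
    si_avail = np.full(n + 1, source)
    si_total = np.empty(n + 1)
    organ_si = {o: np.empty(n + 1) for o in ORGANS}
    conc_pct = np.empty(n + 1)

    def record(i: int, t: float, st: PlantState, acct: SiAccount) -> None:
        time[i] = t
        biomass[i] = st.biomass_total
        for o in ORGANS:
            organ_biomass[o][i] = st.organ_biomass[o]
            organ_si[o][i] = acct.organ_si[o]
        transp[i] = transpiration_rate(st.biomass_total, config.growth)
        cum_transp[i] = st.cumulative_transpiration
        si_total[i] = acct.total_si
        conc_pct[i] = (
            100.0 * acct.total_si / st.biomass_total if st.biomass_total > 0 else 0.0
        )

    record(0, 0.0, state, account)
    for i in range(n):
        sample = environment.sample(i)
        state = driver.step(state, sample, config.dt, config.growth)
        volume = transpiration_rate(state.biomass_total, config.growth) * config.dt
        state = replace(
            state,
            cumulative_transpiration=state.cumulative_transpiration + volume,
        )
        cap = max_si_capacity(state.biomass_total, config.uptake)
        account = uptake_step(account, source, volume, cap, config.uptake)
        record(i + 1, (i + 1) * config.dt, state, account)

    metadata = {
        "version": __version__,
        "config_digest": config.digest(),
        "mode": config.mode,
        "planting_density": config.growth.planting_density,
        "n_steps": n,
        "dt_s": config.dt,
    }
    if config.mode == "soil":
        metadata["areal_availability_mg_m2"] = areal_availability(
            config.effective_soil(), config.availability
        )
    return SimulationResult(
        time=time,
        biomass_total=biomass,
        organ_biomass=organ_biomass,
        transpiration=transp,
        cumulative_transpiration=cum_transp,
        si_available=si_avail,
        si_total=si_total,
        organ_si=organ_si,
        si_concentration_pct=conc_pct,
        metadata=metadata,
    )


#: Sweepable axes: how each axis name rewrites the config / environment spec.
GRID_AXES = ("ph", "om", "soil_temperature", "si_water", "par", "co2", "tair")


def _apply_axis(
    config: SimulationConfig, env_spec: EnvSpec, name: str, value: float
) -> tuple[SimulationConfig, EnvSpec]:
    if name in ("ph", "om", "soil_temperature"):
        if config.soil is None:
            raise ConfigError(f"axis {name!r} requires soil mode")
        fieldname = "temperature" if name == "soil_temperature" else name
        return replace(config, soil=replace(config.soil, **{fieldname: value})), env_spec
    if name == "si_water":
        return replace(config, si_water=value), env_spec
    if name == "par":
        return config, replace(env_spec, par_day=value)
    if name == "co2":
        return config, replace(env_spec, co2=value)
    if name == "tair":
        return config, replace(env_spec, tair_day=value, tair_night=value)
    raise ConfigError(f"unknown sweep axis {name!r}; supported: {GRID_AXES}")


def run_grid(
    config: SimulationConfig,
    env_spec: EnvSpec,
    axes: Mapping[str, Iterable[float]],
    driver: GrowthDriver | None = None,
    limit: int = DEFAULT_GRID_LIMIT,
) -> pd.DataFrame:
    """Cartesian scenario sweep; one summary row per grid point.

    Rows appear in ``itertools.product`` order of the axes as given, so the
    output is deterministic.  Oversize grids are refused outright.
    """
    axes = {name: [float(v) for v in values] for name, values in axes.items()}
    for name, values in axes.items():
        if name not in GRID_AXES:
            raise ConfigError(f"unknown sweep axis {name!r}; supported: {GRID_AXES}")
        if not values:
            raise ConfigError(f"sweep axis {name!r} is empty")
    size = int(np.prod([len(v) for v in axes.values()])) if axes else 1
    if size > limit:
        raise ValidationError(
            f"grid has {size} points, exceeding the limit of {limit}"
        )
    names = list(axes)
    rows = []
    env_cache: dict[EnvSpec, Environment] = {}
    for combo in itertools.product(*(axes[n] for n in names)):
        cfg, spec = config, env_spec
        for name, value in zip(names, combo):
            cfg, spec = _apply_axis(cfg, spec, name, value)
        if spec not in env_cache:
            env_cache[spec] = generate_environment(spec)
        result = run_simulation(cfg, env_cache[spec], driver=driver)
        row = dict(zip(names, combo))
        row.update(result.summary())
        rows.append(row)
    return pd.DataFrame(rows)
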