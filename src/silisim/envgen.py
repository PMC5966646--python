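"""Synthetic greenhouse environment series.

The scenarios the simulator targets prescribe constant PAR over a fixed
photoperiod, day/night air-temperature levels, and constant CO2, so the
default generator emits a square-wave PAR signal (a sinusoidal envelope is
available behind a flag).  Optional Gaussian perturbation uses a single
seeded generator; with ``noise_sd`` zero the output is deterministic
regardless of seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .growth import EnvSample

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class Environment:
    """Uniformly sampled series of PAR, air temperature, and CO2.

    ``time`` is seconds from transplant; sample *i* describes the interval
    ``[time[i], time[i] + dt)``.
    """

    time: np.ndarray  # s
    par: np.ndarray  # umol m^-2 s^-1
    tair: np.ndarray  # degC
    co2: np.ndarray  # uL L^-1

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("time", "par", "tair", "co2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1:
                raise ValidationError(f"{name} must be one-dimensional")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains non-finite values")
            arrays[name] = arr
            object.__setattr__(self, name, arr)
        n = arrays["time"].size
        if n < 2:
            raise ValidationError("environment needs at least two samples")
        if any(arrays[k].size != n for k in ("par", "tair", "co2")):
            raise ValidationError("environment series must share one length")
        steps = np.diff(arrays["time"])
        if not np.all(steps > 0):
            raise ValidationError("time must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-6):
            raise ValidationError("time must be uniformly sampled")
        if np.any(arrays["par"] < 0):
            raise ValidationError("par must be >= 0")
        if np.any(arrays["co2"] <= 0):
            raise ValidationError("co2 must be > 0")

    @property
    def dt(self) -> float:
        """Sampling step, s."""
        return float(self.time[1] - self.time[0])

    @property
    def duration(self) -> float:
        """Total covered time, s (one dt past the last sample's start)."""
        return float(self.time[-1] - self.time[0]) + self.dt

    def __len__(self) -> int:
        return int(self.time.size)

    def sample(self, i: int) -> EnvSample:
        return EnvSample(
            par=float(self.par[i]), tair=float(self.tair[i]), co2=float(self.co2[i])
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "par": self.par,
                "tair_c": self.tair,
                "co2_ppm": self.co2,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Environment":
        required = {"time_s", "par", "tair_c", "co2_ppm"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"environment table missing columns {sorted(missing)}")
        return cls(
            time=frame["time_s"].to_numpy(dtype=float),
            par=frame["par"].to_numpy(dtype=float),
            tair=frame["tair_c"].to_numpy(dtype=float),
            co2=frame["co2_ppm"].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class EnvSpec:
    """Recipe for a synthetic environment series."""

    days: int
    photoperiod_h: float = 12.0
    par_day: float = 400.0
    co2: float = 400.0
    tair_day: float = 30.0
    tair_night: float | None = None
    dt: float = 1800.0
    seed: int = 0
    noise_sd: float = 0.0
    sinusoidal_par: bool = False

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValidationError(f"days must be >= 1, got {self.days}")
        if not 0 < self.photoperiod_h <= 24:
            raise ValidationError(
                f"photoperiod_h must be in (0, 24], got {self.photoperiod_h}"
            )
        if self.par_day < 0:
            raise ValidationError("par_day must be >= 0")
        if self.co2 <= 0:
            raise ValidationError("co2 must be > 0")
        if self.dt <= 0:
            raise ValidationError("dt must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def generate_environment(spec: EnvSpec) -> Environment:
    """Build the environment series described by *spec*.

    The day is lit from midnight for ``photoperiod_h`` hours; ``dt`` must
    divide both the day and the photoperiod so the light budget is exact.
    """
    if SECONDS_PER_DAY % spec.dt != 0:
        raise ValidationError(f"dt={spec.dt} must divide the 86400 s day")
    photoperiod_s = spec.photoperiod_h * 3600.0
    if photoperiod_s % spec.dt != 0:
        raise ValidationError(
            f"dt={spec.dt} must divide the {photoperiod_s:.0f} s photoperiod"
        )
    n = int(spec.days * SECONDS_PER_DAY / spec.dt)
    time = np.arange(n) * spec.dt
    tod = time % SECONDS_PER_DAY  # time of day at sample start
    is_day = tod < photoperiod_s
    if spec.sinusoidal_par:
        # half-sine envelope with the same per-day photon dose as the square wave
        phase = np.where(is_day, np.sin(np.pi * tod / photoperiod_s), 0.0)
        par = spec.par_day * (np.pi / 2.0) * phase
    else:
        par = np.where(is_day, float(spec.par_day), 0.0)
    tair_night = spec.tair_day if spec.tair_night is None else spec.tair_night
    tair = np.where(is_day, float(spec.tair_day), float(tair_night))
    co2 = np.full(n, float(spec.co2))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        par = par + rng.normal(0.0, spec.noise_sd, n)
        tair = tair + rng.normal(0.0, spec.noise_sd, n)
        co2 = co2 + rng.normal(0.0, spec.noise_sd, n)
        par = np.maximum(par, 0.0)
        co2 = np.maximum(co2, 1e-6)
    return Environment(time=time, par=par, tair=tair, co2=co2)
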