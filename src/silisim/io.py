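"""Tabular writers/readers and the per-run manifest.

Every file-producing CLI run writes exactly one ``manifest.json`` next to
its outputs, recording the tool version, the config snapshot, digests of
the inputs, the produced files, and wall time.  Trajectories are stored as
long-format CSV (time_s, variable, value) at 12 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .envgen import Environment
from .errors import ValidationError
from .growth import ORGANS
from .sim import SimulationResult

# full round-trip precision: %.17g re-reads bit-for-bit
FLOAT_FORMAT = "%.17g"


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    outdir: str | Path,
    config_snapshot: Mapping[str, Any] | None,
    inputs: Iterable[str | Path] = (),
    outputs: Iterable[str | Path] = (),
    wall_time_s: float = 0.0,
) -> Path:
    outdir = Path(outdir)
    manifest = {
        "tool": "silisim",
        "version": __version__,
        "config": config_snapshot,
        "inputs": {str(p): file_digest(p) for p in inputs},
        "outputs": sorted(str(Path(p).name) for p in outputs),
        "wall_time_s": wall_time_s,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def result_to_frame(result: SimulationResult) -> pd.DataFrame:
    """Wide table of a result: one row per time point, one column per series."""
    data: dict[str, np.ndarray] = {
        "time_s": result.time,
        "biomass_total": result.biomass_total,
        "transpiration_rate": result.transpiration,
        "cumulative_transpiration": result.cumulative_transpiration,
        "si_available": result.si_available,
        "si_total": result.si_total,
        "si_concentration_pct": result.si_concentration_pct,
    }
    for organ in ORGANS:
        data[f"biomass_{organ}"] = result.organ_biomass[organ]
        data[f"si_{organ}"] = result.organ_si[organ]
    return pd.DataFrame(data)


def result_to_long(result: SimulationResult) -> pd.DataFrame:
    """Long-format trajectory table: time_s, variable, value."""
    wide = result_to_frame(result)
    return wide.melt(id_vars="time_s", var_name="variable", value_name="value")


def read_trajectory(path: str | Path) -> pd.DataFrame:
    """Read a long-format trajectory CSV back into a wide table."""
    long = pd.read_csv(path)
    required = {"time_s", "variable", "value"}
    if not required <= set(long.columns):
        raise ValidationError(f"trajectory file must have columns {sorted(required)}")
    wide = long.pivot(index="time_s", columns="variable", values="value")
    wide = wide.reset_index()
    wide.columns.name = None
    return wide


def write_results(
    result: SimulationResult,
    outdir: str | Path,
    config_snapshot: Mapping[str, Any] | None = None,
    inputs: Iterable[str | Path] = (),
    wall_time_s: float | None = None,
) -> dict[str, Path]:
    """Write trajectory CSV, summary JSON, and manifest for one run."""
    start = _time.perf_counter()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    trajectory_path = outdir / "trajectory.csv"
    result_to_long(result).to_csv(
        trajectory_path, index=False, float_format=FLOAT_FORMAT
    )

    summary_path = outdir / "summary.json"
    summary = {
        "summary": result.summary(),
        "metadata": dict(result.metadata),
    }
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))

    manifest_path = write_manifest(
        outdir,
        config_snapshot,
        inputs=inputs,
        outputs=[trajectory_path, summary_path],
        wall_time_s=(
            wall_time_s if wall_time_s is not None else _time.perf_counter() - start
        ),
    )
    return {
        "trajectory": trajectory_path,
        "summary": summary_path,
        "manifest": manifest_path,
    }


def write_environment(env: Environment, path: str | Path) -> None:
    env.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_environment(path: str | Path) -> Environment:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"environment file not found: {path}")
    return Environment.from_frame(pd.read_csv(path))
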