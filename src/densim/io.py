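"""CSV interchange and JSON configuration round-tripping.

All tabular interchange is plain CSV with stable schemas; coordinates are
kilometres written at 6-decimal precision.  Configs are JSON mirroring the
dataclass field names exactly; unknown keys are rejected with the offending
key named.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .config import ConfigError, GridSpec, SimulationConfig
from .types import (ENCOUNTER_COLUMNS, DetectorArray, EffortLog,
                    EncounterHistory, Population, SimulatedDataset)

__all__ = [
    "write_detectors", "read_detectors", "write_encounters",
    "read_encounters", "write_effort", "read_effort", "write_population",
    "read_population", "write_dataset", "load_config", "save_config",
]

_COORD_FMT = "%.6f"


def _fmt_coords(df: pd.DataFrame, cols=("x_km", "y_km")) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        out[c] = out[c].map(lambda v: float(_COORD_FMT % v))
    return out


def write_detectors(detectors: DetectorArray, path) -> None:
    _fmt_coords(detectors.detectors)[["id", "x_km", "y_km", "type"]].to_csv(
        path, index=False, float_format=_COORD_FMT)


def read_detectors(path) -> DetectorArray:
    df = pd.read_csv(path)
    _check_columns(df, ["id", "x_km", "y_km", "type"], path)
    return DetectorArray(df)


def write_encounters(history: EncounterHistory, path) -> None:
    df = history.records.copy()
    df.attrs = {}
    # the calendar rides along as constant columns so the file stays a
    # single flat CSV
    df["n_camera_occasions"] = history.n_camera_occasions
    df["n_trap_occasions"] = history.n_trap_occasions
    df.to_csv(path, index=False)


def read_encounters(path, n_camera_occasions: int | None = None,
                    n_trap_occasions: int | None = None) -> EncounterHistory:
    df = pd.read_csv(path)
    _check_columns(df, ENCOUNTER_COLUMNS, path)
    if "n_camera_occasions" in df.columns and len(df):
        n_camera_occasions = int(df["n_camera_occasions"].iloc[0])
        n_trap_occasions = int(df["n_trap_occasions"].iloc[0])
    if n_camera_occasions is None or n_trap_occasions is None:
        raise ValueError(
            f"{path}: encounter file lacks calendar columns; pass "
            "n_camera_occasions/n_trap_occasions explicitly")
    df = df[ENCOUNTER_COLUMNS]
    df["removed_flag"] = df["removed_flag"].astype(bool)
    return EncounterHistory(df, n_camera_occasions, n_trap_occasions)


def write_effort(effort: EffortLog, path) -> None:
    effort.effort.to_csv(path, index=False)


def read_effort(path) -> EffortLog:
    df = pd.read_csv(path)
    _check_columns(df, ["occasion", "n_traps_active"], path)
    return EffortLog(df)


def write_population(population: Population, path) -> None:
    _fmt_coords(population.individuals).to_csv(path, index=False,
                                               float_format=_COORD_FMT)


def read_population(path) -> Population:
    df = pd.read_csv(path)
    _check_columns(df, ["individual_id", "x_km", "y_km"], path)
    return Population(df)


def write_dataset(dataset: SimulatedDataset, outdir) -> dict[str, Path]:
    """Write detectors/encounters/effort/population CSVs into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "detectors": outdir / "detectors.csv",
        "encounters": outdir / "encounters.csv",
        "effort": outdir / "effort.csv",
        "population": outdir / "population.csv",
    }
    write_detectors(dataset.detectors, paths["detectors"])
    write_encounters(dataset.history, paths["encounters"])
    write_effort(dataset.effort, paths["effort"])
    write_population(dataset.population, paths["population"])
    return paths


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")


# ---------------------------------------------------------------------------
# configs

ConfigLike = Union[SimulationConfig, GridSpec]


def save_config(config: ConfigLike, path) -> None:
    kind = "simulation" if isinstance(config, SimulationConfig) else "grid"
    payload = {"kind": kind, **config.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_config(path) -> ConfigLike:
    """Load a JSON config; defaults fill anything omitted.

    An empty JSON object parses as the full default simulation config; a
    ``{"kind": "grid"}`` object as the default 588-cell, 5-replicate grid.
    Unknown keys and constraint violations raise :class:`ConfigError`
    naming the offending key.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(path)
    try:
        payload = json.loads(p.read_text())
    except json.JSONDecodeError as e:
        raise ConfigError(f"{path}: invalid JSON ({e})") from e
    if not isinstance(payload, dict):
        raise ConfigError(f"{path}: config must be a JSON object")
    kind = payload.pop("kind", "simulation")
    if kind == "simulation":
        return SimulationConfig.from_dict(payload)
    if kind == "grid":
        return GridSpec.from_dict(payload)
    raise ConfigError(f"kind: must be 'simulation' or 'grid', got {kind!r}")
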