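"""Shared data containers.

Coordinates are planar kilometres with the origin at the camera-grid corner;
occasions are 0-based integers with the camera phase preceding the trap phase
on a single calendar.  Tabular state is held in pandas DataFrames so the CSV
interchange formats are one call away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

CAMERA = "camera"
TRAP = "trap"

ENCOUNTER_COLUMNS = [
    "individual_id", "occasion", "detector_id", "detector_type",
    "removed_flag",
]


@dataclass
class DetectorArray:
    """Camera + corral-trap layout.

    ``detectors`` has columns id, x_km, y_km, type (camera|trap); ids are
    unique and all trap coordinates lie inside the camera bounding box.
    """

    detectors: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.detectors
        missing = {"id", "x_km", "y_km", "type"} - set(df.columns)
        if missing:
            raise ValueError(f"detector table missing columns {sorted(missing)}")
        if df["id"].duplicated().any():
            raise ValueError("detector ids must be unique")
        if not np.isfinite(df[["x_km", "y_km"]].to_numpy()).all():
            raise ValueError("detector coordinates must be finite")
        bad = set(df["type"]) - {CAMERA, TRAP}
        if bad:
            raise ValueError(f"unknown detector type(s) {sorted(bad)}")

    def of_type(self, kind: str) -> pd.DataFrame:
        return self.detectors[self.detectors["type"] == kind].reset_index(
            drop=True)

    @property
    def cameras(self) -> pd.DataFrame:
        return self.of_type(CAMERA)

    @property
    def traps(self) -> pd.DataFrame:
        return self.of_type(TRAP)

    def coords(self, kind: Optional[str] = None) -> np.ndarray:
        df = self.detectors if kind is None else self.of_type(kind)
        return df[["x_km", "y_km"]].to_numpy(float)

    def camera_bbox(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the camera grid."""
        c = self.coords(CAMERA)
        return (c[:, 0].min(), c[:, 1].min(), c[:, 0].max(), c[:, 1].max())

    def convex_hull(self):
        """Shapely convex hull of all detector locations."""
        return MultiPoint([tuple(p) for p in self.coords()]).convex_hull


@dataclass
class Population:
    """Simulated individuals with stationary home-range centroids."""

    individuals: pd.DataFrame  # individual_id, x_km, y_km

    def __post_init__(self) -> None:
        missing = {"individual_id", "x_km", "y_km"} - set(
            self.individuals.columns)
        if missing:
            raise ValueError(f"population table missing {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.individuals)

    def coords(self) -> np.ndarray:
        return self.individuals[["x_km", "y_km"]].to_numpy(float)


def distance_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distances (km) between rows of ``a`` and rows of ``b``."""
    from scipy.spatial.distance import cdist

    return cdist(np.atleast_2d(a), np.atleast_2d(b))


@dataclass
class EncounterHistory:
    """Binary daily-scale encounter records, the simulator/estimator lingua
    franca.

    One row per (individual, occasion, detector); ``removed_flag`` is True on
    the single trap record at which an individual was removed.  The calendar
    places occasions ``0..n_camera_occasions-1`` in the camera phase and the
    rest in the trap phase.
    """

    records: pd.DataFrame
    n_camera_occasions: int
    n_trap_occasions: int

    def __post_init__(self) -> None:
        if list(self.records.columns) != ENCOUNTER_COLUMNS:
            self.records = self.records.reindex(columns=ENCOUNTER_COLUMNS)
        dup = self.records.duplicated(
            subset=["individual_id", "occasion", "detector_id"])
        if dup.any():
            raise ValueError(
                "duplicate (individual, occasion, detector) record: daily "
                "scale allows at most one")

    @property
    def n_occasions(self) -> int:
        return self.n_camera_occasions + self.n_trap_occasions

    def phase(self, kind: str) -> "EncounterHistory":
        """Sub-history of one phase (camera or trap), same calendar."""
        sub = self.records[self.records["detector_type"] == kind]
        return EncounterHistory(sub.reset_index(drop=True),
                                self.n_camera_occasions,
                                self.n_trap_occasions)

    def individuals(self) -> set:
        return set(self.records["individual_id"])

    def removals(self) -> pd.DataFrame:
        """removed individuals with their removal occasion."""
        r = self.records[self.records["removed_flag"]]
        return r[["individual_id", "occasion", "detector_id"]].reset_index(
            drop=True)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class EffortLog:
    """Active traps per trapping night; one row per occasion."""

    effort: pd.DataFrame  # occasion, n_traps_active

    def __post_init__(self) -> None:
        missing = {"occasion", "n_traps_active"} - set(self.effort.columns)
        if missing:
            raise ValueError(f"effort table missing {sorted(missing)}")
        if (self.effort["n_traps_active"] < 0).any():
            raise ValueError("n_traps_active must be >= 0")

    @property
    def total_trap_nights(self) -> int:
        return int(self.effort["n_traps_active"].sum())

    def __len__(self) -> int:
        return len(self.effort)


@dataclass
class AbundanceEstimate:
    """Point estimate of abundance with variance and CI (animals)."""

    n_hat: float
    variance: float
    ci_low: float
    ci_high: float
    method: str

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be >= 0")
        if not (self.ci_low <= self.n_hat <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


@dataclass
class DensityEstimate:
    """Abundance converted to animals/km^2 over an effective sampled area."""

    d_hat: float
    variance: float
    ci_low: float
    ci_high: float
    area_km2: float
    buffer_kind: str
    buffer_km: float
    method: str

    def __post_init__(self) -> None:
        if self.area_km2 <= 0:
            raise ValueError("area must be > 0")

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


@dataclass
class SECRFit:
    """Fitted spatially explicit capture-recapture model.

    Estimates live on natural scales; SEs come from the inverse Hessian on
    the link scales (log D, logit g0, log sigma).
    """

    density: float
    g0: dict
    sigma: float
    se_density: float
    se_log_density: float
    loglik: float
    n_params: int
    aicc: float
    converged: bool
    message: str = ""
    params: Optional[np.ndarray] = None
    cov: Optional[np.ndarray] = None
    model: str = "null"
    n_individuals: int = 0
    ci_low: float = float("nan")
    ci_high: float = float("nan")

    @property
    def cv(self) -> float:
        return self.se_density / self.density if self.density > 0 else float(
            "nan")


@dataclass
class SimulatedDataset:
    """Everything one simulated study produces, fully linked."""

    config: "object"
    population: Population
    detectors: DetectorArray
    history: EncounterHistory
    effort: EffortLog

    @property
    def camera_history(self) -> EncounterHistory:
        return self.history.phase(CAMERA)

    @property
    def trap_history(self) -> EncounterHistory:
        return self.history.phase(TRAP)
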