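"""Simulation and experiment configuration objects.

All generative parameters live in :class:`SimulationConfig`; the factorial
experiment design lives in :class:`GridSpec`.  Both round-trip losslessly
through JSON (see :mod:`densim.io`) and validate eagerly on construction so
that a bad value fails at config time, not mid-grid.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

#: Nightly multinomial over how many distinct detectors an animal that was
#: detected at all visits: P(1), P(2), P(3) detectors.
DEFAULT_VISIT_PROBS: tuple[float, float, float] = (0.82, 0.15, 0.03)

#: Factorial design axes: scale of movement sigma (km), true density
#: (animals/km^2) and baseline camera detection probability g0.
DEFAULT_SIGMA_GRID: tuple[float, ...] = (0.1, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2)
DEFAULT_DENSITY_GRID: tuple[float, ...] = (
    0.25, 0.50, 0.75, 1.25, 2.00, 2.50, 3.75, 5.00, 6.25, 7.50, 10.00, 15.00,
)
DEFAULT_G0_GRID: tuple[float, ...] = (0.1, 0.2, 0.3, 0.5, 0.7, 0.8, 0.9)


class ConfigError(ValueError):
    """A configuration field failed validation; the message names the field."""


def _require(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{key}: {msg}")


@dataclass
class SimulationConfig:
    """Generative parameters for one simulated camera + removal-trap study.

    Parameters
    ----------
    sigma : float
        Scale of movement (km): the standard deviation of the Gaussian
        availability kernel linking home-range centroid to detector distance.
    g0_camera : float
        Baseline per-occasion detection probability at a camera when the
        centroid coincides with the detector.
    density : float
        True population density, animals per km^2, exact by construction.
    trap_g0_ratio : float
        Corral-trap baseline as a fraction of the camera baseline (default
        0.25: trap detection is 75% lower at equal distance).
    n_camera_occasions, n_trap_occasions : int
        Days of camera operation and nights of trapping; trapping follows
        the camera phase on the calendar.
    camera_trunc_mult, trap_trunc_mult : float
        Availability truncation radii in units of sigma; traps attract from
        farther than cameras (bait is scarcer on the landscape then).
    visit_probs : tuple of 3 floats
        Nightly multinomial over 1/2/3 distinct detectors visited.
    behavior_mult : float
        Trap-happiness: multiplier (>= 1) on g0 at a camera where the
        individual has been detected on a previous night, capped at 1.
    cluster_mean_size, cluster_radius_km : float
        Poisson-cluster (Neyman-Scott style) parameters for home-range
        centroids, emulating social grouping.
    landscape_margin_km : float
        Buffer around the detector bounding box defining the landscape, so
        edge animals remain sampleable.  Default is the trap truncation
        radius at the largest design sigma (4 x 1.2 km).
    grid_rows, grid_cols, camera_spacing_km, n_traps : int/float
        Detector layout: rows x cols camera lattice and the number of
        stratified-random corral traps inside it.
    seed : int
        Master seed; every random stream derives from it.
    """

    sigma: float = 0.6
    g0_camera: float = 0.5
    density: float = 2.0
    trap_g0_ratio: float = 0.25
    n_camera_occasions: int = 13
    n_trap_occasions: int = 14
    camera_trunc_mult: float = 3.0
    trap_trunc_mult: float = 4.0
    visit_probs: tuple[float, float, float] = DEFAULT_VISIT_PROBS
    behavior_mult: float = 2.0
    cluster_mean_size: float = 4.0
    cluster_radius_km: float = 0.3
    landscape_margin_km: float = 4.8
    grid_rows: int = 5
    grid_cols: int = 4
    camera_spacing_km: float = 0.75
    n_traps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.visit_probs = tuple(float(p) for p in self.visit_probs)
        _require(self.sigma > 0, "sigma", "must be > 0")
        _require(0 < self.g0_camera <= 1, "g0_camera", "must be in (0, 1]")
        _require(0 < self.trap_g0_ratio <= 1, "trap_g0_ratio",
                 "must be in (0, 1]")
        _require(self.density > 0, "density", "must be > 0")
        _require(len(self.visit_probs) == 3, "visit_probs",
                 "must have length 3")
        _require(all(p >= 0 for p in self.visit_probs), "visit_probs",
                 "entries must be >= 0")
        _require(math.isclose(sum(self.visit_probs), 1.0, abs_tol=1e-12),
                 "visit_probs", f"must sum to 1, got {sum(self.visit_probs)}")
        _require(self.behavior_mult >= 1, "behavior_mult", "must be >= 1")
        _require(self.trap_trunc_mult > self.camera_trunc_mult > 0,
                 "trap_trunc_mult",
                 "must satisfy trap_trunc_mult > camera_trunc_mult > 0")
        _require(self.n_camera_occasions >= 1, "n_camera_occasions",
                 "must be >= 1")
        _require(self.n_trap_occasions >= 1, "n_trap_occasions",
                 "must be >= 1")
        _require(self.cluster_mean_size > 0, "cluster_mean_size",
                 "must be > 0")
        _require(self.cluster_radius_km >= 0, "cluster_radius_km",
                 "must be >= 0")
        _require(self.landscape_margin_km >= 0, "landscape_margin_km",
                 "must be >= 0")
        _require(self.grid_rows >= 1 and self.grid_cols >= 1, "grid_rows",
                 "grid must be at least 1 x 1")
        _require(self.camera_spacing_km > 0, "camera_spacing_km",
                 "must be > 0")
        _require(self.n_traps >= 1, "n_traps", "must be >= 1")

    @property
    def camera_trunc_km(self) -> float:
        """Camera availability truncation radius (km)."""
        return self.camera_trunc_mult * self.sigma

    @property
    def trap_trunc_km(self) -> float:
        """Trap availability truncation radius (km)."""
        return self.trap_trunc_mult * self.sigma

    @property
    def g0_trap(self) -> float:
        """Baseline trap detection probability at distance zero."""
        return self.g0_camera * self.trap_g0_ratio

    def replace(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["visit_probs"] = list(self.visit_probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(
                f"unknown SimulationConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class GridSpec:
    """Factorial simulation-estimation design.

    Defaults are the full study design: 7 sigma x 12 density x 7 detection
    values = 588 parameter combinations, 5 replicate datasets each.
    """

    sigma_values: Sequence[float] = DEFAULT_SIGMA_GRID
    density_values: Sequence[float] = DEFAULT_DENSITY_GRID
    detection_values: Sequence[float] = DEFAULT_G0_GRID
    n_replicates: int = 5
    estimators: Sequence[str] = (
        "camera_lpe", "camera_secr", "trap_secr", "removal")
    seed: int = 0
    #: removal-sampler chain length used inside the grid (see methods note)
    removal_iters: int = 20000
    removal_burn: int = 4000

    def __post_init__(self) -> None:
        self.sigma_values = tuple(float(v) for v in self.sigma_values)
        self.density_values = tuple(float(v) for v in self.density_values)
        self.detection_values = tuple(float(v) for v in self.detection_values)
        self.estimators = tuple(self.estimators)
        _require(len(self.sigma_values) > 0, "sigma_values", "must be non-empty")
        _require(len(self.density_values) > 0, "density_values",
                 "must be non-empty")
        _require(len(self.detection_values) > 0, "detection_values",
                 "must be non-empty")
        _require(all(v > 0 for v in self.sigma_values), "sigma_values",
                 "must be positive")
        _require(all(v > 0 for v in self.density_values), "density_values",
                 "must be positive")
        _require(all(0 < v <= 1 for v in self.detection_values),
                 "detection_values", "must be in (0, 1]")
        _require(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        known = {"camera_lpe", "camera_secr", "trap_secr", "removal"}
        bad = set(self.estimators) - known
        _require(not bad, "estimators", f"unknown estimator(s) {sorted(bad)}")
        _require(self.removal_burn < self.removal_iters, "removal_burn",
                 "must be < removal_iters")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("sigma_values", "density_values", "detection_values",
                  "estimators"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown GridSpec keys: {sorted(unknown)}")
        return cls(**d)
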