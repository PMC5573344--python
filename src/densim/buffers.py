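"""Effective sampled area and abundance-to-density conversion.

Non-spatial abundance estimators (Chapman LPE, removal) need an effective
sampled area A to become densities.  A is the convex hull of the detector
array dilated by a buffer width w: the mean maximum distance moved (MMDM)
estimated from capture locations, half of it (HMMDM), or a naive
literature-derived radius.  For a convex hull the dilated area is exactly

    A(w) = hull_area + perimeter * w + pi * w^2

(Minkowski sum with a disc), which also covers degenerate hulls (segment:
2 L w + pi w^2; point: pi w^2).  Density variance uses the delta method with
the area treated as fixed — buffer uncertainty is not propagated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
from shapely.geometry import MultiPoint

from .types import (AbundanceEstimate, DensityEstimate, DetectorArray,
                    EncounterHistory)

__all__ = ["BufferSpec", "mmdm", "effective_area", "to_density",
           "density_from_abundance"]

#: literature home-range area (km^2) behind the naive buffer; a documented
#: placeholder the user should override with a species-appropriate value
DEFAULT_NAIVE_HOME_RANGE_KM2 = 2.0


@dataclass(frozen=True)
class BufferSpec:
    """Buffer choice: data-driven MMDM / HMMDM or a fixed naive radius."""

    kind: str = "MMDM"
    naive_radius_km: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("MMDM", "HMMDM", "naive"):
            raise ValueError("kind must be MMDM, HMMDM or naive")
        if self.kind == "naive":
            r = self.naive_radius_km
            if r is None:
                r = math.sqrt(DEFAULT_NAIVE_HOME_RANGE_KM2 / math.pi)
                object.__setattr__(self, "naive_radius_km", r)
            if r <= 0:
                raise ValueError("naive_radius_km must be > 0")

    def width_km(self, history: Optional[EncounterHistory] = None,
                 detectors: Optional[DetectorArray] = None) -> float:
        if self.kind == "naive":
            return float(self.naive_radius_km)
        if history is None or detectors is None:
            raise ValueError(f"{self.kind} buffer needs capture data")
        w = mmdm(history, detectors)
        return w / 2 if self.kind == "HMMDM" else w


def mmdm(history: EncounterHistory, detectors: DetectorArray) -> float:
    """Mean maximum distance moved (km), camera and trap records pooled.

    For each individual detected at >= 2 distinct locations, take the
    maximum pairwise distance among its detection locations; average over
    those individuals.  Individuals seen at a single location (however many
    times) carry no movement information and are excluded.
    """
    det = detectors.detectors.set_index("id")
    maxima = []
    for _, grp in history.records.groupby("individual_id"):
        ids = grp["detector_id"].unique()
        if len(ids) < 2:
            continue
        pts = det.loc[list(ids), ["x_km", "y_km"]].to_numpy(float)
        dmax = max(math.dist(a, b) for a, b in combinations(pts, 2))
        maxima.append(dmax)
    if not maxima:
        raise ValueError(
            "MMDM undefined: no individual detected at two distinct "
            "locations (consider a naive buffer)")
    return float(np.mean(maxima))


def effective_area(detectors: DetectorArray, buffer_km: float) -> float:
    """Area (km^2) of the detector convex hull dilated by ``buffer_km``.

    Exact Minkowski closed form for convex sets; handles collinear and
    single-point layouts through their degenerate hulls.
    """
    if buffer_km < 0:
        raise ValueError("buffer width must be >= 0")
    hull = MultiPoint([tuple(p) for p in detectors.coords()]).convex_hull
    w = buffer_km
    if hull.geom_type == "Polygon":
        return hull.area + hull.length * w + math.pi * w ** 2
    if hull.geom_type == "LineString":  # collinear detectors
        return 2 * hull.length * w + math.pi * w ** 2
    # single point
    return math.pi * w ** 2


def to_density(abundance: AbundanceEstimate, area_km2: float,
               buffer_kind: str = "", buffer_km: float = float("nan")
               ) -> DensityEstimate:
    """Delta-method conversion D = N / A with the area treated as fixed."""
    if area_km2 <= 0:
        raise ValueError("area must be > 0")
    return DensityEstimate(
        d_hat=abundance.n_hat / area_km2,
        variance=abundance.variance / area_km2 ** 2,
        ci_low=abundance.ci_low / area_km2,
        ci_high=abundance.ci_high / area_km2,
        area_km2=area_km2,
        buffer_kind=buffer_kind,
        buffer_km=buffer_km,
        method=abundance.method)


def density_from_abundance(abundance: AbundanceEstimate,
                           detectors: DetectorArray,
                           buffer: BufferSpec = BufferSpec(),
                           history: Optional[EncounterHistory] = None
                           ) -> DensityEstimate:
    """Convenience: buffer width -> effective area -> delta-method density."""
    w = buffer.width_km(history, detectors)
    area = effective_area(detectors, w)
    return to_density(abundance, area, buffer_kind=buffer.kind, buffer_km=w)
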