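"""Synthetic camera-grid and removal-trap encounter data.

The observation model works on a daily scale.  An animal's availability at a
detector declines with the distance ``d`` between its stationary home-range
centroid and the detector as a truncated Gaussian

    p(available) = min(1, exp(-d^2 / (2 sigma^2)) / sqrt(2 pi sigma^2)),

zero beyond a truncation radius (a multiple of sigma; larger for baited
corral traps than for cameras).  Detection given availability is a flat
baseline rate g0, so p(detection) is a scaled truncated Gaussian.  The raw
Gaussian density exceeds 1 near d = 0 once sigma < 1/sqrt(2 pi); availability
is a probability, so it is clamped at 1 there.

Nightly camera visits are capped by a multinomial over visiting 1, 2 or 3
distinct cameras (default [0.82, 0.15, 0.03]); a trap-happiness effect
multiplies g0 at cameras where the individual was detected on an earlier
night.  Corral trapping removes an animal at its first (and only) trap
detection.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .types import (CAMERA, ENCOUNTER_COLUMNS, TRAP, DetectorArray, EffortLog,
                    EncounterHistory, Population, SimulatedDataset,
                    distance_matrix)

__all__ = [
    "build_detector_grid", "landscape_bounds", "simulate_centroids",
    "availability_prob", "detection_prob", "simulate_camera_phase",
    "simulate_trap_phase", "simulate_dataset", "simulate_secr_dataset",
]


# ---------------------------------------------------------------------------
# landscape and detector layout

def build_detector_grid(rows: int = 5, cols: int = 4,
                        spacing_km: float = 0.75, n_traps: int = 10,
                        seed: int = 0) -> DetectorArray:
    """Rectangular camera lattice with stratified-random traps inside it.

    ``rows x cols`` cameras sit on a lattice with the given spacing (origin
    at a corner).  Traps are placed by deterministic stratified sampling:
    the camera bounding box is divided into ``n_traps`` strata (a grid of
    cells matching the box aspect ratio) and one trap is jittered uniformly
    inside each of the first ``n_traps`` cells.
    """
    if rows < 1 or cols < 1 or n_traps < 1:
        raise ValueError("rows, cols and n_traps must be >= 1")
    if spacing_km <= 0:
        raise ValueError("spacing_km must be > 0")
    xs = np.arange(rows) * spacing_km
    ys = np.arange(cols) * spacing_km
    cam_x, cam_y = [a.ravel() for a in np.meshgrid(xs, ys, indexing="ij")]
    n_cam = rows * cols

    width = xs.max() - xs.min()
    height = ys.max() - ys.min()
    # strata grid: smallest a x b >= n_traps with cells as square as possible
    if width > 0 and height > 0:
        a = max(1, round(math.sqrt(n_traps * width / height)))
        b = math.ceil(n_traps / a)
        while a * b < n_traps:
            b += 1
    else:
        a, b = n_traps, 1
    if a * b < n_traps:
        raise ValueError("n_traps exceeds the number of strata")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cell_w = width / a if a else 0.0
    cell_h = height / b if b else 0.0
    trap_pts = []
    for idx in range(n_traps):
        i, j = idx % a, idx // a
        u, v = rng.uniform(size=2)
        trap_pts.append((i * cell_w + u * cell_w if width > 0 else 0.0,
                         j * cell_h + v * cell_h if height > 0 else 0.0))
    trap_pts = np.asarray(trap_pts, float).reshape(n_traps, 2)
    # numerical safety: keep traps strictly inside the camera bounding box
    if width > 0:
        trap_pts[:, 0] = np.clip(trap_pts[:, 0], 0.0, width)
    if height > 0:
        trap_pts[:, 1] = np.clip(trap_pts[:, 1], 0.0, height)

    df = pd.DataFrame({
        "id": [f"C{i:02d}" for i in range(n_cam)]
              + [f"T{i:02d}" for i in range(n_traps)],
        "x_km": np.concatenate([cam_x, trap_pts[:, 0]]),
        "y_km": np.concatenate([cam_y, trap_pts[:, 1]]),
        "type": [CAMERA] * n_cam + [TRAP] * n_traps,
    })
    return DetectorArray(df)


def landscape_bounds(detectors: DetectorArray,
                     margin_km: float) -> tuple[float, float, float, float]:
    """Detector bounding box buffered by ``margin_km``: (xmin, ymin, xmax, ymax)."""
    c = detectors.coords()
    return (c[:, 0].min() - margin_km, c[:, 1].min() - margin_km,
            c[:, 0].max() + margin_km, c[:, 1].max() + margin_km)


def landscape_area(detectors: DetectorArray, margin_km: float) -> float:
    x0, y0, x1, y1 = landscape_bounds(detectors, margin_km)
    return (x1 - x0) * (y1 - y0)


def simulate_centroids(config: SimulationConfig,
                       detectors: Optional[DetectorArray] = None,
                       rng: Optional[np.random.Generator] = None
                       ) -> Population:
    """Clustered stationary home-range centroids.

    A partial Poisson cluster process: parent points fall uniformly on the
    landscape, each parent receives Poisson(cluster_mean_size) offspring
    displaced isotropically within ``cluster_radius_km``, and the realized
    point count is thinned/augmented to exactly round(density x area), so
    true density is exact by construction.
    """
    if detectors is None:
        detectors = build_detector_grid(config.grid_rows, config.grid_cols,
                                        config.camera_spacing_km,
                                        config.n_traps, seed=config.seed)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    x0, y0, x1, y1 = landscape_bounds(detectors, config.landscape_margin_km)
    area = (x1 - x0) * (y1 - y0)
    n_target = int(round(config.density * area))
    if n_target <= 0:
        raise ValueError(
            "density x landscape area rounds to zero animals; estimators "
            "are undefined for an empty population")

    n_parents = max(1, int(round(n_target / config.cluster_mean_size)))
    parents = np.column_stack([rng.uniform(x0, x1, n_parents),
                               rng.uniform(y0, y1, n_parents)])

    def offspring_of(parent_idx: np.ndarray) -> np.ndarray:
        k = len(parent_idx)
        theta = rng.uniform(0, 2 * np.pi, k)
        # uniform over the disk of radius cluster_radius_km
        r = config.cluster_radius_km * np.sqrt(rng.uniform(size=k))
        pts = parents[parent_idx] + np.column_stack(
            [r * np.cos(theta), r * np.sin(theta)])
        pts[:, 0] = np.clip(pts[:, 0], x0, x1)
        pts[:, 1] = np.clip(pts[:, 1], y0, y1)
        return pts

    counts = rng.poisson(config.cluster_mean_size, n_parents)
    idx = np.repeat(np.arange(n_parents), counts)
    pts = offspring_of(idx)
    if len(pts) > n_target:
        keep = rng.choice(len(pts), size=n_target, replace=False)
        pts = pts[np.sort(keep)]
    elif len(pts) < n_target:
        extra_idx = rng.integers(0, n_parents, n_target - len(pts))
        pts = np.vstack([pts, offspring_of(extra_idx)])

    df = pd.DataFrame({
        "individual_id": [f"A{i:04d}" for i in range(n_target)],
        "x_km": pts[:, 0],
        "y_km": pts[:, 1],
    })
    return Population(df)


# ---------------------------------------------------------------------------
# availability / detection kernels

def availability_prob(d, sigma: float, trunc_radius: float):
    """Truncated-Gaussian daily availability at centroid-detector distance d.

    ``min(1, N(0, sigma) density at d)`` for ``d <= trunc_radius``, else 0.
    Accepts scalars or arrays; negative distances are rejected.
    """
    d = np.asarray(d, float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if trunc_radius <= 0:
        raise ValueError("trunc_radius must be > 0")
    raw = np.exp(-d ** 2 / (2 * sigma ** 2)) / math.sqrt(
        2 * math.pi * sigma ** 2)
    out = np.where(d <= trunc_radius, np.minimum(1.0, raw), 0.0)
    return out if out.ndim else float(out)


def detection_prob(d, sigma: float, g0_effective: float,
                   trunc_radius: float):
    """Scaled truncated Gaussian: g0 x availability; lies in [0, 1]."""
    if not 0 <= g0_effective <= 1:
        raise ValueError("g0_effective must be in [0, 1]")
    out = g0_effective * np.asarray(
        availability_prob(d, sigma, trunc_radius))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# observation phases

def _records_frame(rows: list) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=ENCOUNTER_COLUMNS) if rows else \
        pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            ENCOUNTER_COLUMNS, [object, int, object, object, bool])})


def simulate_camera_phase(population: Population, detectors: DetectorArray,
                          config: SimulationConfig,
                          rng: Optional[np.random.Generator] = None
                          ) -> EncounterHistory:
    """Daily camera encounters with the multinomial visit cap and
    site-specific trap-happiness.

    Per individual-night: detection happens with probability
    ``1 - prod_k (1 - p_k)`` over in-range cameras; if it does, the number of
    distinct cameras visited is drawn from ``visit_probs`` and that many
    cameras are sampled without replacement with weights proportional to the
    per-camera detection probabilities.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    cams = detectors.cameras
    if len(cams) == 0:
        raise ValueError("no camera detectors")
    cam_ids = cams["id"].to_numpy()
    dmat = distance_matrix(population.coords(), cams[["x_km", "y_km"]]
                           .to_numpy(float))
    avail = np.asarray(availability_prob(dmat, config.sigma,
                                         config.camera_trunc_km))
    # only animals that can ever reach a camera matter
    cand = np.flatnonzero(avail.sum(axis=1) > 0)
    avail = avail[cand]
    ids = population.individuals["individual_id"].to_numpy()[cand]
    n, k = avail.shape
    visited = np.zeros((n, k), bool)
    visit_k = np.arange(1, 4)
    rows: list = []
    for occ in range(config.n_camera_occasions):
        g0_eff = np.minimum(
            1.0, config.g0_camera * np.where(visited, config.behavior_mult,
                                             1.0))
        p = np.minimum(1.0, g0_eff * avail)
        p_any = 1.0 - np.prod(1.0 - p, axis=1)
        hits = np.flatnonzero(rng.uniform(size=n) < p_any)
        new_visits = np.zeros((n, k), bool)
        for i in hits:
            weights = p[i]
            avail_cams = np.flatnonzero(weights > 0)
            n_visit = min(int(rng.choice(visit_k, p=config.visit_probs)),
                          len(avail_cams))
            w = weights[avail_cams] / weights[avail_cams].sum()
            chosen = rng.choice(avail_cams, size=n_visit, replace=False, p=w)
            for c in chosen:
                rows.append((ids[i], occ, cam_ids[c], CAMERA, False))
                new_visits[i, c] = True
        visited |= new_visits  # behavior kicks in on subsequent nights
    return EncounterHistory(_records_frame(rows), config.n_camera_occasions,
                            config.n_trap_occasions)


def simulate_trap_phase(population: Population, detectors: DetectorArray,
                        config: SimulationConfig,
                        prior_history: Optional[EncounterHistory] = None,
                        rng: Optional[np.random.Generator] = None
                        ) -> tuple[EncounterHistory, EffortLog]:
    """Nightly corral trapping with removal on first capture.

    Capture probability per animal-night is ``1 - prod_k (1 - p_k)`` over
    in-range traps (g0 scaled by ``trap_g0_ratio``, trap truncation radius);
    the single capturing trap is drawn with probability proportional to the
    per-trap detection probabilities.  Captured animals are removed and
    contribute no further records.  All traps are active every night.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    traps = detectors.traps
    if len(traps) == 0:
        raise ValueError("no trap detectors")
    trap_ids = traps["id"].to_numpy()
    dmat = distance_matrix(population.coords(),
                           traps[["x_km", "y_km"]].to_numpy(float))
    p = np.minimum(1.0, config.g0_trap * np.asarray(
        availability_prob(dmat, config.sigma, config.trap_trunc_km)))
    ids = population.individuals["individual_id"].to_numpy()
    alive = np.ones(len(ids), bool)
    p_any = 1.0 - np.prod(1.0 - p, axis=1)
    rows: list = []
    effort_rows = []
    for night in range(config.n_trap_occasions):
        occ = config.n_camera_occasions + night
        effort_rows.append((occ, len(traps)))
        at_risk = np.flatnonzero(alive & (p_any > 0))
        if len(at_risk):
            caught = at_risk[rng.uniform(size=len(at_risk)) < p_any[at_risk]]
            for i in caught:
                w = p[i] / p[i].sum()
                t = int(rng.choice(len(trap_ids), p=w))
                rows.append((ids[i], occ, trap_ids[t], TRAP, True))
                alive[i] = False
    history = EncounterHistory(_records_frame(rows),
                               config.n_camera_occasions,
                               config.n_trap_occasions)
    effort = EffortLog(pd.DataFrame(effort_rows,
                                    columns=["occasion", "n_traps_active"]))
    return history, effort


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """One fully linked study: landscape, population, camera then trap phase.

    The master seed is split counter-style (``SeedSequence.spawn``) into
    independent streams for layout, centroids, camera phase and trap phase,
    so each stage is reproducible in isolation.
    """
    ss = np.random.SeedSequence(config.seed)
    s_pop, s_cam, s_trap = ss.spawn(3)
    detectors = build_detector_grid(config.grid_rows, config.grid_cols,
                                    config.camera_spacing_km, config.n_traps,
                                    seed=config.seed)
    population = simulate_centroids(config, detectors,
                                    rng=np.random.default_rng(s_pop))
    cam_hist = simulate_camera_phase(population, detectors, config,
                                     rng=np.random.default_rng(s_cam))
    trap_hist, effort = simulate_trap_phase(population, detectors, config,
                                            rng=np.random.default_rng(s_trap))
    records = pd.concat([cam_hist.records, trap_hist.records],
                        ignore_index=True)
    history = EncounterHistory(records, config.n_camera_occasions,
                               config.n_trap_occasions)
    return SimulatedDataset(config, population, detectors, history, effort)


# ---------------------------------------------------------------------------
# textbook SECR generator (for parameter-recovery checks)

def simulate_secr_dataset(density: float, g0: float, sigma: float,
                          detectors: DetectorArray, n_occasions: int,
                          buffer_km: float, seed: int = 0
                          ) -> EncounterHistory:
    """Data drawn exactly from the half-normal binary-proximity SECR model.

    Activity centers follow a homogeneous Poisson process over the detector
    bounding box buffered by ``buffer_km``; each animal-occasion-detector
    is an independent Bernoulli with p = g0 exp(-d^2 / 2 sigma^2) — no visit
    cap, clustering, truncation or behavioral effect.  This is the generative
    model the SECR likelihood assumes, so fits to it test the estimator
    rather than model mismatch.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x0, y0, x1, y1 = landscape_bounds(detectors, buffer_km)
    area = (x1 - x0) * (y1 - y0)
    n = rng.poisson(density * area)
    centers = np.column_stack([rng.uniform(x0, x1, n),
                               rng.uniform(y0, y1, n)])
    det = detectors.detectors
    dmat = distance_matrix(centers, det[["x_km", "y_km"]].to_numpy(float))
    p = g0 * np.exp(-dmat ** 2 / (2 * sigma ** 2))
    rows = []
    det_ids = det["id"].to_numpy()
    det_types = det["type"].to_numpy()
    for occ in range(n_occasions):
        hits = rng.uniform(size=p.shape) < p
        for i, k in zip(*np.nonzero(hits)):
            rows.append((f"A{i:04d}", occ, det_ids[k], det_types[k], False))
    return EncounterHistory(_records_frame(rows), n_occasions, 0)
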