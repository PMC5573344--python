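"""Factorial simulation-estimation experiment.

Runs every combination of scale of movement, true density and baseline
detection probability through the simulator and the estimator suite
(camera LPE, camera SECR, trap SECR, Bayesian removal; the non-spatial
estimators converted to density with an MMDM buffer), and scores each fit by

    scaled bias = (d_hat - d_true) / d_true
    CV          = se(d_hat) / d_hat   (display-capped at 2.0)

Failed fits are recorded with a status, never dropped: successes plus
failures always add to the replicate count, and cells where a model cannot
run stay visible (the "gray cells" of the result maps).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .buffers import BufferSpec, density_from_abundance
from .config import GridSpec, SimulationConfig
from .lpe import ChapmanEstimator
from .removal import RemovalData, RemovalEstimator
from .secr import SECREstimator
from .simulate import simulate_dataset
from .types import DensityEstimate, SimulatedDataset

__all__ = ["enumerate_grid", "scaled_bias", "cv", "run_cell", "run_grid",
           "summarize", "CV_DISPLAY_CAP"]

logger = logging.getLogger("densim")

CV_DISPLAY_CAP = 2.0

RESULT_COLUMNS = ["sigma", "density", "g0", "estimator", "replicate",
                  "d_hat", "se", "scaled_bias", "cv", "cv_display", "status"]


def enumerate_grid(spec: GridSpec) -> list[tuple[float, float, float]]:
    """Cartesian product (sigma, density, g0) in deterministic order."""
    return list(itertools.product(spec.sigma_values, spec.density_values,
                                  spec.detection_values))


def scaled_bias(d_hat: float, d_true: float) -> float:
    """(estimated density - true density) / true density."""
    if d_true <= 0:
        raise ValueError("true density must be > 0")
    return (d_hat - d_true) / d_true


def cv(d_hat: float, se: float) -> tuple[float, float]:
    """Coefficient of variation: (raw, display-capped at 2.0).

    Returns (nan, nan) when the estimate is non-positive.
    """
    if se < 0:
        raise ValueError("se must be >= 0")
    if not d_hat > 0:
        return (float("nan"), float("nan"))
    raw = se / d_hat
    return (raw, min(raw, CV_DISPLAY_CAP))


def _density_row(est: DensityEstimate) -> tuple[float, float]:
    return est.d_hat, est.se


def _run_estimator(name: str, dataset: SimulatedDataset, spec: GridSpec,
                   seed: int) -> tuple[float, float, str]:
    """(d_hat, se, status) for one estimator on one dataset."""
    mmdm_buffer = BufferSpec("MMDM")
    if name == "camera_lpe":
        cam, trap = dataset.camera_history, dataset.trap_history
        if not cam.individuals() and not trap.individuals():
            return (math.nan, math.nan, "failed: no detections")
        chap = ChapmanEstimator().fit(cam, trap)
        try:
            dens = density_from_abundance(chap.estimate_, dataset.detectors,
                                          mmdm_buffer, dataset.history)
        except ValueError:
            return (math.nan, math.nan, "failed: MMDM undefined")
        return (*_density_row(dens), "ok")
    if name in ("camera_secr", "trap_secr"):
        used = "camera" if name == "camera_secr" else "all"
        try:
            secr = SECREstimator(detectors_used=used, seed=seed).fit(
                dataset.history, dataset.detectors)
        except ValueError as e:
            return (math.nan, math.nan, f"failed: {e}")
        if not secr.converged_:
            return (math.nan, math.nan, f"failed: {secr.fit_.message}")
        return (secr.density_, secr.se_density_, "ok")
    if name == "removal":
        data = RemovalData.from_history(dataset.trap_history, dataset.effort)
        if data.total_catch == 0:
            return (math.nan, math.nan, "failed: zero catch")
        rem = RemovalEstimator(n_iter=spec.removal_iters,
                               burn_in=spec.removal_burn, seed=seed).fit(data)
        try:
            dens = density_from_abundance(rem.estimate_, dataset.detectors,
                                          mmdm_buffer, dataset.history)
        except ValueError:
            return (math.nan, math.nan, "failed: MMDM undefined")
        return (*_density_row(dens), "ok")
    raise ValueError(f"unknown estimator {name!r}")


def replicate_seed(master_seed: int, cell_index: int, replicate: int) -> int:
    """Deterministic per-cell, per-replicate seed (order-independent)."""
    ss = np.random.SeedSequence(master_seed,
                                spawn_key=(cell_index, replicate))
    return int(ss.generate_state(1, np.uint32)[0])


def run_cell(triple: tuple[float, float, float], cell_index: int,
             spec: GridSpec, sim_defaults: Optional[SimulationConfig] = None
             ) -> pd.DataFrame:
    """All replicates and estimators for one (sigma, density, g0) cell."""
    sigma, density, g0 = triple
    base = sim_defaults if sim_defaults is not None else SimulationConfig()
    rows = []
    for rep in range(spec.n_replicates):
        seed = replicate_seed(spec.seed, cell_index, rep)
        config = base.replace(sigma=sigma, density=density, g0_camera=g0,
                              seed=seed)
        dataset = simulate_dataset(config)
        for name in spec.estimators:
            try:
                d_hat, se, status = _run_estimator(name, dataset, spec, seed)
            except Exception as e:  # a cell failure must not kill the grid
                d_hat, se, status = math.nan, math.nan, f"error: {e}"
            if status == "ok" and np.isfinite(d_hat):
                sb = scaled_bias(d_hat, density)
                cv_raw, cv_disp = cv(d_hat, se) if np.isfinite(se) else (
                    math.nan, math.nan)
            else:
                sb = cv_raw = cv_disp = math.nan
            rows.append((sigma, density, g0, name, rep, d_hat, se, sb,
                         cv_raw, cv_disp, status))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_grid(spec: GridSpec,
             sim_defaults: Optional[SimulationConfig] = None,
             progress: bool = False) -> pd.DataFrame:
    """Long-format evaluation table over the full factorial grid.

    Row count is |grid| x n_replicates x |estimators|; identical spec and
    seed reproduce the table bit-for-bit, and cells are independent work
    units (their seeds derive from (cell index, replicate) counters), so
    execution order cannot change results.
    """
    triples = enumerate_grid(spec)
    frames = []
    for idx, triple in enumerate(triples):
        if progress:
            logger.info("cell %d/%d sigma=%.2f D=%.2f g0=%.2f", idx + 1,
                        len(triples), *triple)
        frames.append(run_cell(triple, idx, spec, sim_defaults))
    table = pd.concat(frames, ignore_index=True)
    expected = len(triples) * spec.n_replicates * len(spec.estimators)
    assert len(table) == expected, "replicate bookkeeping lost rows"
    return table


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell, per-estimator aggregates over converged replicates.

    Mean (and median) scaled bias and mean CV over replicates with status
    "ok"; ``n_failed`` keeps failures visible.  Cells where nothing
    converged keep NaN aggregates (gray cells).
    """
    def _agg(grp: pd.DataFrame) -> pd.Series:
        ok = grp[grp["status"] == "ok"]
        return pd.Series({
            "n_ok": len(ok),
            "n_failed": len(grp) - len(ok),
            "mean_scaled_bias": ok["scaled_bias"].mean(),
            "median_scaled_bias": ok["scaled_bias"].median(),
            "mean_cv": ok["cv"].mean(),
            "mean_cv_display": ok["cv_display"].mean(),
            "mean_d_hat": ok["d_hat"].mean(),
        })

    out = (table.groupby(["sigma", "density", "g0", "estimator"],
                         sort=True)
           .apply(_agg, include_groups=False)
           .reset_index())
    for c in ("n_ok", "n_failed"):
        out[c] = out[c].astype(int)
    return out
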