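import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import densim as d

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def detector_grid() -> d.DetectorArray:
    """Default field layout: 5x4 cameras at 750 m, 10 traps inside."""
    return d.build_detector_grid(5, 4, 0.75, 10, seed=0)


@pytest.fixture(scope="session")
def camera_array(detector_grid) -> d.DetectorArray:
    return d.DetectorArray(detector_grid.cameras)


@pytest.fixture(scope="session")
def midrange_config() -> d.SimulationConfig:
    """A data-rich interior cell; the smaller margin keeps tests quick."""
    return d.SimulationConfig(sigma=0.6, density=2.5, g0_camera=0.5,
                              landscape_margin_km=2.4, seed=11)


@pytest.fixture(scope="session")
def midrange_dataset(midrange_config) -> d.SimulatedDataset:
    return d.simulate_dataset(midrange_config)


def toy_secr_problem():
    """Tiny SECR instance for brute-force likelihood checks.

    Three detectors (two cameras, one trap), three occasions of which the
    last is the trap night, two detected individuals, one of them removed
    at the trap.
    """
    det = d.DetectorArray(pd.DataFrame({
        "id": ["C0", "C1", "T0"],
        "x_km": [0.0, 0.8, 0.4],
        "y_km": [0.0, 0.0, 0.3],
        "type": ["camera", "camera", "trap"],
    }))
    records = pd.DataFrame(
        [("A", 0, "C0", "camera", False),
         ("A", 1, "C1", "camera", False),
         ("A", 2, "T0", "trap", True),
         ("B", 0, "C1", "camera", False),
         ("B", 1, "C1", "camera", False)],
        columns=["individual_id", "occasion", "detector_id",
                 "detector_type", "removed_flag"])
    history = d.EncounterHistory(records, n_camera_occasions=2,
                                 n_trap_occasions=1)
    mask = d.build_mask(det, buffer_km=1.0, spacing_km=0.4)
    return det, history, mask


def brute_force_secr_loglik(history, detectors, mask, params, spec):
    """Independent SECR likelihood: explicit loops over mask point, animal,
    occasion and detector, with the behavioral state reconstructed
    sequentially from the raw records."""
    det = detectors.detectors
    ids = sorted(history.records["individual_id"].unique())
    n = len(ids)
    ncam = history.n_camera_occasions
    n_occ = history.n_occasions
    g0, sigma, dens = params["g0"], params["sigma"], params["density"]
    bbk = params.get("beta_bk", 0.0)
    btype = params.get("beta_type", 0.0)

    def p_of(dist, is_trap, experienced):
        lo = np.log(g0 / (1 - g0))
        if spec.type_effect and is_trap:
            lo += btype
        if spec.behavior and experienced:
            lo += bbk
        g = 1 / (1 + np.exp(-lo))
        return g * np.exp(-dist ** 2 / (2 * sigma ** 2))

    rec = history.records
    sum_log_ai = 0.0
    for aid in ids:
        mine = rec[rec["individual_id"] == aid]
        removed = mine[mine["removed_flag"]]
        last = int(removed["occasion"].min()) if len(removed) else n_occ - 1
        integral = 0.0
        for s in mask.points:
            prob = 1.0
            seen = set()
            for occ in range(last + 1):
                for _, drow in det.iterrows():
                    is_trap = drow["type"] == "trap"
                    active = (occ >= ncam) if is_trap else (occ < ncam)
                    if not active:
                        continue
                    dist = np.hypot(s[0] - drow["x_km"], s[1] - drow["y_km"])
                    p = p_of(dist, is_trap, drow["id"] in seen)
                    hit = ((mine["occasion"] == occ)
                           & (mine["detector_id"] == drow["id"])).any()
                    prob *= p if hit else (1 - p)
                # state updates after the night ends
                tonight = mine[mine["occasion"] == occ]["detector_id"]
                seen.update(tonight)
            integral += prob * mask.cell_area
        sum_log_ai += np.log(integral)

    a = 0.0
    for s in mask.points:
        miss = 1.0
        for _, drow in det.iterrows():
            is_trap = drow["type"] == "trap"
            t_active = (n_occ - ncam) if is_trap else ncam
            dist = np.hypot(s[0] - drow["x_km"], s[1] - drow["y_km"])
            p = p_of(dist, is_trap, False)
            miss *= (1 - p) ** t_active
        a += (1 - miss) * mask.cell_area
    from scipy.special import gammaln
    return (-dens * a + n * np.log(dens) + sum_log_ai - gammaln(n + 1))
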