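import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.spatial.distance import pdist

import densim as d
from densim.simulate import landscape_area


class TestDetectorGrid:
    def test_default_layout(self, detector_grid):
        cams = detector_grid.cameras
        assert len(cams) == 20
        x0, y0, x1, y1 = detector_grid.camera_bbox()
        assert (x1 - x0, y1 - y0) == (3.0, 2.25)
        traps = detector_grid.traps
        assert len(traps) == 10
        assert (traps["x_km"].between(x0, x1)).all()
        assert (traps["y_km"].between(y0, y1)).all()
        assert detector_grid.detectors["id"].is_unique

    def test_nearest_neighbor_spacing_brute_force(self, detector_grid):
        pts = detector_grid.coords("camera")
        nn = min(pdist(pts))
        assert nn == pytest.approx(0.75, abs=1e-12)

    def test_degenerate_single_camera(self):
        arr = d.build_detector_grid(1, 1, 0.75, 1, seed=3)
        cams = arr.cameras
        assert len(cams) == 1
        assert (cams[["x_km", "y_km"]].to_numpy() == 0).all()
        assert len(arr.traps) == 1

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            d.build_detector_grid(0, 4, 0.75, 10)
        with pytest.raises(ValueError):
            d.build_detector_grid(5, 4, -1.0, 10)

    def test_layout_reproducible_by_seed(self):
        a = d.build_detector_grid(5, 4, 0.75, 10, seed=9)
        b = d.build_detector_grid(5, 4, 0.75, 10, seed=9)
        pd.testing.assert_frame_equal(a.detectors, b.detectors)


class TestCentroids:
    def test_exact_count_from_density(self):
        # 1x1 camera grid at the origin with a 2.5 km margin: 25 km^2
        cfg = d.SimulationConfig(density=2.0, grid_rows=1, grid_cols=1,
                                 n_traps=1, landscape_margin_km=2.5, seed=4)
        det = d.build_detector_grid(1, 1, 0.75, 1, seed=4)
        assert landscape_area(det, 2.5) == pytest.approx(25.0)
        pop = d.simulate_centroids(cfg, det)
        assert len(pop) == 50

    def test_zero_radius_collapses_to_parents(self):
        cfg = d.SimulationConfig(density=2.0, cluster_radius_km=0.0,
                                 cluster_mean_size=4.0,
                                 landscape_margin_km=2.4, seed=5)
        pop = d.simulate_centroids(cfg)
        n_parents = max(1, round(len(pop) / cfg.cluster_mean_size))
        n_unique = len(np.unique(pop.coords(), axis=0))
        assert n_unique <= n_parents

    def test_clustering_shrinks_nearest_neighbor_distance(self):
        # Monte-Carlo: strong clustering gives smaller mean NN distance
        def mean_nn(mean_size, seed):
            cfg = d.SimulationConfig(density=2.0, cluster_mean_size=mean_size,
                                     cluster_radius_km=0.3,
                                     landscape_margin_km=2.4, seed=seed)
            pts = d.simulate_centroids(cfg).coords()
            from scipy.spatial import cKDTree
            dist, _ = cKDTree(pts).query(pts, k=2)
            return dist[:, 1].mean()

        clustered = np.mean([mean_nn(5.0, s) for s in range(100)])
        unclustered = np.mean([mean_nn(1.0, s) for s in range(100, 200)])
        assert clustered < unclustered

    def test_empty_population_is_an_error(self):
        cfg = d.SimulationConfig(density=0.001, grid_rows=1, grid_cols=1,
                                 n_traps=1, landscape_margin_km=0.5, seed=0)
        det = d.build_detector_grid(1, 1, 0.75, 1, seed=0)
        with pytest.raises(ValueError, match="zero"):
            d.simulate_centroids(cfg, det)


class TestAvailability:
    @pytest.mark.parametrize("dist,sigma,trunc,expected", [
        (0.0, 1.0, 3.0, 0.3989422804),
        (5.0, 1.0, 3.0, 0.0),          # beyond truncation
        (0.0, 0.1, 0.3, 1.0),          # raw value 3.989 clamped
        (1.0, 1.0, 3.0, 0.2419707245),
    ])
    def test_values(self, dist, sigma, trunc, expected):
        assert d.availability_prob(dist, sigma, trunc) == pytest.approx(
            expected, abs=1e-9)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            d.availability_prob(-0.1, 1.0, 3.0)

    @given(st.floats(0, 5), st.floats(0.05, 2), st.floats(0.1, 10))
    def test_monotone_and_bounded(self, dist, sigma, trunc):
        p = d.availability_prob(dist, sigma, trunc)
        p2 = d.availability_prob(dist * 1.5 + 0.01, sigma, trunc)
        assert 0.0 <= p <= 1.0
        assert p2 <= p + 1e-12

    def test_clamp_only_when_raw_exceeds_one(self):
        # equals the raw Gaussian value whenever that value is <= 1
        sigma = 1.0  # 1/sqrt(2 pi sigma^2) < 1
        for dist in (0.0, 0.5, 1.7):
            raw = math.exp(-dist ** 2 / 2) / math.sqrt(2 * math.pi)
            assert d.availability_prob(dist, sigma, 5.0) == pytest.approx(raw)


class TestDetectionProb:
    def test_scaled_by_g0(self):
        assert d.detection_prob(0.0, 1.0, 0.5, 3.0) == pytest.approx(
            0.1994711402)
        assert d.detection_prob(1.3, 1.0, 0.0, 3.0) == 0.0

    def test_trap_ratio_quarters_camera_baseline(self):
        cfg = d.SimulationConfig(g0_camera=0.8)
        assert cfg.g0_trap == pytest.approx(0.2)
        dist = 0.4
        p_cam = d.detection_prob(dist, cfg.sigma, cfg.g0_camera, 10.0)
        p_trap = d.detection_prob(dist, cfg.sigma, cfg.g0_trap, 10.0)
        assert p_trap == pytest.approx(0.25 * p_cam)

    def test_invalid_g0(self):
        with pytest.raises(ValueError):
            d.detection_prob(0.0, 1.0, 1.5, 3.0)


def _single_animal_setup(n_occasions, sigma, g0, behavior_mult=1.0,
                         visit_probs=(0.82, 0.15, 0.03)):
    cfg = d.SimulationConfig(sigma=sigma, g0_camera=g0,
                             n_camera_occasions=n_occasions,
                             behavior_mult=behavior_mult,
                             visit_probs=visit_probs,
                             grid_rows=1, grid_cols=1, n_traps=1,
                             landscape_margin_km=0.5, seed=2)
    det = d.build_detector_grid(1, 1, 0.75, 1, seed=2)
    pop = d.Population(pd.DataFrame(
        {"individual_id": ["A0000"], "x_km": [0.0], "y_km": [0.0]}))
    return cfg, det, pop


class TestCameraPhase:
    def test_deterministic_under_seed(self, midrange_config):
        det = d.build_detector_grid(seed=midrange_config.seed)
        pop = d.simulate_centroids(midrange_config, det)
        h1 = d.simulate_camera_phase(pop, det, midrange_config)
        h2 = d.simulate_camera_phase(pop, det, midrange_config)
        pd.testing.assert_frame_equal(h1.records, h2.records)

    def test_visit_cap_and_daily_scale(self, midrange_dataset):
        rec = midrange_dataset.camera_history.records
        per_night = rec.groupby(["individual_id", "occasion"])[
            "detector_id"].nunique()
        assert per_night.max() <= 3
        assert not rec.duplicated(
            ["individual_id", "occasion", "detector_id"]).any()

    def test_detection_rate_matches_analytic_expectation(self):
        # one animal on top of the single camera: nightly detection
        # probability is g0 * availability(0)
        sigma, g0 = 1.2, 0.9
        cfg, det, pop = _single_animal_setup(1000, sigma, g0)
        hist = d.simulate_camera_phase(pop, det, cfg)
        nights = hist.records["occasion"].nunique()
        expected = g0 * d.availability_prob(0.0, sigma, cfg.camera_trunc_km)
        se = math.sqrt(expected * (1 - expected) / 1000)
        assert abs(nights / 1000 - expected) < 3 * se

    def test_visit_multinomial_matches_probs(self):
        # three tightly packed cameras, animal in reach of all of them:
        # the distinct-camera count per detected night follows visit_probs
        cfg = d.SimulationConfig(sigma=1.2, g0_camera=0.9,
                                 n_camera_occasions=1500, behavior_mult=1.0,
                                 grid_rows=3, grid_cols=1,
                                 camera_spacing_km=0.05, n_traps=1,
                                 landscape_margin_km=0.5, seed=8)
        det = d.build_detector_grid(3, 1, 0.05, 1, seed=8)
        pop = d.Population(pd.DataFrame(
            {"individual_id": ["A0000"], "x_km": [0.05], "y_km": [0.0]}))
        hist = d.simulate_camera_phase(pop, det, cfg)
        k = hist.records.groupby("occasion")["detector_id"].nunique()
        observed = np.array([(k == i).sum() for i in (1, 2, 3)])
        assert observed.sum() > 0
        chi = stats.chisquare(observed,
                              observed.sum() * np.array(cfg.visit_probs))
        assert chi.pvalue > 1e-3

    def test_trap_happiness_raises_return_rate(self):
        # behavior_mult = 2 doubles g0 after first detection; with g0=0.2
        # the return rate should clearly exceed the naive rate
        sigma, g0 = 1.2, 0.2
        base = g0 * d.availability_prob(0.0, sigma, 3 * sigma)
        cfg, det, pop = _single_animal_setup(2000, sigma, g0,
                                             behavior_mult=2.0)
        hist = d.simulate_camera_phase(pop, det, cfg)
        nights = hist.records["occasion"].to_numpy()
        first = nights.min()
        rate_after = (len(nights) - 1) / (2000 - first - 1)
        se = math.sqrt(2 * base * (1 - 2 * base) / (2000 - first - 1))
        assert rate_after > base + 3 * se  # naive rate would sit near base


class TestTrapPhase:
    def test_default_effort_is_140_trap_nights(self, midrange_dataset):
        assert midrange_dataset.effort.total_trap_nights == 140
        assert len(midrange_dataset.effort) == 14

    def test_removal_truncates_records(self, midrange_dataset):
        trap = midrange_dataset.trap_history.records
        assert trap["removed_flag"].all()
        per_ind = trap.groupby("individual_id").size()
        assert (per_ind == 1).all()  # one trap record ever, then removed
        # no record of any kind after the removal occasion
        removals = midrange_dataset.history.removals()
        rec = midrange_dataset.history.records
        for _, row in removals.iterrows():
            later = rec[(rec["individual_id"] == row["individual_id"])
                        & (rec["occasion"] > row["occasion"])]
            assert len(later) == 0

    def test_exhaustive_depletion_removes_everyone(self):
        # p -> 1 regime: clamped availability over a tiny landscape and
        # g0_effective = 1 at the traps
        cfg = d.SimulationConfig(sigma=0.1, g0_camera=1.0, trap_g0_ratio=1.0,
                                 density=400.0, grid_rows=1, grid_cols=1,
                                 n_traps=1, landscape_margin_km=0.08,
                                 cluster_radius_km=0.02, seed=6)
        det = d.build_detector_grid(1, 1, 0.75, 1, seed=6)
        pop = d.simulate_centroids(cfg, det)
        hist, effort = d.simulate_trap_phase(pop, det, cfg)
        assert len(hist.records) == len(pop)  # cumulative catch = N
        assert set(hist.records["individual_id"]) == set(
            pop.individuals["individual_id"])

    def test_conservation(self, midrange_dataset):
        n = len(midrange_dataset.population)
        removed = set(midrange_dataset.history.removals()["individual_id"])
        assert len(removed) + (n - len(removed)) == n
        assert len(removed) <= n


class TestSimulateDataset:
    def test_same_seed_identical_exports(self, midrange_config, tmp_path):
        from densim.io import write_dataset
        a = write_dataset(d.simulate_dataset(midrange_config), tmp_path / "a")
        b = write_dataset(d.simulate_dataset(midrange_config), tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes()

    def test_sparse_regime_often_has_zero_trap_catch(self):
        zero = 0
        for s in range(40):
            cfg = d.SimulationConfig(sigma=0.1, density=0.25, g0_camera=0.1,
                                     seed=s)
            ds = d.simulate_dataset(cfg)
            zero += ds.trap_history.records.empty
        assert zero >= 20  # the sparse corner the estimators choke on
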