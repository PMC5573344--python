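import numpy as np
import pandas as pd
import pytest

import densim as d
from densim.secr import SECRModelSpec, _spatial_recaptures

from conftest import brute_force_secr_loglik, toy_secr_problem


class TestMask:
    def test_detectors_inside_extent(self, detector_grid):
        mask = d.build_mask(detector_grid, buffer_km=2.0, spacing_km=0.25)
        x0, y0, x1, y1 = mask.extent()
        c = detector_grid.coords()
        assert (c[:, 0] >= x0).all() and (c[:, 0] <= x1).all()
        assert (c[:, 1] >= y0).all() and (c[:, 1] <= y1).all()

    def test_halving_spacing_quadruples_points(self, detector_grid):
        coarse = d.build_mask(detector_grid, 2.0, 0.5)
        fine = d.build_mask(detector_grid, 2.0, 0.25)
        assert fine.n_points == pytest.approx(4 * coarse.n_points, rel=0.1)
        assert fine.area == pytest.approx(coarse.area, abs=coarse.cell_area
                                          * 60)

    def test_zero_buffer_equals_bounding_box(self, detector_grid):
        mask = d.build_mask(detector_grid, 0.0, 0.25)
        x0, y0, x1, y1 = mask.extent()
        c = detector_grid.coords()
        assert x0 == pytest.approx(c[:, 0].min(), abs=1e-9)
        assert x1 >= c[:, 0].max()

    def test_invalid_spacing(self, detector_grid):
        with pytest.raises(ValueError):
            d.build_mask(detector_grid, 1.0, 0.0)


class TestLoglik:
    @pytest.mark.parametrize("spec,params", [
        (SECRModelSpec(), dict(density=1.5, g0=0.4, sigma=0.5)),
        (SECRModelSpec(behavior=True),
         dict(density=1.5, g0=0.4, sigma=0.5, beta_bk=0.7)),
        (SECRModelSpec(type_effect=True),
         dict(density=2.5, g0=0.3, sigma=0.4, beta_type=-1.1)),
        (SECRModelSpec(behavior=True, type_effect=True),
         dict(density=1.0, g0=0.5, sigma=0.6, beta_bk=0.5, beta_type=-0.8)),
    ])
    def test_matches_brute_force_enumeration(self, spec, params):
        det, history, mask = toy_secr_problem()
        mine = d.secr_loglik(history, det, mask, params, spec)
        oracle = brute_force_secr_loglik(history, det, mask, params, spec)
        assert mine == pytest.approx(oracle, rel=1e-6)

    def test_vanishing_g0_kills_nonempty_history(self):
        # the likelihood of a nonempty history diverges to -inf as g0 -> 0
        det, history, mask = toy_secr_problem()
        lls = [d.secr_loglik(history, det, mask,
                             dict(density=1.5, g0=g, sigma=0.5))
               for g in (1e-3, 1e-6, 1e-9)]
        assert lls[0] > lls[1] > lls[2]
        assert lls[2] < -90  # ~ 5 detections x log(1e-9)

    def test_mask_refinement_stability(self, camera_array):
        hist = d.simulate_secr_dataset(2.0, 0.5, 0.6, camera_array, 13,
                                       buffer_km=2.4, seed=5)
        params = dict(density=2.0, g0=0.5, sigma=0.6)
        lls = [d.secr_loglik(hist, camera_array,
                             d.build_mask(camera_array, 2.4, s), params)
               for s in (0.1, 0.2)]
        assert abs(lls[0] - lls[1]) < 0.1

    def test_empty_history_rejected(self, camera_array):
        empty = d.EncounterHistory(
            pd.DataFrame(columns=["individual_id", "occasion", "detector_id",
                                  "detector_type", "removed_flag"]), 13, 0)
        mask = d.build_mask(camera_array, 2.0, 0.3)
        with pytest.raises(ValueError, match="no detections"):
            d.secr_loglik(empty, camera_array, mask,
                          dict(density=1.0, g0=0.3, sigma=0.5))


class TestFit:
    def test_single_detection_per_animal_flags_unidentifiable(self,
                                                              camera_array):
        rows = [(f"A{i}", 0, f"C{i:02d}", "camera", False) for i in range(5)]
        hist = d.EncounterHistory(
            pd.DataFrame(rows, columns=["individual_id", "occasion",
                                        "detector_id", "detector_type",
                                        "removed_flag"]), 13, 0)
        assert _spatial_recaptures(hist) == 0
        mask = d.build_mask(camera_array, 2.0, 0.3)
        fit = d.fit_secr(hist, camera_array, mask)
        assert not fit.converged
        assert "sigma" in fit.message

    def test_recovers_generative_parameters(self, camera_array):
        hist = d.simulate_secr_dataset(2.0, 0.5, 0.6, camera_array, 13,
                                       buffer_km=2.4, seed=3)
        est = d.SECREstimator(detectors_used="camera", seed=0).fit(
            hist, camera_array)
        assert est.converged_
        assert est.density_ == pytest.approx(2.0, rel=0.35)
        assert est.sigma_ == pytest.approx(0.6, rel=0.3)
        assert est.g0_["camera"] == pytest.approx(0.5, abs=0.15)

    def test_trap_secr_no_less_precise_than_camera(self, midrange_config):
        # the trap phase adds occasions and detectors; SE(D) should usually
        # shrink
        wins = 0
        n_ok = 0
        for s in range(10):
            ds = d.simulate_dataset(midrange_config.replace(seed=100 + s))
            cam = d.SECREstimator(detectors_used="camera", seed=s).fit(
                ds.history, ds.detectors)
            both = d.SECREstimator(detectors_used="all", seed=s).fit(
                ds.history, ds.detectors)
            if cam.converged_ and both.converged_:
                n_ok += 1
                wins += both.se_density_ <= cam.se_density_
        assert n_ok >= 6
        assert wins > n_ok / 2

    def test_type_effect_recovers_quarter_ratio(self, midrange_config):
        # traps are simulated at 1/4 the camera baseline; the fitted type
        # effect should place the ratio well below 1
        ratios = []
        for s in range(12):
            ds = d.simulate_dataset(
                midrange_config.replace(seed=300 + s, g0_camera=0.7))
            est = d.SECREstimator(detectors_used="all", type_effect=True,
                                  seed=s).fit(ds.history, ds.detectors)
            if est.converged_:
                ratios.append(est.g0_["trap"] / est.g0_["camera"])
        assert len(ratios) >= 6
        inside = sum(0.1 < r < 0.5 for r in ratios)
        assert inside > len(ratios) / 2


class TestAICc:
    def test_formula(self):
        fit = d.SECRFit(density=1, g0={}, sigma=1, se_density=0,
                        se_log_density=0, loglik=-100.0, n_params=3,
                        aicc=0, converged=True)
        table = d.aicc_table([fit], n_individuals=20)
        assert table["aicc"].iloc[0] == pytest.approx(207.5)
        assert table["weight"].iloc[0] == pytest.approx(1.0)

    def test_weights_normalize(self):
        fits = [d.SECRFit(density=1, g0={}, sigma=1, se_density=0,
                          se_log_density=0, loglik=ll, n_params=k,
                          aicc=0, converged=True, model=f"m{k}")
                for ll, k in [(-100, 3), (-99, 4), (-98.5, 5)]]
        table = d.aicc_table(fits, n_individuals=40)
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert (table["delta_aicc"].iloc[0] == 0)

    def test_small_sample_rejected(self):
        fit = d.SECRFit(density=1, g0={}, sigma=1, se_density=0,
                        se_log_density=0, loglik=-10.0, n_params=3,
                        aicc=0, converged=True)
        with pytest.raises(ValueError, match="n > K"):
            d.aicc_table([fit], n_individuals=4)

    def test_model_averaging_within_two_aicc(self):
        fits = [d.SECRFit(density=2.0, g0={}, sigma=1, se_density=0,
                          se_log_density=0, loglik=-100.0, n_params=3,
                          aicc=0, converged=True, model="a"),
                d.SECRFit(density=4.0, g0={}, sigma=1, se_density=0,
                          se_log_density=0, loglik=-100.5, n_params=3,
                          aicc=0, converged=True, model="b")]
        table = d.aicc_table(fits, n_individuals=50)
        assert table.attrs["averaged"]
        assert 2.0 < table.attrs["d_hat"] < 4.0
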