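"""Simulator ground truth: seeding, rates, viability, rendering."""

import numpy as np
import pandas as pd
import pytest

from fluorowell.geometry import ChipGeometry
from fluorowell.population import (PRESETS, ConfigurationError,
                                   PopulationModel, lognormal_params)
from fluorowell.quantification import CalibrationForward
from fluorowell.synthetic import (NOISELESS, RenderParams,
                                  SimulationConfig, apply_viability,
                                  assign_rates, render_calibration_series,
                                  render_phase_images, seed_cells,
                                  simulate_experiment, well_occupancy)


class TestSeedCells:
    def test_degenerate_distribution_fills_every_well(self, geo_mini):
        truth = seed_cells(geo_mini, (0, 1, 0, 0), 0)
        counts = well_occupancy(truth, geo_mini)
        assert (counts == 1).all()

    def test_default_occupancy_single_cell_fraction_near_92pct(self):
        geo = ChipGeometry()
        model = PRESETS["lncap-basal"]
        truth = seed_cells(geo, model.occupancy_probs, 5)
        counts = well_occupancy(truth, geo)
        single = 100.0 * (counts == 1).mean()
        assert single == pytest.approx(92.0, abs=2.0)

    def test_occupancy_histogram_matches_multinomial_error(self, geo_mini):
        probs = np.array(PRESETS["lncap-basal"].occupancy_probs)
        totals = np.zeros(4)
        n_seeds = 50
        for seed in range(n_seeds):
            counts = well_occupancy(seed_cells(geo_mini, probs, seed), geo_mini)
            totals += np.bincount(counts, minlength=4)[:4]
        n = n_seeds * geo_mini.n_wells
        # exact multinomial SD per category
        sd = np.sqrt(n * probs * (1 - probs))
        assert (np.abs(totals - n * probs) <= 3 * sd + 1e-9).all()

    def test_invalid_probabilities_rejected(self, geo_mini):
        with pytest.raises(ConfigurationError):
            seed_cells(geo_mini, (0.5, 0.2, 0.1, 0.1), 0)

    def test_cosseeded_cells_respect_minimum_separation(self, geo_mini):
        truth = seed_cells(geo_mini, (0.0, 0.0, 0.5, 0.5), 1)
        sep = RenderParams().min_separation_um
        for _, grp in truth.groupby("well_id"):
            pos = grp[["x_um", "y_um"]].to_numpy()
            for i in range(len(pos)):
                for j in range(i + 1, len(pos)):
                    assert np.hypot(*(pos[i] - pos[j])) >= sep


class TestAssignRates:
    def test_mixture_mean_increase_is_90_percent(self, geo_mini):
        # 90% of secretors respond with a 2x fold; population mean +90%
        model = PopulationModel(secreting_fraction_t0=1.0,
                                phenotype_fractions=(0.9, 0.1, 0.0),
                                stimulation_fold=2.0, basal_rate_cv=0.0)
        truth = seed_cells(geo_mini, (0, 1, 0, 0), 2)
        truth = assign_rates(truth, model, 3)
        change = (truth.rate_t1 / truth.rate_t0 - 1.0) * 100
        expected = 100 * (0.9 * 2.0 + 0.1 * 1.0 - 1.0)
        assert change.mean() == pytest.approx(expected, abs=5.0)

    def test_zero_cv_gives_constant_rates(self, geo_mini):
        model = PopulationModel(secreting_fraction_t0=1.0, basal_rate_cv=0.0)
        truth = assign_rates(seed_cells(geo_mini, (0, 1, 0, 0), 2), model, 3)
        assert (truth.rate_t0 == model.basal_rate_mean_pg_day).all()

    def test_lognormal_moments_match_closed_form(self):
        mean, cv = 6.1, 0.74
        mu, sigma = lognormal_params(mean, cv)
        rng = np.random.default_rng(0)
        draws = rng.lognormal(mu, sigma, size=100_000)
        assert draws.mean() == pytest.approx(mean, rel=0.02)
        assert draws.std() / draws.mean() == pytest.approx(cv, rel=0.02)

    def test_inhibition_applies_to_sensitive_cells_only(self, geo_mini):
        model = PopulationModel(secreting_fraction_t0=1.0,
                                phenotype_fractions=(0.5, 0.25, 0.25),
                                stimulation_fold=2.0, inhibition_factor=0.15)
        truth = assign_rates(seed_cells(geo_mini, (0, 1, 0, 0), 2), model, 3)
        sens = truth[truth.phenotype == "sensitive"]
        res = truth[truth.phenotype == "resistant"]
        low = truth[truth.phenotype == "insensitive_low"]
        assert np.allclose(sens.rate_t2, sens.rate_t1 * 0.15)
        assert np.allclose(res.rate_t2, res.rate_t1)
        assert np.allclose(low.rate_t1, low.rate_t0)


class TestApplyViability:
    def test_full_viability_keeps_everyone_alive(self, geo_mini):
        model = PopulationModel()
        truth = assign_rates(seed_cells(geo_mini, (0, 1, 0, 0), 2), model, 3)
        truth = apply_viability(truth, model, "enzalutamide", 4)
        assert truth.alive_t2.all()

    def test_enza_preset_marginal_viability_hits_24pct(self):
        geo = ChipGeometry()
        model = PRESETS["lncap-timecourse"]
        truth = assign_rates(seed_cells(geo, model.occupancy_probs, 1),
                             model, 2)
        truth = apply_viability(truth, model, "enzalutamide", 3)
        n = len(truth)
        frac = truth.alive_t2.mean()
        sd = np.sqrt(0.24 * 0.76 / n)
        assert abs(frac - 0.24) <= 3 * sd

    def test_conditional_survival_t1_to_t2_matches_chain_rule(self):
        geo = ChipGeometry()
        model = PRESETS["lncap-timecourse"]
        truth = assign_rates(seed_cells(geo, (0, 1, 0, 0), 1), model, 2)
        truth = apply_viability(truth, model, "enzalutamide", 3)
        at_t1 = truth[truth.alive_t1]
        cond = at_t1.alive_t2.mean()
        expected = 0.24 / 0.78
        sd = np.sqrt(expected * (1 - expected) / len(at_t1))
        assert abs(cond - expected) <= 3 * sd

    def test_death_is_permanent_and_silences_secretion(self, geo_mini):
        model = PopulationModel(viability={"t0": 0.7, "t1": 0.4,
                                           "t2_enza": 0.1, "t2_abi": 0.2},
                                secreting_fraction_t0=1.0)
        truth = assign_rates(seed_cells(geo_mini, (0, 1, 0, 0), 2), model, 3)
        truth = apply_viability(truth, model, "abiraterone", 4)
        alive = truth[["alive_t0", "alive_t1", "alive_t2"]].to_numpy()
        assert (np.diff(alive.astype(int), axis=1) <= 0).all()
        dead_t1 = truth[~truth.alive_t1]
        assert (dead_t1.rate_t1 == 0).all() and (dead_t1.rate_t2 == 0).all()

    def test_non_monotone_viability_rejected(self):
        with pytest.raises(ConfigurationError, match="non-increasing"):
            PopulationModel(viability={"t0": 0.5, "t1": 0.8,
                                       "t2_enza": 0.2, "t2_abi": 0.2})


class TestRendering:
    def test_empty_wells_read_background_in_membrane_roi(self, geo_mini):
        model = PopulationModel()
        truth = assign_rates(seed_cells(geo_mini, (1, 0, 0, 0), 2), model, 3)
        truth = apply_viability(truth, model, "enzalutamide", 4)
        imgs = render_phase_images(truth, geo_mini, NOISELESS,
                                   CalibrationForward(), 24.0, 5)
        assert float(imgs["membrane"].mean()) == pytest.approx(100.0, abs=0.5)

    def test_known_mass_recovered_from_roi_mean_noise_free(self, geo_mini):
        # single secreting cell; ROI-mean inversion must return its mass
        model = PopulationModel(secreting_fraction_t0=1.0, basal_rate_cv=0.0,
                                basal_rate_mean_pg_day=6.0)
        truth = assign_rates(seed_cells(geo_mini, (0, 1, 0, 0), 2), model, 3)
        truth = apply_viability(truth, model, "enzalutamide", 4)
        fwd = CalibrationForward()
        imgs = render_phase_images(truth, geo_mini, NOISELESS, fwd, 24.0, 5)
        from fluorowell.quantification import roi_mean_intensity
        from fluorowell.geometry import well_center_xy
        centers = well_center_xy(geo_mini)
        roi_area = np.pi * geo_mini.spot_roi_radius_um**2
        mid = geo_mini.n_wells // 2 + geo_mini.n_cols // 2
        mean_i = roi_mean_intensity(imgs["membrane"].astype(float),
                                    centers[mid], geo_mini.spot_roi_radius_um,
                                    geo_mini.pixel_size_um)
        excess = mean_i - 100.0
        rho = fwd.rho_half_pg_um2 * excess / (fwd.i_max - excess)
        assert rho * roi_area == pytest.approx(6.0, rel=0.01)

    def test_doubling_duration_doubles_spot_mass(self, geo_mini):
        model = PopulationModel(secreting_fraction_t0=1.0, basal_rate_cv=0.0,
                                basal_rate_mean_pg_day=2.0)
        truth = assign_rates(seed_cells(geo_mini, (0, 1, 0, 0), 2), model, 3)
        truth = apply_viability(truth, model, "enzalutamide", 4)
        fwd = CalibrationForward()
        from fluorowell.quantification import roi_mean_intensity
        from fluorowell.geometry import well_center_xy
        centers = well_center_xy(geo_mini)
        mid = geo_mini.n_wells // 2 + geo_mini.n_cols // 2

        def recovered_mass(duration):
            imgs = render_phase_images(truth, geo_mini, NOISELESS, fwd,
                                       duration, 5)
            mean_i = roi_mean_intensity(imgs["membrane"].astype(float),
                                        centers[mid],
                                        geo_mini.spot_roi_radius_um,
                                        geo_mini.pixel_size_um)
            excess = mean_i - 100.0
            rho = fwd.rho_half_pg_um2 * excess / (fwd.i_max - excess)
            return rho * np.pi * geo_mini.spot_roi_radius_um**2

        assert recovered_mass(48.0) == pytest.approx(2 * recovered_mass(24.0),
                                                     rel=0.02)

    def test_calibration_series_zero_density_reads_background(self, geo_mini):
        img, truth = render_calibration_series(
            geo_mini, [0.0, 0.01, 0.03, 0.075], NOISELESS, 6)
        zero = truth.iloc[0]
        s = geo_mini.pixel_size_um
        px = (np.arange(img.shape[1]) + 0.5) * s
        py = (np.arange(img.shape[0]) + 0.5) * s
        mask = ((px[None, :] - zero.x_um) ** 2 + (py[:, None] - zero.y_um) ** 2
                ) <= (zero.radius_um - 10) ** 2
        assert float(img[mask].mean()) == pytest.approx(100.0, abs=0.5)

    def test_calibration_series_monotone_in_density(self, geo_mini):
        densities = [0.0, 0.005, 0.02, 0.05, 0.075]
        img, truth = render_calibration_series(geo_mini, densities,
                                               NOISELESS, 6)
        s = geo_mini.pixel_size_um
        px = (np.arange(img.shape[1]) + 0.5) * s
        py = (np.arange(img.shape[0]) + 0.5) * s
        means = []
        for row in truth.itertuples():
            mask = ((px[None, :] - row.x_um) ** 2
                    + (py[:, None] - row.y_um) ** 2
                    ) <= (row.radius_um - 10) ** 2
            means.append(float(img[mask].mean()))
        assert (np.diff(means) > 0).all()

    def test_drop_arithmetic_for_printed_standard_series(self):
        # 1 uL of 300 ug/mL spread over 4e6 um^2 -> 0.075 pg/um^2
        mass_pg = 1e-6 * 0.3 * 1e12  # 1e-6 L x 0.3 g/L -> g -> pg
        assert mass_pg == pytest.approx(3e5)
        assert mass_pg / 4e6 == pytest.approx(0.075)


class TestSimulateExperiment:
    def test_identical_config_and_seed_reproduce_truth_bitwise(self, geo_mini):
        cfg = SimulationConfig(preset="lncap-basal", geometry=geo_mini,
                               seed=99, phases=("t0",))
        a = simulate_experiment(cfg)
        b = simulate_experiment(cfg)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        np.testing.assert_array_equal(a.images["t0"]["membrane"],
                                      b.images["t0"]["membrane"])
        np.testing.assert_array_equal(a.calibration_image, b.calibration_image)

    def test_basal_presets_hit_published_rate_moments(self):
        geo = ChipGeometry()
        for preset, mean, sd in [("lncap-basal", 6.1, 4.5),
                                 ("vcap-basal", 3.7, 1.9)]:
            cfg = SimulationConfig(preset=preset, geometry=geo, seed=4,
                                   phases=())
            exp = simulate_experiment(cfg)
            secretors = exp.truth[exp.truth.secretor & exp.truth.alive_t0]
            assert secretors.rate_t0.mean() == pytest.approx(mean, rel=0.05)
            assert secretors.rate_t0.std() == pytest.approx(sd, rel=0.10)

    def test_timecourse_unaltered_fraction_matches_preset(self, geo_mini):
        cfg = SimulationConfig(preset="lncap-timecourse-enza",
                               geometry=geo_mini, seed=12, phases=())
        exp = simulate_experiment(cfg)
        sec = exp.truth[exp.truth.secretor]
        flat = (sec.rate_t1 == sec.rate_t0) & (sec.rate_t0 > 0)
        expected = 0.085  # insensitive_low fraction
        assert flat.mean() == pytest.approx(expected, abs=0.03)

    def test_membrane_mass_conservation_noise_free(self, noiseless_experiment):
        # sum of per-well recovered masses equals total truth mass
        exp = noiseless_experiment
        geo = exp.geometry
        fwd = exp.config.calibration_forward
        from fluorowell.geometry import well_center_xy
        from fluorowell.quantification import measure_well_rois
        centers = well_center_xy(geo)
        means = measure_well_rois(exp.images["t0"]["membrane"].astype(float),
                                  centers, geo.spot_roi_radius_um,
                                  geo.pixel_size_um)
        excess = np.clip(means - 100.0, 0, None)
        rho = fwd.rho_half_pg_um2 * excess / (fwd.i_max - excess)
        mass = rho * np.pi * geo.spot_roi_radius_um**2
        truth_mass = exp.truth.rate_t0.sum()  # 24 h of secretion
        assert mass.sum() == pytest.approx(truth_mass, rel=0.02)
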