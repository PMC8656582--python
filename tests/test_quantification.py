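"""Calibration fitting, background rule, and mass inversion."""

import numpy as np
import pytest

from fluorowell.quantification import (BackgroundStats, CalibrationError,
                                       CalibrationForward,
                                       InsufficientBackgroundError,
                                       estimate_background, fit_calibration,
                                       per_cell_rate, quantify_spot)


def synthetic_standards(densities, noise_sd=0.0, n_px=2000, seed=0,
                        fwd=CalibrationForward(), bg=100.0):
    rng = np.random.default_rng(seed)
    out = []
    for rho in densities:
        base = bg + fwd.excess(rho)
        out.append((rho, base + rng.normal(0, noise_sd, n_px)))
    return out


STANDARDS = (0.0, 0.0075, 0.01875, 0.0375, 0.05625, 0.075)


class TestFitCalibration:
    def test_noise_free_fit_recovers_forward_parameters(self):
        curve = fit_calibration(synthetic_standards(STANDARDS))
        assert curve.i_bg == pytest.approx(100.0, rel=0.005)
        assert curve.i_max == pytest.approx(30000.0, rel=0.005)
        assert curve.rho_half == pytest.approx(0.05, rel=0.005)

    def test_zero_density_anchor_matches_background(self):
        curve = fit_calibration(synthetic_standards(STANDARDS, noise_sd=5.0))
        zero_mean = curve.standards[0][1]
        assert curve.i_bg == pytest.approx(zero_mean, abs=1.0)

    def test_printed_standard_series_is_accepted(self):
        # 0-300 ug/mL in 1 uL over 4e6 um^2 spots -> up to 0.075 pg/um^2
        densities = (0.0, 0.01875, 0.0375, 0.075)
        curve = fit_calibration(synthetic_standards(densities))
        assert curve.rho_max == pytest.approx(0.075)

    def test_too_few_standards_rejected(self):
        with pytest.raises(CalibrationError, match="4 distinct"):
            fit_calibration(synthetic_standards((0.0, 0.01, 0.05)))

    def test_missing_zero_anchor_rejected(self):
        with pytest.raises(CalibrationError, match="zero-density"):
            fit_calibration(synthetic_standards((0.01, 0.02, 0.05, 0.075)))

    def test_non_monotone_standards_rejected(self):
        stds = synthetic_standards(STANDARDS)
        # swap the responses of the two largest densities
        broken = stds[:4] + [(stds[4][0], stds[5][1] * 0 + 5000.0),
                             (stds[5][0], np.full(2000, 2000.0))]
        with pytest.raises(CalibrationError, match="decrease"):
            fit_calibration(broken)


class TestBackground:
    def test_floor_of_50_empty_wells(self):
        with pytest.raises(InsufficientBackgroundError):
            estimate_background(np.full(49, 100.0))
        stats = estimate_background(np.random.default_rng(0).normal(100, 1, 50))
        assert stats.n_wells_used == 50

    def test_override_floor_is_explicit(self):
        stats = estimate_background(np.array([100.0, 101.0, 99.0]),
                                    allow_fewer=True)
        assert stats.mean_intensity == pytest.approx(100.0)

    def test_simulated_background_matches_noise_model(self, basal_analysis):
        bg = basal_analysis.backgrounds["t0"]
        # empty-well ROI means scatter around the configured background of
        # 100 counts; allow for shot noise and neighbour-spot spill
        assert bg.mean_intensity == pytest.approx(100.0, abs=3 * bg.sd_intensity)


class TestQuantifySpot:
    CURVE = fit_calibration(synthetic_standards(STANDARDS))
    BG = BackgroundStats(100.0, 0.5, 60)

    def test_background_intensity_maps_to_zero_mass(self):
        m = quantify_spot(self.BG.mean_intensity, 1000.0, self.CURVE, self.BG)
        assert m.mass_pg == 0.0
        assert not m.above_background
        assert m.censored == "below_range"

    def test_round_trip_mass_within_2pct_across_range(self):
        fwd = CalibrationForward()
        roi_area = np.pi * 35.0**2
        for mass in (0.5, 2.0, 6.0, 20.0, 100.0, 250.0):
            rho = mass / roi_area
            intensity = 100.0 + float(fwd.excess(rho))
            m = quantify_spot(intensity, roi_area, self.CURVE, self.BG)
            assert m.mass_pg == pytest.approx(mass, rel=0.02)

    def test_ceiling_intensity_censored_above_range(self):
        m = quantify_spot(self.CURVE.intensity_ceiling + 10, 1000.0,
                          self.CURVE, self.BG)
        assert m.censored == "above_range"
        assert m.mass_pg == pytest.approx(self.CURVE.rho_max * 1000.0)

    def test_monotone_intensity_to_mass(self):
        intensities = np.linspace(101, self.CURVE.intensity_ceiling - 1, 50)
        masses = [quantify_spot(i, 1000.0, self.CURVE, self.BG).mass_pg
                  for i in intensities]
        assert (np.diff(masses) >= 0).all()


class TestPerCellRate:
    def test_published_scale_example(self):
        assert per_cell_rate(9.6, 2, 24.0) == pytest.approx(4.8)

    def test_half_day_doubles_daily_rate(self):
        assert per_cell_rate(5.0, 1, 12.0) == pytest.approx(10.0)

    def test_homogeneity_in_mass_and_cells(self):
        assert per_cell_rate(4.0, 2, 24.0) == per_cell_rate(8.0, 4, 24.0)

    def test_empty_well_carries_no_rate(self):
        with pytest.raises(ValueError, match="at least one cell"):
            per_cell_rate(1.0, 0, 24.0)


class TestPipelineRecovery:
    def test_noise_free_pipeline_mass_identity(self, noiseless_experiment):
        from fluorowell.pipeline import AnalysisParams, analyze_experiment

        exp = noiseless_experiment
        res = analyze_experiment(exp, AnalysisParams(allow_fewer_empty=True))
        sec = res.secretion["t0"].set_index("well_id")
        truth_mass = exp.truth.groupby("well_id").rate_t0.sum()
        secreting = truth_mass[truth_mass > 0.2]
        got = sec.loc[secreting.index, "mass_pg"]
        rel = np.abs(got.to_numpy() - secreting.to_numpy()) / secreting.to_numpy()
        assert np.quantile(rel, 0.95) <= 0.02

    def test_basal_cohort_mean_recovered_within_10pct(self, basal_experiment,
                                                      basal_analysis):
        sec = basal_analysis.secretion["t0"]
        mask = (sec.n_live == 1) & sec.above_background
        got = sec.loc[mask, "rate_pg_per_cell_day"].mean()
        assert got == pytest.approx(6.1, rel=0.10)
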