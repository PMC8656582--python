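"""Shared fixtures: small chips and cached simulated experiments.

Everything is generated programmatically; the mini chip (20 x 20 wells,
2 x 2 mm) keeps per-test simulation and analysis in the ~1 s range.
"""

from __future__ import annotations

import numpy as np
import pytest

from fluorowell.geometry import ChipGeometry
from fluorowell.pipeline import AnalysisParams, analyze_experiment
from fluorowell.synthetic import (NOISELESS, SimulationConfig,
                                  simulate_experiment)


def mini_geometry(n: int = 20) -> ChipGeometry:
    return ChipGeometry(n_rows=n, n_cols=n,
                        active_area_mm=(n * 0.1, n * 0.1), tile_grid=(2, 2))


@pytest.fixture(scope="session")
def geo_mini() -> ChipGeometry:
    return mini_geometry()


@pytest.fixture(scope="session")
def basal_experiment(geo_mini):
    """Mini-chip LNCaP basal preset experiment, all phases, default noise."""
    cfg = SimulationConfig(preset="lncap-basal", geometry=geo_mini, seed=11)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def basal_analysis(basal_experiment):
    return analyze_experiment(basal_experiment,
                              AnalysisParams(allow_fewer_empty=True))


@pytest.fixture(scope="session")
def timecourse_experiment(geo_mini):
    """Mini-chip LNCaP time-course (enzalutamide arm) experiment."""
    cfg = SimulationConfig(preset="lncap-timecourse-enza", geometry=geo_mini,
                           seed=23)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def timecourse_analysis(timecourse_experiment):
    # a 400-well chip with 53% secretors has fewer than 50 spots left on
    # the post-inhibition membrane; lower the registration floor
    return analyze_experiment(timecourse_experiment,
                              AnalysisParams(allow_fewer_empty=True,
                                             min_registration_spots=20))


@pytest.fixture(scope="session")
def noiseless_experiment(geo_mini):
    """Noise-free mini-chip experiment for exact-recovery checks."""
    cfg = SimulationConfig(preset="lncap-basal", geometry=geo_mini, seed=7,
                           noise=NOISELESS, membrane_shift_max_um=0.0,
                           membrane_theta_max_deg=0.0)
    return simulate_experiment(cfg)


def truth_live_counts(experiment, phase: str = "t0") -> np.ndarray:
    """Ground-truth live-cell count per well, indexed by well id."""
    geo = experiment.geometry
    counts = np.zeros(geo.n_wells, dtype=int)
    live = experiment.truth[experiment.truth[f"alive_{phase}"]]
    vc = live.groupby("well_id").size()
    counts[vc.index.to_numpy()] = vc.to_numpy()
    return counts
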