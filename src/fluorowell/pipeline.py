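"""End-to-end analysis: detection -> registration -> calibration ->
quantification -> dynamics, on in-memory images.

This is the library face of the pipeline; the command-line layer adds
only file plumbing around it.  The analysis never touches the
simulator's ground truth: cell counts come from the rendered channels,
the membrane transform is re-estimated from the spots, the calibration
curve is re-fitted from the rendered standards, and background comes
from wells the detector itself called empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import (DetectionParams, observations_to_frame,
                        viability_per_well)
from .dynamics import (ClassificationThresholds, SecretionTimeSeries,
                       build_timeseries, cohort_metrics)
from .geometry import ChipGeometry
from .population import PHASES
from .quantification import (BackgroundStats, CalibrationCurve,
                             estimate_background, fit_calibration,
                             measure_well_rois, quantify_spot)
from .registration import RigidTransform, assign_spots_to_wells, estimate_alignment

__all__ = ["AnalysisParams", "AnalysisResult", "analyze_experiment",
           "extract_standard_samples", "quantify_phase"]


@dataclass(frozen=True)
class AnalysisParams:
    """Stage tuning shared by the library and CLI entry points."""

    detection: DetectionParams = field(default_factory=DetectionParams)
    thresholds: ClassificationThresholds = field(
        default_factory=ClassificationThresholds)
    background_k_sd: float = 3.0
    min_empty_wells: int = 50
    allow_fewer_empty: bool = False
    min_registration_spots: int = 50
    phase_duration_h: float = 24.0


@dataclass
class AnalysisResult:
    geometry: ChipGeometry
    observations: dict[str, pd.DataFrame]
    transforms: dict[str, RigidTransform]
    curve: CalibrationCurve
    backgrounds: dict[str, BackgroundStats]
    secretion: dict[str, pd.DataFrame]
    series: list[SecretionTimeSeries]
    cohort: dict
    cohort_single_cell: dict
    drug_arm: str = ""


def extract_standard_samples(calibration_image: np.ndarray,
                             calibration_truth: pd.DataFrame,
                             pixel_size_um: float,
                             margin_um: float = 10.0):
    """(density, pixel sample) pairs from the standard discs.

    Disc positions and densities are experimental metadata (the
    experimenter spotted them); pixels are taken inside each disc with a
    margin so edge pixels do not dilute the sample.
    """
    img = np.asarray(calibration_image)
    ny, nx = img.shape
    s = pixel_size_um
    px = (np.arange(nx) + 0.5) * s
    py = (np.arange(ny) + 0.5) * s
    samples = []
    for row in calibration_truth.itertuples():
        r = row.radius_um - margin_um
        mask = ((px[None, :] - row.x_um) ** 2
                + (py[:, None] - row.y_um) ** 2) <= r * r
        samples.append((row.density_pg_um2, img[mask]))
    return samples


def quantify_phase(membrane, geometry: ChipGeometry, transform: RigidTransform,
                   curve: CalibrationCurve, background: BackgroundStats,
                   observations: pd.DataFrame, phase: str,
                   duration_h: float = 24.0,
                   k_sd: float = 3.0) -> pd.DataFrame:
    """Quantify every well's spot on one registered membrane.

    Returns one row per well: mean ROI intensity, inverted mass, the
    above-background call, censoring status, and -- where the well holds
    at least one live cell -- the per-cell rate in pg/cell/day.
    """
    data = np.asarray(getattr(membrane, "data", membrane))
    centers = assign_spots_to_wells(data, transform, geometry)
    roi_means = measure_well_rois(data, centers, geometry.spot_roi_radius_um,
                                  geometry.pixel_size_um)
    roi_area = np.pi * geometry.spot_roi_radius_um**2
    n_live = observations.set_index("well_id")["n_live"]
    rows = []
    for well_id, mean_i in enumerate(roi_means):
        m = quantify_spot(mean_i, roi_area, curve, background,
                          well_id=well_id, phase=phase, k_sd=k_sd)
        live = int(n_live.get(well_id, 0) or 0)
        rate = (m.mass_pg / live / (duration_h / 24.0)) if live >= 1 else np.nan
        rows.append({"well_id": well_id, "phase": phase,
                     "mean_intensity": m.mean_intensity,
                     "roi_area_um2": m.roi_area_um2, "mass_pg": m.mass_pg,
                     "n_live": live, "rate_pg_per_cell_day": rate,
                     "above_background": m.above_background,
                     "censored": m.censored})
    return pd.DataFrame(rows)


def analyze_experiment(experiment, params: AnalysisParams | None = None
                       ) -> AnalysisResult:
    """Run the full analysis on a simulated (or loaded) experiment.

    ``experiment`` must expose ``geometry``, ``images`` ({phase:
    {"cell", "dead", "membrane"}}), ``calibration_image`` and
    ``calibration_truth``; :class:`~fluorowell.synthetic.SimulatedExperiment`
    and the on-disk loader both do.
    """
    params = params or AnalysisParams()
    geometry = experiment.geometry
    phases = [p for p in PHASES if p in experiment.images]

    observations: dict[str, pd.DataFrame] = {}
    for phase in phases:
        obs = viability_per_well(experiment.images[phase]["cell"],
                                 experiment.images[phase]["dead"],
                                 geometry, params.detection, phase=phase)
        observations[phase] = observations_to_frame(obs)

    samples = extract_standard_samples(experiment.calibration_image,
                                       experiment.calibration_truth,
                                       geometry.pixel_size_um)
    curve = fit_calibration(samples)

    # Empty wells are defined once, at t0, before any treatment.
    t0_obs = observations[phases[0]]
    empty_ids = t0_obs.loc[t0_obs["n_cells_detected"] == 0, "well_id"].to_numpy()

    transforms: dict[str, RigidTransform] = {}
    backgrounds: dict[str, BackgroundStats] = {}
    secretion: dict[str, pd.DataFrame] = {}
    for phase in phases:
        membrane = experiment.images[phase]["membrane"]
        tr = estimate_alignment(membrane, geometry,
                                min_spots=params.min_registration_spots)
        transforms[phase] = tr
        centers = assign_spots_to_wells(membrane, tr, geometry)
        roi_means = measure_well_rois(np.asarray(membrane), centers,
                                      geometry.spot_roi_radius_um,
                                      geometry.pixel_size_um)
        bg = estimate_background(roi_means[empty_ids],
                                 min_wells=params.min_empty_wells,
                                 allow_fewer=params.allow_fewer_empty)
        backgrounds[phase] = bg
        secretion[phase] = quantify_phase(
            membrane, geometry, tr, curve, bg, observations[phase], phase,
            duration_h=params.phase_duration_h, k_sd=params.background_k_sd)

    drug_arm = getattr(experiment, "drug_arm", "")
    series = []
    if "t0" in secretion:
        series = build_timeseries(secretion, observations,
                                  duration_h=params.phase_duration_h,
                                  drug_arm=drug_arm)
    cohort = cohort_metrics(series, params.thresholds) if series else {}
    single = [s for s in series if s.n_cells == 1]
    cohort_single = cohort_metrics(single, params.thresholds) if single else {}

    return AnalysisResult(geometry=geometry, observations=observations,
                          transforms=transforms, curve=curve,
                          backgrounds=backgrounds, secretion=secretion,
                          series=series, cohort=cohort,
                          cohort_single_cell=cohort_single, drug_arm=drug_arm)
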