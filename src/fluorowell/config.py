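"""One-YAML run configuration: schema validation and object building.

Every numeric default of the pipeline is overridable here and the
resolved configuration is snapshotted into the run directory, so a run
is fully described by (config, seed).  Unknown keys are rejected rather
than ignored -- a typo must fail loudly, not silently fall back to a
default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detection import DetectionParams
from .dynamics import ClassificationThresholds
from .geometry import ChipGeometry
from .population import ConfigurationError, PopulationModel
from .pipeline import AnalysisParams
from .quantification import CalibrationForward
from .synthetic import NoiseModel, RenderParams, SimulationConfig

__all__ = ["RunConfig", "load_run_config"]

_SIMULATE_KEYS = {"membrane_shift_max_um", "membrane_theta_max_deg",
                  "phases", "phase_duration_h", "calibration_densities"}
_QUANTIFY_KEYS = {"background_k_sd", "min_empty_wells", "allow_fewer_empty",
                  "min_registration_spots"}
_TOP_KEYS = {"preset", "population", "drug_arm", "seed", "geometry", "noise",
             "render", "calibration_forward", "simulate", "detection",
             "thresholds", "quantify"}


def _check_keys(d: dict, allowed: set[str], context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} under {context!r}; "
            f"allowed: {sorted(allowed)}")


def _build(cls, d: dict | None, context: str):
    d = d or {}
    fields = {f.name for f in dataclasses.fields(cls)}
    _check_keys(d, fields, context)
    kwargs = dict(d)
    for key in ("occupancy_probs", "phenotype_fractions", "phases",
                "calibration_densities", "active_area_mm", "tile_grid"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    if "rate_mean_by_occupancy" in kwargs and kwargs["rate_mean_by_occupancy"]:
        kwargs["rate_mean_by_occupancy"] = {
            int(k): float(v) for k, v in kwargs["rate_mean_by_occupancy"].items()}
    return cls(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """Validated top-level run description."""

    preset: str | None = "lncap-timecourse-enza"
    population: PopulationModel | None = None
    drug_arm: str | None = None
    seed: int = 0
    geometry: ChipGeometry = field(default_factory=ChipGeometry)
    noise: NoiseModel = field(default_factory=NoiseModel)
    render: RenderParams = field(default_factory=RenderParams)
    calibration_forward: CalibrationForward = field(
        default_factory=CalibrationForward)
    simulate: dict = field(default_factory=dict)
    detection: DetectionParams = field(default_factory=DetectionParams)
    thresholds: ClassificationThresholds = field(
        default_factory=ClassificationThresholds)
    quantify: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d or {})
        _check_keys(d, _TOP_KEYS, "config root")
        sim = dict(d.get("simulate") or {})
        _check_keys(sim, _SIMULATE_KEYS, "simulate")
        if "phases" in sim:
            sim["phases"] = tuple(sim["phases"])
        if "calibration_densities" in sim:
            sim["calibration_densities"] = tuple(sim["calibration_densities"])
        quant = dict(d.get("quantify") or {})
        _check_keys(quant, _QUANTIFY_KEYS, "quantify")
        population = d.get("population")
        if population is not None:
            population = _build(PopulationModel, population, "population")
        return cls(
            preset=d.get("preset") if population is None else None,
            population=population,
            drug_arm=d.get("drug_arm"),
            seed=int(d.get("seed", 0)),
            geometry=_build(ChipGeometry, d.get("geometry"), "geometry"),
            noise=_build(NoiseModel, d.get("noise"), "noise"),
            render=_build(RenderParams, d.get("render"), "render"),
            calibration_forward=_build(CalibrationForward,
                                       d.get("calibration_forward"),
                                       "calibration_forward"),
            simulate=sim,
            detection=_build(DetectionParams, d.get("detection"), "detection"),
            thresholds=_build(ClassificationThresholds, d.get("thresholds"),
                              "thresholds"),
            quantify=quant,
        )

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            preset=self.preset, model=self.population, drug_arm=self.drug_arm,
            geometry=self.geometry, render=self.render, noise=self.noise,
            calibration_forward=self.calibration_forward, seed=self.seed,
            **self.simulate)

    def analysis_params(self) -> AnalysisParams:
        return AnalysisParams(
            detection=self.detection, thresholds=self.thresholds,
            background_k_sd=self.quantify.get("background_k_sd", 3.0),
            min_empty_wells=self.quantify.get("min_empty_wells", 50),
            allow_fewer_empty=self.quantify.get("allow_fewer_empty", False),
            min_registration_spots=self.quantify.get(
                "min_registration_spots", 50),
            phase_duration_h=self.simulate.get("phase_duration_h", 24.0))

    def snapshot(self) -> dict:
        """Fully resolved configuration for the run directory."""
        model, arm = self.simulation_config().resolve()
        return {
            "preset": self.preset,
            "drug_arm": arm,
            "seed": self.seed,
            "population": dataclasses.asdict(model),
            "geometry": self.geometry.to_dict(),
            "noise": dataclasses.asdict(self.noise),
            "render": dataclasses.asdict(self.render),
            "calibration_forward": dataclasses.asdict(self.calibration_forward),
            "simulate": {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in self.simulate.items()},
            "detection": dataclasses.asdict(self.detection),
            "thresholds": dataclasses.asdict(self.thresholds),
            "quantify": dict(self.quantify),
        }


def load_run_config(path) -> RunConfig:
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)
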