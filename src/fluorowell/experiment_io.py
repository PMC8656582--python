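"""On-disk layout of a simulated experiment and of analysis outputs.

A simulated experiment directory holds, per phase, tiled 16-bit TIFFs
named ``{phase}_{channel}_r{R}_c{C}.tif`` (channels ``cell``, ``dead``,
``membrane``), the calibration-standard image ``calibration.tif`` with
its metadata table ``truth_calibration.csv``, the simulator ground truth
``truth_cells.csv`` and the injected membrane transforms
``truth_transforms.yaml`` (kept for scoring, never read by the
analysis), and a ``manifest.yaml`` describing geometry, tile map and
phase metadata (drug and concentration per phase).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import ChipGeometry
from .image_io import Mosaic, load_manifest, read_tile_grid, write_tile_grid
from .population import PHASES

__all__ = ["write_experiment", "load_experiment", "LoadedExperiment"]

PHASE_TREATMENT = {
    "t0": "none",
    "t1": "R1881 2 nM",
    "t2": "{drug_arm}",
}
DRUG_CONCENTRATION = {"enzalutamide": "2 uM", "abiraterone": "1 uM"}


def write_experiment(experiment, out_dir) -> Path:
    """Write a SimulatedExperiment to disk (tiles + manifest + truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geometry = experiment.geometry
    manifest_path = out / "manifest.yaml"
    manifest = {
        "geometry": geometry.to_dict(),
        "pixel_size_um": geometry.pixel_size_um,
        "tile_grid": list(geometry.tile_grid),
        "drug_arm": experiment.drug_arm,
        "phases": {},
        "tiles": [],
    }
    for phase in experiment.images:
        treatment = PHASE_TREATMENT[phase].format(drug_arm=experiment.drug_arm)
        if phase == "t2":
            treatment += f" {DRUG_CONCENTRATION[experiment.drug_arm]}"
        manifest["phases"][phase] = {
            "duration_h": experiment.config.phase_duration_h,
            "treatment": treatment,
        }
    from .image_io import save_manifest

    save_manifest(manifest, manifest_path)
    for phase, channels in experiment.images.items():
        for channel, img in channels.items():
            mosaic = Mosaic(data=img, pixel_size_um=geometry.pixel_size_um)
            write_tile_grid(mosaic, manifest_path, phase, channel,
                            tile_grid=geometry.tile_grid)

    tifffile.imwrite(out / "calibration.tif",
                     np.ascontiguousarray(experiment.calibration_image,
                                          dtype=np.uint16),
                     compression=None)
    experiment.calibration_truth.to_csv(out / "truth_calibration.csv",
                                        index=False)
    experiment.truth.to_csv(out / "truth_cells.csv", index=False)
    with open(out / "truth_transforms.yaml", "w") as fh:
        yaml.safe_dump(
            {p: list(map(float, t))
             for p, t in experiment.membrane_transforms.items()}, fh)
    return out


@dataclass
class LoadedExperiment:
    """Experiment re-read from disk; satisfies the analysis contract."""

    geometry: ChipGeometry
    images: dict[str, dict[str, np.ndarray]]
    calibration_image: np.ndarray
    calibration_truth: pd.DataFrame
    drug_arm: str
    manifest: dict
    truth: pd.DataFrame | None = None


def load_experiment(exp_dir, phases=None, channels=("cell", "dead", "membrane"),
                    with_truth: bool = False) -> LoadedExperiment:
    exp_dir = Path(exp_dir)
    manifest_path = exp_dir / "manifest.yaml"
    manifest = load_manifest(manifest_path)
    geometry = ChipGeometry.from_dict(manifest["geometry"])
    listed = sorted({t["phase"] for t in manifest["tiles"]},
                    key=lambda p: PHASES.index(p) if p in PHASES else 99)
    phases = list(phases) if phases is not None else listed
    images = {
        phase: {ch: read_tile_grid(manifest_path, phase, ch).data
                for ch in channels}
        for phase in phases
    }
    truth = None
    if with_truth and (exp_dir / "truth_cells.csv").exists():
        truth = pd.read_csv(exp_dir / "truth_cells.csv")
    return LoadedExperiment(
        geometry=geometry, images=images,
        calibration_image=tifffile.imread(exp_dir / "calibration.tif"),
        calibration_truth=pd.read_csv(exp_dir / "truth_calibration.csv"),
        drug_arm=manifest.get("drug_arm", ""), manifest=manifest, truth=truth)
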