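"""Forward simulator for a three-phase microwell fluorospot experiment.

Generates ground-truth cells (positions, phenotypes, per-phase secretion
rates, viability) and renders all the images the analysis pipeline
consumes: a calcein-AM live-cell channel and an ethidium-homodimer
dead-cell channel per phase, one capture-membrane image per phase, and a
calibration-standard membrane with uniform discs of known areal PSA
density.  Rendering is a pure function of the truth plus a noise seed, so
identical configurations reproduce bit-identical outputs.

Imaging model
-------------
Cells appear as isotropic Gaussian blobs at fixed jittered positions
inside their well.  Each live cell contributes its secretion-rate mass
(rate x duration/24 h) to a diffusion-broadened Gaussian membrane spot
centred on the well's pore.  The spot amplitude is normalised so that the
mean intensity over the fixed measurement ROI equals the forward
calibration of the well's areal density (mass / ROI area); fixed-ROI
quantification is therefore mass-conserving by construction.  All
channels add a constant background, Poisson shot noise and Gaussian read
noise, and are clipped to the unsigned 16-bit range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ChipGeometry, well_center_xy
from .population import (
    PHASES,
    PHENOTYPES,
    ConfigurationError,
    PopulationModel,
    get_preset,
    lognormal_params,
)
from .quantification import CalibrationForward

__all__ = [
    "NoiseModel",
    "RenderParams",
    "SimulationConfig",
    "SimulatedExperiment",
    "seed_cells",
    "assign_rates",
    "apply_viability",
    "render_phase_images",
    "render_calibration_series",
    "simulate_experiment",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive background plus shot and read noise, in camera counts."""

    background: float = 100.0
    read_noise_sd: float = 8.0
    poisson: bool = True

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Noise the clean (background-included) image and quantise to uint16."""
        if self.poisson:
            img = rng.poisson(np.clip(clean, 0, None)).astype(float)
        else:
            img = clean.astype(float, copy=True)
        if self.read_noise_sd > 0:
            img += rng.normal(0.0, self.read_noise_sd, size=img.shape)
        clipped = (img > 65535).any()
        img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
        if clipped:
            warnings.warn("rendered intensities exceeded the 16-bit ceiling; clipped",
                          stacklevel=2)
        return img


NOISELESS = NoiseModel(read_noise_sd=0.0, poisson=False)


@dataclass(frozen=True)
class RenderParams:
    """Optical/placement parameters of the renderer (micrometres)."""

    cell_sigma_um: float = 4.0
    cell_peak: float = 3000.0
    dead_peak: float = 3000.0
    jitter_radius_um: float = 25.0
    min_separation_um: float = 18.0
    spot_sigma_um: float = 20.0
    patch_sigma_mult: float = 5.0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Ground truth


def seed_cells(geometry: ChipGeometry, occupancy_probs, rng_seed,
               render: RenderParams | None = None) -> pd.DataFrame:
    """Draw per-well cell counts i.i.d. and place cells inside their wells.

    Returns the truth table: one row per cell with columns well_id,
    cell_index, x_um, y_um.  Positions are uniform in a disc of the jitter
    radius around the well centre, with a minimum pairwise separation so
    co-seeded cells do not physically overlap; they stay fixed across
    phases (the cell adheres where it lands).
    """
    render = render or RenderParams()
    probs = np.asarray(occupancy_probs, dtype=float)
    if probs.ndim != 1 or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6:
        raise ConfigurationError("occupancy_probs must be non-negative and sum to 1")
    probs = probs / probs.sum()
    if render.jitter_radius_um >= geometry.pitch_um / 2:
        raise ConfigurationError("jitter radius must be below half the pitch")
    rng = _as_rng(rng_seed)
    centers = well_center_xy(geometry)
    n_cells = rng.choice(len(probs), size=geometry.n_wells, p=probs)

    rows: list[tuple[int, int, float, float]] = []
    for well_id in np.flatnonzero(n_cells):
        k = int(n_cells[well_id])
        cx, cy = centers[well_id]
        pos = _place_cells(rng, k, render.jitter_radius_um,
                           render.min_separation_um)
        for j in range(k):
            rows.append((well_id, j, cx + pos[j, 0], cy + pos[j, 1]))
    truth = pd.DataFrame(rows, columns=["well_id", "cell_index", "x_um", "y_um"])
    truth["well_id"] = truth["well_id"].astype(int)
    truth["cell_index"] = truth["cell_index"].astype(int)
    truth.attrs["n_wells"] = geometry.n_wells
    return truth


def _place_cells(rng: np.random.Generator, k: int, radius: float,
                 min_sep: float, max_tries: int = 200) -> np.ndarray:
    """Uniform positions in a disc with pairwise separation >= min_sep."""
    for _ in range(max_tries):
        r = radius * np.sqrt(rng.random(k))
        phi = rng.random(k) * 2 * np.pi
        pos = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
        if k == 1:
            return pos
        d = np.hypot(*(pos[:, None, :] - pos[None, :, :]).transpose(2, 0, 1))
        if d[np.triu_indices(k, 1)].min() >= min_sep:
            return pos
    raise ConfigurationError(
        f"could not place {k} cells with separation {min_sep} in radius {radius}"
    )


def assign_rates(truth: pd.DataFrame, model: PopulationModel, rng_seed) -> pd.DataFrame:
    """Label cells secretor/phenotype and assign per-phase secretion rates.

    Secretor basal rates are lognormal with the model's mean and CV (CV 0
    degenerates to the constant mean); non-secretors get the residual rate.
    Stimulation at t1 multiplies sensitive and resistant secretors by the
    stimulation fold; inhibition at t2 multiplies sensitive cells by the
    inhibition factor.  Viability is applied separately.
    """
    rng = _as_rng(rng_seed)
    truth = truth.copy()
    n = len(truth)
    truth["secretor"] = rng.random(n) < model.secreting_fraction_t0
    truth["phenotype"] = rng.choice(
        PHENOTYPES, size=n, p=np.asarray(model.phenotype_fractions))

    occupancy = truth.groupby("well_id")["cell_index"].transform("size").to_numpy()
    rate0 = np.full(n, model.nonsecretor_rate_pg_day, dtype=float)
    sec = truth["secretor"].to_numpy()
    for occ in np.unique(occupancy):
        mean = model.basal_mean_for_occupancy(int(occ))
        mask = sec & (occupancy == occ)
        if model.basal_rate_cv == 0:
            rate0[mask] = mean
        else:
            mu, sigma = lognormal_params(mean, model.basal_rate_cv)
            rate0[mask] = rng.lognormal(mu, sigma, size=int(mask.sum()))

    phen = truth["phenotype"].to_numpy()
    responsive = sec & np.isin(phen, ["sensitive", "resistant"])
    rate1 = np.where(responsive, rate0 * model.stimulation_fold, rate0)
    inhibited = sec & (phen == "sensitive")
    rate2 = np.where(inhibited, rate1 * model.inhibition_factor, rate1)
    truth["rate_t0"], truth["rate_t1"], truth["rate_t2"] = rate0, rate1, rate2
    return truth


def apply_viability(truth: pd.DataFrame, model: PopulationModel, drug_arm: str,
                    rng_seed) -> pd.DataFrame:
    """Draw per-cell survival so each phase's marginal viable fraction
    matches the model; death is permanent and zeroes later rates."""
    rng = _as_rng(rng_seed)
    v = model.marginal_viability(drug_arm)
    truth = truth.copy()
    n = len(truth)
    alive = np.ones(n, dtype=bool)
    prev = 1.0
    for phase, marginal in zip(PHASES, v):
        cond = 1.0 if prev == 0 else marginal / prev
        alive = alive & (rng.random(n) < cond)
        truth[f"alive_{phase}"] = alive
        truth.loc[~alive, f"rate_{phase}"] = 0.0
        prev = marginal
    truth.attrs["drug_arm"] = drug_arm
    return truth


def well_occupancy(truth: pd.DataFrame, geometry: ChipGeometry) -> np.ndarray:
    """Per-well true cell counts, indexed by well_id."""
    counts = np.zeros(geometry.n_wells, dtype=int)
    vc = truth["well_id"].value_counts()
    counts[vc.index.to_numpy()] = vc.to_numpy()
    return counts


# ---------------------------------------------------------------------------
# Rendering


def _add_blobs(img: np.ndarray, xs, ys, amps, sigma_um: float,
               pixel_size_um: float, patch_mult: float) -> None:
    """Accumulate Gaussian blobs (chip-frame um coordinates) into img."""
    s = pixel_size_um
    half = int(np.ceil(patch_mult * sigma_um / s))
    ny, nx = img.shape
    for x, y, a in zip(np.asarray(xs), np.asarray(ys), np.asarray(amps)):
        cj = int(np.floor(x / s))
        ci = int(np.floor(y / s))
        j0, j1 = max(cj - half, 0), min(cj + half + 1, nx)
        i0, i1 = max(ci - half, 0), min(ci + half + 1, ny)
        if j0 >= j1 or i0 >= i1:
            continue
        px = (np.arange(j0, j1) + 0.5) * s
        py = (np.arange(i0, i1) + 0.5) * s
        gx = np.exp(-((px - x) ** 2) / (2 * sigma_um**2))
        gy = np.exp(-((py - y) ** 2) / (2 * sigma_um**2))
        img[i0:i1, j0:j1] += a * gy[:, None] * gx[None, :]


def roi_shape_mean(geometry: ChipGeometry, sigma_um: float) -> float:
    """Mean of a unit-peak Gaussian over the pixelised measurement ROI."""
    s = geometry.pixel_size_um
    r = geometry.spot_roi_radius_um
    half = int(np.ceil(r / s)) + 1
    off = (np.arange(-half, half + 1) + 0.0) * s
    xx, yy = np.meshgrid(off, off)
    rr2 = xx**2 + yy**2
    mask = rr2 <= r * r
    return float(np.exp(-rr2[mask] / (2 * sigma_um**2)).mean())


def _rigid_forward(points: np.ndarray, center: np.ndarray,
                   dx: float, dy: float, theta_deg: float) -> np.ndarray:
    """Map chip-frame points into the membrane frame (rotation about the
    chip centre, then translation)."""
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    rel = points - center
    rot = np.column_stack([c * rel[:, 0] - s * rel[:, 1],
                           s * rel[:, 0] + c * rel[:, 1]])
    return rot + center + np.array([dx, dy])


def render_phase_images(
    truth: pd.DataFrame,
    geometry: ChipGeometry,
    noise: NoiseModel,
    calibration_forward: CalibrationForward,
    duration_h: float,
    rng_seed,
    phase: str = "t0",
    render: RenderParams | None = None,
    membrane_transform: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> dict[str, np.ndarray]:
    """Render the live-cell, dead-cell and membrane images for one phase.

    The membrane may carry a rigid mounting transform (dx_um, dy_um,
    theta_deg about the chip centre); spots are drawn at the transformed
    pore positions, which is what the registration stage must undo.
    """
    render = render or RenderParams()
    rng = _as_rng(rng_seed)
    shape = geometry.image_shape
    alive = truth[f"alive_{phase}"].to_numpy()

    cell = np.full(shape, noise.background, dtype=float)
    _add_blobs(cell, truth.loc[alive, "x_um"], truth.loc[alive, "y_um"],
               np.full(int(alive.sum()), render.cell_peak),
               render.cell_sigma_um, geometry.pixel_size_um,
               render.patch_sigma_mult)

    dead = np.full(shape, noise.background, dtype=float)
    _add_blobs(dead, truth.loc[~alive, "x_um"], truth.loc[~alive, "y_um"],
               np.full(int((~alive).sum()), render.dead_peak),
               render.cell_sigma_um, geometry.pixel_size_um,
               render.patch_sigma_mult)

    membrane = np.full(shape, noise.background, dtype=float)
    mass = (truth[f"rate_{phase}"].to_numpy() * duration_h / 24.0)
    per_well = (pd.Series(mass).groupby(truth["well_id"].to_numpy()).sum())
    well_ids = per_well.index.to_numpy()
    masses = per_well.to_numpy()
    nonzero = masses > 0
    if nonzero.any():
        centers = well_center_xy(geometry)[well_ids[nonzero]]
        chip_center = np.array([geometry.n_cols * geometry.pitch_um / 2.0,
                                geometry.n_rows * geometry.pitch_um / 2.0])
        spots = _rigid_forward(centers, chip_center, *membrane_transform)
        roi_area = np.pi * geometry.spot_roi_radius_um**2
        shape_mean = roi_shape_mean(geometry, render.spot_sigma_um)
        amps = calibration_forward.excess(masses[nonzero] / roi_area) / shape_mean
        _add_blobs(membrane, spots[:, 0], spots[:, 1], amps,
                   render.spot_sigma_um, geometry.pixel_size_um,
                   render.patch_sigma_mult)

    return {
        "cell": noise.apply(cell, rng),
        "dead": noise.apply(dead, rng),
        "membrane": noise.apply(membrane, rng),
    }


def render_calibration_series(
    geometry: ChipGeometry,
    densities,
    noise: NoiseModel,
    rng_seed,
    calibration_forward: CalibrationForward | None = None,
    disc_radius_um: float = 150.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the calibration-standard membrane: one uniform disc per
    areal density (pg/um^2), plus the noise model's background.

    Returns the image and a truth table (spot_id, density, centre, radius).
    """
    densities = np.asarray(densities, dtype=float)
    if np.any(densities < 0):
        raise ConfigurationError("calibration densities must be non-negative")
    calibration_forward = calibration_forward or CalibrationForward()
    rng = _as_rng(rng_seed)
    s = geometry.pixel_size_um
    step = 2 * disc_radius_um + 100.0
    width_px = int(np.ceil(len(densities) * step / s))
    height_px = int(np.ceil(step / s))
    img = np.full((height_px, width_px), noise.background, dtype=float)
    py = (np.arange(height_px) + 0.5) * s
    cy = step / 2.0
    rows = []
    for k, rho in enumerate(densities):
        cx = (k + 0.5) * step
        px = (np.arange(width_px) + 0.5) * s
        rr2 = (px[None, :] - cx) ** 2 + (py[:, None] - cy) ** 2
        img[rr2 <= disc_radius_um**2] += calibration_forward.excess(rho)
        rows.append((k, rho, cx, cy, disc_radius_um))
    truth = pd.DataFrame(
        rows, columns=["spot_id", "density_pg_um2", "x_um", "y_um", "radius_um"])
    return noise.apply(img, rng), truth


# ---------------------------------------------------------------------------
# Whole experiments


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to regenerate one experiment bit-for-bit."""

    preset: str | None = "lncap-basal"
    model: PopulationModel | None = None
    drug_arm: str | None = None
    geometry: ChipGeometry = field(default_factory=ChipGeometry)
    render: RenderParams = field(default_factory=RenderParams)
    noise: NoiseModel = field(default_factory=NoiseModel)
    calibration_forward: CalibrationForward = field(default_factory=CalibrationForward)
    seed: int = 0
    phases: tuple[str, ...] = PHASES
    phase_duration_h: float = 24.0
    membrane_shift_max_um: float = 30.0
    membrane_theta_max_deg: float = 0.5
    calibration_densities: tuple[float, ...] = (
        0.0, 0.0075, 0.01875, 0.0375, 0.05625, 0.075)

    def resolve(self) -> tuple[PopulationModel, str]:
        if self.model is not None:
            return self.model, (self.drug_arm or "enzalutamide")
        model, arm = get_preset(self.preset)
        return model, (self.drug_arm or arm)


@dataclass
class SimulatedExperiment:
    """In-memory experiment: truth plus every rendered image."""

    config: SimulationConfig
    truth: pd.DataFrame
    images: dict[str, dict[str, np.ndarray]]
    membrane_transforms: dict[str, tuple[float, float, float]]
    calibration_image: np.ndarray
    calibration_truth: pd.DataFrame
    drug_arm: str

    @property
    def geometry(self) -> ChipGeometry:
        return self.config.geometry


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Run the full forward simulation for one chip.

    All randomness flows from the config seed through named substreams
    (cells, rates, viability, transforms, one per rendered phase, and the
    calibration series), so any stage re-run alone reproduces its output.
    """
    model, arm = config.resolve()
    ss = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(child) for name, child in zip(
        ["cells", "rates", "viability", "transforms",
         "render_t0", "render_t1", "render_t2", "calibration"],
        ss.spawn(8),
    )}

    truth = seed_cells(config.geometry, model.occupancy_probs,
                       streams["cells"], config.render)
    truth = assign_rates(truth, model, streams["rates"])
    truth = apply_viability(truth, model, arm, streams["viability"])

    transforms: dict[str, tuple[float, float, float]] = {}
    trng = streams["transforms"]
    for phase in PHASES:
        dx, dy = trng.uniform(-config.membrane_shift_max_um,
                              config.membrane_shift_max_um, size=2)
        th = trng.uniform(-config.membrane_theta_max_deg,
                          config.membrane_theta_max_deg)
        transforms[phase] = (float(dx), float(dy), float(th))

    images = {}
    for phase in config.phases:
        images[phase] = render_phase_images(
            truth, config.geometry, config.noise, config.calibration_forward,
            config.phase_duration_h, streams[f"render_{phase}"], phase=phase,
            render=config.render, membrane_transform=transforms[phase])

    cal_img, cal_truth = render_calibration_series(
        config.geometry, config.calibration_densities, config.noise,
        streams["calibration"], config.calibration_forward)

    return SimulatedExperiment(
        config=config, truth=truth, images=images,
        membrane_transforms={p: transforms[p] for p in config.phases},
        calibration_image=cal_img, calibration_truth=cal_truth, drug_arm=arm)
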