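"""Membrane intensity -> absolute PSA mass and per-cell secretion rates.

The calibration standards are drops of known PSA concentration spotted on
the capture membrane; dividing the drop's PSA content by the spot area
gives an areal density in pg/um^2, and the measured mean fluorescence
intensity versus density defines the calibration curve.  Membrane
chemistry saturates, so the curve is fitted as a saturating hyperbola
with additive background,

    I(rho) = I_bg + I_max * rho / (rho_half + rho),

which is strictly increasing and inverts in closed form.  A well's spot
is then read back as mass = rho_hat * ROI area, and divided by cell count
and incubation time to give pg/cell/day.

Background ("empty-well") statistics come from wells where the cell
detector found no cell; a spot counts as above background when its mean
ROI intensity exceeds the empty-well mean by 3 empty-well SDs, the
conventional limit-of-detection rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "CalibrationForward",
    "CalibrationCurve",
    "BackgroundStats",
    "SpotMeasurement",
    "CalibrationError",
    "InsufficientBackgroundError",
    "fit_calibration",
    "estimate_background",
    "quantify_spot",
    "per_cell_rate",
    "roi_mean_intensity",
    "measure_well_rois",
]


class CalibrationError(ValueError):
    """Calibration standards cannot support a valid fit."""


class InsufficientBackgroundError(ValueError):
    """Fewer empty wells than the background rule requires."""


@dataclass(frozen=True)
class CalibrationForward:
    """Ground-truth saturating response used by the simulator (background
    excluded; the imaging background is owned by the noise model)."""

    i_max: float = 30000.0
    rho_half_pg_um2: float = 0.05

    def excess(self, rho) -> np.ndarray:
        rho = np.asarray(rho, dtype=float)
        return self.i_max * rho / (self.rho_half_pg_um2 + rho)


def _saturating(rho, i_bg, i_max, rho_half):
    return i_bg + i_max * rho / (rho_half + rho)


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted monotone map between areal density and mean intensity."""

    i_bg: float
    i_max: float
    rho_half: float
    rho_max: float  # largest standard density; upper edge of the valid range
    standards: tuple[tuple[float, float, float, int], ...] = ()
    # (density, mean_intensity, sd_intensity, n_pixels) per standard

    @property
    def intensity_ceiling(self) -> float:
        return _saturating(self.rho_max, self.i_bg, self.i_max, self.rho_half)

    def intensity(self, rho) -> np.ndarray:
        return _saturating(np.asarray(rho, dtype=float),
                           self.i_bg, self.i_max, self.rho_half)

    def density(self, intensity) -> np.ndarray:
        """Closed-form inverse on (i_bg, intensity ceiling)."""
        excess = np.asarray(intensity, dtype=float) - self.i_bg
        excess = np.clip(excess, 0.0, None)
        return self.rho_half * excess / (self.i_max - excess)


def fit_calibration(standards) -> CalibrationCurve:
    """Least-squares fit of the saturating model to standard spots.

    ``standards`` is a sequence of (density_pg_um2, pixel_sample) pairs,
    the pixel sample being the intensities inside one uniform disc.
    Requires at least 4 distinct densities including 0, and mean
    intensities that increase with density beyond their standard errors.
    """
    table = []
    for rho, pixels in standards:
        px = np.asarray(pixels, dtype=float).ravel()
        if px.size == 0:
            raise CalibrationError("empty pixel sample in calibration standard")
        table.append((float(rho), float(px.mean()),
                      float(px.std(ddof=1)) if px.size > 1 else 0.0, px.size))
    table.sort(key=lambda t: t[0])
    densities = np.array([t[0] for t in table])
    means = np.array([t[1] for t in table])
    if len(np.unique(densities)) < 4:
        raise CalibrationError("need at least 4 distinct standard densities")
    if densities.min() > 1e-12:
        raise CalibrationError("standards must include a zero-density anchor")
    sems = np.array([t[2] / np.sqrt(t[3]) for t in table])
    drops = np.diff(means) < -3 * np.hypot(sems[:-1], sems[1:])
    if drops.any():
        raise CalibrationError(
            "mean standard intensities decrease with density beyond noise")

    i_bg0 = means[0]
    i_max0 = max(means[-1] - i_bg0, 1.0) * 2
    p0 = (i_bg0, i_max0, densities[-1] / 2 or 0.01)
    popt, _ = curve_fit(_saturating, densities, means, p0=p0, maxfev=20000)
    i_bg, i_max, rho_half = (float(v) for v in popt)
    if i_max <= 0 or rho_half <= 0:
        raise CalibrationError(
            f"fit produced non-positive parameters (I_max={i_max}, "
            f"rho_half={rho_half})")
    return CalibrationCurve(i_bg=i_bg, i_max=i_max, rho_half=rho_half,
                            rho_max=float(densities.max()),
                            standards=tuple(table))


@dataclass(frozen=True)
class BackgroundStats:
    """Mean/SD of empty-well ROI mean intensities (the detection floor)."""

    mean_intensity: float
    sd_intensity: float
    n_wells_used: int


def estimate_background(empty_well_intensities, min_wells: int = 50,
                        allow_fewer: bool = False) -> BackgroundStats:
    """Background statistics over the ROI means of wells with no cell.

    At least ``min_wells`` (default 50) empty wells are required; the
    floor may be lowered explicitly with ``allow_fewer`` for small chips.
    """
    vals = np.asarray(empty_well_intensities, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size < min_wells and not allow_fewer:
        raise InsufficientBackgroundError(
            f"only {vals.size} empty wells available; {min_wells} required "
            "(pass allow_fewer=True to override)")
    if vals.size < 2:
        raise InsufficientBackgroundError("need at least 2 empty wells")
    return BackgroundStats(mean_intensity=float(vals.mean()),
                           sd_intensity=float(vals.std(ddof=1)),
                           n_wells_used=int(vals.size))


@dataclass(frozen=True)
class SpotMeasurement:
    """One well's membrane readout for one phase."""

    well_id: int
    phase: str
    mean_intensity: float
    roi_area_um2: float
    mass_pg: float
    rate_pg_per_cell_day: float | None
    above_background: bool
    censored: str  # none | below_range | above_range


def quantify_spot(mean_intensity: float, roi_area_um2: float,
                  curve: CalibrationCurve, background: BackgroundStats,
                  well_id: int = -1, phase: str = "t0",
                  k_sd: float = 3.0) -> SpotMeasurement:
    """Invert one ROI mean intensity through the calibration curve.

    Intensities at or below the fitted background map to mass 0
    (censored below range -- rates are physical quantities, never
    negative); intensities at or beyond the curve's ceiling are reported
    at the range ceiling and censored above range.
    """
    i = float(mean_intensity)
    censored = "none"
    if i <= curve.i_bg:
        mass = 0.0
        censored = "below_range"
    elif i >= curve.intensity_ceiling:
        mass = curve.rho_max * roi_area_um2
        censored = "above_range"
    else:
        mass = float(curve.density(i)) * roi_area_um2
    above = i > background.mean_intensity + k_sd * background.sd_intensity
    return SpotMeasurement(well_id=int(well_id), phase=phase, mean_intensity=i,
                           roi_area_um2=float(roi_area_um2), mass_pg=mass,
                           rate_pg_per_cell_day=None, above_background=bool(above),
                           censored=censored)


def per_cell_rate(mass_pg: float, n_cells: int, duration_h: float) -> float:
    """pg/cell/day from a well's captured mass, cell count and duration."""
    if n_cells < 1:
        raise ValueError("per-cell rate requires at least one cell in the well")
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    return mass_pg / n_cells / (duration_h / 24.0)


def roi_mean_intensity(image: np.ndarray, center_um, radius_um: float,
                       pixel_size_um: float) -> float:
    """Mean intensity over pixels whose centres fall inside the ROI disc."""
    ny, nx = image.shape
    s = pixel_size_um
    cx, cy = center_um
    half = int(np.ceil(radius_um / s)) + 1
    cj = int(np.floor(cx / s))
    ci = int(np.floor(cy / s))
    j0, j1 = max(cj - half, 0), min(cj + half + 1, nx)
    i0, i1 = max(ci - half, 0), min(ci + half + 1, ny)
    if j0 >= j1 or i0 >= i1:
        return float("nan")
    px = (np.arange(j0, j1) + 0.5) * s
    py = (np.arange(i0, i1) + 0.5) * s
    mask = ((px[None, :] - cx) ** 2 + (py[:, None] - cy) ** 2) <= radius_um**2
    if not mask.any():
        return float("nan")
    return float(image[i0:i1, j0:j1][mask].mean())


def measure_well_rois(image: np.ndarray, centers_um: np.ndarray,
                      radius_um: float, pixel_size_um: float) -> np.ndarray:
    """ROI mean intensity for every centre in a (n, 2) array of um coords."""
    return np.array([
        roi_mean_intensity(image, c, radius_um, pixel_size_um)
        for c in np.asarray(centers_um, dtype=float)
    ])
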