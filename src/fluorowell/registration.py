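"""Rigid registration of capture-membrane images to the chip frame.

Each 24 h phase uses a fresh membrane, remounted by hand, so its spot
pattern is translated (and very slightly rotated) relative to the well
grid.  The location of a spot identifies the well -- and hence the cell --
that secreted it, so the transform must be recovered before
quantification.  The estimator detects spot centroids, then searches
translation x rotation for the transform that maximises the number of
centroids landing within a quarter pitch of a well centre (robust to the
many wells with no spot and to merged or missing spots), and finally
polishes the inlier set with a closed-form rigid least-squares
(Kabsch) fit.  Mounting offsets must stay below half a pitch for the
lattice match to be unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from .geometry import ChipGeometry, well_center_xy

__all__ = ["RigidTransform", "RegistrationError", "estimate_alignment",
           "assign_spots_to_wells", "detect_spot_centroids"]


class RegistrationError(ValueError):
    """The membrane does not contain enough signal to register."""


@dataclass(frozen=True)
class RigidTransform:
    """Chip-frame -> membrane-frame rigid map (rotation about chip centre
    by theta_deg, then translation by (dx_um, dy_um))."""

    dx_um: float
    dy_um: float
    theta_deg: float
    residual_um: float = float("nan")
    n_inliers: int = 0
    low_confidence: bool = False

    def apply(self, points_um: np.ndarray, geometry: ChipGeometry) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        c = _chip_center(geometry)
        th = np.deg2rad(self.theta_deg)
        co, si = np.cos(th), np.sin(th)
        rel = pts - c
        out = np.column_stack([co * rel[:, 0] - si * rel[:, 1],
                               si * rel[:, 0] + co * rel[:, 1]])
        return out + c + np.array([self.dx_um, self.dy_um])

    def invert(self, points_um: np.ndarray, geometry: ChipGeometry) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        c = _chip_center(geometry)
        th = np.deg2rad(-self.theta_deg)
        co, si = np.cos(th), np.sin(th)
        rel = pts - c - np.array([self.dx_um, self.dy_um])
        out = np.column_stack([co * rel[:, 0] - si * rel[:, 1],
                               si * rel[:, 0] + co * rel[:, 1]])
        return out + c


def _chip_center(geometry: ChipGeometry) -> np.ndarray:
    return np.array([geometry.n_cols * geometry.pitch_um / 2.0,
                     geometry.n_rows * geometry.pitch_um / 2.0])


def detect_spot_centroids(membrane, geometry: ChipGeometry,
                          smooth_sigma_um: float = 10.0,
                          k_sd: float = 6.0) -> np.ndarray:
    """Sub-pixel centroids of membrane spots, as (n, 2) um coordinates.

    Robust background (median/MAD) thresholding, peaks separated by at
    least half a pitch, and a background-subtracted intensity-weighted
    centroid within a 25 um window around each peak.
    """
    data = np.asarray(getattr(membrane, "data", membrane), dtype=float)
    s = geometry.pixel_size_um
    sm = ndimage.gaussian_filter(data, smooth_sigma_um / s)
    med = float(np.median(sm))
    mad = float(np.median(np.abs(sm - med)))
    thresh = med + k_sd * max(1.4826 * mad, 1e-3)
    min_dist = max(int(round(geometry.pitch_um / 2 / s)), 1)
    peaks = peak_local_max(sm, min_distance=min_dist, threshold_abs=thresh,
                           exclude_border=False)
    if len(peaks) == 0:
        return np.empty((0, 2))
    win = max(int(round(25.0 / s)), 2)
    ny, nx = data.shape
    out = []
    for pi, pj in peaks:
        i0, i1 = max(pi - win, 0), min(pi + win + 1, ny)
        j0, j1 = max(pj - win, 0), min(pj + win + 1, nx)
        patch = sm[i0:i1, j0:j1]
        border = np.concatenate([patch[0], patch[-1], patch[:, 0], patch[:, -1]])
        w = np.clip(patch - float(np.median(border)), 0.0, None)
        if w.sum() <= 0:
            continue
        ii, jj = np.mgrid[i0:i1, j0:j1]
        ci = float((w * ii).sum() / w.sum())
        cj = float((w * jj).sum() / w.sum())
        out.append(((cj + 0.5) * s, (ci + 0.5) * s))
    return np.asarray(out)


def _lattice_misfit(points_chip: np.ndarray, geometry: ChipGeometry) -> np.ndarray:
    """Distance from each chip-frame point to its nearest well centre."""
    p = geometry.pitch_um
    col = np.clip(np.round(points_chip[:, 0] / p - 0.5), 0, geometry.n_cols - 1)
    row = np.clip(np.round(points_chip[:, 1] / p - 0.5), 0, geometry.n_rows - 1)
    return np.hypot(points_chip[:, 0] - (col + 0.5) * p,
                    points_chip[:, 1] - (row + 0.5) * p)


def _nearest_wells(points_chip: np.ndarray, geometry: ChipGeometry) -> np.ndarray:
    p = geometry.pitch_um
    col = np.clip(np.round(points_chip[:, 0] / p - 0.5), 0,
                  geometry.n_cols - 1).astype(int)
    row = np.clip(np.round(points_chip[:, 1] / p - 0.5), 0,
                  geometry.n_rows - 1).astype(int)
    return row * geometry.n_cols + col


def estimate_alignment(membrane, geometry: ChipGeometry,
                       min_spots: int = 50,
                       shift_max_um: float = 45.0,
                       theta_max_deg: float = 1.5) -> RigidTransform:
    """Estimate the membrane's rigid mounting transform from its spots.

    Coarse inlier-count grid search over (dx, dy, theta), then two rounds
    of rigid least squares on the matched centroid/well-centre pairs.
    Raises :class:`RegistrationError` below ``min_spots`` detectable
    spots; a residual above a quarter pitch marks the result low
    confidence instead of failing.
    """
    centroids = detect_spot_centroids(membrane, geometry)
    if len(centroids) < min_spots:
        raise RegistrationError(
            f"only {len(centroids)} spots detected; at least {min_spots} "
            "are required for alignment")
    c = _chip_center(geometry)
    tol = geometry.pitch_um / 4.0

    best = (-1, 0.0, 0.0, 0.0)
    steps = np.arange(-shift_max_um, shift_max_um + 1e-9, 5.0)
    thetas = np.arange(-theta_max_deg, theta_max_deg + 1e-9, 0.25)
    rel = centroids - c
    for th in thetas:
        rad = np.deg2rad(-th)
        co, si = np.cos(rad), np.sin(rad)
        unrot = np.column_stack([co * rel[:, 0] - si * rel[:, 1],
                                 si * rel[:, 0] + co * rel[:, 1]]) + c
        for dx in steps:
            for dy in steps:
                # inverse transform with candidate (dx, dy, th)
                pts = unrot - _rot_vec(dx, dy, -th)
                score = int((_lattice_misfit(pts, geometry) <= tol).sum())
                if score > best[0]:
                    best = (score, dx, dy, th)
    _, dx, dy, th = best
    tr = RigidTransform(dx, dy, th)

    for _ in range(2):
        chip_pts = tr.invert(centroids, geometry)
        mis = _lattice_misfit(chip_pts, geometry)
        inlier = mis <= tol
        if inlier.sum() < 3:
            break
        wells = _nearest_wells(chip_pts[inlier], geometry)
        targets = well_center_xy(geometry)[wells]
        tr = _fit_rigid(targets, centroids[inlier], c)

    chip_pts = tr.invert(centroids, geometry)
    mis = _lattice_misfit(chip_pts, geometry)
    inlier = mis <= tol
    residual = float(np.sqrt(np.mean(mis[inlier] ** 2))) if inlier.any() else float("inf")
    low = residual > tol
    if low:
        warnings.warn(f"registration residual {residual:.1f} um exceeds "
                      f"pitch/4; low-confidence alignment", stacklevel=2)
    return RigidTransform(tr.dx_um, tr.dy_um, tr.theta_deg,
                          residual_um=residual, n_inliers=int(inlier.sum()),
                          low_confidence=low)


def _rot_vec(dx: float, dy: float, theta_deg: float) -> np.ndarray:
    th = np.deg2rad(theta_deg)
    co, si = np.cos(th), np.sin(th)
    return np.array([co * dx - si * dy, si * dx + co * dy])


def _fit_rigid(chip_pts: np.ndarray, membrane_pts: np.ndarray,
               center: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid fit mapping chip -> membrane,
    parameterised as rotation about the chip centre plus translation."""
    a = chip_pts - center
    b = membrane_pts - center
    am = a - a.mean(axis=0)
    bm = b - b.mean(axis=0)
    h = am.T @ bm
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, d]) @ u.T
    theta = float(np.degrees(np.arctan2(r[1, 0], r[0, 0])))
    t = b.mean(axis=0) - (r @ a.mean(axis=0))
    return RigidTransform(float(t[0]), float(t[1]), theta)


def assign_spots_to_wells(membrane, transform: RigidTransform,
                          geometry: ChipGeometry) -> np.ndarray:
    """Measurement ROI centre for every well, in the membrane frame.

    Purely geometric: every well gets an ROI (disc of the geometry's spot
    ROI radius) centred on its transformed pore position, whether or not
    a spot is visible -- background and below-background wells need ROIs
    too.  Returns an (n_wells, 2) array ordered by well id.
    """
    return transform.apply(well_center_xy(geometry), geometry)
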