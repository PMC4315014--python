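"""CT→MRI registration, dose mapping, motion-adjusted dose accumulation, and DVH.

The dose grid lives in the CT frame; a rigid transform (maximizing a
32x32-bin histogram estimate of mutual information, found by multi-start
Powell optimization) links the MRI frame to it.  The cardiac-motion-adjusted
accumulative dose of each phase-0 myocardial material point X is the
phase-weighted average of the static dose sampled along its trajectory
``X + u_k(X)`` — the dose grid is warped, not recalculated, so this is an
approximation that ignores density changes over the cycle.  Blood-pool
pixels are excluded throughout (only myocardial dose is accumulated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .io_core import DoseGrid, ImageFrame, RigidTransform, logger
from .tracking import DisplacementField

__all__ = [
    "RigidTransform",
    "DoseGrid",
    "AccumulatedDoseMap",
    "RegistrationError",
    "mutual_information",
    "register_mi",
    "map_dose",
    "accumulate_dose",
    "dvh",
]


class RegistrationError(RuntimeError):
    """The MI optimizer failed to converge; carries the optimizer trace."""


@dataclass
class AccumulatedDoseMap:
    """Motion-adjusted accumulated dose (Gy) on the phase-0 myocardium grid."""

    dose: np.ndarray  # (nx, ny), zero outside mask
    phase_weights: np.ndarray
    mask: np.ndarray  # myocardium, phase 0
    valid_mask: np.ndarray  # mask pixels whose whole trajectory stayed on the grid
    frame: ImageFrame


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Histogram mutual information (nats) of two equally-shaped samples."""
    hist, _, _ = np.histogram2d(np.ravel(a), np.ravel(b), bins=bins)
    pxy = hist / hist.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


def _resample_moving(
    moving: np.ndarray,
    moving_frame: ImageFrame,
    fixed_coords: np.ndarray,
    transform: RigidTransform,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the moving image at T(fixed grid); returns (values, in_grid_mask)."""
    pts = transform.apply(fixed_coords)
    idx = moving_frame.index_of(pts)
    vals = ndimage.map_coordinates(
        moving, [idx[..., 0], idx[..., 1]], order=1, mode="constant", cval=np.nan
    )
    in_grid = np.isfinite(vals)
    return np.where(in_grid, vals, 0.0), in_grid


def register_mi(
    fixed: np.ndarray,
    fixed_frame: ImageFrame,
    moving: np.ndarray,
    moving_frame: ImageFrame,
    initial: RigidTransform | None = None,
    bins: int = 32,
    multi_start: bool = True,
    smooth_sigma_px: float = 1.0,
) -> tuple[RigidTransform, float]:
    """Rigid transform (MRI→CT coordinates) maximizing mutual information.

    Both images are lightly smoothed to regularize the histogram-MI
    landscape; Powell searches (rotation°, tx, ty) from the initial guess
    and, with ``multi_start``, from a small grid of perturbed starts, and the
    best optimum is polished once more.  Returns ``(transform, mi_value)``.
    """
    fixed_s = ndimage.gaussian_filter(np.asarray(fixed, dtype=float), smooth_sigma_px)
    moving_s = ndimage.gaussian_filter(np.asarray(moving, dtype=float), smooth_sigma_px)
    center = fixed_frame.center_mm
    coords = fixed_frame.pixel_centers()
    if initial is None:
        initial = RigidTransform(rotation=0.0, translation=(0.0, 0.0), center=center)

    def neg_mi(params: np.ndarray) -> float:
        t = RigidTransform(
            rotation=np.deg2rad(params[0]), translation=params[1:3], center=center
        )
        vals, in_grid = _resample_moving(moving_s, moving_frame, coords, t)
        if in_grid.sum() < 0.25 * in_grid.size:
            return 0.0  # hopeless overlap
        return -mutual_information(fixed_s[in_grid], vals[in_grid], bins=bins)

    x_init = np.array(
        [np.rad2deg(initial.rotation), initial.translation[0], initial.translation[1]]
    )
    starts = [x_init]
    if multi_start:
        for dr in (-4.0, 0.0, 4.0):
            for dx in (-6.0, 0.0, 6.0):
                for dy in (-6.0, 0.0, 6.0):
                    if dr == dx == dy == 0.0:
                        continue
                    starts.append(x_init + np.array([dr, dx, dy]))
    best = None
    trace = []
    for x0 in starts:
        res = optimize.minimize(
            neg_mi, x0, method="Powell", options={"xtol": 1e-3, "ftol": 1e-7, "maxiter": 200}
        )
        trace.append((x0.tolist(), res.x.tolist(), float(res.fun), bool(res.success)))
        if best is None or res.fun < best.fun:
            best = res
    polish = optimize.minimize(
        neg_mi, best.x, method="Powell", options={"xtol": 1e-5, "ftol": 1e-10, "maxiter": 400}
    )
    if polish.fun <= best.fun:
        best = polish
    if not best.success and not polish.success:
        raise RegistrationError(f"MI optimization did not converge; trace: {trace}")
    transform = RigidTransform(
        rotation=np.deg2rad(best.x[0]), translation=best.x[1:3].copy(), center=center
    )
    mi_value = -float(best.fun)
    logger.debug("registration: rot %.3f deg, t (%.3f, %.3f) mm, MI %.4f",
                 best.x[0], best.x[1], best.x[2], mi_value)
    return transform, mi_value


def map_dose(
    dose: DoseGrid,
    transform: RigidTransform,
    target_frame: ImageFrame,
) -> np.ndarray:
    """Resample the dose grid onto the MRI frame (bilinear; out-of-grid → 0)."""
    pts = transform.apply(target_frame.pixel_centers())
    idx = dose.frame.index_of(pts)
    vals = ndimage.map_coordinates(
        dose.values, [idx[..., 0], idx[..., 1]], order=1, mode="constant", cval=np.nan
    )
    n_out = int(np.sum(~np.isfinite(vals)))
    if n_out:
        logger.warning("map_dose: %d target pixels fell outside the dose grid (set to 0)", n_out)
    return np.where(np.isfinite(vals), vals, 0.0)


def accumulate_dose(
    dose_mri: np.ndarray,
    displacement_fields: Sequence[DisplacementField],
    myocardium_mask: np.ndarray,
    frame: ImageFrame,
    phase_weights: Sequence[float] | None = None,
) -> AccumulatedDoseMap:
    """Phase-weighted dose along each myocardial material trajectory.

    ``accumulated(X) = Σ_k w_k · dose(X + u_k(X))`` for phase-0 myocardial
    pixels X (blood pool excluded), bilinear dose sampling.  Uniform weights
    (equal dwell time per ECG-gated phase) by default; weights must sum to 1.
    Pixels whose trajectory leaves the dose grid at any phase are flagged
    and excluded from statistics via ``valid_mask``.
    """
    mask = np.asarray(myocardium_mask, dtype=bool)
    P = len(displacement_fields)
    if phase_weights is None:
        w = np.full(P, 1.0 / P)
    else:
        w = np.asarray(phase_weights, dtype=float)
        if w.shape != (P,) or np.any(w < 0):
            raise ValueError("phase_weights must be non-negative, one per phase")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"phase_weights must sum to 1 (got {w.sum()!r})")
    dose_mri = np.asarray(dose_mri, dtype=float)
    acc = np.zeros(frame.shape)
    valid = mask.copy()
    coords = frame.pixel_centers()
    for k, fld in enumerate(displacement_fields):
        frame.require_equal(fld.frame, "dose and displacement")
        pos = coords + fld.vectors
        idx = frame.index_of(pos)
        vals = ndimage.map_coordinates(
            dose_mri, [idx[..., 0], idx[..., 1]], order=1, mode="constant", cval=np.nan
        )
        valid &= np.isfinite(vals)
        acc += w[k] * np.where(np.isfinite(vals), vals, 0.0)
    acc = np.where(mask, acc, 0.0)
    return AccumulatedDoseMap(
        dose=acc, phase_weights=w, mask=mask, valid_mask=valid, frame=frame
    )


def dvh(dose_map: np.ndarray, mask: np.ndarray, bin_width: float = 0.5) -> pd.DataFrame:
    """Cumulative dose-volume histogram V(d) = fraction of mask pixels with dose ≥ d.

    Evaluated at bin edges 0, bin_width, … up to just past the maximum dose;
    V(0) = 1 and V is monotone non-increasing.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    vals = np.asarray(dose_map, dtype=float)[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty mask: DVH undefined")
    top = max(vals.max(), 0.0) + bin_width
    edges = np.arange(0.0, top + bin_width, bin_width)
    volume = np.array([(vals >= d).mean() for d in edges])
    return pd.DataFrame({"dose_Gy": edges, "volume_fraction": volume})
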