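"""Pixel-wise myocardial strain from Lagrangian displacement fields.

Strain is the spatial derivative of displacement.  The finite
(Green–Lagrange) tensor ``E = (G + Gᵀ + GᵀG)/2`` with ``G = ∂u/∂X`` is the
default because the phantom twists: a rigid rotation produces exactly zero
Green–Lagrange strain, while the linearized (infinitesimal) tensor — kept
behind ``finite=False`` for comparison — would misreport it as strain.

Scalar components are projected on the local radial/circumferential unit
vectors about the LV center (the standard cardiac reporting frame), and an
abnormality mask flags myocardial pixels whose strain falls outside a
low/high band — the package's proxy for regional functional loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_core import ImageFrame
from .tracking import DisplacementField


@dataclass
class StrainMap:
    """Per-pixel symmetric 2x2 Lagrangian strain plus polar scalar components."""

    tensor: np.ndarray  # (nx, ny, 2, 2)
    radial: np.ndarray  # (nx, ny)
    circumferential: np.ndarray  # (nx, ny)
    phase_index: int
    validity_mask: np.ndarray  # (nx, ny) bool


@dataclass
class AbnormalityMask:
    """Myocardial pixels whose strain scalar lies outside [low, high]."""

    mask: np.ndarray
    low_threshold: float
    high_threshold: float
    component: str


def smooth_displacement(
    vectors: np.ndarray, mask: np.ndarray, sigma_px: float = 1.0
) -> np.ndarray:
    """Mask-aware Gaussian smoothing (normalized convolution, no leakage from invalid pixels)."""
    if sigma_px <= 0:
        return vectors
    m = mask.astype(float)
    wm = ndimage.gaussian_filter(m, sigma_px)
    out = np.zeros_like(vectors)
    for c in range(vectors.shape[-1]):
        num = ndimage.gaussian_filter(vectors[..., c] * m, sigma_px)
        out[..., c] = np.divide(num, wm, out=np.zeros_like(num), where=wm > 1e-12)
    return np.where(mask[..., None], out, vectors)


def _masked_derivative(a: np.ndarray, mask: np.ndarray, axis: int, h: float):
    """Central differences where both neighbours are valid, one-sided at mask borders.

    Returns ``(derivative, ok)``; ``ok`` is False where a pixel has no valid
    neighbour along this axis.
    """
    def shifted(arr, step):
        out = np.zeros_like(arr)
        src = [slice(None)] * arr.ndim
        dst = [slice(None)] * arr.ndim
        if step > 0:
            src[axis] = slice(step, None)
            dst[axis] = slice(None, -step)
        else:
            src[axis] = slice(None, step)
            dst[axis] = slice(-step, None)
        out[tuple(dst)] = arr[tuple(src)]
        return out

    a_plus, a_minus = shifted(a, +1), shifted(a, -1)
    v_plus = shifted(mask, +1).astype(bool)
    v_minus = shifted(mask, -1).astype(bool)
    g = np.zeros_like(a)
    central = mask & v_plus & v_minus
    fwd = mask & v_plus & ~v_minus
    bwd = mask & ~v_plus & v_minus
    g[central] = (a_plus[central] - a_minus[central]) / (2.0 * h)
    g[fwd] = (a_plus[fwd] - a[fwd]) / h
    g[bwd] = (a[bwd] - a_minus[bwd]) / h
    ok = central | fwd | bwd
    return g, ok


def displacement_gradient(
    field: DisplacementField,
    spacing: tuple[float, float] | None = None,
    smoothing_sigma_px: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel displacement gradient G[..., i, j] = ∂u_i/∂X_j (dimensionless).

    Central differences in the interior, one-sided at validity-mask borders;
    pixels with no valid neighbour along either axis are dropped from the
    returned mask.  Optional mask-aware Gaussian pre-smoothing tames noise
    amplification by the differentiation.
    """
    spacing = spacing or field.frame.pixel_spacing
    mask = field.validity_mask.astype(bool)
    u = field.vectors
    if smoothing_sigma_px > 0:
        u = smooth_displacement(u, mask, smoothing_sigma_px)
    nx, ny = mask.shape
    grad = np.zeros((nx, ny, 2, 2))
    ok = mask.copy()
    for i in range(2):
        for j in range(2):
            g, ok_ij = _masked_derivative(u[..., i], mask, axis=j, h=spacing[j])
            grad[..., i, j] = g
            ok &= ok_ij
    return grad, ok


def lagrangian_strain(gradient: np.ndarray, finite: bool = True) -> np.ndarray:
    """Strain tensor from the displacement gradient.

    Green–Lagrange ``E = (G + Gᵀ + GᵀG)/2`` by default; the linearized
    small-strain tensor ``(G + Gᵀ)/2`` when ``finite=False``.  Symmetric by
    construction.
    """
    g = np.asarray(gradient, dtype=float)
    gt = np.swapaxes(g, -1, -2)
    e = 0.5 * (g + gt)
    if finite:
        e = e + 0.5 * np.einsum("...ki,...kj->...ij", g, g)
    return e


def polar_components(
    tensor: np.ndarray,
    coords_mm: np.ndarray,
    lv_center: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Project the strain tensor on radial/circumferential unit vectors about the LV center.

    ``E_rr = ê_rᵀ E ê_r`` and ``E_cc = ê_cᵀ E ê_c`` with ``ê_r`` pointing away
    from the center and ``ê_c`` its 90° rotation.  Undefined (zero) exactly at
    the center pixel.
    """
    rel = np.asarray(coords_mm, dtype=float) - np.asarray(lv_center, dtype=float)
    r = np.linalg.norm(rel, axis=-1)
    safe_r = np.where(r > 0, r, 1.0)
    er = rel / safe_r[..., None]
    ec = np.stack([-er[..., 1], er[..., 0]], axis=-1)
    e_rr = np.einsum("...i,...ij,...j->...", er, tensor, er)
    e_cc = np.einsum("...i,...ij,...j->...", ec, tensor, ec)
    e_rr = np.where(r > 0, e_rr, 0.0)
    e_cc = np.where(r > 0, e_cc, 0.0)
    return e_rr, e_cc


def compute_strain(
    field: DisplacementField,
    lv_center: np.ndarray,
    finite: bool = True,
    smoothing_sigma_px: float = 1.0,
) -> StrainMap:
    """Displacement field → StrainMap (gradient, tensor, polar scalars)."""
    grad, ok = displacement_gradient(field, smoothing_sigma_px=smoothing_sigma_px)
    tensor = lagrangian_strain(grad, finite=finite)
    coords = field.frame.pixel_centers()
    e_rr, e_cc = polar_components(tensor, coords, lv_center)
    return StrainMap(
        tensor=tensor,
        radial=e_rr,
        circumferential=e_cc,
        phase_index=field.phase_index,
        validity_mask=ok,
    )


def percentile_thresholds(
    values: np.ndarray, mask: np.ndarray, percentiles: tuple[float, float] = (5.0, 95.0)
) -> tuple[float, float]:
    """Low/high strain thresholds from percentiles of a designated normal region.

    Meant for a region known to be healthy; applied to a mixed region a
    sizeable lesion contaminates the percentiles (use
    :func:`robust_thresholds` there).
    """
    sel = np.asarray(values)[np.asarray(mask, dtype=bool)]
    lo, hi = np.percentile(sel, percentiles)
    return float(lo), float(hi)


def transmural_normalize(
    values: np.ndarray,
    mask: np.ndarray,
    coords_mm: np.ndarray,
    lv_center: np.ndarray,
    n_bins: int = 8,
) -> np.ndarray:
    """Divide a strain scalar by its per-radius angular median over the mask.

    Circumferential strain falls off with radius across the wall, so a
    lesion is not an outlier of the pooled distribution; the ratio to the
    expected transmural profile (median over all angles at the same radius,
    robust to a minority lesion) is ~1 in normal tissue and drops toward 0
    with local functional loss.  Pixels in radial bins whose median is too
    close to zero are returned as NaN.
    """
    vals = np.asarray(values, dtype=float)
    m = np.asarray(mask, dtype=bool)
    rel = np.asarray(coords_mm, dtype=float) - np.asarray(lv_center, dtype=float)
    r = np.linalg.norm(rel, axis=-1)
    r_in = r[m]
    edges = np.linspace(r_in.min(), r_in.max() + 1e-9, n_bins + 1)
    ratio = np.full(vals.shape, np.nan)
    scale = np.median(np.abs(vals[m]))
    for b in range(n_bins):
        sel = m & (r >= edges[b]) & (r < edges[b + 1])
        if not sel.any():
            continue
        med = np.median(vals[sel])
        if abs(med) > 0.05 * scale:
            ratio[sel] = vals[sel] / med
    return ratio


def robust_thresholds(
    values: np.ndarray, mask: np.ndarray, n_mads: float = 3.0
) -> tuple[float, float]:
    """Outlier interval ``median ± n_mads * scaled MAD`` over the mask.

    The median absolute deviation (scaled by 1.4826 to estimate sigma) is
    insensitive to a minority of lesioned pixels, so the interval brackets
    the normal strain distribution even when no healthy reference region is
    designated; values outside it are flagged abnormal.
    """
    sel = np.asarray(values, dtype=float)[np.asarray(mask, dtype=bool)]
    med = float(np.median(sel))
    mad = 1.4826 * float(np.median(np.abs(sel - med)))
    return med - n_mads * mad, med + n_mads * mad


def flag_abnormal(
    scalar_map: np.ndarray,
    myocardium_mask: np.ndarray,
    low_threshold: float,
    high_threshold: float,
    component: str = "circumferential",
) -> AbnormalityMask:
    """Flag myocardial pixels with strain below ``low`` or above ``high``."""
    if not low_threshold < high_threshold:
        raise ValueError(f"need low < high, got {low_threshold} >= {high_threshold}")
    myo = np.asarray(myocardium_mask, dtype=bool)
    vals = np.asarray(scalar_map)
    mask = myo & ((vals < low_threshold) | (vals > high_threshold))
    return AbnormalityMask(
        mask=mask, low_threshold=low_threshold, high_threshold=high_threshold, component=component
    )
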