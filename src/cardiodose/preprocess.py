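"""Intensity preprocessing: coil-shading correction and inter-phase decay normalization.

Surface-coil non-uniformity is modeled as a smooth multiplicative field and
estimated by least-squares fitting a low-order 2D polynomial to the
log-intensity over a support region, exponentiating, and normalizing to unit
mean over that support.  The corrected image is ``image / field``; note that
the unit-mean convention fixes the field only up to the support it is
normalized on, so bias correction is defined up to a global scale.

Inter-phase intensity decay (tag fading lowers the median signal of early
phases) is compensated by a single global factor per phase that matches each
phase's median intensity over the support to that of phase 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import logger


class PreprocessError(ValueError):
    pass


@dataclass
class BiasFieldEstimate:
    """Multiplicative coil-shading estimate: strictly positive, unit mean on the support."""

    field: np.ndarray
    polynomial_order: int


def auto_support(image: np.ndarray, fraction: float = 0.1) -> np.ndarray:
    """Foreground support: pixels above ``fraction`` of the 99.5th percentile."""
    image = np.asarray(image, dtype=float)
    hi = np.percentile(image, 99.5)
    return image > fraction * hi


def bias_support(
    tag_free_image: np.ndarray,
    frame=None,
    min_fraction: float = 0.02,
) -> np.ndarray:
    """Single-tissue-class support for bias estimation.

    A polynomial surface fitted to log-intensity over mixed tissue classes
    absorbs the anatomy itself, so the shading must be estimated over one
    near-uniform class.  A rough myocardium segmentation of the (still
    uncorrected) tag-free image provides it, eroded by two pixels to drop
    the partial-volume shell whose log-intensities would corrupt the fit;
    when no ring is found, or the eroded ring covers less than
    ``min_fraction`` of the image, the foreground support is the fallback.
    """
    from scipy import ndimage as _ndi

    from .tagseg import SegmentationError, segment_myocardium

    img = np.asarray(tag_free_image, dtype=float)
    try:
        seg = segment_myocardium(img, frame)
    except SegmentationError:
        logger.warning("bias_support: no myocardial ring found; using foreground support")
        return auto_support(img)
    sup = _ndi.binary_erosion(seg.mask, iterations=2)
    if sup.sum() < min_fraction * img.size:
        logger.warning("bias_support: ring too small (%d px); using foreground support", int(sup.sum()))
        return auto_support(img)
    return sup


def _poly_design(shape: tuple[int, int], order: int, mask: np.ndarray) -> np.ndarray:
    xs = np.linspace(-1, 1, shape[0])
    ys = np.linspace(-1, 1, shape[1])
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    cols = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            cols.append((gx**i * gy**j)[mask])
    return np.stack(cols, axis=-1)


def _poly_eval(shape: tuple[int, int], order: int, coeffs: np.ndarray) -> np.ndarray:
    full = np.ones(shape, dtype=bool)
    design = _poly_design(shape, order, full)
    return (design @ coeffs).reshape(shape)


def estimate_bias_field(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    polynomial_order: int = 2,
) -> BiasFieldEstimate:
    """Estimate the multiplicative shading field from one image.

    Fits a 2D polynomial surface of the given order to log-intensity over the
    mask (``None`` → automatic foreground support), exponentiates it and
    normalizes to unit mean over the mask.  Divide by ``.field`` to correct.
    """
    image = np.asarray(image, dtype=float)
    if not 1 <= polynomial_order <= 4:
        raise PreprocessError(f"polynomial_order must be in [1, 4], got {polynomial_order}")
    if not np.any(image > 0):
        raise PreprocessError("cannot estimate a bias field from an all-nonpositive image")
    if mask is None:
        mask = auto_support(image)
    mask = np.asarray(mask, dtype=bool) & (image > 0)
    n_min = 0.02 * image.size
    if mask.sum() < n_min:
        raise PreprocessError(
            f"support mask covers {mask.sum()} pixels; need at least 2% of the image ({n_min:.0f})"
        )
    design = _poly_design(image.shape, polynomial_order, mask)
    coeffs, *_ = np.linalg.lstsq(design, np.log(image[mask]), rcond=None)
    field = np.exp(_poly_eval(image.shape, polynomial_order, coeffs))
    field /= field[mask].mean()
    logger.debug("bias field estimated: order %d, support %d px", polynomial_order, mask.sum())
    return BiasFieldEstimate(field=field, polynomial_order=polynomial_order)


def correct_bias(image: np.ndarray, estimate: BiasFieldEstimate) -> np.ndarray:
    """Divide out the shading field (preserves sign and zero pixels)."""
    return np.asarray(image, dtype=float) / estimate.field


def normalize_phase_decay(
    series: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale each phase by one global factor so support medians match phase 0.

    The median (robust to tag troughs) is taken over ``mask`` or, when
    ``None``, the automatic foreground support of phase 0.  Phase 0 is
    returned unchanged (factor exactly 1).  Returns ``(series, factors)``.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 3 or series.shape[0] < 2:
        raise PreprocessError("need a (P, nx, ny) series with at least 2 phases")
    if mask is None:
        mask = auto_support(series[0])
    mask = np.asarray(mask, dtype=bool)
    ref_median = np.median(series[0][mask])
    medians = np.array([np.median(ph[mask]) for ph in series])
    if np.any(medians <= 0):
        raise PreprocessError("zero or negative median intensity in the support region")
    factors = ref_median / medians
    factors[0] = 1.0
    out = series * factors[:, None, None]
    return out, factors
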