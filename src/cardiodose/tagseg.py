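"""Tag removal by frequency-domain notch filtering and myocardium segmentation.

The SPAMM grating concentrates its energy in narrow spectral peaks at
multiples of 1/tag_spacing along each tagged axis.  Gaussian band-stop
(notch) filters centered on those frequencies — applied as a function of the
tagged axis' frequency coordinate only, so grid-tag cross terms are caught
too — remove the tags while preserving the edge sharpness the segmentation
needs.  Tag removal is linear and phase-preserving outside the notches.

Segmentation of the tag-free short-axis image is classical: multi-Otsu
thresholding isolates the bright myocardial annulus, morphological cleanup
follows, and the endo-/epicardial contours are extracted as closed,
counter-clockwise polygons (in mm) resampled to a fixed vertex count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure, morphology
from skimage.filters import threshold_multiotsu

from .io_core import ImageFrame, logger

#: Notch width as a fraction of the tag frequency (sigma_f = 0.15 / tag_spacing).
NOTCH_SIGMA_FACTOR = 0.15
CONTOUR_VERTICES = 128


class SegmentationError(RuntimeError):
    """No LV-like annular structure could be found."""


@dataclass
class MyocardiumSegmentation:
    """Endo/epi contours (closed CCW polygons, mm) and the annular mask."""

    endo_contour: np.ndarray  # (V, 2) mm
    epi_contour: np.ndarray  # (V, 2) mm
    mask: np.ndarray  # (nx, ny) bool

    @property
    def lv_center(self) -> np.ndarray:
        """Centroid of the endocardial contour (mm)."""
        return self.endo_contour.mean(axis=0)


def notch_filter_response(
    shape: tuple[int, int],
    tag_spacing: float,
    directions: tuple[str, ...],
    pixel_spacing: tuple[float, float],
    sigma_factor: float = NOTCH_SIGMA_FACTOR,
) -> np.ndarray:
    """Frequency response of the tag-removal filter (1 = pass, 0 = stop)."""
    f_tag = 1.0 / tag_spacing
    sigma = sigma_factor / tag_spacing
    h = np.ones(shape)
    axes = {"x": 0, "y": 1}
    for d in directions:
        ax = axes[d]
        nyq = 1.0 / (2.0 * pixel_spacing[ax])
        if f_tag >= nyq:
            raise ValueError(
                f"tag frequency {f_tag:.4f}/mm is at or above Nyquist {nyq:.4f}/mm along {d}"
            )
        freqs = np.fft.fftfreq(shape[ax], d=pixel_spacing[ax])
        resp = np.ones_like(freqs)
        m = 1
        while m * f_tag < nyq:
            for sign in (+1, -1):
                resp *= 1.0 - np.exp(-((freqs - sign * m * f_tag) ** 2) / (2.0 * sigma**2))
            m += 1
        shape_nd = [1, 1]
        shape_nd[ax] = shape[ax]
        h = h * resp.reshape(shape_nd)
    return h


def estimate_tag_depth(
    spectrum: np.ndarray,
    tag_spacing: float,
    direction: str,
    pixel_spacing: tuple[float, float],
    sigma_factor: float = NOTCH_SIGMA_FACTOR,
    reference_spectrum: np.ndarray | None = None,
) -> float:
    """Effective tag depth from the spectral peak-to-DC ratio.

    For a sin^2 grating of depth d the +1 peak carries d/4 of the anatomy
    spectrum while the DC carries 1 - d/2, so d = 4 rho / (1 + 2 rho) with
    rho = |peak| / |DC|.  An untagged image gives rho ~ 0, hence depth ~ 0.
    With ``reference_spectrum`` (the same anatomy without this grating, e.g.
    the orthogonally tagged series) the peak is measured on the difference
    spectrum, removing the anatomy's own in-band energy from the estimate.
    """
    ax = {"x": 0, "y": 1}[direction]
    f_tag = 1.0 / tag_spacing
    sigma = sigma_factor / tag_spacing
    fx = np.fft.fftfreq(spectrum.shape[0], d=pixel_spacing[0])
    fy = np.fft.fftfreq(spectrum.shape[1], d=pixel_spacing[1])
    gfx, gfy = np.meshgrid(fx, fy, indexing="ij")
    f_axis = (gfx, gfy)[ax]
    f_perp = (gfy, gfx)[ax]
    window = (np.abs(np.abs(f_axis) - f_tag) < 2 * sigma) & (np.abs(f_perp) < 2 * sigma)
    dc = np.abs(spectrum[0, 0])
    if dc == 0 or not window.any():
        return 0.0
    peak_spectrum = spectrum if reference_spectrum is None else spectrum - reference_spectrum
    rho = np.max(np.abs(peak_spectrum)[window]) / dc
    return float(np.clip(4.0 * rho / (1.0 + 2.0 * rho), 0.0, 1.0))


def remove_tags(
    tagged_image: np.ndarray,
    tag_spacing: float,
    directions: tuple[str, ...] = ("x", "y"),
    pixel_spacing: tuple[float, float] | float = 1.0,
    sigma_factor: float = NOTCH_SIGMA_FACTOR,
    anatomy_reference: np.ndarray | None = None,
) -> np.ndarray:
    """Suppress the tag grating with Gaussian notch filters.

    The grating also attenuates the image mean by 1 - d/2 per tagged
    direction; the effective depth d is estimated from the spectral
    peak-to-DC ratio and the attenuation divided out, so the result matches
    the untagged anatomy level (an untagged input passes through unchanged).

    ``anatomy_reference`` — an image of the same anatomy without this
    grating, in practice the orthogonally tagged series — sharpens the
    removal: the fringe spectrum is predicted by shifting the reference
    spectrum to ±1/tag_spacing and subtracted before notching, cancelling
    the anatomy-modulated fringe tails that extend beyond any notch.
    Output is real-valued and clipped non-negative.
    """
    img = np.asarray(tagged_image, dtype=float)
    if np.isscalar(pixel_spacing):
        pixel_spacing = (float(pixel_spacing), float(pixel_spacing))
    h = notch_filter_response(img.shape, tag_spacing, tuple(directions), pixel_spacing, sigma_factor)
    spectrum = np.fft.fft2(img)
    ref_spectrum = (
        np.fft.fft2(np.asarray(anatomy_reference, dtype=float))
        if anatomy_reference is not None
        else None
    )
    gain = 1.0
    for d in directions:
        depth = estimate_tag_depth(
            spectrum, tag_spacing, d, pixel_spacing, sigma_factor,
            reference_spectrum=ref_spectrum,
        )
        gain *= 1.0 - depth / 2.0
        if ref_spectrum is not None and depth > 0:
            ax = {"x": 0, "y": 1}[d]
            shift_bins = (1.0 / tag_spacing) * img.shape[ax] * pixel_spacing[ax]
            n = int(round(shift_bins))
            if abs(shift_bins - n) < 1e-6:  # tag frequency on the FFT grid
                # 1 - d*sin^2 = (1 - d/2) + (d/2)cos: fringe carries +d/4 of
                # the anatomy spectrum, and the reference carries (1 - d/2) of it
                coef = (depth / 4.0) / (1.0 - depth / 2.0)
                fringe = coef * (np.roll(ref_spectrum, n, axis=ax) + np.roll(ref_spectrum, -n, axis=ax))
                spectrum = spectrum - fringe
    out = np.fft.ifft2(spectrum * h).real / gain
    return np.clip(out, 0.0, None)


def _contour_mm(mask_region: np.ndarray, frame: ImageFrame) -> np.ndarray:
    """Longest iso-0.5 contour of a binary region, closed, CCW, resampled, in mm."""
    contours = measure.find_contours(mask_region.astype(float), 0.5)
    if not contours:
        raise SegmentationError("no contour found for region")
    c = max(contours, key=len)  # (N, 2) in index units
    pts = c * np.asarray(frame.pixel_spacing) + np.asarray(frame.origin)
    # close, orient CCW (positive shoelace area), resample by arc length
    if not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    area2 = np.sum(pts[:-1, 0] * pts[1:, 1] - pts[1:, 0] * pts[:-1, 1])
    if area2 < 0:
        pts = pts[::-1]
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arclen[-1], CONTOUR_VERTICES, endpoint=False)
    resampled = np.stack(
        [np.interp(targets, arclen, pts[:, 0]), np.interp(targets, arclen, pts[:, 1])], axis=-1
    )
    return resampled


def segment_myocardium(
    tag_free_image: np.ndarray,
    frame: ImageFrame | None = None,
    min_myo_area_mm2: float = 150.0,
    min_cavity_area_mm2: float = 30.0,
    smooth_sigma_px: float = 1.0,
) -> MyocardiumSegmentation:
    """Extract the bright myocardial annulus and its endo/epi contours.

    Multi-Otsu (3 classes) thresholding keeps the brightest class, small
    objects are removed and the largest connected component must enclose a
    blood-pool cavity; otherwise :class:`SegmentationError` is raised rather
    than returning a spurious segmentation.
    """
    img = np.asarray(tag_free_image, dtype=float)
    if frame is None:
        frame = ImageFrame(shape=img.shape, pixel_spacing=(1.0, 1.0))
    px_area = frame.pixel_spacing[0] * frame.pixel_spacing[1]
    smoothed = ndimage.gaussian_filter(img, smooth_sigma_px)
    try:
        thresholds = threshold_multiotsu(smoothed, classes=3)
    except ValueError as exc:  # degenerate histogram
        raise SegmentationError(f"could not threshold image: {exc}") from exc
    bright = smoothed >= thresholds[-1]
    bright = morphology.closing(bright, morphology.disk(2))
    bright = morphology.remove_small_objects(bright, max_size=max(8, int(min_myo_area_mm2 / px_area / 4)))
    labels, n = ndimage.label(bright)
    if n == 0:
        raise SegmentationError("no bright structure found in the tag-free image")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    ring = labels == (1 + int(np.argmax(sizes)))
    if ring.sum() * px_area < min_myo_area_mm2:
        raise SegmentationError(
            f"largest bright component is {ring.sum() * px_area:.0f} mm^2, "
            f"smaller than the minimum plausible myocardium ({min_myo_area_mm2} mm^2)"
        )
    filled = ndimage.binary_fill_holes(ring)
    border = np.zeros_like(filled)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    if np.any(filled & border):
        raise SegmentationError(
            "bright structure touches the image border; not a contained LV"
        )
    cavities, n_cav = ndimage.label(filled & ~ring)
    if n_cav == 0:
        raise SegmentationError("bright component has no blood-pool cavity (not an annulus)")
    cav_sizes = ndimage.sum_labels(np.ones_like(cavities), cavities, index=np.arange(1, n_cav + 1))
    cavity = cavities == (1 + int(np.argmax(cav_sizes)))
    if cavity.sum() * px_area < min_cavity_area_mm2:
        raise SegmentationError(
            f"cavity of {cavity.sum() * px_area:.0f} mm^2 is too small for a blood pool"
        )
    mask = filled & ~cavity

    # Refine both boundaries to the class-midpoint crossings: the single
    # Otsu cut sits between the myocardium and the *brightest other* class,
    # which biases endo- and epicardium into the ring by a fraction of the
    # edge width.
    myo_level = np.median(smoothed[mask])
    blood_level = np.median(smoothed[cavity]) if cavity.any() else 0.0
    shell = morphology.dilation(filled, morphology.disk(4)) & ~filled
    out_level = np.median(smoothed[shell]) if shell.any() else 0.0
    if blood_level < myo_level and out_level < myo_level:
        t_epi = 0.5 * (myo_level + out_level)
        epi_labels, n_epi = ndimage.label(smoothed > t_epi)
        if n_epi:
            hit = np.bincount(epi_labels[mask].ravel())
            hit[0] = 0
            filled = ndimage.binary_fill_holes(epi_labels == int(np.argmax(hit)))
        t_endo = 0.5 * (myo_level + blood_level)
        cav_labels, n_cav2 = ndimage.label(filled & (smoothed < t_endo))
        if n_cav2:
            hit = np.bincount(cav_labels[cavity].ravel())
            hit[0] = 0
            if hit.max() > 0:
                cavity = ndimage.binary_fill_holes(cav_labels == int(np.argmax(hit)))
        mask = filled & ~cavity
    epi = _contour_mm(filled, frame)
    endo = _contour_mm(ndimage.binary_fill_holes(cavity), frame)
    if not Polygon(epi).buffer(1e-6).contains(Polygon(endo)):
        raise SegmentationError("endocardial contour is not strictly inside the epicardial one")
    logger.debug("segmented myocardium: %d px, center %s", mask.sum(), endo.mean(axis=0))
    return MyocardiumSegmentation(endo_contour=endo, epi_contour=epi, mask=mask)
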