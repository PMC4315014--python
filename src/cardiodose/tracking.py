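"""Dense myocardial motion from tagged images via harmonic-phase demodulation.

The tag grating imprints the material coordinate of each tissue point as the
phase of a complex "harmonic" image: isolating the +1 spectral peak of the
grating (Gaussian bandpass at 1/tag_spacing along the tagged axis) and
taking the complex angle yields a wrapped phase that is, up to 2π, a linear
function of the *material* coordinate — a property the tissue carries with
it as it moves.  Differencing the wrapped phase of two cardiac phases at a
fixed pixel therefore measures the displacement component along the tag
axis; two orthogonal tag directions give the full 2-vector.

Per-pixel wrapping (no global unwrapping) limits each comparison to motions
below half a tag spacing per direction (the aperture limit); larger motions
are handled by tracking adjacent phases and composing the fields in
ascending phase order with bilinear resampling.

Fields are Lagrangian: anchored to the reference-phase (phase-0) pixel grid,
matching the strain computation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io_core import ImageFrame, logger

#: Bandpass width as a fraction of the tag frequency (sigma_f = 0.2 / tag_spacing).
BANDPASS_SIGMA_FACTOR = 0.2
#: Minimum ratio of in-band peak magnitude to the high-frequency noise floor.
#: A tagless pure-noise image peaks around 2.5-3x the floor (Rayleigh max
#: over the window); even heavily faded tags sit clearly above that.
MIN_PEAK_SNR = 3.0
#: Harmonic-magnitude anomaly tolerance for the phase quality mask.  For
#: additive in-band interference the relative magnitude perturbation and the
#: phase perturbation (radians) share the same scale, so pixels whose
#: magnitude deviates from the in-mask median by more than this fraction are
#: flagged unreliable.
QUALITY_TAU = 0.3
#: Default width (px) of the quality-weighted field regularization.
REGULARIZE_SIGMA_PX = 2.0

_AXES = {"x": 0, "y": 1}


class HarmonicExtractionError(RuntimeError):
    """The tag spectral peak is absent or below the noise floor."""


@dataclass
class HarmonicPhaseImage:
    """Wrapped harmonic phase (radians, (-pi, pi]) and magnitude of one tag direction."""

    wrapped_phase: np.ndarray
    magnitude: np.ndarray
    direction: str
    tag_spacing: float
    frame: ImageFrame


@dataclass
class DisplacementField:
    """Dense per-pixel 2-vector displacement (mm) on the reference-phase grid."""

    vectors: np.ndarray  # (nx, ny, 2)
    phase_index: int
    validity_mask: np.ndarray  # (nx, ny) bool
    frame: ImageFrame
    reference_phase: int = 0


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(phi)))


def extract_harmonic_phase(
    tagged_image: np.ndarray,
    tag_spacing: float,
    direction: str,
    frame: ImageFrame | None = None,
    bandpass_sigma_factor: float = BANDPASS_SIGMA_FACTOR,
    min_peak_snr: float = MIN_PEAK_SNR,
    anatomy_reference: np.ndarray | None = None,
) -> HarmonicPhaseImage:
    """Isolate the +1 tag spectral peak and return its wrapped phase and magnitude.

    ``anatomy_reference`` is an image of the *same* anatomy at the same
    phase without this direction's grating — in practice the
    orthogonally-tagged series.  Its spectrum is subtracted before
    windowing, cancelling the anatomy's own in-band energy (the dominant
    phase-bias source once tags have faded) while leaving this direction's
    tag peak untouched; the idea is the same anatomy-suppression that
    subtractive (CSPAMM-style) tagging achieves, using the orthogonal
    acquisition as the reference.
    """
    img = np.asarray(tagged_image, dtype=float)
    if frame is None:
        frame = ImageFrame(shape=img.shape, pixel_spacing=(1.0, 1.0))
    ax = _AXES[direction]
    f_tag = 1.0 / tag_spacing
    nyq = 1.0 / (2.0 * frame.pixel_spacing[ax])
    if f_tag >= nyq:
        raise ValueError(f"tag frequency {f_tag:.4f}/mm >= Nyquist {nyq:.4f}/mm along {direction}")
    fx = np.fft.fftfreq(img.shape[0], d=frame.pixel_spacing[0])
    fy = np.fft.fftfreq(img.shape[1], d=frame.pixel_spacing[1])
    gfx, gfy = np.meshgrid(fx, fy, indexing="ij")
    f_axis = (gfx, gfy)[ax]
    f_perp = (gfy, gfx)[ax]
    sigma = bandpass_sigma_factor / tag_spacing
    window = np.exp(-((f_axis - f_tag) ** 2 + f_perp**2) / (2.0 * sigma**2))
    spectrum = np.fft.fft2(img)
    # SNR guard on the raw spectrum (the reference subtraction below raises
    # the noise floor by sqrt(2) without touching the tag peak)
    peak = np.max(np.abs(spectrum) * window)
    nyq_x = 1.0 / (2.0 * frame.pixel_spacing[0])
    nyq_y = 1.0 / (2.0 * frame.pixel_spacing[1])
    f_mag = np.hypot(gfx / nyq_x, gfy / nyq_y)
    floor_region = f_mag > 0.7
    floor = np.median(np.abs(spectrum)[floor_region]) if floor_region.any() else 0.0
    if anatomy_reference is not None:
        spectrum = spectrum - np.fft.fft2(np.asarray(anatomy_reference, dtype=float))
    if floor > 0 and peak < min_peak_snr * floor:
        raise HarmonicExtractionError(
            f"tag peak along {direction} ({peak:.1f}) is below {min_peak_snr}x the "
            f"noise floor ({floor:.1f}); no usable tag pattern"
        )
    harmonic = np.fft.ifft2(spectrum * window)
    return HarmonicPhaseImage(
        wrapped_phase=np.angle(harmonic),
        magnitude=np.abs(harmonic),
        direction=direction,
        tag_spacing=tag_spacing,
        frame=frame,
    )


def _by_direction(pair: Sequence[HarmonicPhaseImage]) -> dict[str, HarmonicPhaseImage]:
    d = {h.direction: h for h in pair}
    if set(d) != {"x", "y"}:
        raise ValueError(f"need one harmonic image per direction x and y, got {sorted(d)}")
    return d


def _sample(field: np.ndarray, idx: np.ndarray, order: int = 1) -> np.ndarray:
    return ndimage.map_coordinates(field, [idx[..., 0], idx[..., 1]], order=order, mode="nearest")


def quality_mask(
    harmonics: Sequence[HarmonicPhaseImage],
    support: np.ndarray | None = None,
    tau: float = QUALITY_TAU,
) -> np.ndarray:
    """Phase-reliability mask from the harmonic-magnitude anomaly test.

    Within the support (myocardium) the tag envelope is near-uniform, so the
    harmonic magnitude should sit near its median; additive interference —
    tissue-boundary leakage, noise — perturbs magnitude and phase at the
    same relative scale.  Pixels where any harmonic's magnitude deviates
    from the in-support median by more than ``tau`` are flagged unreliable
    (phase error potentially above ``tau`` radians).
    """
    ok: np.ndarray | None = None
    for h in harmonics:
        m = h.magnitude
        sel = m[support] if support is not None else m.ravel()
        med = np.median(sel)
        good = np.abs(m / med - 1.0) < tau if med > 0 else np.zeros_like(m, dtype=bool)
        ok = good if ok is None else (ok & good)
    assert ok is not None
    return ok if support is None else (ok & support)


def track_displacement(
    reference: Sequence[HarmonicPhaseImage],
    target: Sequence[HarmonicPhaseImage],
    tag_spacing: float | None = None,
    myocardium_mask: np.ndarray | None = None,
    phase_index: int = 0,
    reference_phase: int = 0,
    quality_tau: float = QUALITY_TAU,
    lagrangian_iterations: int = 4,
) -> DisplacementField:
    """Recover the dense displacement between two phases from wrapped-phase differences.

    For each pixel the per-direction wrapped difference Δφ_d = wrap(φ_tgt −
    φ_ref) gives the displacement component u_d = −(s/2π)·Δφ_d of the tissue
    *arriving* at that pixel (Eulerian); a short fixed-point iteration then
    resamples this onto the reference-phase material grid (Lagrangian).
    Identical reference and target yield the zero field exactly.

    ``validity_mask`` is the harmonic-magnitude quality mask (see
    :func:`quality_mask`) of all four harmonic images intersected with the
    myocardium; motions beyond half a tag spacing per direction alias and
    cannot be flagged pointwise (use compose mode for those).
    """
    ref = _by_direction(reference)
    tgt = _by_direction(target)
    frame = ref["x"].frame
    s = tag_spacing if tag_spacing is not None else ref["x"].tag_spacing
    u_e = np.empty(frame.shape + (2,))
    for d, ax in _AXES.items():
        frame.require_equal(tgt[d].frame, "harmonic images")
        dphi = wrap_phase(tgt[d].wrapped_phase - ref[d].wrapped_phase)
        u_e[..., ax] = -(s / (2.0 * np.pi)) * dphi
    validity = quality_mask(
        [ref["x"], ref["y"], tgt["x"], tgt["y"]], support=myocardium_mask, tau=quality_tau
    )

    # Lagrangianize: u_L(X) solves u_L = u_E(X + u_L); start from u_E(X).
    spacing = np.asarray(frame.pixel_spacing)
    u_l = u_e.copy()
    for _ in range(lagrangian_iterations):
        idx = (frame.pixel_centers() + u_l - np.asarray(frame.origin)) / spacing
        u_l = np.stack([_sample(u_e[..., 0], idx), _sample(u_e[..., 1], idx)], axis=-1)
    return DisplacementField(
        vectors=u_l,
        phase_index=phase_index,
        validity_mask=validity,
        frame=frame,
        reference_phase=reference_phase,
    )


def regularize_field(
    field: DisplacementField,
    support: np.ndarray | None = None,
    sigma_px: float = REGULARIZE_SIGMA_PX,
) -> DisplacementField:
    """Quality-weighted smooth reconstruction of the field over a support region.

    The true cardiac displacement field is spatially smooth, so a normalized
    Gaussian convolution weighted by the validity (quality) mask both
    denoises reliable pixels and fills unreliable ones from their
    neighbours.  The returned field is defined on all support pixels within
    reach of a valid pixel; its validity mask still marks only the directly
    measured (quality) pixels.
    """
    if sigma_px <= 0:
        return field
    sup = support if support is not None else np.ones(field.frame.shape, bool)
    w = field.validity_mask.astype(float)
    wm = ndimage.gaussian_filter(w, sigma_px)
    reachable = wm > 1e-6
    u = np.stack(
        [
            np.divide(
                ndimage.gaussian_filter(field.vectors[..., c] * w, sigma_px),
                wm,
                out=np.zeros(field.frame.shape),
                where=reachable,
            )
            for c in (0, 1)
        ],
        axis=-1,
    )
    u = np.where((sup & reachable)[..., None], u, field.vectors)
    return DisplacementField(
        vectors=u,
        phase_index=field.phase_index,
        validity_mask=field.validity_mask & sup & reachable,
        frame=field.frame,
        reference_phase=field.reference_phase,
    )


def compose_fields(base: DisplacementField, increment: DisplacementField) -> DisplacementField:
    """Compose phase-0→k (``base``) with k→k+1 (``increment``, on the phase-k grid).

    ``u_{0→k+1}(X) = u_{0→k}(X) + w_k(X + u_{0→k}(X))`` with bilinear
    resampling of the incremental field at the moved position.
    """
    frame = base.frame
    frame.require_equal(increment.frame, "displacement fields")
    spacing = np.asarray(frame.pixel_spacing)
    idx = (frame.pixel_centers() + base.vectors - np.asarray(frame.origin)) / spacing
    w = np.stack(
        [_sample(increment.vectors[..., 0], idx), _sample(increment.vectors[..., 1], idx)], axis=-1
    )
    valid_inc = _sample(increment.validity_mask.astype(float), idx, order=0) > 0.5
    return DisplacementField(
        vectors=base.vectors + w,
        phase_index=increment.phase_index,
        validity_mask=base.validity_mask & valid_inc,
        frame=frame,
        reference_phase=base.reference_phase,
    )


def track_series(
    tagged_x: np.ndarray,
    tagged_y: np.ndarray,
    tag_spacing: float,
    frame: ImageFrame,
    myocardium_mask: np.ndarray | None = None,
    mode: str = "direct",
    bandpass_sigma_factor: float = BANDPASS_SIGMA_FACTOR,
    quality_tau: float = QUALITY_TAU,
    regularize_sigma_px: float = REGULARIZE_SIGMA_PX,
) -> list[DisplacementField]:
    """Track all phases of a two-direction tagged series against phase 0.

    ``direct`` differences every phase against phase 0 (valid while motion
    stays below the s/2 aperture); ``compose`` chains adjacent-phase fields
    in ascending order.  Each per-phase field is regularized over the
    myocardium (quality-weighted smoothing, see :func:`regularize_field`)
    unless ``regularize_sigma_px`` is 0.  Returns one Lagrangian field per
    phase; phase 0 is identically zero.
    """
    if mode not in ("direct", "compose"):
        raise ValueError(f"mode must be 'direct' or 'compose', got {mode!r}")
    P = tagged_x.shape[0]
    harmonics = []
    for k in range(P):
        harmonics.append(
            [
                extract_harmonic_phase(
                    tagged_x[k], tag_spacing, "x", frame, bandpass_sigma_factor,
                    anatomy_reference=tagged_y[k],
                ),
                extract_harmonic_phase(
                    tagged_y[k], tag_spacing, "y", frame, bandpass_sigma_factor,
                    anatomy_reference=tagged_x[k],
                ),
            ]
        )
    fields: list[DisplacementField] = []
    zero = DisplacementField(
        vectors=np.zeros(frame.shape + (2,)),
        phase_index=0,
        validity_mask=(
            myocardium_mask.copy() if myocardium_mask is not None else np.ones(frame.shape, bool)
        ),
        frame=frame,
    )
    fields.append(zero)
    if mode == "direct":
        for k in range(1, P):
            fields.append(
                track_displacement(
                    harmonics[0], harmonics[k], tag_spacing, myocardium_mask,
                    phase_index=k, quality_tau=quality_tau,
                )
            )
    else:
        for k in range(1, P):
            inc = track_displacement(
                harmonics[k - 1], harmonics[k], tag_spacing, myocardium_mask,
                phase_index=k, reference_phase=k - 1, quality_tau=quality_tau,
            )
            fields.append(compose_fields(fields[-1], inc))
        if myocardium_mask is not None:
            for f in fields:
                f.validity_mask &= myocardium_mask
    if regularize_sigma_px > 0:
        fields = [fields[0]] + [
            regularize_field(f, support=myocardium_mask, sigma_px=regularize_sigma_px)
            for f in fields[1:]
        ]
    logger.debug("tracked %d phases in %s mode", P, mode)
    return fields


def invert_displacement(field: DisplacementField, iterations: int = 6) -> np.ndarray:
    """Eulerian displacement u_E(x) = u_L(x - u_E(x)) by fixed-point iteration."""
    frame = field.frame
    spacing = np.asarray(frame.pixel_spacing)
    coords = frame.pixel_centers()
    u_e = field.vectors.copy()
    for _ in range(iterations):
        idx = (coords - u_e - np.asarray(frame.origin)) / spacing
        u_e = np.stack(
            [_sample(field.vectors[..., 0], idx), _sample(field.vectors[..., 1], idx)], axis=-1
        )
    return u_e


def warp_mask_by_field(mask: np.ndarray, field: DisplacementField) -> np.ndarray:
    """Propagate a reference-phase mask to the field's phase (nearest-neighbour pullback)."""
    u_e = invert_displacement(field)
    frame = field.frame
    idx = (frame.pixel_centers() - u_e - np.asarray(frame.origin)) / np.asarray(frame.pixel_spacing)
    return _sample(mask.astype(float), idx, order=0) > 0.5
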