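"""Synthetic SPAMM-tagged MRI studies of a deforming left ventricle.

The phantom is a short-axis slice of an annular left ventricle (blood pool
inside the endocardium, myocardium between endo- and epicardium, background
outside) that contracts and twists over an ECG-gated cardiac cycle with an
analytically known, closed-form-invertible motion law:

* radial contraction — exactly area-preserving on the annulus:
  ``r' = sqrt(r^2 - c)`` for material radius ``r >= endo_radius`` and a
  linear scaling of the blood pool below it, with
  ``c = endo_radius^2 (1 - (1 - a g(t))^2)`` so that the endocardial radius
  contracts by the fraction ``a`` at peak activation;
* a rigid twist by ``twist_amplitude * g(t)`` about the LV center.

``g(t)`` is a raised-cosine activation: 0 at phase 0 (end-diastole, the
motion reference), 1 at the peak-systole phase, and back to 0 at the last
phase.  An optional angular "wedge" locally suppresses the contraction
amplitude, emulating a hypokinetic region whose strain deficit downstream
stages should detect.

Tagging is 1-1 SPAMM rendered as a multiplicative sin^2 grating evaluated at
*material* coordinates (tags move with the tissue), with per-phase tag
fading.  Surface-coil shading is a smooth multiplicative polynomial bias
field; noise is additive Gaussian.  A co-registered synthetic CT (same
anatomy, different intensity classes, offset by a known rigid transform) and
a tangential-beam-like dose grid with a sigmoid penumbra complete the study.

Everything the generator knows — per-phase dense displacement fields,
myocardium masks, the CT→MRI transform, the bias field, the dose — is
emitted as :class:`PhantomTruth` for use as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

from .io_core import DoseGrid, ImageFrame, RigidTransform, logger

#: Nominal intensity classes of the synthetic (magnitude-like) MR image.
#: Besides the LV, the scene has a chest-wall slab and an RV-like blob:
#: without rotationally asymmetric anatomy a rigid registration of the
#: annular LV would be degenerate in rotation.
MRI_INTENSITY = {
    "background": 5.0,
    "blood": 40.0,
    "myocardium": 100.0,
    "chest_wall": 65.0,
    "rv_blood": 75.0,
}
#: CT intensity classes: deliberately *not* a monotone remapping of the MR
#: classes, so that only a multimodality metric (MI) can register the pair.
CT_INTENSITY = {
    "background": 0.0,
    "blood": 90.0,
    "myocardium": 45.0,
    "chest_wall": 60.0,
    "rv_blood": 90.0,
}

#: Width (mm) of the smooth class-boundary profile (partial-volume stand-in).
#: Wide enough that the anatomy spectrum has decayed at the tag frequency,
#: as it has in real (band-limited) MR reconstructions.
EDGE_WIDTH_MM = 2.0

DIRECTIONS = ("x", "y")


def raised_cosine_profile(phase_count: int, peak_phase: int | None = None) -> Callable[[int], float]:
    """Activation g(k): 0 at phase 0, 1 at ``peak_phase``, 0 again at the last phase."""
    if peak_phase is None:
        peak_phase = max(1, phase_count // 3)
    last = phase_count - 1

    def g(k: int) -> float:
        if not 0 <= k < phase_count:
            raise IndexError(f"phase {k} out of range [0, {phase_count})")
        if k <= peak_phase:
            return 0.5 * (1.0 - np.cos(np.pi * k / peak_phase))
        return 0.5 * (1.0 + np.cos(np.pi * (k - peak_phase) / (last - peak_phase)))

    return g


@dataclass(frozen=True)
class LVGeometry:
    """Annular LV geometry on a square pixel grid (all lengths in mm)."""

    center: tuple[float, float]
    endo_radius: float
    epi_radius: float
    image_shape: tuple[int, int] = (160, 160)
    pixel_spacing: float = 1.25

    def __post_init__(self) -> None:
        if not 0 < self.endo_radius < self.epi_radius:
            raise ValueError(
                f"need 0 < endo_radius < epi_radius, got {self.endo_radius}, {self.epi_radius}"
            )
        extent = min(self.image_shape) * self.pixel_spacing
        cx, cy = self.center
        for c, n in zip(self.center, self.image_shape):
            if c - self.epi_radius < 0 or c + self.epi_radius > n * self.pixel_spacing:
                raise ValueError("epicardium does not fit inside the image extent")

    @property
    def frame(self) -> ImageFrame:
        return ImageFrame(
            shape=self.image_shape,
            pixel_spacing=(self.pixel_spacing, self.pixel_spacing),
        )

    @classmethod
    def default(cls) -> "LVGeometry":
        shape = (160, 160)
        spacing = 1.25
        c = (shape[0] - 1) / 2 * spacing
        return cls(center=(c, c), endo_radius=20.0, epi_radius=32.0, image_shape=shape, pixel_spacing=spacing)


@dataclass(frozen=True)
class MotionModel:
    """Contraction + rigid twist with a raised-cosine temporal activation.

    ``contraction_amplitude`` is the peak fractional contraction of the
    endocardial radius (dimensionless); ``twist_amplitude`` the peak rigid
    rotation (radians).  The optional wedge suppresses contraction inside a
    cos^2-tapered angular sector (material angles), leaving the twist rigid.
    """

    contraction_amplitude: float = 0.10
    twist_amplitude: float = 0.08
    phase_count: int = 24
    peak_phase: int | None = None
    temporal_profile: Callable[[int], float] | None = None
    wedge_center: float | None = None
    wedge_width: float = float(np.pi / 2)
    wedge_suppression: float = 0.8

    def __post_init__(self) -> None:
        if self.phase_count < 2:
            raise ValueError("phase_count must be >= 2")
        if not 0 <= self.contraction_amplitude < 1:
            raise ValueError("contraction_amplitude must be in [0, 1)")

    def activation(self, phase: int) -> float:
        profile = self.temporal_profile or raised_cosine_profile(self.phase_count, self.peak_phase)
        return float(profile(phase))

    @property
    def resolved_peak_phase(self) -> int:
        return self.peak_phase if self.peak_phase is not None else max(1, self.phase_count // 3)

    def contraction_at(self, theta: np.ndarray | float) -> np.ndarray:
        """Local contraction amplitude a_eff(theta) with the wedge applied."""
        a = np.full_like(np.asarray(theta, dtype=float), self.contraction_amplitude)
        if self.wedge_center is not None and self.wedge_suppression > 0:
            delta = np.angle(np.exp(1j * (np.asarray(theta) - self.wedge_center)))
            inside = np.abs(delta) < self.wedge_width / 2
            taper = np.where(inside, np.cos(np.pi * delta / self.wedge_width) ** 2, 0.0)
            a = a * (1.0 - self.wedge_suppression * taper)
        return a


@dataclass(frozen=True)
class SpammParams:
    """1-1 SPAMM tag grating parameters."""

    tag_spacing: float = 8.0
    tag_depth: float = 0.8
    directions: tuple[str, ...] = DIRECTIONS
    fading_rate: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.tag_depth <= 1.0:
            raise ValueError("tag_depth must be in [0, 1]")
        if not 0.0 <= self.fading_rate <= 1.0:
            raise ValueError("fading_rate must be in [0, 1]")
        bad = set(self.directions) - set(DIRECTIONS)
        if bad:
            raise ValueError(f"unknown tag directions {bad}; use {DIRECTIONS}")

    def effective_depth(self, phase: int) -> float:
        """Tag depth after fading: ``tag_depth * (1 - fading_rate)**phase``."""
        return self.tag_depth * (1.0 - self.fading_rate) ** phase


@dataclass
class TaggedStudy:
    """A synthetic acquisition: tagged series, ED image, CT, and dose grid."""

    tagged: dict[str, np.ndarray]  # direction -> (P, nx, ny)
    nontagged_ed: np.ndarray  # (nx, ny)
    frame: ImageFrame
    tag_spacing: float
    phase_count: int
    slice_thickness: float
    ct_image: np.ndarray
    ct_frame: ImageFrame
    dose: DoseGrid
    params: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class PhantomTruth:
    """Everything the generator knows, for use as a ground-truth oracle."""

    displacement_fields: np.ndarray  # (P, nx, ny, 2) Lagrangian, mm, phase-0 grid
    eulerian_fields: np.ndarray  # (P, nx, ny, 2) motion of the point now at x
    myocardium_masks: np.ndarray  # (P, nx, ny) bool
    dose_truth: DoseGrid
    ct_to_mri_transform: RigidTransform
    bias_field: np.ndarray
    geometry: LVGeometry
    motion: MotionModel
    spamm: SpammParams

    @property
    def lv_center(self) -> np.ndarray:
        return np.asarray(self.geometry.center, dtype=float)


# ---------------------------------------------------------------------------
# Analytic motion law
# ---------------------------------------------------------------------------


def _radial_params(motion: MotionModel, geometry: LVGeometry, theta: np.ndarray, phase: int):
    g = motion.activation(phase)
    a_eff = motion.contraction_at(theta) * 1.0
    scale = 1.0 - a_eff * g  # endo radius scale factor
    c = geometry.endo_radius**2 * (1.0 - scale**2)
    return g, scale, c


def analytic_displacement(
    points_mm: np.ndarray,
    phase: int,
    geometry: LVGeometry,
    motion: MotionModel,
) -> np.ndarray:
    """Lagrangian displacement (mm) of material points from phase 0 to ``phase``.

    The center is a fixed point; the displacement is continuous everywhere
    and the annulus map is exactly area-preserving (absent a wedge).
    """
    if not 0 <= phase < motion.phase_count:
        raise IndexError(f"phase {phase} out of range [0, {motion.phase_count})")
    pts = np.asarray(points_mm, dtype=float)
    if motion.activation(phase) == 0.0:  # reference / fully relaxed: exactly zero
        return np.zeros_like(pts)
    rel = pts - np.asarray(geometry.center)
    r = np.hypot(rel[..., 0], rel[..., 1])
    theta = np.arctan2(rel[..., 1], rel[..., 0])
    g, scale, c = _radial_params(motion, geometry, theta, phase)
    with np.errstate(invalid="ignore"):
        outer = np.sqrt(np.maximum(r**2 - c, 0.0))
    r_new = np.where(r >= geometry.endo_radius, outer, r * scale)
    tau = motion.twist_amplitude * g
    theta_new = theta + tau
    new_rel = np.stack([r_new * np.cos(theta_new), r_new * np.sin(theta_new)], axis=-1)
    disp = new_rel - rel
    return np.where(r[..., None] > 0, disp, 0.0)


def inverse_map(
    points_mm: np.ndarray,
    phase: int,
    geometry: LVGeometry,
    motion: MotionModel,
) -> np.ndarray:
    """Material (phase-0) coordinates of the points occupying ``points_mm`` at ``phase``."""
    if not 0 <= phase < motion.phase_count:
        raise IndexError(f"phase {phase} out of range [0, {motion.phase_count})")
    pts = np.asarray(points_mm, dtype=float)
    if motion.activation(phase) == 0.0:
        return pts.copy()
    rel = pts - np.asarray(geometry.center)
    rp = np.hypot(rel[..., 0], rel[..., 1])
    theta_p = np.arctan2(rel[..., 1], rel[..., 0])
    g = motion.activation(phase)
    tau = motion.twist_amplitude * g
    theta = theta_p - tau  # material angle (twist is rigid)
    _, scale, c = _radial_params(motion, geometry, theta, phase)
    endo_deformed = geometry.endo_radius * scale
    r = np.where(
        rp >= endo_deformed,
        np.sqrt(rp**2 + c),
        np.divide(rp, scale, out=np.zeros_like(rp), where=scale > 0),
    )
    mat_rel = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=-1)
    return np.where(rp[..., None] > 0, mat_rel + np.asarray(geometry.center), pts)


def analytic_polar_strain(
    r_mm: np.ndarray,
    phase: int,
    geometry: LVGeometry,
    motion: MotionModel,
    theta: np.ndarray | float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form Green–Lagrange (E_rr, E_cc) of the motion law at material radius r.

    Exact for the axisymmetric law; with a wedge the returned values use the
    local contraction amplitude at ``theta`` and neglect the small shear from
    the angular taper.
    """
    r = np.asarray(r_mm, dtype=float)
    _, _, c = _radial_params(motion, geometry, np.asarray(theta, dtype=float), phase)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam_c2 = np.maximum(r**2 - c, 0.0) / r**2  # (r'/r)^2
        e_cc = 0.5 * (lam_c2 - 1.0)
        e_rr = 0.5 * (1.0 / lam_c2 - 1.0)
    return e_rr, e_cc


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def scene_intensity(
    material_mm: np.ndarray, geometry: LVGeometry, intensities: dict
) -> np.ndarray:
    """Smooth intensity of the full scene at material coordinates.

    The LV (blood pool / myocardial annulus) sits over a background that
    also carries a chest-wall slab and an RV-like blood blob; all boundaries
    use a logistic profile of width :data:`EDGE_WIDTH_MM` as a partial-volume
    stand-in.  The off-axis structures make the scene rotationally
    asymmetric so a rigid registration is well-posed.
    """
    w4 = EDGE_WIDTH_MM / 4.0
    pts = np.asarray(material_mm, dtype=float)
    rel = pts - np.asarray(geometry.center)
    r = np.hypot(rel[..., 0], rel[..., 1])

    # background composite: chest-wall slab along x, RV blob at lower-left
    base = np.full(r.shape, intensities["background"])
    slab_lo, slab_hi = 10.0, 22.0
    d_slab = np.maximum(slab_lo - pts[..., 0], pts[..., 0] - slab_hi)
    base = base + (intensities["chest_wall"] - intensities["background"]) * expit(-d_slab / w4)
    rv_center = np.asarray(geometry.center) + np.array([-46.0, 18.0])
    rv_axes = np.array([12.0, 9.0])
    f = np.sqrt(np.sum(((pts - rv_center) / rv_axes) ** 2, axis=-1))
    d_rv = (f - 1.0) * rv_axes.min()
    base = base + (intensities["rv_blood"] - intensities["background"]) * expit(-d_rv / w4)

    # LV painted over the composite
    inner = intensities["blood"] + (intensities["myocardium"] - intensities["blood"]) * expit(
        (r - geometry.endo_radius) / w4
    )
    w_lv = expit(-(r - geometry.epi_radius) / w4)
    return base + (inner - base) * w_lv


def _material_scene(frame: ImageFrame, phase: int, geometry: LVGeometry, motion: MotionModel):
    coords = frame.pixel_centers()
    mat = inverse_map(coords, phase, geometry, motion)
    rel = mat - np.asarray(geometry.center)
    return np.hypot(rel[..., 0], rel[..., 1]), mat, coords


def render_phase(
    geometry: LVGeometry,
    motion: MotionModel,
    phase: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    intensities: dict | None = None,
    frame: ImageFrame | None = None,
) -> np.ndarray:
    """Render the (untagged) anatomy at a cardiac phase, deformed by the motion law.

    Intensity at pixel x is the class profile evaluated at the material point
    occupying x (i.e. the image is warped by the inverse of
    :func:`analytic_displacement`).  Deterministic given ``seed``.
    """
    frame = frame or geometry.frame
    intensities = intensities or MRI_INTENSITY
    _, mat, _ = _material_scene(frame, phase, geometry, motion)
    img = scene_intensity(mat, geometry, intensities)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img


def truth_mask(
    geometry: LVGeometry, motion: MotionModel, phase: int, frame: ImageFrame | None = None
) -> np.ndarray:
    """Binary myocardium mask at a phase (material radius in [endo, epi])."""
    frame = frame or geometry.frame
    r_mat, _, _ = _material_scene(frame, phase, geometry, motion)
    return (r_mat >= geometry.endo_radius) & (r_mat <= geometry.epi_radius)


def spamm_modulate(
    image: np.ndarray,
    params: SpammParams,
    phase: int,
    displacement: np.ndarray | None = None,
    frame: ImageFrame | None = None,
) -> np.ndarray:
    """Multiply an image by SPAMM tag gratings evaluated at material coordinates.

    ``displacement`` is the Eulerian motion field at this phase (motion from
    tagging time, phase 0, of the tissue now at each pixel); the material
    coordinate is ``x - displacement``.  ``None`` means no motion.  For each
    direction the modulation is ``1 - d_eff * sin^2(pi * x0_d / s)`` with
    ``d_eff = tag_depth * (1 - fading_rate)**phase`` (tag fading).
    """
    image = np.asarray(image, dtype=float)
    if frame is None:
        frame = ImageFrame(shape=image.shape, pixel_spacing=(1.0, 1.0))
    if params.tag_spacing <= 2.0 * max(frame.pixel_spacing):
        raise ValueError(
            f"tag spacing {params.tag_spacing} mm is not resolvable at pixel spacing "
            f"{frame.pixel_spacing} mm (need > 2 px per tag period)"
        )
    coords = frame.pixel_centers()
    material = coords if displacement is None else coords - np.asarray(displacement)
    d_eff = params.effective_depth(phase)
    out = image.copy()
    for direction in params.directions:
        axis = DIRECTIONS.index(direction)
        x0 = material[..., axis]
        out = out * (1.0 - d_eff * np.sin(np.pi * x0 / params.tag_spacing) ** 2)
    return out


def make_bias_field(
    shape: tuple[int, int], bias_strength: float, seed: int = 0, order: int = 2
) -> np.ndarray:
    """Smooth multiplicative coil-shading field: unit mean, strictly positive.

    The exponential of a random low-order polynomial over normalized
    coordinates, scaled so the peak log-deviation is ``ln(1+bias_strength)``
    and normalized to unit mean over the image.  Strict positivity is
    automatic, and the log-domain polynomial form matches what a
    log-intensity surface fit can represent exactly.
    """
    if bias_strength < 0:
        raise ValueError("bias_strength must be >= 0")
    if bias_strength == 0:
        return np.ones(shape)
    rng = np.random.default_rng(seed)
    xs = np.linspace(-1, 1, shape[0])
    ys = np.linspace(-1, 1, shape[1])
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    q = np.zeros(shape)
    for i in range(order + 1):
        for j in range(order + 1 - i):
            if i == j == 0:
                continue
            q = q + rng.normal() * gx**i * gy**j
    q -= q.mean()
    q /= np.max(np.abs(q))
    b = np.exp(np.log1p(bias_strength) * q)
    return b / b.mean()


def apply_bias_field(image: np.ndarray, bias_strength: float, seed: int = 0, order: int = 2):
    """Apply the seeded coil-shading field; returns ``(biased_image, field)``."""
    field = make_bias_field(np.asarray(image).shape, bias_strength, seed=seed, order=order)
    return np.asarray(image, dtype=float) * field, field


def make_dose_grid(
    geometry: LVGeometry,
    beam_edge_position: float | None = None,
    max_dose: float = 50.0,
    penumbra_width: float = 10.0,
    frame: ImageFrame | None = None,
) -> DoseGrid:
    """Tangential-beam-like dose: ``max_dose`` in-field, sigmoid fall-off across the edge.

    The fall-off runs along +x; ``penumbra_width`` is the 80%–20% distance of
    the logistic profile, and the dose is exactly ``max_dose/2`` at the edge.
    """
    if penumbra_width <= 0:
        raise ValueError("penumbra_width must be > 0")
    frame = frame or geometry.frame
    if beam_edge_position is None:
        beam_edge_position = float(frame.center_mm[0])
    k = penumbra_width / (2.0 * np.log(4.0))
    x = frame.pixel_centers()[..., 0]
    values = max_dose * expit((beam_edge_position - x) / k)
    return DoseGrid(values=values, frame=frame)


def dose_profile(
    x_mm: np.ndarray, beam_edge_position: float, max_dose: float, penumbra_width: float
) -> np.ndarray:
    """Closed-form 1D dose profile along the fall-off axis (same law as the grid)."""
    k = penumbra_width / (2.0 * np.log(4.0))
    return max_dose * expit((beam_edge_position - np.asarray(x_mm, dtype=float)) / k)


# ---------------------------------------------------------------------------
# Full study assembly
# ---------------------------------------------------------------------------


def make_study(
    geometry: LVGeometry | None = None,
    motion: MotionModel | None = None,
    spamm: SpammParams | None = None,
    noise_sd: float = 5.0,
    bias_strength: float = 0.3,
    ct_offset_mm: Sequence[float] = (4.0, -3.0),
    ct_rotation_deg: float = 3.0,
    beam_edge_mm: float | None = None,
    max_dose_gy: float = 50.0,
    penumbra_mm: float = 10.0,
    slice_thickness: float = 5.0,
    seed: int = 0,
) -> tuple[TaggedStudy, PhantomTruth]:
    """Generate a complete synthetic study plus its ground truth.

    Defaults follow the emulated acquisition protocol: 24 cardiac phases,
    8 mm tag spacing, horizontal and vertical tag series, 5 mm nominal slice
    thickness, tag fading across phases, and coil-shading non-uniformity.
    Deterministic: identical seeds and parameters yield bit-identical output.
    """
    geometry = geometry or LVGeometry.default()
    motion = motion or MotionModel()
    spamm = spamm or SpammParams()
    frame = geometry.frame
    nx, ny = frame.shape
    P = motion.phase_count
    root_seed = np.random.SeedSequence(seed)
    # fixed substream layout so adding consumers never reshuffles existing ones
    noise_seeds = np.random.default_rng(root_seed.spawn(1)[0]).integers(0, 2**31 - 1, size=(P, 3))
    bias_seed = int(np.random.default_rng(root_seed.spawn(2)[1]).integers(0, 2**31 - 1))

    bias = make_bias_field((nx, ny), bias_strength, seed=bias_seed) if bias_strength > 0 else np.ones((nx, ny))

    coords = frame.pixel_centers()
    tagged = {d: np.empty((P, nx, ny)) for d in spamm.directions}
    lagrangian = np.empty((P, nx, ny, 2))
    eulerian = np.empty((P, nx, ny, 2))
    masks = np.empty((P, nx, ny), dtype=bool)
    for k in range(P):
        mat = inverse_map(coords, k, geometry, motion)
        u_e = coords - mat
        rel = mat - np.asarray(geometry.center)
        r_mat = np.hypot(rel[..., 0], rel[..., 1])
        clean = scene_intensity(mat, geometry, MRI_INTENSITY)
        lagrangian[k] = analytic_displacement(coords, k, geometry, motion)
        eulerian[k] = u_e
        masks[k] = (r_mat >= geometry.endo_radius) & (r_mat <= geometry.epi_radius)
        for di, d in enumerate(spamm.directions):
            single = SpammParams(
                tag_spacing=spamm.tag_spacing,
                tag_depth=spamm.tag_depth,
                directions=(d,),
                fading_rate=spamm.fading_rate,
            )
            img = spamm_modulate(clean, single, k, displacement=u_e, frame=frame) * bias
            if noise_sd > 0:
                rng = np.random.default_rng(int(noise_seeds[k, di]))
                img = img + rng.normal(0.0, noise_sd, size=img.shape)
            tagged[d][k] = img

    ed = scene_intensity(coords, geometry, MRI_INTENSITY) * bias
    if noise_sd > 0:
        rng = np.random.default_rng(int(noise_seeds[0, 2]))
        ed = ed + rng.normal(0.0, noise_sd, size=ed.shape)

    # Synthetic CT: same end-diastole anatomy in its own frame, offset from
    # the MRI frame by a known rigid transform p_ct = T(p_mri).
    ct_frame = ImageFrame(shape=frame.shape, pixel_spacing=frame.pixel_spacing)
    transform = RigidTransform(
        rotation=np.deg2rad(ct_rotation_deg),
        translation=np.asarray(ct_offset_mm, dtype=float),
        center=frame.center_mm,
    )
    ct_coords_in_mri = transform.inverse().apply(ct_frame.pixel_centers())
    ct_img = scene_intensity(ct_coords_in_mri, geometry, CT_INTENSITY)
    if noise_sd > 0:
        rng = np.random.default_rng(int(noise_seeds[1, 2]))
        ct_img = ct_img + rng.normal(0.0, noise_sd / 2.0, size=ct_img.shape)

    dose = make_dose_grid(
        geometry,
        beam_edge_position=beam_edge_mm,
        max_dose=max_dose_gy,
        penumbra_width=penumbra_mm,
        frame=ct_frame,
    )

    params = {
        "tag_spacing_mm": spamm.tag_spacing,
        "tag_depth": spamm.tag_depth,
        "fading_rate": spamm.fading_rate,
        "phase_count": P,
        "pixel_spacing_mm": geometry.pixel_spacing,
        "slice_thickness_mm": slice_thickness,
        "directions": list(spamm.directions),
        "noise_sd": noise_sd,
        "bias_strength": bias_strength,
        "contraction_amplitude": motion.contraction_amplitude,
        "twist_amplitude_rad": motion.twist_amplitude,
        "wedge_center_rad": motion.wedge_center,
        "wedge_width_rad": motion.wedge_width,
        "wedge_suppression": motion.wedge_suppression,
        "ct_offset_mm": list(np.asarray(ct_offset_mm, dtype=float)),
        "ct_rotation_deg": ct_rotation_deg,
        "max_dose_gy": max_dose_gy,
        "penumbra_mm": penumbra_mm,
        "beam_edge_mm": beam_edge_mm if beam_edge_mm is not None else float(ct_frame.center_mm[0]),
        "lv_center_mm": list(np.asarray(geometry.center, dtype=float)),
        "endo_radius_mm": geometry.endo_radius,
        "epi_radius_mm": geometry.epi_radius,
    }
    study = TaggedStudy(
        tagged=tagged,
        nontagged_ed=ed,
        frame=frame,
        tag_spacing=spamm.tag_spacing,
        phase_count=P,
        slice_thickness=slice_thickness,
        ct_image=ct_img,
        ct_frame=ct_frame,
        dose=dose,
        params=params,
        seed=seed,
    )
    truth = PhantomTruth(
        displacement_fields=lagrangian,
        eulerian_fields=eulerian,
        myocardium_masks=masks,
        dose_truth=dose,
        ct_to_mri_transform=transform,
        bias_field=bias,
        geometry=geometry,
        motion=motion,
        spamm=spamm,
    )
    logger.debug("phantom study generated: %d phases, seed %d", P, seed)
    return study, truth
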