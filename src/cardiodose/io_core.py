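"""Shared spatial-frame bookkeeping, NIfTI I/O, manifests, and the pipeline driver.

Conventions used throughout the package:

* Images are 2D numpy arrays indexed ``[i, j]``; axis 0 maps to physical x,
  axis 1 to physical y.  Multi-phase series are stacked phase-first in
  memory (``(P, nx, ny)``) and phase-last on disk (NIfTI axis order
  ``(nx, ny, P)``).
* Physical coordinates are millimetres: ``x = origin + index * pixel_spacing``
  with pixel centers at integer indices and the frame origin at the corner
  of the first pixel (index 0).
* Every image carries exactly one :class:`ImageFrame`; frames are compared
  with a 1e-6 mm tolerance and a mismatch is an error, never a silent
  resampling.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import nibabel as nib
import numpy as np

logger = logging.getLogger("cardiodose")

FRAME_TOL_MM = 1e-6


def configure_logging(verbose: bool = False, logfile: str | Path | None = None) -> None:
    """Attach a stderr handler (and optional logfile) to the package logger."""
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
    fmt = logging.Formatter("%(levelname)s %(name)s: %(message)s")
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(fmt)
        logger.addHandler(sh)
    if logfile is not None:
        fh = logging.FileHandler(str(logfile))
        fh.setFormatter(fmt)
        logger.addHandler(fh)


class FrameMismatchError(ValueError):
    """Two images that must share a spatial frame do not."""


class ManifestError(ValueError):
    """A study manifest references missing files or is malformed."""


@dataclass(frozen=True)
class ImageFrame:
    """Spatial frame of a 2D image: shape (pixels), spacing and origin (mm)."""

    shape: tuple[int, int]
    pixel_spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)
    units: str = "mm"

    def __post_init__(self) -> None:
        if len(self.shape) != 2:
            raise ValueError(f"ImageFrame is 2D; got shape {self.shape}")
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError(f"pixel spacing must be positive, got {self.pixel_spacing}")

    @property
    def extent_mm(self) -> tuple[float, float]:
        return (self.shape[0] * self.pixel_spacing[0], self.shape[1] * self.pixel_spacing[1])

    @property
    def center_mm(self) -> np.ndarray:
        """Physical coordinate of the image center (between pixel centers)."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) / 2.0 * np.asarray(
            self.pixel_spacing
        )

    def pixel_centers(self) -> np.ndarray:
        """Physical coordinates of all pixel centers, shape ``(nx, ny, 2)`` mm."""
        xs = self.origin[0] + np.arange(self.shape[0]) * self.pixel_spacing[0]
        ys = self.origin[1] + np.arange(self.shape[1]) * self.pixel_spacing[1]
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.stack([gx, gy], axis=-1)

    def index_of(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous (fractional) array indices of physical points (..., 2)."""
        pts = np.asarray(points_mm, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.pixel_spacing)

    def approx_equal(self, other: "ImageFrame", tol: float = FRAME_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and all(abs(a - b) <= tol for a, b in zip(self.pixel_spacing, other.pixel_spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )

    def require_equal(self, other: "ImageFrame", what: str = "images") -> None:
        if not self.approx_equal(other):
            raise FrameMismatchError(
                f"{what} are defined on different frames: {self} vs {other}; "
                "resample explicitly instead of relying on implicit alignment"
            )


@dataclass
class RigidTransform:
    """2D rigid map ``T(p) = R(rotation) @ (p - center) + center + translation``.

    ``rotation`` is counter-clockwise in radians; ``translation`` and
    ``center`` are in mm.  In the registration stage the transform maps MRI
    physical coordinates to CT physical coordinates.
    """

    rotation: float
    translation: np.ndarray
    center: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.rotation = float(self.rotation)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        self.center = (
            np.zeros(2) if self.center is None else np.asarray(self.center, dtype=float).reshape(2)
        )

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix of the transform."""
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        rot = np.array([[c, -s], [s, c]])
        m = np.eye(3)
        m[:2, :2] = rot
        m[:2, 2] = self.center + self.translation - rot @ self.center
        return m

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.asarray(points_mm, dtype=float)
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        rot = np.array([[c, -s], [s, c]])
        rel = pts - self.center
        out = rel @ rot.T + self.center + self.translation
        return out

    def inverse(self) -> "RigidTransform":
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        rot_inv = np.array([[c, s], [-s, c]])
        return RigidTransform(
            rotation=-self.rotation,
            translation=-(rot_inv @ self.translation),
            center=self.center.copy(),
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first), about ``self.center``."""
        m = self.matrix @ other.matrix
        rotation = float(np.arctan2(m[1, 0], m[0, 0]))
        c = self.center
        cr, sr = np.cos(rotation), np.sin(rotation)
        rot = np.array([[cr, -sr], [sr, cr]])
        translation = m[:2, 2] - c + rot @ c
        return RigidTransform(rotation=rotation, translation=translation, center=c.copy())

    def to_dict(self) -> dict[str, Any]:
        return {
            "rotation_rad": self.rotation,
            "translation_mm": self.translation.tolist(),
            "center_mm": self.center.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RigidTransform":
        return cls(
            rotation=d["rotation_rad"],
            translation=np.asarray(d["translation_mm"]),
            center=np.asarray(d["center_mm"]),
        )


@dataclass
class DoseGrid:
    """Scalar absorbed-dose image (Gy) living on its own spatial frame."""

    values: np.ndarray
    frame: ImageFrame
    units: str = "Gy"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.frame.shape:
            raise ValueError(
                f"dose array shape {self.values.shape} != frame shape {self.frame.shape}"
            )


# ---------------------------------------------------------------------------
# NIfTI + JSON sidecar I/O
# ---------------------------------------------------------------------------


def _affine_for(frame: ImageFrame) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = frame.pixel_spacing[0]
    aff[1, 1] = frame.pixel_spacing[1]
    aff[0, 3] = frame.origin[0]
    aff[1, 3] = frame.origin[1]
    return aff


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def write_json(obj: Any, path: str | Path) -> None:
    """Deterministic JSON writer (sorted keys, no timestamps)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())


def write_image(
    image: np.ndarray,
    frame: ImageFrame,
    path: str | Path,
    sidecar: Mapping[str, Any] | None = None,
) -> None:
    """Write an image (2D, phase-stacked 3D, or vector 4D) as NIfTI-1.

    In-memory phase-first arrays ``(P, nx, ny[, 2])`` are stored phase-last
    ``(nx, ny, P[, 2])``; :func:`read_image` undoes this.  A JSON sidecar is
    written next to the image when ``sidecar`` is given.
    """
    path = Path(path)
    arr = np.asarray(image)
    if arr.ndim == 2:
        data = arr
    elif arr.ndim == 3:  # (P, nx, ny) -> (nx, ny, P)
        data = np.moveaxis(arr, 0, -1)
    elif arr.ndim == 4:  # (P, nx, ny, C) -> (nx, ny, P, C)
        data = np.moveaxis(arr, 0, 2)
    else:
        raise ValueError(f"unsupported image ndim {arr.ndim}")
    if data.shape[:2] != frame.shape:
        raise ValueError(f"image spatial shape {data.shape[:2]} != frame shape {frame.shape}")
    img = nib.Nifti1Image(np.asarray(data), _affine_for(frame))
    img.header.set_zooms((frame.pixel_spacing[0], frame.pixel_spacing[1]) + (1.0,) * (data.ndim - 2))
    nib.save(img, str(path))
    if sidecar is not None:
        meta = dict(sidecar)
        meta.setdefault("units", frame.units)
        write_json(meta, _sidecar_path(path))


def read_image(
    path: str | Path,
    require_sidecar_keys: Sequence[str] | None = None,
) -> tuple[np.ndarray, ImageFrame, dict[str, Any] | None]:
    """Read a NIfTI image back as ``(array, frame, sidecar)``.

    Round-trips :func:`write_image` bit-exactly (values) and within 1e-6 mm
    (frame).  ``require_sidecar_keys`` names keys that must exist in the
    sidecar; a missing sidecar or key raises :class:`ManifestError`.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    aff = img.affine
    frame = ImageFrame(
        shape=(int(data.shape[0]), int(data.shape[1])),
        pixel_spacing=(float(aff[0, 0]), float(aff[1, 1])),
        origin=(float(aff[0, 3]), float(aff[1, 3])),
    )
    if data.ndim == 3:
        data = np.moveaxis(data, -1, 0)
    elif data.ndim == 4:
        data = np.moveaxis(data, 2, 0)
    sidecar = None
    sc_path = _sidecar_path(path)
    if sc_path.exists():
        sidecar = read_json(sc_path)
    if require_sidecar_keys:
        if sidecar is None:
            raise ManifestError(
                f"{path} requires a JSON sidecar with keys {list(require_sidecar_keys)}; "
                f"expected at {sc_path}"
            )
        for key in require_sidecar_keys:
            if key not in sidecar:
                raise ManifestError(f"sidecar {sc_path} is missing required key '{key}'")
    return data, frame, sidecar


@dataclass
class StudyManifest:
    """Paths and roles of all series in a study workspace plus parameter records."""

    files: dict[str, str] = field(default_factory=dict)
    params: dict[str, Any] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)

    def path(self, root: str | Path, role: str) -> Path:
        if role not in self.files:
            raise ManifestError(f"manifest has no entry for role '{role}'")
        return Path(root) / self.files[role]

    def validate(self, root: str | Path) -> None:
        missing = [str(Path(root) / rel) for rel in self.files.values() if not (Path(root) / rel).exists()]
        if missing:
            raise ManifestError("manifest references missing files: " + ", ".join(missing))

    def save(self, root: str | Path) -> None:
        write_json(dataclasses.asdict(self), Path(root) / "manifest.json")

    @classmethod
    def load(cls, root: str | Path) -> "StudyManifest":
        p = Path(root) / "manifest.json"
        if not p.exists():
            raise ManifestError(f"no manifest.json in {root}")
        d = read_json(p)
        m = cls(files=d.get("files", {}), params=d.get("params", {}), seeds=d.get("seeds", {}))
        m.validate(root)
        return m


# ---------------------------------------------------------------------------
# Pipeline configuration and driver
# ---------------------------------------------------------------------------

from pydantic import BaseModel, Field, model_validator  # noqa: E402


class PhantomConfig(BaseModel):
    image_shape: tuple[int, int] = (160, 160)
    pixel_spacing_mm: float = 1.25
    endo_radius_mm: float = 20.0
    epi_radius_mm: float = 32.0
    contraction_amplitude: float = 0.10
    twist_amplitude_rad: float = 0.08
    phase_count: int = Field(24, ge=2)
    tag_spacing_mm: float = 8.0
    tag_depth: float = Field(0.8, ge=0.0, le=1.0)
    fading_rate: float = Field(0.1, ge=0.0, le=1.0)
    noise_sd: float = 5.0
    bias_strength: float = 0.3
    wedge_center_rad: float | None = None
    wedge_width_rad: float = float(np.pi / 2)
    wedge_suppression: float = 0.8
    ct_offset_mm: tuple[float, float] = (4.0, -3.0)
    ct_rotation_deg: float = 3.0
    beam_edge_mm: float | None = None  # default: image center x
    max_dose_gy: float = 50.0
    penumbra_mm: float = 10.0


class PreprocessConfig(BaseModel):
    bias_order: int = Field(2, ge=1, le=4)


class TrackingConfig(BaseModel):
    mode: str = "direct"  # direct | compose
    bandpass_sigma_factor: float = 0.2

    @model_validator(mode="after")
    def _check_mode(self) -> "TrackingConfig":
        if self.mode not in ("direct", "compose"):
            raise ValueError(f"tracking mode must be 'direct' or 'compose', got {self.mode!r}")
        return self


class StrainConfig(BaseModel):
    """Abnormality is flagged on the transmural-ratio map (normal tissue ~ 1).

    ``absolute`` thresholds default to ratio < 0.5 (under half the expected
    contraction, i.e. hypokinesis) or > 2; ``robust``/``percentile`` derive
    the band from the ratio distribution instead.
    """

    finite: bool = True
    smoothing_sigma_px: float = 1.0
    threshold_method: str = "absolute"  # absolute | robust | percentile
    low_threshold: float = 0.5
    high_threshold: float = 2.0
    n_mads: float = 3.0
    percentiles: tuple[float, float] = (5.0, 95.0)

    @model_validator(mode="after")
    def _check_method(self) -> "StrainConfig":
        if self.threshold_method not in ("absolute", "robust", "percentile"):
            raise ValueError("threshold_method must be 'absolute', 'robust' or 'percentile'")
        return self


class DoseConfig(BaseModel):
    phase_weights: list[float] | None = None
    dvh_bin_gy: float = 0.5
    registration_bins: int = 32


class CorrelateConfig(BaseModel):
    """``strain_deficit`` (mean contraction deficit vs the transmural profile)
    is the default response: it is continuous and always defined, where the
    thresholded ``abnormal_fraction`` degenerates on healthy studies and is
    brittle at realistic noise levels."""

    n_sectors: int = Field(12, ge=2)
    degree: int = Field(2, ge=1)
    n_permutations: int = 1000
    response: str = "strain_deficit"  # or abnormal_fraction


class PipelineConfig(BaseModel):
    """Schema-validated configuration of the whole pipeline."""

    seed: int = 0
    phantom: PhantomConfig = PhantomConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    tracking: TrackingConfig = TrackingConfig()
    strain: StrainConfig = StrainConfig()
    dose: DoseConfig = DoseConfig()
    correlate: CorrelateConfig = CorrelateConfig()


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, out_dir: str | Path):
    """Execute phantom → preprocess → segment → track → strain → dose → correlate.

    Each stage reads the workspace written by its predecessors and adds its
    own outputs (no stage mutates existing files), so any stage can be re-run
    from on-disk intermediates via the CLI.  Returns a
    :class:`cardiodose.pipeline.PipelineResult`.
    """
    from . import pipeline as _pipeline

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: list[tuple[str, Callable[[], Any]]] = [
        ("phantom", lambda: _pipeline.stage_phantom(config, out_dir)),
        ("preprocess", lambda: _pipeline.stage_preprocess(config, out_dir)),
        ("segment", lambda: _pipeline.stage_segment(config, out_dir)),
        ("track", lambda: _pipeline.stage_track(config, out_dir)),
        ("strain", lambda: _pipeline.stage_strain(config, out_dir)),
        ("dose", lambda: _pipeline.stage_dose(config, out_dir)),
        ("correlate", lambda: _pipeline.stage_correlate(config, out_dir)),
    ]
    for name, fn in stages:
        logger.info("running stage %s", name)
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with the failing stage named
            raise StageFailure(name, exc) from exc
    return _pipeline.load_result(out_dir)
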