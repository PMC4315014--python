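"""On-disk pipeline stages: each reads the workspace and adds its outputs.

The workspace is a directory with a ``manifest.json`` mapping file roles to
relative paths; every stage loads what it needs through the manifest, writes
new files (never mutating existing ones), and registers them.  This is what
makes each stage resumable from intermediates and drivable from the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlate as corr
from . import dosemap, phantom, preprocess, strain, tagseg, tracking
from .io_core import (
    ImageFrame,
    PipelineConfig,
    RigidTransform,
    StudyManifest,
    logger,
    read_image,
    read_json,
    write_image,
    write_json,
)


def _phantom_inputs(cfg: PipelineConfig):
    p = cfg.phantom
    spacing = p.pixel_spacing_mm
    center = ((p.image_shape[0] - 1) / 2 * spacing, (p.image_shape[1] - 1) / 2 * spacing)
    geometry = phantom.LVGeometry(
        center=center,
        endo_radius=p.endo_radius_mm,
        epi_radius=p.epi_radius_mm,
        image_shape=tuple(p.image_shape),
        pixel_spacing=spacing,
    )
    motion = phantom.MotionModel(
        contraction_amplitude=p.contraction_amplitude,
        twist_amplitude=p.twist_amplitude_rad,
        phase_count=p.phase_count,
        wedge_center=p.wedge_center_rad,
        wedge_width=p.wedge_width_rad,
        wedge_suppression=p.wedge_suppression,
    )
    spamm = phantom.SpammParams(
        tag_spacing=p.tag_spacing_mm, tag_depth=p.tag_depth, fading_rate=p.fading_rate
    )
    return geometry, motion, spamm


def stage_phantom(cfg: PipelineConfig, ws: Path) -> None:
    p = cfg.phantom
    geometry, motion, spamm = _phantom_inputs(cfg)
    study, truth = phantom.make_study(
        geometry=geometry,
        motion=motion,
        spamm=spamm,
        noise_sd=p.noise_sd,
        bias_strength=p.bias_strength,
        ct_offset_mm=p.ct_offset_mm,
        ct_rotation_deg=p.ct_rotation_deg,
        beam_edge_mm=p.beam_edge_mm,
        max_dose_gy=p.max_dose_gy,
        penumbra_mm=p.penumbra_mm,
        seed=cfg.seed,
    )
    m = StudyManifest(params={"phantom": study.params}, seeds={"phantom": cfg.seed})
    sidecar = dict(study.params)
    sidecar["seed"] = cfg.seed
    for d in spamm.directions:
        name = f"tagged_{d}.nii"
        write_image(study.tagged[d], study.frame, ws / name, sidecar={**sidecar, "direction": d})
        m.files[f"tagged_{d}"] = name
    write_image(study.nontagged_ed, study.frame, ws / "nontagged_ed.nii", sidecar=sidecar)
    write_image(study.ct_image, study.ct_frame, ws / "ct.nii", sidecar={"modality": "CT-like"})
    write_image(
        study.dose.values, study.dose.frame, ws / "dose_ct.nii", sidecar={"units": "Gy"}
    )
    write_image(truth.displacement_fields, study.frame, ws / "truth_displacement.nii",
                sidecar={"units": "mm", "convention": "lagrangian, phase-0 grid"})
    write_image(truth.myocardium_masks.astype(np.uint8), study.frame, ws / "truth_masks.nii")
    write_image(truth.bias_field, study.frame, ws / "truth_bias.nii")
    write_json(truth.ct_to_mri_transform.to_dict(), ws / "truth_transform.json")
    m.files.update(
        {
            "nontagged_ed": "nontagged_ed.nii",
            "ct": "ct.nii",
            "dose_ct": "dose_ct.nii",
            "truth_displacement": "truth_displacement.nii",
            "truth_masks": "truth_masks.nii",
            "truth_bias": "truth_bias.nii",
            "truth_transform": "truth_transform.json",
        }
    )
    m.save(ws)


def stage_preprocess(cfg: PipelineConfig, ws: Path) -> None:
    m = StudyManifest.load(ws)
    series_by_dir: dict[str, np.ndarray] = {}
    sidecars: dict[str, dict] = {}
    frame = None
    for d in ("x", "y"):
        series, frame, sidecar = read_image(
            m.path(ws, f"tagged_{d}"), require_sidecar_keys=["tag_spacing_mm", "phase_count"]
        )
        series_by_dir[d] = np.asarray(series, dtype=float)
        sidecars[d] = sidecar
    tag_spacing = sidecars["x"]["tag_spacing_mm"]
    # the bias support needs one near-uniform tissue class: take a rough
    # (pre-correction) tag-free phase-0 image and its myocardial ring
    rough = 0.5 * (
        tagseg.remove_tags(series_by_dir["x"][0], tag_spacing, ("x",), frame.pixel_spacing,
                           anatomy_reference=series_by_dir["y"][0])
        + tagseg.remove_tags(series_by_dir["y"][0], tag_spacing, ("y",), frame.pixel_spacing,
                             anatomy_reference=series_by_dir["x"][0])
    )
    support = preprocess.bias_support(rough, frame)
    factors_rec: dict[str, list[float]] = {}
    for d in ("x", "y"):
        series = series_by_dir[d]
        corrected = np.empty_like(series)
        for k in range(series.shape[0]):
            est = preprocess.estimate_bias_field(
                series[k], mask=support, polynomial_order=cfg.preprocess.bias_order
            )
            corrected[k] = preprocess.correct_bias(series[k], est)
        normalized, factors = preprocess.normalize_phase_decay(corrected, mask=support)
        factors_rec[d] = [float(f) for f in factors]
        name = f"preproc_tagged_{d}.nii"
        write_image(normalized, frame, ws / name, sidecar=sidecars[d])
        m.files[f"preproc_tagged_{d}"] = name
    m.params["preprocess"] = {
        "bias_order": cfg.preprocess.bias_order,
        "decay_factors": factors_rec,
    }
    m.save(ws)


def stage_segment(cfg: PipelineConfig, ws: Path) -> None:
    m = StudyManifest.load(ws)
    series = {}
    for d in ("x", "y"):
        series[d], frame, sidecar = read_image(m.path(ws, f"preproc_tagged_{d}"))
    tag_spacing = sidecar["tag_spacing_mm"]
    tag_free = [
        tagseg.remove_tags(
            series[d][0], tag_spacing=tag_spacing, directions=(d,),
            pixel_spacing=frame.pixel_spacing,
            anatomy_reference=series[other][0],
        )
        for d, other in (("x", "y"), ("y", "x"))
    ]
    fused = 0.5 * (tag_free[0] + tag_free[1])
    seg = tagseg.segment_myocardium(fused, frame)
    write_image(fused, frame, ws / "tagfree_ed.nii")
    write_image(seg.mask.astype(np.uint8), frame, ws / "myocardium_mask.nii")
    write_json(
        {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"role": role, "units": "mm"},
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [np.asarray(poly).tolist()],
                    },
                }
                for role, poly in (("endocardium", seg.endo_contour), ("epicardium", seg.epi_contour))
            ],
            "lv_center_mm": seg.lv_center.tolist(),
        },
        ws / "contours.json",
    )
    m.files.update(
        {"tagfree_ed": "tagfree_ed.nii", "myocardium_mask": "myocardium_mask.nii",
         "contours": "contours.json"}
    )
    m.save(ws)


def stage_track(cfg: PipelineConfig, ws: Path) -> None:
    m = StudyManifest.load(ws)
    tx, frame, sidecar = read_image(m.path(ws, "preproc_tagged_x"))
    ty, _, _ = read_image(m.path(ws, "preproc_tagged_y"))
    myo = read_image(m.path(ws, "myocardium_mask"))[0].astype(bool)
    fields = tracking.track_series(
        np.asarray(tx, dtype=float),
        np.asarray(ty, dtype=float),
        tag_spacing=sidecar["tag_spacing_mm"],
        frame=frame,
        myocardium_mask=myo,
        mode=cfg.tracking.mode,
        bandpass_sigma_factor=cfg.tracking.bandpass_sigma_factor,
    )
    vectors = np.stack([f.vectors for f in fields])
    validity = np.stack([f.validity_mask for f in fields]).astype(np.uint8)
    write_image(vectors, frame, ws / "displacement.nii",
                sidecar={"units": "mm", "convention": "lagrangian, phase-0 grid",
                         "mode": cfg.tracking.mode})
    write_image(validity, frame, ws / "validity.nii")
    m.files.update({"displacement": "displacement.nii", "validity": "validity.nii"})
    m.params["tracking"] = {"mode": cfg.tracking.mode,
                            "bandpass_sigma_factor": cfg.tracking.bandpass_sigma_factor}
    m.save(ws)


def _load_fields(ws: Path, m: StudyManifest) -> tuple[list[tracking.DisplacementField], ImageFrame]:
    vectors, frame, _ = read_image(m.path(ws, "displacement"))
    validity = read_image(m.path(ws, "validity"))[0].astype(bool)
    fields = [
        tracking.DisplacementField(
            vectors=np.asarray(vectors[k], dtype=float),
            phase_index=k,
            validity_mask=validity[k],
            frame=frame,
        )
        for k in range(vectors.shape[0])
    ]
    return fields, frame


def stage_strain(cfg: PipelineConfig, ws: Path) -> None:
    m = StudyManifest.load(ws)
    fields, frame = _load_fields(ws, m)
    myo = read_image(m.path(ws, "myocardium_mask"))[0].astype(bool)
    lv_center = np.asarray(read_json(m.path(ws, "contours"))["lv_center_mm"])
    e_cc = np.zeros((len(fields),) + frame.shape)
    e_rr = np.zeros_like(e_cc)
    ok = np.zeros(e_cc.shape, dtype=bool)
    for k, fld in enumerate(fields):
        # differentiate the regularized field over the whole contiguous
        # myocardium: the per-pixel quality mask is too fragmented for
        # finite differences and the regularized vectors are defined there
        full = tracking.DisplacementField(
            vectors=fld.vectors, phase_index=fld.phase_index,
            validity_mask=myo, frame=frame,
        )
        smap = strain.compute_strain(
            full, lv_center, finite=cfg.strain.finite,
            smoothing_sigma_px=cfg.strain.smoothing_sigma_px,
        )
        e_cc[k], e_rr[k], ok[k] = smap.circumferential, smap.radial, smap.validity_mask
    medians = [
        float(np.median(np.abs(e_cc[k][myo & ok[k]]))) if (myo & ok[k]).any() else 0.0
        for k in range(len(fields))
    ]
    peak_phase = int(np.argmax(medians))
    # average over the systolic plateau (phases within 15% of the peak
    # median) to beat down per-pixel strain noise before flagging
    plateau = [k for k, v in enumerate(medians) if v >= 0.85 * medians[peak_phase]]
    peak_map = e_cc[plateau].mean(axis=0)
    stats_mask = myo & ok[peak_phase]
    # abnormality is judged on the transmural-profile-normalized map, where
    # normal tissue sits near ratio 1 regardless of wall depth
    ratio = strain.transmural_normalize(
        peak_map, stats_mask, frame.pixel_centers(), lv_center
    )
    ratio_mask = stats_mask & np.isfinite(ratio)
    flag_map = np.nan_to_num(ratio, nan=1.0)
    if cfg.strain.threshold_method == "absolute":
        lo, hi = cfg.strain.low_threshold, cfg.strain.high_threshold
    elif cfg.strain.threshold_method == "robust":
        lo, hi = strain.robust_thresholds(flag_map, ratio_mask, cfg.strain.n_mads)
    else:
        lo, hi = strain.percentile_thresholds(flag_map, ratio_mask, cfg.strain.percentiles)
    abnormal = strain.flag_abnormal(flag_map, ratio_mask, lo, hi, component="ecc_transmural_ratio")
    deficit = np.where(ratio_mask, np.clip(1.0 - flag_map, 0.0, None), 0.0)
    write_image(e_cc, frame, ws / "strain_ecc.nii")
    write_image(e_rr, frame, ws / "strain_err.nii")
    write_image(ok.astype(np.uint8), frame, ws / "strain_valid.nii")
    write_image(abnormal.mask.astype(np.uint8), frame, ws / "abnormal_mask.nii")
    write_image(deficit, frame, ws / "strain_deficit.nii")
    write_image(peak_map, frame, ws / "strain_ecc_peak.nii")
    write_json(
        {"peak_phase": peak_phase, "plateau_phases": plateau,
         "median_abs_ecc_per_phase": medians,
         "low_threshold": lo, "high_threshold": hi, "component": "circumferential",
         "finite": cfg.strain.finite},
        ws / "strain.json",
    )
    m.files.update(
        {"strain_ecc": "strain_ecc.nii", "strain_err": "strain_err.nii",
         "strain_valid": "strain_valid.nii", "abnormal_mask": "abnormal_mask.nii",
         "strain_deficit": "strain_deficit.nii", "strain_ecc_peak": "strain_ecc_peak.nii",
         "strain_meta": "strain.json"}
    )
    m.save(ws)


def stage_dose(cfg: PipelineConfig, ws: Path) -> None:
    m = StudyManifest.load(ws)
    ed, frame, _ = read_image(m.path(ws, "nontagged_ed"))
    ct, ct_frame, _ = read_image(m.path(ws, "ct"))
    dose_vals, dose_frame, _ = read_image(m.path(ws, "dose_ct"))
    transform, mi_value = dosemap.register_mi(
        np.asarray(ed, dtype=float), frame, np.asarray(ct, dtype=float), ct_frame,
        bins=cfg.dose.registration_bins,
    )
    dose_mri = dosemap.map_dose(dosemap.DoseGrid(dose_vals, dose_frame), transform, frame)
    fields, _ = _load_fields(ws, m)
    myo = read_image(m.path(ws, "myocardium_mask"))[0].astype(bool)
    weights = cfg.dose.phase_weights
    acc = dosemap.accumulate_dose(dose_mri, fields, myo, frame, phase_weights=weights)
    curve = dosemap.dvh(acc.dose, acc.valid_mask, bin_width=cfg.dose.dvh_bin_gy)
    static_curve = dosemap.dvh(dose_mri, acc.valid_mask, bin_width=cfg.dose.dvh_bin_gy)
    write_json({**transform.to_dict(), "mutual_information": mi_value}, ws / "registration.json")
    write_image(dose_mri, frame, ws / "dose_mri.nii", sidecar={"units": "Gy"})
    write_image(acc.dose, frame, ws / "accumulated_dose.nii", sidecar={"units": "Gy"})
    write_image(acc.valid_mask.astype(np.uint8), frame, ws / "dose_valid.nii")
    curve.to_csv(ws / "dvh_accumulated.csv", index=False)
    static_curve.to_csv(ws / "dvh_static.csv", index=False)
    m.files.update(
        {"registration": "registration.json", "dose_mri": "dose_mri.nii",
         "accumulated_dose": "accumulated_dose.nii", "dose_valid": "dose_valid.nii",
         "dvh_accumulated": "dvh_accumulated.csv", "dvh_static": "dvh_static.csv"}
    )
    m.save(ws)


def stage_correlate(cfg: PipelineConfig, ws: Path) -> None:
    m = StudyManifest.load(ws)
    acc, frame, _ = read_image(m.path(ws, "accumulated_dose"))
    myo = read_image(m.path(ws, "myocardium_mask"))[0].astype(bool)
    dose_valid = read_image(m.path(ws, "dose_valid"))[0].astype(bool)
    abnormal = read_image(m.path(ws, "abnormal_mask"))[0].astype(bool)
    meta = read_json(m.path(ws, "strain_meta"))
    strain_valid = read_image(m.path(ws, "strain_valid"))[0].astype(bool)
    peak = meta["peak_phase"]
    lv_center = np.asarray(read_json(m.path(ws, "contours"))["lv_center_mm"])
    deficit = read_image(m.path(ws, "strain_deficit"))[0]
    peak_map = read_image(m.path(ws, "strain_ecc_peak"))[0]
    table = corr.regionalize(
        strain_map=np.asarray(peak_map, dtype=float),
        dose_map=np.asarray(acc, dtype=float),
        myocardium_mask=myo,
        n_sectors=cfg.correlate.n_sectors,
        lv_center=lv_center,
        frame=frame,
        abnormal_mask=abnormal,
        valid_mask=dose_valid & strain_valid[peak],
        deficit_map=np.asarray(deficit, dtype=float),
    )
    response = cfg.correlate.response
    t = table.dropna(subset=["mean_dose_Gy", response])
    # a healthy study can legitimately flag nothing; fall back to the graded
    # deficit response so the correlation stage stays defined
    if np.ptp(t[response].to_numpy()) == 0 and response == "abnormal_fraction":
        response = "strain_deficit"
        t = table.dropna(subset=["mean_dose_Gy", response])
    pearson = corr.dose_strain_correlation(t, method="linear", response=response)
    spearman = corr.dose_strain_correlation(t, method="rank", response=response)
    perm_seed = cfg.seed + 1
    observed, p_value, _ = corr.permutation_test(
        t["mean_dose_Gy"].to_numpy(), t[response].to_numpy(),
        n_permutations=cfg.correlate.n_permutations, seed=perm_seed,
        statistic="pearson", alternative="greater",
    )
    fit = corr.fit_dose_response(t, degree=cfg.correlate.degree, response=response)
    linear = corr.fit_dose_response(t, degree=1, response=response)
    table.to_csv(ws / "regional_table.csv", index=False)
    write_json(
        {
            "response": response,
            "n_sectors": cfg.correlate.n_sectors,
            "pearson": pearson,
            "spearman": spearman,
            "permutation": {"statistic": "pearson", "observed": observed,
                            "p_value": p_value, "alternative": "greater",
                            "n_permutations": cfg.correlate.n_permutations,
                            "seed": perm_seed},
            "fit": {"degree": fit.degree, "coefficients": fit.coefficients.tolist(),
                    "residual_rmse": fit.residual_rmse},
            "linear_fit": {"slope_per_Gy": float(linear.coefficients[1]),
                           "intercept": float(linear.coefficients[0]),
                           "residual_rmse": linear.residual_rmse},
        },
        ws / "dose_response.json",
    )
    m.files.update({"regional_table": "regional_table.csv", "dose_response": "dose_response.json"})
    m.save(ws)


@dataclass
class PipelineResult:
    """Final outputs of a full pipeline run, loaded from a workspace."""

    workspace: Path
    regional_table: pd.DataFrame
    dose_response: dict
    transform: RigidTransform
    peak_phase: int


def load_result(ws: Path) -> PipelineResult:
    m = StudyManifest.load(ws)
    reg = read_json(m.path(ws, "registration"))
    return PipelineResult(
        workspace=Path(ws),
        regional_table=pd.read_csv(m.path(ws, "regional_table")),
        dose_response=read_json(m.path(ws, "dose_response")),
        transform=RigidTransform.from_dict(reg),
        peak_phase=read_json(m.path(ws, "strain_meta"))["peak_phase"],
    )
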