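# cardiodose

Cardiac-motion-adjusted radiation dosimetry from tagged MRI, exercised
end-to-end on a synthetic deforming-heart phantom with analytically known
ground truth.

## The problem

Radiotherapy planning for left-sided breast cancer evaluates heart toxicity
from a dose-volume histogram (DVH) computed on a *static* planning CT.  The
heart, however, beats against the fixed beam: myocardial tissue sweeps
through the steep dose gradient at the field edge, so the static DVH
misrepresents the dose each piece of muscle actually receives — and CT can
neither see that motion nor separate myocardium from blood (whose dose is
irrelevant to cardiac risk).  SPAMM-tagged MRI can: a magnetization grating
imprinted at end-diastole deforms with the tissue across an ECG-gated cine
(24 phases, 8 mm tag spacing, horizontal and vertical tag series, 5 mm
short-axis slice), making dense myocardial motion, strain, and hence a
motion-adjusted accumulated dose computable.

`cardiodose` implements that analysis chain as a tested pipeline:

1. **phantom** — a synthetic short-axis left ventricle (area-preserving
   radial contraction `r' = √(r² − c)` plus rigid twist, raised-cosine
   activation) rendered as SPAMM-tagged series with tag fading, coil
   shading, noise, a co-registered CT-like volume offset by a known rigid
   transform, and a tangential-beam dose grid — all with dense ground truth.
2. **preprocess** — log-domain polynomial coil-shading correction and
   per-phase intensity-decay normalization.
3. **tagseg** — Gaussian notch (band-stop) tag removal at ±m/s and
   myocardial annulus segmentation with endo-/epicardial contours.
4. **tracking** — harmonic-phase (HARP) motion recovery: the wrapped phase
   of the +1 tag spectral peak is a material property; per-pixel wrapped
   differences give displacement via Δφ_d = −(2π/s)(u·ê_d), Lagrangian on
   the end-diastole grid.
5. **strain** — Green–Lagrange tensor E = ½(∇u + ∇uᵀ + ∇uᵀ∇u) (exactly zero
   for the rigid twist), projected to radial/circumferential components
   E_rr, E_cc about the LV center; abnormality flagged on the
   transmural-profile-normalized E_cc ratio.
6. **dosemap** — mutual-information rigid registration of the CT frame to
   the end-diastole MRI, dose resampling, and the motion-adjusted
   accumulated dose `D(X) = Σ_k w_k · D_static(X + u_k(X))` over the
   myocardium only, plus DVH curves.
7. **correlate** — equal-angle regional tables, dose–strain correlation
   with a seeded permutation test, and a polynomial dose-response fit.

## Worked example

Place a hypokinetic wedge (a simulated regional injury) on the high-dose
side of the phantom and run the whole pipeline:

```yaml
# lesion.yaml
seed: 3
phantom:
  wedge_center_rad: 3.14159265
```

```bash
cardiodose run --config lesion.yaml --out ws
```

prints

```
peak strain phase: 8
dose-response: pearson 0.797, spearman 0.923, permutation p 0.0010
linear slope: 0.00453 per Gy; outputs in ws
```

Peak contraction is found at phase 8 of 24 (end-systole).  Because the
contraction-suppressed wedge sits where the accumulated dose is highest, the
regional strain deficit rises with regional dose: Pearson r = 0.80 across
the 12 angular sectors, significant at p = 0.001 under a 1000-draw
permutation of sector labels, with a fitted response slope of 0.0045 per Gy.
The workspace `ws/` holds every intermediate as NIfTI + JSON (tagged series,
displacement fields, strain maps, the recovered CT→MRI transform, the
accumulated-dose map, `dvh_accumulated.csv`, `regional_table.csv`,
`dose_response.json`), and each stage can be re-run from those intermediates
via the `cardiodose` subcommands (`phantom`, `preprocess`, `segment`,
`track`, `strain`, `dose`, `correlate`).

The same pipeline is available as a library:

```python
from cardiodose import PipelineConfig, run_pipeline
result = run_pipeline(PipelineConfig(seed=3, phantom={"wedge_center_rad": 3.14159265}), "ws")
print(result.dose_response["linear_fit"])
```

## Scope

Single short-axis slice (2D+t); rigid CT↔MRI registration; the dose grid is
warped along material trajectories, not recalculated per phase.  See
`docs/methods.md` for the model details, parameter choices, and limitations.
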