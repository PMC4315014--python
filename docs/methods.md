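# Methods

## The phantom and its motion law

The synthetic study is a single short-axis slice of a left ventricle:
blood pool inside the endocardium (radius `r_endo`, default 20 mm),
myocardium out to the epicardium (`r_epi`, 32 mm), on a 160×160 grid at
1.25 mm/px.  The scene also carries a chest-wall slab and an RV-like blood
blob; these are not tracked, but without rotationally asymmetric anatomy a
rigid registration of an annulus is degenerate in rotation.  Class
boundaries use a logistic profile of width 2 mm as a partial-volume
stand-in, which also keeps the anatomy spectrum band-limited the way real
MR reconstructions are.

Motion is radial contraction plus rigid twist about the LV center, scaled
by a raised-cosine activation g(t) that is 0 at phase 0 (end-diastole, the
reference), 1 at the peak-systole phase (phase_count//3, i.e. 8 of 24) and
0 again at the last phase:

* contraction: `r ↦ √(r² − c)` for `r ≥ r_endo` with
  `c = r_endo²(1 − (1 − a·g)²)`, and linear scaling of the blood pool below
  `r_endo`.  The annulus map is *exactly* area-preserving (2D
  incompressibility), continuous, and closed-form invertible; `a` is the
  peak fractional contraction of the endocardial radius (default 0.10,
  ~2 mm endocardial excursion — at the modest end of normal so that all
  per-phase motions stay inside the ±s/2 harmonic-phase aperture).
* twist: rigid rotation by `τ·g` (default τ = 0.08 rad ≈ 4.6°).  Rigid so
  that the finite-strain tensor must report it as exactly strain-free.
* closed-form polar strain follows: E_cc = −c/(2r²),
  E_rr = ½(r²/(r²−c) − 1), used as the strain oracle.

An optional angular wedge (cos²-tapered, default width 90°, suppression
0.8) locally reduces `a` — a hypokinetic region emulating regional injury.
The contraction wedge leaves the twist rigid, and the map stays closed-form
invertible.

Tagging is 1-1 SPAMM as a multiplicative grating
`1 − d_eff·sin²(π x₀/s)` per direction, evaluated at *material*
coordinates x₀ (tags move with tissue), with `s` = 8 mm and
`d_eff = d·(1−fading)^k` implementing tag fading (defaults d = 0.8,
fading = 0.1/phase — plausible for T1 relaxation over a cycle, and
configurable since the emulated protocol does not state them).  Horizontal
and vertical tags are separate series, as acquired in practice.  Coil
shading is exp(random order-2 polynomial), unit mean, peak deviation
`bias_strength` (0.3) — the exponential-of-polynomial form is strictly
positive by construction and exactly representable by the log-domain
estimator below.  Noise is additive Gaussian (σ = 5 on a myocardial signal
of 100; Rician realism is out of scope).

The CT-like volume shares the anatomy (rendered at end-diastole through a
known rigid transform, default 4 mm/−3 mm/3°) with intensity classes that
are deliberately a non-monotone remapping of the MR classes, so only a
multimodality metric can register the pair.  The dose grid lives in the CT
frame: `D(x) = D_max·σ((x_edge − x)/k)`, a tangential-beam-like logistic
fall-off whose 80%–20% distance is the penumbra width (10 mm), edge through
the LV center, D_max = 50 Gy.

What the phantom does *not* emulate: MR physics (relaxation, k-space),
respiration, through-plane motion, inter-fraction anatomy change, Rician
noise, realistic CT texture.  Tests passing here show the pipeline's
numerics are correct under its stated model, not that it is validated on
clinical data.

## Preprocessing

Coil shading is estimated by least-squares fitting a 2D polynomial
(default order 2) to log-intensity over a support region, exponentiating,
and normalizing to unit mean over that support; the corrected image is
image/field.  The support must be a single near-uniform tissue class —
over mixed classes the polynomial absorbs the anatomy itself — so the
pipeline derives it from a rough ring segmentation of the uncorrected
tag-free end-diastole image, eroded 2 px to drop partial-volume pixels
(~3% of the frame; the estimator enforces a 2% floor).  Because the
unit-mean convention depends on the support, correction is defined up to a
global scale; downstream stages are insensitive to it.

Inter-phase decay (tag fading raises late-phase medians after correction)
is compensated by one global factor per phase matching each phase's median
over the support to phase 0 — median, not mean, for robustness to tag
troughs.  Order: shading first (per phase, shared support), then decay.

## Tag removal and segmentation

Tags concentrate at ±m/s along the tagged axis; Gaussian notches
(σ_f = 0.15/s, fundamental and harmonics to Nyquist, applied as a function
of the tagged axis' frequency only so grid cross-terms are caught) remove
them.  The grating attenuates the image mean by (1 − d/2); d is estimated
from the spectral peak-to-DC ratio and divided out.  When the orthogonal
series is available its spectrum serves two further purposes: measured as
a difference spectrum it cleans the depth estimate, and shifted to ±1/s
and scaled by (d/4)/(1−d/2) it predicts the fringe spectrum, which is
subtracted before notching — cancelling the anatomy-modulated fringe tails
that extend beyond any notch (myocardial residual ~8% instead of ~13%).

Segmentation of the tag-free image is classical: 3-class multi-Otsu keeps
the brightest class, morphological cleanup, the largest component must be
a contained annulus (border contact, missing cavity, or implausible area
raise `SegmentationError` rather than returning a spurious result), and
both boundaries are refined to the class-midpoint crossings — a single
Otsu cut sits between the myocardium and the brightest *other* class and
would bias both boundaries into the ring.  Contours are closed CCW
polygons resampled to 128 vertices, in mm.

## Tracking

Harmonic-phase demodulation: Gaussian bandpass (σ_f = 0.2/s, a kernel of
spatial scale 1/(2π σ_f) ≈ 6.4 mm — the resolution/noise trade) isolates
the +1 peak; the complex angle is the wrapped harmonic phase, a material
property of the tissue.  Per-pixel wrapped differences give the Eulerian
displacement component per direction; a short fixed-point iteration
re-anchors the field to the phase-0 grid (Lagrangian), matching the strain
stage.  Per-pixel wrapping limits each comparison to |u_d| < s/2 = 4 mm;
`compose` mode chains adjacent phases (ascending, bilinear resampling) for
larger motions, while the default `direct` mode suffices for the phantom's
amplitudes.

Two measures handle interference from the anatomy's own in-band spectral
energy, which otherwise biases the phase badly once tags fade:

* **Orthogonal-series anatomy cancellation.**  The y-tagged series images
  the same anatomy without the x-grating, so subtracting its spectrum
  before windowing the x-peak removes the anatomy's in-band energy while
  leaving the tag peak intact — the anatomy-suppression idea of
  subtractive (CSPAMM-style) tagging, realized with the data the protocol
  already acquires.  Noise grows by √2; the deterministic bias (up to
  ~0.6 mm at late phases) disappears.
* **Magnitude-anomaly quality mask + regularization.**  For additive
  interference the relative magnitude perturbation and the phase error
  share a scale, so pixels whose harmonic magnitude deviates more than 30%
  from the in-myocardium median are flagged unreliable; the field is then
  reconstructed everywhere by quality-weighted Gaussian smoothing (σ = 2 px)
  — reliable pixels denoised, unreliable ones filled from neighbours.  The
  validity mask reports the directly-measured pixels.

## Strain

Displacements are smoothed (mask-aware Gaussian, σ = 1 px) and
differentiated by central differences (one-sided at mask borders; pixels
with no valid neighbour dropped).  The Green–Lagrange tensor
`E = ½(G + Gᵀ + GᵀG)` is the default — a twisting phantom makes the
linearized tensor (kept behind `finite=False`) report spurious strain.
Polar projection uses ê_r from the segmented LV center.

Abnormality is judged on the transmural ratio: E_cc divided by its
per-radius angular median (8 radial bins; median robust to a minority
lesion).  E_cc falls as 1/r² across the wall, so pooled-distribution
thresholds confound wall depth with dysfunction; the ratio is ~1 in normal
tissue regardless of depth.  Default flags: ratio < 0.5 (contraction below
half the expected profile — hypokinesis) or > 2.  The per-pixel maps used
for flagging average the systolic plateau (phases within 15% of the peak
median |E_cc|) to suppress noise.  A continuous per-pixel deficit
max(0, 1 − ratio) accompanies the binary mask.

## Registration and dose

Rigid registration maximizes 32×32-bin histogram mutual information
between the (lightly smoothed) end-diastole MRI and the resampled CT;
Powell searches (rotation, t_x, t_y) from 27 perturbed starts with a final
polish.  Dose is resampled bilinearly (masks nearest-neighbour — dose
gradients are sensitive to the choice, so it is fixed and stated);
out-of-grid samples are zero with a logged count.

Accumulation warps the *fixed* dose grid along material trajectories —
`D(X) = Σ_k w_k · D(X + u_k(X))` on the phase-0 myocardium (blood
excluded), uniform weights 1/phase_count by default (equal ECG-gated dwell
time; configurable).  Regenerating CT and recalculating dose per phase is
deliberately out of scope; the warp is an approximation that ignores
density change.  The accumulated value is a time-weighted mean (not a
sum): the distinction is a global scale.  Pixels whose trajectory leaves
the grid are flagged and excluded from statistics.  DVH:
V(d) = fraction of mask pixels with dose ≥ d at bin edges.

## Regional correlation

The myocardium is split into equal-angle sectors about the LV center.
Twelve sectors are the default: with six, a 90° lesion occupies two
sectors and a permutation test over sector labels has almost no
resolution (p ≈ 0.05–0.14 at the phantom's effect size); twelve keep
>100 px per sector and localize the same lesion at p ≈ 0.003–0.02.  The
default response is the mean strain deficit per sector — continuous and
always defined, where the thresholded abnormal fraction is identically
zero on healthy studies (undefined correlation) and brittle near
threshold; the abnormal fraction is still tabulated and selectable, with
an automatic fallback to the deficit when it is degenerate.  Association
uses Pearson/Spearman correlation plus a seeded 1000-draw permutation test
(sectors are spatially correlated, so parametric p-values would be
anti-conservative), and a least-squares polynomial (default degree 2; the
degree-1 slope is always reported) maps dose to response.

## Numerical conventions

Pixel centers at integer indices, physical mm = origin + index·spacing,
origin at the image corner; frames compared at 1e-6 mm and mismatches are
errors, never silent resampling.  All randomness flows from explicit
seeds; pipeline outputs are byte-reproducible.  NIfTI-1 + JSON sidecars
throughout (DICOM is out of scope).

## Problem sizes

Unit tests run a 96×96, 8-phase phantom (endo 16 mm/epi 26 mm); the
acceptance suite and `scripts/acceptance.py` run the full emulated
protocol (160×160, 24 phases, both tag directions) and two complete
wedge-lesion pipelines.  The full suite completes in a few minutes on one
CPU.

## Known limitations

Boundary pixels of the thin wall are the hardest: the 6.4 mm demodulation
kernel mixes tissue with blood/background there, which is why the quality
mask exists and why lesion contrast in measured strain is attenuated
(~50% of the true deficit for a wedge whose half-maximum core is ~8–10 mm
across) — localization survives, amplitude calibration does not.  Rigid
2D registration cannot express through-plane or deformable misalignment.
The dose-response fit is exercised on a single synthetic slice with one
lesion; nothing here validates clinical dose-toxicity modeling.
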