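# Methods

`prostacc` re-creates, end to end and on fully synthetic data, a clinical
workflow for estimating the *delivered* dose of a moderately
hypofractionated prostate radiotherapy course with a simultaneous
integrated boost (SIB): per-fraction cone-beam CT (CBCT) anatomy is
density-overridden, rigidly aligned from the recorded couch shift,
deformably registered to the reference planning CT, and the per-fraction
dose is pulled back through the resulting deformation vector field (DVF)
and summed over all 33 fractions.  The cohort layer compares planned and
delivered dose–volume endpoints and stratifies the dominant intraprostatic
lesion (DIL) dose by dorsal (posterior-medial peripheral zone, PZpm) versus
ventral location.

## Coordinate and unit conventions

Voxel indices are 0-based, axes ordered (LR, AP, SI): axis 0 runs
left→right, axis 1 anterior→posterior, axis 2 inferior→superior.  World
coordinates are `origin + index · spacing` (mm) at voxel centers.
Displacement fields are in mm and follow one direction convention
throughout: `u(x)` maps a reference-frame point `x` to its fraction-frame
counterpart `x + u(x)`, so fraction dose is pulled back onto the reference
by trilinear sampling at `x + u(x)` with no field inversion.

## Synthetic pelvic phantom

The default lattice is 96 × 96 × 64 voxels at 2 mm isotropic spacing —
desk-scale while keeping ≥ 10 voxels across the prostate.  Organs are
analytic solids (ellipsoids, spheres, a rectal cylinder with a gas-filled
lumen) painted with nominal HU: soft tissue ≈ 0–60 HU, femoral heads
700 HU, rectal gas −700 HU, air −1000 HU.  A dorsal DIL is placed at the
posterior prostate capsule, directly adjacent to the rectal wall (the
configuration in which PZpm lesions sit clinically); a ventral DIL sits
symmetrically at the anterior capsule.

Per-fraction motion is an analytic, closed-form displacement field — the
point of the design is that the ground truth is known exactly for
registration validation:

* bladder and rectum "filling" as Gaussian-windowed radial scalings around
  the organ centroids, `u(x) = α (x − c) exp(−|x−c|²/2w²)` with `w` twice
  the organ radius and `α ~ N(0, 0.2)` per fraction per organ (≈ 2 mm SD
  of wall displacement, occasionally 4–5 mm — typical inter-fraction
  variation);
* a correlated prostate drift: `N(0, 1.5 mm)` per axis, plus an
  anterior push proportional to rectal inflation (coupling 0.4);
* the field is zeroed outside the body mask.

For the default amplitudes the discrete Jacobian determinant of the
ground-truth map stays positive everywhere (no folding; property-tested).

CBCTs are synthesized by resampling the reference HU volume through the
*inverse* of the ground-truth map (fixed-point inversion, 6 iterations),
translating by a per-fraction setup error drawn with per-axis SDs
(2.9, 2.8, 2.7) mm in (LR, AP, SI), then applying a low-frequency
multiplicative bias field (20 HU amplitude on the HU + 1000 scale) and
additive Gaussian noise (15 HU).  The recorded couch shift equals the
setup error, as with an image-guidance system.  Imaging follows the
institutional schedule: fractions 1–5 daily, then every third fraction
(8, 11, …, 32) — 14 CBCTs per 33-fraction course.

What the phantom does *not* emulate: CBCT scatter/extinction/beam-hardening
artifacts, intra-fraction motion, rotational setup error, and genuinely
deformable target volumes.  Passing tests therefore demonstrate the
correctness and self-consistency of the accumulation machinery under known
ground truth, not clinical accuracy on real CBCT data.

Per-patient anatomical variability: organ sizes are jittered by ≈ 6 %
(lesion radius 10 %, clipped, and kept inside the prostate) with
patient-specific seeds (`master seed + patient index`), so cohort
statistics have realistic between-patient variance.

## Density override

A five-level step table maps HU to mass density (g/cm³), applied
identically to planning CT and CBCTs: < −850 → 0.001 (air); [−850, −200) →
0.26 (lung); [−200, 120) → 1.00 (adipose/soft tissue); [120, 1200) → 1.60
(cartilage/bone); ≥ 1200 → 4.50 (prosthesis).  Intervals are half-open and
closed below, so a boundary HU joins the upper interval.  Because the same
table is applied to both sides, the conversion error enters planned and
delivered dose alike and cancels in the comparison.

## Target volumes and dose engine

`CTV_P−SV` = prostate + caudal third of the seminal vesicles (the "base";
the fraction is configurable since no geometric definition exists);
`CTV_P+SV` adds the whole vesicles.  `PTV_Boost` = 5 mm isotropic
expansion of `CTV_P−SV` minus the rectum; `PTV` = 10 mm expansion of
`CTV_P+SV`, reduced to 7 mm dorsally.  Margins are Euclidean
(distance-transform) expansions; the dorsal value applies to voxels whose
nearest source point lies anterior of them.

The dose engine is an idealized, analytic stand-in for a treatment
planning system.  Per fraction,

    D(x) = A(x) · [ d_low·g(δ_PTV(x)) + (d_boost − d_low)·g(δ_B(x)) ]
                · [ 1 − s·exp(−δ_rectum(x)²/(2σ_s²)) ]

with `d_low = 1.82 Gy`, `d_boost = 2.31 Gy`, `δ_S(x)` the Euclidean
distance to structure `S` (0 inside), `g(δ) = exp(−δ²/2σ²)` a Gaussian
penumbra (σ = 3 mm), and `A(x) = exp(−μ·(r(x) − r_ref(x)))` a first-order
attenuation correction with `r` the density-weighted path length along the
anterior→posterior beam axis (μ = 0.005 /mm).  The last factor models the
steep optimizer-driven dose gradient that spares the rectum; its default
depth `s = 1 − d_low/d_boost ≈ 0.21` pulls the dose at the rectal wall to
the low prescription level (σ_s = σ).  Setting `rectum_sparing=0` recovers
a pure plateau-plus-penumbra shape.  The engine reproduces the
prescription arithmetic exactly — 33 × 1.82 = 60.06 Gy on the PTV plateau
and 33 × 2.31 = 76.23 Gy on the boost plateau — and is deterministic and
linear in the prescription.  The rectum notch is what gives dorsal lesions
their characteristic edge-of-boost dose profile; without it every in-boost
voxel sits on an exactly flat plateau and lesion location cannot matter.

This engine deliberately omits VMAT arc geometry, fluence optimization and
scatter; absolute OAR doses (e.g. femoral heads under a single AP
effective beam) are not clinically representative and are only compared
planned-vs-delivered within the model.

## Registration

Couch-shift alignment is a rigid translation resample
(`out(x) = in(x + shift)`, trilinear, air fill).

Deformable registration is an intensity-based, diffusion-regularized
demons iteration on the density-overridden volumes, multi-resolution
(downsampling ×4/×2/×1 with 50/50/25 sweeps; the fine level dominates cost
and only refines).  The per-voxel step is the classic Newton-style force
`−diff·∇f/(‖∇f‖² + diff²)` capped at one voxel, smoothed with σ_fluid =
2 mm; the accumulated field is smoothed with σ_diffusion = 2 mm; a level
stops early once the mean update over gradient-carrying voxels falls below
0.01 mm.  The field is clamped to zero outside the dilated body support.
Registration is deterministic.

Because density-overridden volumes are piecewise constant, image forces
exist only at density-class interfaces (body outline, bone, rectal gas);
the regularizer propagates boundary displacements into homogeneous
interiors.  Consequences, measured on phantoms with known ground truth:

* displacements are recovered to ≈ 0.1–0.5 mm mean error in a 6 mm band
  around density interfaces (the rectal gas boundary — the interface that
  matters for the lesion analysis — is the best-recovered);
* motion of density-invisible boundaries (bladder/prostate interfaces) is
  only partially recovered via nearby interfaces, so delivered-dose
  deviations are, if anything, *under*-estimated;
* resampling blur at sharp static edges means *global* NCC can decrease
  slightly after warping even when the field is accurate; similarity is
  therefore tracked as the mean squared difference restricted to the
  voxels where the two images initially disagree, which improves ~3–5×.

## Accumulation

Fractions without imaging use the most recent earlier CBCT (previous-CBCT
substitution) together with that CBCT's couch shift — the substitute CBCT
is the best available anatomy-plus-setup proxy.  Fractions sharing a
source CBCT reuse the cached registration and mapped dose; inputs being
identical, this equals recomputation.  Dose warping is plain trilinear
pull-back (no mass/energy conservation, matching TPS-style dose mapping);
the course total is the voxelwise float64 sum of the per-fraction doses,
kept exact so that the no-motion pipeline reproduces the planned dose to
< 1e-6 Gy end to end.

## DVH metrics and statistics

`Dx%` is the minimum dose to the hottest x% of the structure volume:
voxel doses sorted descending, linear interpolation between order
statistics at volume fraction x/100 (the (100−x)-th linear-interpolation
percentile).  Whole voxels carry equal volume.  `D_Mean` is the arithmetic
mean.  Exported cumulative DVH curves use 0.01 Gy bins; metrics always
come from the sorted voxels, not the binned curve.

Planned-vs-delivered endpoints use a paired t-test when the Shapiro–Wilk
p of the paired differences is ≥ 0.05, otherwise a Wilcoxon matched-pairs
signed-rank test (two-sided; zeros dropped, mid-rank ties; exact tie-aware
null by dynamic programming over doubled ranks up to n = 25, tie-corrected
normal approximation above).  The Shapiro–Wilk test is applied to the
*differences*, since that is what the paired t-test assumes normal.
Dorsal-vs-ventral lesion dose uses a pooled-variance unpaired t-test with
df = n₁ + n₂ − 2, a 95 % CI of the mean difference, and Cohen's d with the
pooled SD.  The dorsal/ventral call itself is a geometric stand-in for the
radiological PZpm sector read: dorsal iff the lesion centroid lies in the
posterior third of the prostate's AP extent at the lesion's axial level
and within the medial half of its LR extent (both fractions configurable).
Couch-shift summaries pool all axis components for the |shift| ≤ 2 mm,
≤ 5 mm and > 7 mm fractions.

## Numerical choices and degenerate inputs

* float32 volumes; dose totals and statistics in float64.
* Trilinear interpolation everywhere; out-of-domain fills: air HU for
  anatomy, 0 Gy for dose, 0 mm for fields.
* Zero couch shift / zero field short-circuit to exact copies, which makes
  the identity pipeline bit-exact rather than merely close.
* All-zero paired differences are reported as a degenerate comparison with
  p = 1; zero pooled variance in the unpaired test reports an explicit
  infinite-t convention.
* Empty masks, lattice mismatches, non-finite inputs and a DIL configured
  outside the prostate are rejected with specific errors.

## Problem sizes used in the test suite

The suite exercises full 33-fraction courses at the default 96 × 96 × 64
lattice: a 10-patient cohort for the location analysis, a 6-fraction
4-level motion-sweep for the monotone-degradation property, and single
registrations for the DVF-recovery bounds.  These sizes were chosen so the
entire suite runs comfortably on one CPU while still covering the full
course length and lattice scale of the study design.

## Known limitations

* The dose engine is not a dosimetric model; only relative planned-vs-
  delivered behavior is meaningful.
* Intensity-only demons cannot track density-invisible interfaces; the
  clinical algorithm it stands in for is a hybrid (contour-guided) method.
* The phantom's CBCT degradation model (noise + smooth bias) is far milder
  than real CBCT artifact physics.
* Whole-voxel DVH volumes (no partial-volume weighting) bias small-
  structure metrics by up to one voxel's worth of volume.
* The idealized imaging schedule is the same for every patient; real
  cohorts deviate (the clinical mean was 14.7 CBCTs per patient versus the
  schedule's 14).
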