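# Methods

`mntrace` quantifies manganese-enhanced MRI (MEMRI) tract tracing in
longitudinal small-animal studies. Mn(II) is a calcium analog and T1
contrast agent: injected focally, it enters active neurons, travels along
axons, and accumulates at distal projection targets, so intensity increases
between imaging sessions map anatomical connectivity in the living brain.
Because the in vivo datasets such studies rest on are rarely deposited, the
package pairs the analysis pipeline with a synthetic phantom generator that
reproduces the *structure* of such a study with known ground truth; every
stage is validated by recovery of what was planted.

## The phantom as a study model

Each simulated subject is imaged at four sessions (pre-injection, 30 min,
6 h, 24 h) at 0.1 mm isotropic resolution on an 80×64×48 grid. The brain is
an ellipsoid (semi-axes 3.0 × 2.4 × 1.7 mm, the scale of an adult mouse
brain) with three tissue compartments — a dominant white-matter-like plateau
at intensity 100, deep gray at 108, a thin cortical shell at 118 — plus a
deterministic two-scale sinusoidal texture (periods ≈ 2 mm and ≈ 1 mm,
amplitudes 9 and 6.3). The texture plays three roles: it gives NCC/SSD
registration a sharp optimum with a nonzero intensity gradient almost
everywhere (a single separable product would leave nodal planes where
displacement along the plane is unconstrained), its phase offsets break the
180° rotational near-symmetry of the ellipsoidal compartments (which would
otherwise create a spurious registration optimum half a turn away), and it
contributes realistic within-tissue variance. The whole template is
band-limited with a Gaussian PSF (σ = 1.2 voxels): sharp compartment steps
would alias under resampling and impose a hard ceiling (pairwise NCC ≈ 0.86)
on inter-subject similarity that no registration could cross.

The atlas bundle carries an integer label volume with 14 named segments
(bilateral pairs painted mirror-symmetrically about the midline plane, so
left/right voxel counts are exactly equal, plus midline structures), a
hypothalamus parent subdivided into four sub-segments, one fiber-tract label
flagged for exclusion from quantification, an FSLeyes-style lookup table,
and stereotaxic metadata: bregma and the mid-sagittal plane are world
coordinates, not image features, because MR cannot image the skull landmark
itself. Unassigned parent-hypothalamus tissue keeps a 0.5 mm moat around
every named segment so that smoothing and residual registration error cannot
bleed a planted effect into it.

Nuisance processes per subject: a rigid misalignment (≤ 0.3 mm, ≤ 3°), a
smooth random deformation built from an ~8-voxel displacement lattice
upsampled cubically and clamped to 0.2 mm, a multiplicative bias field
exp(p) with p a random degree-2 polynomial scaled to ±0.2, a global
intensity factor in [0.8, 1.25], and white Gaussian noise with σ = 4% of the
tissue mode (SNR ≈ 25, a plausible figure for 100 µm in vivo imaging; the
source study reports no SNR, so this is a chosen condition, not a calibrated
one). The injection bolus is biphasic: intensities multiply by 0.3 inside a
0.3 mm core (high Mn(II) concentration darkens T1-weighted signal), by up to
1.25 in a Gaussian halo out to 0.8 mm, fading to 50% at 6 h and 1% at 24 h
("virtually disappearing"). Injection placement follows the stereotaxic
plan (ML/AP/DV relative to midline, bregma, and the *brain surface*) with a
per-subject placement scatter of σ = 0.15 mm, matching the dispersion such
studies report. Distal transport is emulated by multiplying scheduled
segments by (1 + f) at scheduled timepoints, f = 5–15%, applied before
bias/scale/noise so that modal rescaling cannot remove it. The two default
cohorts carry disjoint target sets (anterior-injection group: its own
injection segment plus DS, RTN, SNr, PAG, LC, DMH, MBO; posterior-ventral
group: its injection segment plus BLA, AHN, LHA), mirroring the 0.84 mm AP
separation and divergent projection fields of the motivating design.

What the phantom does *not* model: pulse-sequence physics, Rician noise
statistics (negligible at this SNR), motion-during-scan artifacts, real
anatomical variability between animals, partial-volume anatomy beyond the
PSF, or a skull (images are brain-only plus background noise). Passing
recovery tests therefore demonstrates correctness of the analysis chain
under controlled conditions, not performance on arbitrary real data.

## Normalization

* **Masking**: Otsu threshold, largest 6-connected component, morphological
  closing (ball radius 2), hole filling. Intensity models run on a mask
  eroded by 0.25 mm because partial-volume rim voxels are arbitrarily dark
  (they break log positivity and can mimic an injection core).
* **Bias correction**: a degree-3 polynomial is least-squares fitted to log
  intensity, with two trimming passes (drop residuals beyond 2.5 scaled
  MADs) so focal anomalies cannot tilt the field. The field is estimated on
  the **pre-injection image only** and divided out of all four sessions.
  This extends the study design's two-step principle from geometry to
  intensity: a per-session fit lets the bolus imprint a session-differential
  whole-brain gradient of a few tenths of a percent — invisible to the eye
  but amplified by paired t-tests across ten subjects into large false
  clusters. Any smooth anatomy trend that a polynomial can fit is absorbed
  along with the bias; that flattening is common to all subjects and
  sessions and therefore harmless to every longitudinal and between-subject
  comparison the pipeline makes.
* **Modal scaling**: one multiplicative gain aligns the in-mask histogram
  mode (256 bins between the 1st and 99th percentile, ties toward the lower
  bin) to a reference image's mode, the minimal reading of "align the modes
  and adjust all other voxels". The reference is chosen by seeded random
  draw and logged.

## Registration

* **Rigid** (6 parameters, Euler angles about the fixed-image center):
  maximizes masked NCC by 3-level multi-resolution Powell search. The
  search itself is unconstrained — scipy's box-constrained Powell line
  search can return points worse than its start — with a soft quadratic
  wall outside ±10°/±2 mm; a solution at the bounds is an error, and the
  identity is always a fallback candidate so accepted alignment never has
  lower NCC than no alignment.
* **B-spline warp**: cubic control lattice at 0.5 mm spacing, optimized by
  L-BFGS-B on masked SSD (normalized by the fixed image's in-mask variance)
  plus a weak second-difference bending penalty (weight 0.01), two
  resolution levels, displacement cap 1 mm through the box bounds and the
  partition of unity. Three numerical choices matter and were reached by
  measurement on planted deformations: (1) the moving image is sampled
  through a cubic spline whose finite-difference gradient is consistent with
  the sampled cost — a linear interpolant's cell-wise slopes stall L-BFGS;
  (2) residuals are weighted by 1/√(|∇F|² + g₀²) (g₀ the median in-mask
  gradient), since the brain-edge gradient is an order of magnitude above
  interior texture and otherwise monopolizes the descent while the interior
  never converges; (3) the 0.5 mm spacing is finer than the 0.8 mm a first
  design used, because the *inverse* of a smooth deformation with ≈ 0.7 mm
  correlation length carries harmonics a 0.8 mm lattice cannot represent
  (the best 0.8 mm fit of the true inverse already had a 0.09 mm landmark
  floor). With these settings a planted 0.3 mm deformation is recovered to
  ≈ 0.04 mm mean landmark error at zero noise.
* **MDT**: pass 1 rigid-aligns all pre-injection images to a seeded-randomly
  chosen reference and averages; pass 2 re-aligns every image (rigid +
  warp) to that average and averages again. Convergence is reported as the
  mean pairwise NCC of the pass-2 aligned images at the 0.3 mm analysis
  smoothing scale — the resolution at which the aligned images are actually
  consumed (unsmoothed NCC is bounded by the noise floor rather than by
  alignment quality).
* **Two-step propagation**: each subject's rigid + warp chain is estimated
  on its pre-injection image against the final MDT and applied, unchanged
  and in a single concatenated resampling, to all post-injection sessions.
  Registration is never estimated on a Mn(II)-enhanced image. In a
  controlled comparison (same subject simulated without noise, so the routes
  differ only by the bolus) direct registration of the 30 min image costs
  ≈ 0.07–0.08 mm of distal landmark error against ≈ 0.025 mm for the
  two-step chain.

## Statistics

Within-group contrasts are paired t-tests across timepoints of the same
subjects (df = n−1); the between-group contrast is a pooled-variance
two-sample t-test at 24 h (df = n_A+n_B−2). All directional maps are
one-sided. Zero-variance voxels with zero mean get t = 0; zero-variance
voxels with nonzero mean (constant-background artifacts of phantoms) are
excluded from the p-value pool. Multiple comparisons are controlled per
contrast map by Benjamini–Hochberg over in-mask voxels; the realized
critical t (smallest t among rejected voxels) is reported but is
data-dependent by construction and never a target. Maps run on images
smoothed at 0.3 mm FWHM with mask renormalization (smooth(img·mask) /
smooth(mask)) so brain-edge voxels are not dimmed; ROI measurements use the
unsmoothed aligned images.

Realized FDR of the suite is defined per contrast map (mean false discovery
proportion over cohort × contrast), the quantity BH controls; on 200 null
cohorts it measures ≈ 0.03–0.05 at q = 0.05.

A caveat the phantom makes quantitative: smoothed-noise false discoveries
arrive in spatial islands of 10–30 voxels, so a small atlas segment can
stochastically exceed a 5% false-fraction bound even under exact FDR
control. The default atlas keeps every segment above ≈ 280 voxels, which
brings the probability of such an excursion in a full default study to a few
percent per run; it cannot be made zero at q = 0.05 and 0.3 mm smoothing.

## Quantification

* **Atlas alignment**: a 12-parameter affine from the MDT to the atlas gray
  template (NCC, multi-resolution Powell), whose inverse carries the gray
  template (linear), the label volume (nearest-neighbour — labels are never
  interpolated) and the bregma/midline metadata into study space. The atlas
  gray is bias-flattened with the same log-polynomial model before
  registration so both images share a modality (the MDT averages flattened
  images).
* **Fractional accumulation volumes**: per segment, suprathreshold voxels /
  total voxels, counted bilaterally through the lookup table's lateral
  pairing (per-hemisphere rows optional), fiber tracts excluded.
* **Dynamics classification**: greater-at-6h if frac₆ − frac₂₄ > δ,
  greater-at-24h for the reverse, accumulating if the 24h>6h map itself
  occupies > δ of the segment, else similar; segments below δ at both
  timepoints are omitted. δ = 0.05 of segment volume is a declared
  convention (the category definitions in such studies are verbal), is
  configurable, and is logged with the table.
* **Injection sites**: the hypo-intense core is the largest 6-connected
  component below mode − 3·MAD (scaled) within a search region (default the
  dorsal anterior quadrant; the pipeline passes the anterior half of the
  mask, which also covers deeper ventral placements), after trimming a
  0.25 mm rim. Its deficit-weighted centroid converts to stereotaxic ML
  (right of midline), AP (anterior of bregma) and DV (below the brain
  surface, the topmost in-mask voxel of that (x, y) column). Cohort
  summaries report per-axis mean ± sample SD and the largest distance from
  the centroid.
* **ROI time courses**: 3×3×3-voxel cubes at segment centroids; per-
  timepoint means and ratios to 30 min. Group inference uses the subject as
  the unit on log-ratios — a paired t-test for 24 h vs 6 h within groups and
  a Welch test between groups — with BH across ROIs per family. These are
  the balanced-design equivalents of a subject-level mixed model; with one
  cube per subject × ROI × timepoint they are the exact likelihood-based
  tests the mixed model would reduce to.

## Problem sizes and determinism

The validation suite exercises the full default study (two cohorts × 10
subjects × 4 sessions at 80×64×48) once, reduced 32³ cohorts for the
200-replicate null calibration, and 48×40×32 cohorts for the 100-replicate
ROI power study; these sizes were chosen so each experiment carries enough
voxels and subjects for its inference while keeping whole-suite runs
convenient to repeat. A single master seed fans out to stage seeds through
`numpy.random.SeedSequence`, every random draw in the generator derives from
the spec seed plus group/subject indices, and tabular outputs are
byte-stable across reruns of the same config.

## Known limitations

* The phantom's ellipsoidal anatomy and deterministic texture are far more
  registration-friendly than real brains; registration accuracy figures are
  upper bounds on real-data performance.
* The polynomial bias model matches the generator's bias family by
  construction; real coil shading is not polynomial, and the log-polynomial
  fit removes smooth anatomy trends along with it.
* Dynamics categories depend on the declared δ; there is no ground-truth
  verbal category to recover.
* Between-session intensity normalization assumes the subject's gain and
  shading are stable across sessions up to a global factor; session-specific
  shading changes would require per-session bias estimation, reintroducing
  the bolus-tilt trade-off discussed above.
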