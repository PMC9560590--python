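# Methods

`dbsaudit` implements a neuroimaging-style appraisal of deep brain
stimulation (DBS) electrode placement: how far each implanted electrode sits
from its target nucleus, how that accuracy varies across surgical strata
(nucleus, hemisphere / implantation order, reference region), whether it
relates to intraoperative brain shift and pneumocephalus, how much of the
target a simplified stimulation-field model activates, and whether any of
this predicts clinical outcome. Because the patient imaging such analyses
normally consume is not available, the package pairs every metric with a
synthetic cohort generator that injects known ground truth, so the whole
pipeline is validated by parameter recovery rather than by re-processing
scans.

## Coordinate conventions

All world coordinates are RAS+ millimetres: X lateral (positive towards the
subject's right), Y anterior, Z superior. Volumes are integer label grids
with a 4×4 voxel-to-world affine (NIfTI-1 on disk). The left hemisphere is
always implantation order 1; the emulated cohort was implanted left side
first in every case, so "second electrode" and "right hemisphere" coincide.

## Accuracy metrics

Two definitions are computed per electrode and per reference region (whole
nucleus, or its motor sub-region):

* **Boundary distance** — the shortest Euclidean distance from any contact
  centre to the surface of the region; exactly 0 when a contact lies inside
  it. On-target electrodes therefore contribute zero, which is what makes
  sub-voxel cohort means meaningful. A signed variant (negative depth inside)
  is available as an opt-in diagnostic. Implementation: Euclidean distance
  transform of the complement mask (in mm, anisotropy-aware), sampled with
  trilinear interpolation at the contact positions. Query points that fall
  off the label grid are served exactly via a KD-tree over surface-voxel
  centres. The test oracle is an independent exhaustive minimum over
  contacts × surface-voxel centres (surface voxel = labelled voxel with at
  least one unlabelled 6-neighbour), with agreement required to within one
  voxel diagonal.
* **Centroid offset** — the displacement (dx, dy, dz) of a reference
  contact from the region's centre of gravity, and its norm. The reference
  contact is the contact nearest the centroid, paralleling the "any
  contact" convention of the boundary definition. Offsets feed the target
  plots (X vs Y per nucleus × hemisphere × reference, Z retained in the
  table).

Both metrics are computed with and without the subcortical-refine (SCRF)
affine. Electrodes are represented in SCRF-corrected space; the "nSCRF"
variant maps each electrode through the inverse of its hemisphere's SCRF
matrix.

Outliers are flagged with a one-sided Tukey rule (value > Q3 + 1.5·IQR);
distances are bounded below by zero so only the high side is screened. The
"within target" convention counts electrodes with boundary distance at or
under a configurable threshold, default 2 mm. Stratified summaries report
n, mean, SD, mean ± 2 SD (the reporting convention of the emulated study),
outlier counts and within-threshold counts.

## Brain shift and pneumocephalus

Brain shift is proxied by the magnitude of the SCRF affine: the sum of
|T − I| over the 12 active elements (3×3 linear block plus translation
column). This index is zero exactly at the identity and increases linearly
along a translation ray, but it is dimensionally heterogeneous — it mixes
unitless rotation terms with millimetre translations — and is therefore
used only as a relative severity index, averaged over the two hemispheres.

Pneumocephalus is the difference between an expected (template) brain-mask
volume and the actually extracted brain-mask volume, in mL; negative
differences clamp to zero with a warning. The three pairwise Pearson
correlations among per-subject mean accuracy, SCRF magnitude and air volume
are Bonferroni-corrected as a family of three.

## Volume of activated tissue (VAT)

The stimulation field is solved on a regular voxel grid as a steady-state
conduction problem, div(σ∇V) = 0, with four compartments: grey matter
(0.33 S/m), white matter (0.14 S/m), contact metal (1e8 S/m) and lead
insulation (1e-6 S/m) — conventional isotropic values, all configurable.
Stimulation is monopolar: Dirichlet V = V₀ on the active contact and V = 0
on the outer grid boundary. The discretisation uses harmonic-mean face
conductances (7-point stencil), which makes the solution invariant under a
global conductivity rescaling. The linear system is symmetrically
Jacobi-scaled before conjugate-gradient solution; without that scaling the
~14 orders of magnitude between metal and insulation conductances let the
residual criterion converge on the metal rows while tissue voxels are still
wrong. Convergence requires a relative residual below 1e-6.

The regular-grid finite-difference scheme is a deliberate desk-scale
stand-in for the tetrahedral finite-element discretisations used by
electrode-localisation toolboxes: it solves the same boundary-value problem
with the same activation-threshold contract at a fraction of the
complexity. The default solver grid is a 40 mm cube around the active
contact at 0.5 mm spacing; the lead is painted as an insulating cylinder of
radius 0.635 mm with metal rings at the contact positions, and the active
contact is the contact nearest the motor-subnucleus centroid.

The field magnitude |∇V| (central differences, one-sided at edges) is
thresholded at 0.2 V/mm by default and intersected with tissue (electrode
compartments excluded) to give the binary VAT; overlap with the target
nucleus and its motor component is reported in mm³ and as a fraction of the
region.

Verification uses the concentric-spheres monopole problem: a spherical
contact of radius r₀ inside a grounded sphere of radius R has
V(r) = A(1/r − 1/R) with A = V₀/(1/r₀ − 1/R), which approaches the textbook
V₀·r₀/r monopole as R → ∞; the finite-R term is retained because the test
domain is finite. At 0.2 mm spacing the solved potential agrees within 5%
at mid radii and the activation radius √(A/threshold) within one voxel.
Staircase voxelisation of the contact perturbs its effective
electrostatic radius by O(h), which is the dominant error at coarse
spacings; thin-shaft lead geometry is similarly under-resolved above
~0.75 mm spacing, so VAT volumes from coarse verification grids are not
comparable across resolutions.

## Statistical battery

All tests are two-sided. The two-sample t-test uses the pooled-variance
(Student) form — degrees of freedom n₁ + n₂ − 2, matching the df the
emulated analyses report — not Welch's. Paired t, one-way ANOVA, Pearson
correlation (p from t = r√(n−2)/√(1−r²)), and OLS with an always-included
intercept (QR factorisation; rank deficiency is an error naming the
collinear columns) complete the battery. Zero-variance inputs raise a
dedicated error, distinguished from the legitimate all-zero-differences
case (t = 0, p = 1). Bonferroni correction is min(1, m·p) with the family
size logged explicitly; the pipeline treats each reporting table as one
family, except the shift/pneumocephalus analysis whose family is the three
correlations.

The power computation uses the Fisher z approximation for a two-sided
correlation test: n = ⌈((z₁₋α/₂ + z_power)/C)² + 3⌉ with
C = ½·ln((1+r)/(1−r)). Its inverse (power at given n) is used as the test
oracle: the returned n achieves the target power and n − 1 does not.

Calibration is checked empirically: under 2000 seeded null replicates each
test rejects at α = 0.05 with empirical rate 0.05 ± 0.02.

## Synthetic cohort generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

* **Atlas.** Bilateral axis-aligned ellipsoids for GPi (≈470 mm³ per side,
  centred ±20, −4, −2) and STN (≈160 mm³ per side, centred ±11, −13, −7) —
  order-of-magnitude anatomical volumes and template-like positions — inside
  an ellipsoidal brain mask, on a 121×145×121 grid at 1 mm. The motor
  sub-region is the posterior half-ellipsoid for the STN and a
  posteroventral half (oblique y+z cut) for the GPi; every motor voxel is by
  construction also a main-nucleus voxel, and generated label volumes
  round-trip losslessly through the NIfTI writer/reader.
* **Electrodes.** The planned trajectory is a typical frontal burr-hole
  approach (superior, slightly anterior and lateral); a mid-array contact is
  planned onto the motor-subnucleus centroid, as a surgeon places the
  expected active contact at target with spare contacts either side. The
  realised position adds a displacement drawn per stratum
  (hemisphere × nucleus): Gaussian per axis, the simplest model supporting
  the lateral-variance manipulation. Defaults: zero-mean SD 1.0 mm (GPi) and
  0.7 mm (STN) on the first (left) side; the second (right) side adds a
  +0.5 mm (GPi) / +0.3 mm (STN) lateral bias and its lateral SD is inflated
  by the `right_x_variance_multiplier` (default 2.0), emulating the
  X-dominant second-side variance the analysis is designed to detect. Lead
  geometries come from an editable JSON library of approximate manufacturer
  constants (directional leads collapse to ring centres; the metrics are
  purely positional). The lead-model mix follows the emulated cohort's
  manufacturer counts.
* **Post-operative state.** An ellipsoidal air cavity of volume drawn
  uniformly from 0–20 mL (the emulated study reports no per-subject air
  volumes; this spans typical post-durotomy pneumocephalus) is carved from
  the anterior third of the brain mask, scaled by bisection so the carved
  voxel count matches the request; the recorded truth is the exactly carved
  volume. SCRF affines are small rigid transforms (translations SD 0.5 mm,
  rotations SD 0.5°); zero scales give the exact identity.
* **Outcomes.** Five scores (UPDRS 3, UPDRS 4, LEDD, PDQ-39, body weight)
  with pre-operative baselines and percentage changes calibrated to the
  emulated cohort's outcome table (which prints mean ± 2 SD; the generator
  divides the parentheticals by two). LEDD effects are target-specific:
  −54.3% for STN versus +0.9% for GPi. post = pre·(1 + pct/100), floored at
  zero.
* **Determinism.** One root seed is expanded into per-(subject, stream)
  substreams, so identical configurations are bit-identical and subject k
  is invariant to the cohort size. Attrition is simulated by randomly
  excluding subjects at the registration (default 6 of 38) and VAT
  (default 2) stages; downstream analyses use completers only and the
  completion percentage is reported to the nearest integer.

What the generator does **not** emulate: image intensities, CT metal
artefact, registration error fields, nonlinear deformation, anatomically
shaped (non-ellipsoidal) nuclei, or correlated structure between accuracy
and outcomes (outcome effects are independent of electrode position by
construction). Passing tests therefore demonstrate that the metrics recover
known truth under the stated geometric and statistical model — not that the
pipeline would behave identically on real imaging.

## Numerical choices and degenerate inputs

* Distance fields require orthogonal affines (oblique grids are rejected).
* Tukey flagging needs ≥ 4 values; the correlation analysis needs ≥ 4
  complete records, with missing values dropped pairwise and counted.
* A cohort in which every electrode is exactly on target yields constant
  (all-zero) accuracy: contrasts on it are skipped with a logged warning
  and the shift-correlation table is emitted empty rather than aborting.
* Pipeline problem sizes: the default run is 38 subjects with VAT solved on
  the 40 mm / 0.5 mm grid (roughly 4 s per electrode); verification and
  example runs in the test suite use 6–8 subjects and coarser VAT grids,
  which exercise identical code paths.

## Known limitations

The SCRF magnitude mixes units (see above) and is comparable only within a
run. VAT volumes depend on grid resolution through the staircase lead
geometry. The outlier rule and the within-2 mm convention are reporting
choices, not inferential procedures. The generator's Gaussian displacement
model has no axial (along-lead) anisotropy, and the nearest-contact
centroid-offset convention wraps displacements larger than half the contact
pitch onto the adjacent contact, symmetrically about the planned contact.
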