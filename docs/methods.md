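# Methods

## Overview

`aslprodrome` implements a complete pulsed-ASL (arterial spin labeling)
perfusion analysis for cohorts spanning the cognitive-aging continuum
(cognitively normal → early/late mild cognitive impairment → mild dementia):
denoising of the raw label/control series, one-compartment CBF
quantification, adaptive outlier cleaning, partial-volume correction,
composite-ROI biomarker extraction, and the group/severity statistical
battery.  Because raw clinical ASL data of this kind are access-restricted,
the package ships a digital phantom that generates synthetic subjects and
cohorts with known ground truth; every stage is validated against that
truth.  What passing tests show is therefore *internal* validity — the
pipeline recovers what the forward model put in — not performance on real
scanner data (see Limitations).

## Acquisition model

The simulated acquisition mirrors a product PICORE/Q2TIPS pulsed sequence
on a 3 T system: 64 × 64 in-plane matrix, 24 sequential 4 mm slices with a
25 % gap (5 mm slice pitch in the affine; in-plane voxels 3.4 mm),
TR 3400 ms, bolus duration TI1 = 700 ms, inversion-to-imaging time
TI2 = 1900 ms, 105 volumes: one M0 (equilibrium magnetization) calibration
image followed by 52 label/control pairs.  By default the label member of
each pair comes first; the flag is configurable and subtraction is always
control − label regardless.

## CBF quantification

Under the one-compartment (well-mixed) kinetic model with a Q2TIPS-defined
bolus, perfusion relates to the pairwise difference signal ΔM as

    CBF = 6000 · λ · ΔM / (2 · α · M0 · (TI1/1000) · exp(−TI2_slice / T1b))

in ml/100 g/min, where λ is the blood–brain partition coefficient
(default 0.9 ml/g), α the labeling efficiency (default 0.95 for pulsed
labeling), T1b the longitudinal relaxation time of arterial blood
(default 1664 ms at 3 T), and TI2_slice = TI2 + slice_index · 45 ms accounts
for the sequential 2D readout (the 45 ms per-slice increment is an assumed
product-sequence value; all constants are config-exposed and no internal
code depends on the defaults).  Voxels whose M0 falls below 10 % of the
robust maximum (98th percentile) carry no usable calibration signal and are
zeroed and flagged.  Negative CBF values elsewhere are deliberately
retained at this stage; screening them is the quality-control stage's job.

The phantom's forward model is the exact algebraic inverse of this
equation (both read the same parameter object), so a noise-free simulation
must round-trip to machine precision — one of the package's core
invariants, tested at ≤ 1e−8 relative error.

## The digital phantom

**Anatomy.** A nested-ellipsoid head: CSF core ("ventricles"), WM shell,
GM outer shell, with sigmoidal transitions (~2 mm) creating genuine
partial-volume voxels while keeping pure-tissue cores.  The in-plane
semi-axes are unequal (0.76 vs 0.88 of the half-FOV) — a realistic head
ellipse that also makes axial rotation identifiable for registration.
True perfusion is the mixture `gm_cbf_true·P_GM + wm_cbf_true·P_WM`
(defaults 60/20 ml/100 g/min).

**Signal.** Control volumes equal the proton-density image; label volumes
subtract the ΔM implied by the true CBF map.  On top: Gaussian thermal
noise (default SD 0.6 signal units on an M0 scale of 1000 — chosen, as an
assumption the source acquisition leaves open, so that a clean difference
map correlates with the mean of the others at ≈ 0.2–0.4 over gray matter,
the regime in which correlation-based cleaning of real series operates);
a slow sinusoidal gain drift weighted by proton density (amplitude 2,
period 300 s); optional per-volume rigid motion (trilinear resampling about
the volume center); and scheduled corrupted volumes of two kinds:
*decorrelated-noise replacement* (labeling instability — the perfusion
signal is replaced by strong spatially independent noise, SD 10) and
*global additive offset* (hardware instability — a uniform +30 jump).  The
two kinds are deliberately complementary: an offset leaves Pearson
correlations untouched and must be caught by the whole-brain-mean screen,
while decorrelated noise must be caught by the correlation floor.
Everything is deterministic given the spec's seed.

**Cohort.** `simulate_cohort` draws per-subject covariates and biomarkers
from group-level distributions: group sizes default to 44/31/30/15;
meta-ROI CBF declines across the continuum (48/46/43.4/39.3, SD 8 — effect
sizes d ≈ 0.25/0.58/1.09 vs the normal group, emulating the graded
hypoperfusion such cohorts show) while the visual-control region has no
group effect; hippocampal volume shows marked atrophy only at the dementia
stage (d ≈ 1.3), with the early-MCI group slightly *larger* than normal
(d ≈ −0.35), mirroring the non-monotone pattern reported in this
population.  The severity score (CDR sum of boxes) is generated linearly
from the true biomarkers plus a group offset and noise; coefficients are
set so the age/education-adjusted partial correlations are ≈ −0.3 to −0.4.
With offsets and noise zeroed the score is exactly linear in the
biomarkers — a test anchor.  Demographics and psychometrics (age,
education, sex ratio, MMSE, delayed logical-memory recall) use group
means/SDs typical of aging-continuum cohorts.

## Preprocessing

Fixed order: motion correction → spatial smoothing → temporal high-pass →
nuisance regression.  Output grids always equal input grids.

* **Motion correction**: each volume is rigidly registered to the M0
  reference with SimpleITK (Euler3D transform about the volume center,
  mean-squares metric over the brain mask, two-level multi-resolution
  regular-step gradient descent, trilinear interpolation).  Estimates start
  from the identity — resting-state head motion is small, and identity
  starts leave genuinely still volumes at an exactly zero estimate.  An
  effectively identity result (< 0.01 mm / 0.01°) skips resampling so still
  volumes are not blurred by interpolation.  All-zero volumes are flagged
  and passed through with zero parameters.
* **Smoothing**: per-volume isotropic Gaussian, FWHM 4 mm
  (σ = FWHM/(2√(2 ln 2)) converted to voxel units per axis), zero-padded
  boundary.  The M0 volume is left unsmoothed so quantification divides by
  the acquired calibration image.
* **High-pass**: zero-phase (forward–backward) Butterworth, order 2, cutoff
  0.01 Hz at the 1/TR sampling rate, applied per voxel to the non-M0
  frames; the per-voxel temporal mean is re-added afterwards so the
  absolute intensity scale (and hence M0-relative quantification) is
  preserved.  Edge transients use Gustafsson's method: the default
  pad-and-reflect handling attenuates a Nyquist alternation — the perfusion
  signal — by several percent on short series, Gustafsson leaves it exact.
  Order 2 and zero-phase application were chosen for stability on
  ~100-point series.
* **Brain mask**: voxels above 0.3 × the 98th-percentile robust maximum of
  M0, largest connected component.  A percentile threshold is scale-free.
  This replaces external skull-stripping binaries: on phantoms (and any
  data without skull signal) threshold masking is adequate and keeps the
  package self-contained.
* **Nuisance regression**: per-voxel OLS removal of 9 regressors (6 motion,
  global mean, WM mean, CSF mean; WM/CSF segments at probability > 0.9).
  The label/control alternation is the perfusion signal and lives at the
  Nyquist frequency — exactly where the global/WM/CSF regressors also carry
  it.  The design therefore includes a protected ±1 alternation covariate
  whose fitted component (with the intercept) is retained, and each
  nuisance regressor is first orthogonalized against the protected columns;
  without the projection, near-collinearity lets the nuisance fit absorb an
  arbitrary share of the perfusion signal (on a clean phantom this wiped
  out the perfusion effect entirely).  Regressors that vanish after
  orthogonalization are dropped with a warning.  The protection is
  switchable for users who want literal global-signal regression.

On a noise-free, motion-free phantom the full chain changes the mean
control−label difference in a deep (eroded) gray-matter ROI by < 2 %
(measured ≈ 0.4 %, all attributable to smoothing).

## Adaptive outlier cleaning

Two layers:

1. **Initial screen** — pairs whose framewise displacement (sum of absolute
   translation increments plus rotation increments on a 50 mm arm) exceeds
   1.5 mm, or whose whole-brain mean CBF lies outside mean ± 2.5 SD of the
   series.  These thresholds follow common toolbox practice and are
   config-exposed.
2. **Adaptive correlation screen** — per pass, every map's gray-matter
   voxels are correlated with the voxelwise mean of the *other* kept maps
   (leave-one-out; an include-self variant exists).  Kept maps with
   CC < 0.15 or outside mean ± 2 SD of the pass's correlations become new
   outliers; the pass repeats until stable.  Maps removed by the initial
   screen never contribute to the reference means.

The ± 2 SD band is computed, by default, over the correlations of **all**
maps of the current pass, including already-removed ones (whose near-zero
correlations keep the band wide).  This is a deliberate design choice: if
the band is instead re-estimated over the surviving maps only
(`band_scope="kept"`), each pass re-standardizes an already-clean sample
and removes the ~5 % of good maps that any finite sample puts beyond 2 SD,
cascading over several iterations.  Simulation shows the kept-only variant
discards ~4 clean maps from an outlier-free series where the all-maps band
discards none, and the all-maps band converges in a single removal pass —
the behaviour real series show.  Characterization over 100 seeded phantoms
with 2–6 corrupted pairs each (mixed corruption kinds, native 52-pair
length): recall 1.0, precision ≥ 0.99.

The surviving maps are averaged voxelwise into the final CBF image.
Subject-level flags then mark (a) inadequate brain coverage — fewer than
90 % of reference-extent voxels carrying signal (> 5 % of the volume's
robust maximum, so smoothing spill-over into unacquired slices does not
count) in every volume; the reference extent should be anatomical (tissue
maps), since a mask derived from a truncated acquisition cannot reveal the
truncation — and (b) extensive non-physiological negativity, more than
10 % of gray-matter voxels negative in the final map.

A note on series length: with 2–6 corrupted of only ~20 pairs, the
corrupted maps contaminate the leave-one-out reference mean enough to drag
clean-map correlations below the 0.15 floor, and cleaning degenerates.
The correlation floor is calibrated to the native 52-pair series, so all
characterization runs use the native length (on a reduced 32 × 32 × 16
grid, which only scales voxel counts).

## Partial-volume correction and ROIs

Cortical voxels mix GM, WM, and CSF; CSF carries no perfusion signal and WM
perfuses at a fraction of GM, so uncorrected GM CBF is biased low.  The
correction is the linear mixing model `CBF_corr = CBF / (P_GM + 0.4·P_WM)`
for voxels with P_GM ≥ 0.3 (both parameters exposed); other voxels are
zeroed and excluded from ROI means.  The 0.4 WM/GM perfusion ratio is the
conventional value.  The correction never changes sign and only inflates
magnitudes where the denominator is below 1.  A regression-based
alternative is a reserved interface, not yet implemented.

ROI summaries are means over (ROI ∩ GM ∩ PVE-included) of unions of
spheres defined in template mm coordinates and stored in YAML — never
hard-coded voxel indices.  The shipped phantom-space configuration places a
composite "meta-ROI" (posterior-midline precuneus-like sphere plus
bilateral parietal and temporal spheres, radius 0.13 × the smallest FOV
extent) in the mid-GM shell, and a disjoint occipital control sphere that
should show no group effect.  In the synthetic setting all subjects share
one grid, so template registration is a no-op; the registration seam is an
explicit interface for future real-data use.

Hippocampal volume is normalized as mean(left, right) / ICV with
ICV = GM + WM + CSF volumes — a unitless, head-size-invariant atrophy
measure.  Hippocampal segmentation itself is out of scope; volumes are
pipeline inputs.

## Statistics

* **Demographics**: pooled-variance two-sample t from printed summaries
  (df = n1+n2−2) and Pearson χ² without continuity correction for 2 × 2
  frequencies.
* **Group model**: OLS of the biomarker on an intercept, three group
  dummies (normal group as reference), and age.  Reported: overall model F,
  partial F for the dummy block, and planned per-group contrasts vs the
  reference (model t) with Cohen's d.  d is computed from raw
  (covariate-unadjusted) group means over the pooled SD — primary, because
  the adjusted variant depends on the covariate distribution — with the
  adjusted-coefficient d also emitted.  Sign convention: negative t and d
  mean the patient group is lower than the reference.
* **Severity**: partial Pearson correlation by the residual method (x and y
  each residualized on the covariates; p from t with df = n−k−2).  With no
  covariates this is the plain Pearson correlation.
* **Stepwise**: hierarchical regression forcing age and education, then
  admitting the perfusion and atrophy biomarkers one at a time by smallest
  partial-F p < 0.05 (for one added regressor the partial F equals the
  squared coefficient t).  Coefficients are standardized betas (all
  variables z-scored).  Verified against exhaustive evaluation of all four
  candidate models.
* Conventions: all tests two-sided; listwise deletion per analysis; no
  multiple-testing correction (planned-comparison framing).  All
  procedures are deterministic given the input table.

Model fitting is delegated to statsmodels; independent hand-rolled linear
algebra serves as the test oracle, never the implementation.

## Numerical choices and problem sizes

* Degenerate inputs: constant outcomes return exactly zero coefficients
  (not floating-point noise); zero-variance vectors in correlations are
  handled explicitly; all-zero volumes skip registration.
* Exact-recovery tolerances are 1e−8 relative; orthogonality assertions
  1e−10.
* The test and acceptance suites run phantoms at 32 × 32 × 16 (native
  voxel size and, wherever cleaning behaviour matters, the native 105-volume
  series) and registration tests at 48 × 48 × 20 — sizes chosen so the full
  validation battery runs on a laptop-class single core in a few minutes
  while preserving every behaviour the full 64 × 64 × 24 grid shows.
  Type-I-error calibration uses 1000 null replicates; QC characterization
  100 phantoms.

## Limitations

* The phantom has smooth nested-shell anatomy: no gyri, no skull, no B0 or
  coil inhomogeneity, no EPI distortion, no physiological pulsation, no
  slice-timing offsets beyond the quantification term.  Registration and
  masking are therefore easier than on real data.
* The one-compartment model ignores transit-time dispersion and
  multi-compartment exchange; background suppression is not modeled.
* Cohort-level image simulation modulates perfusion territory-wise
  (meta-ROI region scaled per subject); real hypoperfusion topography is
  more graded.
* Statistical effect sizes in the default cohort emulate, not reproduce,
  any particular study's values; tests assert directions, calibration, and
  internal consistency, not published point estimates from restricted
  data.
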