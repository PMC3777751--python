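# aslprodrome

Pulsed arterial-spin-labeling (ASL) perfusion analysis for cohorts spanning
the cognitive-aging continuum — cognitively normal adults, early and late
mild cognitive impairment, and mild dementia — validated end to end on a
digital phantom with known ground truth.

ASL MRI measures cerebral blood flow (CBF) non-invasively by magnetically
labeling arterial blood water: subtracting label from control images leaves
a difference signal ΔM proportional to perfusion.  Regional hypoperfusion
in a predetermined composite of posterior-midline, parietal, and temporal
regions (a "meta-ROI") tracks neurodegeneration much like FDG-PET
hypometabolism, making ASL a candidate MRI-only functional biomarker.
This package is for researchers who want a tested, fully scriptable
reference implementation of that analysis — and a simulation harness to
probe how each processing choice (filtering, nuisance regression, outlier
cleaning, partial-volume correction) affects the downstream biomarker and
group statistics.

## The pipeline

1. **Phantom simulation** — synthetic subjects (nested-shell head, true CBF
   map, 105-volume pulsed-ASL series with noise, drift, motion, and
   corrupted volumes) and cohort tables with group-graded perfusion and
   hippocampal effects.
2. **Preprocessing** — rigid motion correction to the M0 reference,
   isotropic Gaussian smoothing (FWHM 4 mm), zero-phase Butterworth
   high-pass (0.01 Hz, mean re-added), and nuisance regression (6 motion +
   global + WM + CSF regressors) with a protected label/control alternation
   covariate so the perfusion signal survives.
3. **Quantification** — pairwise control−label subtraction and the
   one-compartment pulsed-ASL model:

   CBF = 6000 λ ΔM / (2 α M0 (TI1/1000) e^(−TI2,slice/T1b)) [ml/100 g/min]

   with TI1/TI2 = 700/1900 ms, λ = 0.9 ml/g, α = 0.95, T1b = 1664 ms, and a
   per-slice TI2 increment for the sequential readout (all overridable).
4. **Quality control** — framewise-displacement and whole-brain screens,
   then iterative leave-one-out cleaning: maps whose gray-matter Pearson
   correlation with the mean of the remaining maps falls below 0.15 or
   outside mean ± 2 SD are removed until the series is stable; survivors
   are averaged into the final CBF image.  Subject-level flags catch
   inadequate brain coverage and extensive negative gray-matter CBF.
5. **PVC + ROIs** — linear partial-volume correction
   CBF/(P_GM + 0.4 P_WM), spherical meta-ROI and visual-control-ROI means,
   hippocampal volume normalized by intracranial volume.
6. **Statistics** — summary t-tests and χ², age-adjusted four-level group
   regression with planned contrasts and Cohen's d, partial correlations
   with disease severity (CDR sum of boxes), and hierarchical stepwise
   regression testing whether perfusion and atrophy carry independent
   information.

## Worked example

Simulate one subject with two corrupted volumes, clean and quantify, and
extract ROI perfusion:

```python
from aslprodrome import (
    PhantomSpec, make_ground_truth, simulate_subject_series,
    quantify_series, run_qc, make_brain_mask, pve_correct,
    roi_mean_cbf, sphere_mask, phantom_roi_specs,
)

spec = PhantomSpec(
    grid_shape=(32, 32, 16), n_volumes=105, seed=42,
    outlier_schedule=((9, "noise"), (44, "offset")),
)
truth = make_ground_truth(spec)
series = simulate_subject_series(spec, truth)

cbf = quantify_series(series, params=spec.quant_params())
gm = truth.tissue.gm > 0.5
report, final_map = run_qc(cbf, gm, make_brain_mask(series.m0), series=series)
print(f"maps: {cbf.n_maps}, removed: {report.removed_indices()}, "
      f"iterations: {report.n_iterations}")

corrected, included = pve_correct(final_map, truth.tissue)
for roi in phantom_roi_specs(spec):
    mask = sphere_mask(roi, tuple(spec.grid_shape), spec.affine)
    print(f"{roi.name} ROI mean CBF: "
          f"{roi_mean_cbf(corrected, mask, gm, included):.1f} ml/100 g/min")
```

Output:

```
maps: 52, removed: [4, 21], iterations: 1
meta ROI mean CBF: 59.9 ml/100 g/min
control ROI mean CBF: 60.1 ml/100 g/min
```

The 105-volume series quantifies to 52 CBF maps.  Volume 9 (a
decorrelated-noise volume, pair 4) is caught by the correlation floor and
volume 44 (a global intensity jump, pair 21) by the whole-brain screen;
cleaning converges in one pass.  After partial-volume correction both ROI
means recover the phantom's true gray-matter perfusion of
60 ml/100 g/min to within sampling noise.

The same flow is scriptable from the shell:

```bash
aslprodrome simulate --out sim/ --seed 42
aslprodrome qc --series sim/asl.nii.gz --tissue-dir sim/ --out qc/
aslprodrome stats --cohort sim/cohort.csv
aslprodrome run --config cfg.yaml --seed 7     # full cohort pipeline
```

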