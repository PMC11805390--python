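# pvsq — perivascular-space quantification on T1-weighted MRI

Perivascular spaces (PVS, Virchow–Robin spaces) are fluid-filled
sheaths around small brain vessels and part of the glymphatic
clearance system. On a T1-weighted image they appear as thin, dark,
tube-like structures inside the bright white matter. Tracking their
total burden over time is of interest in longitudinal studies — for
example of pediatric brain-tumor patients before and after
radiotherapy and chemotherapy — where scan-to-scan intensity
variation, anesthesia, CSF-shunt procedures, age and sex all influence
the measurement and must be modelled.

`pvsq` implements the full quantification and analysis chain:

1. **Intensity normalization** — each volume is rescaled
   multiplicatively so the white-matter (WM) mean equals 110, either
   from the supplied WM mask directly or from the brightest cluster of
   a fuzzy c-means intensity clustering. This makes a single fixed
   segmentation threshold comparable across exams.
2. **Multiscale Frangi vesselness** — the Hessian of the
   Gaussian-smoothed image is computed at a set of scales σ with
   γ-normalization (second derivatives × σ²); its eigenvalues
   |λ₁| ≤ |λ₂| ≤ |λ₃| are combined into

       R_A = |λ₂|/|λ₃|,  R_B = |λ₁|/√(|λ₂λ₃|),  S = √(λ₁²+λ₂²+λ₃²)
       V = (1 − e^(−R_A²/2α²)) · e^(−R_B²/2β²) · (1 − e^(−S²/2c²))

   for voxels with λ₂ > 0 and λ₃ > 0 (dark tube on bright
   background), with α = β = 0.5 and c = 2, maximum over scales,
   restricted to the WM mask.
3. **Segmentation** — vesselness > 0.05 inside WM; connected
   components (26-connectivity) smaller than 5 voxels are removed as
   noise islands and larger than 150 voxels as non-PVS hypointensities
   (ventriculostomy catheters, leukoencephalopathy patches).
4. **Quantification** — PVS volume in cm³ and PVS ratio in ‰ of the
   WM volume.
5. **Statistics** — a linear mixed model over all exams,
   `PVS = β₀ + β₁·TP + β₂·Anesthesia + β₃·Age + β₄·Sex + β₅·DOSE + β₆·Shunt`,
   with a per-patient random intercept (REML) and Bonferroni-adjusted
   pairwise contrasts; and a paired model of per-patient changes
   ΔPVS between consecutive time points under matched
   anesthesia/shunt conditions, tested with one-sample t-tests and
   compared across radiation-dose groups with one-way ANOVA. A QC rule
   flags exams beyond mean ± 2·SD plus a seeded random review sample.

Because real MRI exams cannot ship with the package, a first-class
synthetic-data module generates (a) 3D tube phantoms with exact
ground-truth PVS masks, plus catheter/blob/speckle confounders, and
(b) longitudinal cohort tables with a known effect structure, so every
stage is tested against a known truth.

## Worked example

```python
import pvsq

# a 64^3 phantom: bright WM shell, 12 dark tubes, known ground truth
spec = pvsq.PhantomSpec(n_tubes=12)
image, wm_mask, truth = pvsq.generate_phantom(spec, seed=42)
print(f"true PVS ratio: {truth.true_pvs_ratio_permil:.2f} permil")

measurement, artifacts = pvsq.process_exam(image, wm_mask)
print(f"recovered ratio: {measurement.pvs_ratio_permil:.2f} permil "
      f"({measurement.n_components} components)")
```

prints

```
true PVS ratio: 7.48 permil
recovered ratio: 7.80 permil (12 components)
```

— the pipeline recovers the simulated PVS burden to ~4% here; over a
batch of phantoms spanning different burdens the median relative error
is well under 15% and confounders contribute no voxels to the final
masks.

On the statistics side:

```python
cohort = pvsq.generate_cohort(seed=0)          # 241 patients, 4 time points
fit = pvsq.fit_full_model(cohort)              # REML mixed model
print(fit.coefficients["C(anesthesia)[T.yes]"])  # ~ -0.5 permil
deltas = pvsq.build_paired_deltas(cohort)
print(pvsq.test_deltas(deltas).query("period == '3M-12M'")[
    ["dose", "n", "mean_delta", "p_value"]])
```

shows the simulated chemotherapy-period decrease of the PVS ratio in
every dose group.

The same stages are available from the shell:

```bash
pvsq simulate phantom --out phantom/ --seed 1
pvsq normalize --image phantom/phantom_t1w.nii.gz --wm-mask phantom/phantom_wm.nii.gz --out norm.nii.gz
pvsq frangi --image norm.nii.gz --wm-mask phantom/phantom_wm.nii.gz --out vess.nii.gz
pvsq segment --vesselness vess.nii.gz --wm-mask phantom/phantom_wm.nii.gz --out pvs.nii.gz
pvsq quantify --pvs-mask pvs.nii.gz --wm-mask phantom/phantom_wm.nii.gz
pvsq stats full --table cohort.csv --response ratio --out fit.json
```

## Layout

```
src/pvsq/io.py            volumes, masks, cohort tables (NIfTI/CSV/XLSX)
src/pvsq/normalization.py WM-target intensity normalization, fuzzy c-means
src/pvsq/vesselness.py    multiscale Hessian / Frangi filter
src/pvsq/segmentation.py  threshold + size filters, quantification
src/pvsq/synthetic.py     tube phantoms and cohort simulation
src/pvsq/stats.py         mixed model, paired deltas, QC rule
src/pvsq/pipeline.py      per-exam and cohort orchestration, manifests
src/pvsq/cli.py           the `pvsq` command
docs/methods.md           model assumptions, parameter choices, limitations
```
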