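# trabmech

Trabecular bone microstructure analysis and voxel micro-finite-element
mechanics, for researchers studying whether clinical-resolution scanners
(dental cone-beam CT, HR-pQCT) can stand in for micro-CT when assessing
bone quality in osteoporosis research.

The package implements the full analysis chain of a cross-modality bone
study, plus a synthetic-data generator so the chain can be exercised and
validated without scanner data:

* **Segmentation** — an automated region-growing (ARG) scheme for
  clinical-resolution gray-scale volumes with uncalibrated intensities:
  seeds from the attenuation histogram, 50 homogeneity thresholds swept
  from the seed homogeneity to 1.6× it, final mask chosen by the minimum of
  an assessment function; plus Otsu histogram thresholding for
  high-contrast micro-CT-like data, and contrast-to-noise measurement.
* **Histomorphometry** — 3D thinning to voxel-wide lines and the seven
  standard structure parameters: BV/TV, Tb.Th, Tb.Sp, Tb.Sc, Tb.N
  (= 1/Tb.Sc), Tb.Nd (skeleton junctions /mm³), Tb.Tm (free ends /mm³).
  Thickness is model-independent sphere fitting (largest inscribed
  sphere).
* **Micro-FE** — each bone voxel becomes a linear hexahedral element
  (tissue E = 12 GPa, ν = 0.3); six load cases under kinematic uniform
  boundary conditions (u = ε̄·x on the cube surface) yield the 6×6
  apparent stiffness C; Young's moduli E1 ≤ E2 ≤ E3 and the minimum shear
  modulus G^min come from the compliance C⁻¹.
* **Statistics** — Pearson correlations with Fisher-z 95% CIs, simple and
  SPSS-style stepwise regression (entry p ≤ 0.05, removal p ≥ 0.10) with
  R²/adjusted R², Bland–Altman test–retest analysis, descriptive tables.
* **Synthetic phantoms** — thresholded anisotropic Gaussian random fields
  with exact target volume fraction, imaged by simulated scanners (PSF
  blur, detector binning, noise, arbitrary intensity units).

## Worked example

```python
import trabmech as tm

spec = tm.PhantomSpec(side_mm=3.2, fine_voxel_mm=0.1, target_bvtv=0.2,
                      thickness_scale_mm=0.3, rng_seed=3)
truth = tm.generate_ground_truth(spec)          # BV/TV = 0.2000 exactly
scan = tm.simulate_scan(truth, tm.ImagingSpec(out_voxel_mm=0.1,
                                              psf_fwhm_mm=0.16,
                                              noise_sd=125, rng_seed=4))
res = tm.arg_segment(scan)
m = tm.compute_metrics(res.selected_mask)
stiff = tm.homogenize(tm.build_model(tm.extract_fe_cube(res.selected_mask, 1.6)))
```

printed results from this run:

```
truth BV/TV: 0.2
ARG selected iteration: 49  mask BV/TV: 0.1378
Tb.Th 0.331 mm  Tb.Sp 1.477 mm  Tb.N 0.482 /mm  Tb.Nd 0.37 /mm3
E1 1.057  E2 1.203  E3 1.846 GPa   Gmin 0.633 GPa
```

Reading it: the ARG sweep settled on its most permissive iteration and
recovered a mask somewhat below the true volume fraction at this
signal-to-noise; mean trabecular thickness is 0.33 mm with ~0.48
trabeculae per mm; the 1.6 mm micro-FE cube of this structure has an
apparent stiffness of 1.85 GPa along its stiffest axis — about 15% of the
12 GPa tissue modulus at 14% volume fraction — and a minimum shear modulus
of 0.63 GPa.

The same steps are available from the shell:

```bash
trabmech generate --side-mm 3.2 --voxel-mm 0.1 --bvtv 0.2 -o truth.mhd --scan-voxel-mm 0.2
trabmech segment truth_scan.mhd --method arg -o mask.mhd   # + JSON log
trabmech morpho mask.mhd
trabmech fe mask.mhd --side-mm 1.6
trabmech run-study --smoke --seed 1 -o study_out/          # full pipeline
trabmech stats specimen_table.csv -o reports/              # stats on a table
```

`run-study` generates a specimen set, segments every scan (Otsu for the
fine reference, ARG for clinical analogs), computes structure parameters
per modality, runs micro-FE on the fine segmentation, and writes the
per-specimen table, correlation/regression/stepwise/descriptive report
tables, Bland–Altman reproducibility for the repeated scan, and a JSON
manifest with every seed and parameter. Runs are byte-identical for a
fixed configuration and master seed. `reproduce-tables` applies the same
statistical layer to an existing per-specimen table (CSV/XLSX, column
mapping configurable).

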