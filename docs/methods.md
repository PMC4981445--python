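# Methods

`trabmech` implements an in-silico version of a cadaveric-bone imaging
study design: trabecular bone cubes are imaged at fine (micro-CT-like)
resolution — the gold standard — and re-imaged by clinical-resolution
scanners (cone-beam CT and HR-pQCT analogs); structure parameters computed
from each modality are related, statistically, to apparent stiffness and
shear computed by micro-finite-element homogenization of the fine
segmentation. This note records the models, the parameter choices, and what
the synthetic pipeline does and does not establish.

## Synthetic phantoms

Ground truth is a thresholded anisotropic Gaussian random field: white noise
smoothed with an anisotropic Gaussian kernel (correlation length
`thickness_scale_mm` transversely, times `anisotropy` along axis 3), then
thresholded at the intensity quantile that yields the target bone volume
fraction exactly (up to voxel quantization, < 0.005). This produces
plate/rod mixtures whose trabecular thickness scales with the correlation
length — empirically, at BV/TV 0.10, mean sphere-fitting thickness is about
1.6x the correlation length — and whose stiffest axis follows the
anisotropy. A random-field phantom was preferred over CAD rod lattices
because it exercises the skeleton census and thickness metrics with
realistic morphology.

Two known departures from real trabecular bone matter for interpretation:

* **Percolation.** Excursion sets of a smooth random field lose
  connectivity near volume fractions where real (load-adapted) bone is
  still connected. Below roughly BV/TV 0.08 the largest face-connected
  component of a phantom may not span the analysis cube; the pipeline then
  reports zero apparent stiffness (the physically correct
  displacement-controlled limit for a structure with no load path).
* **Thickness at clinical resolution.** With ~2-voxel-thick structures, the
  half-voxel discretization of sphere-fitting thickness partially cancels
  partial-volume inflation, so apparent Tb.Th at clinical resolution can
  sit *below* the fine-resolution value even though it increases
  monotonically with voxel size between clinical scans. Studies on real
  bone, where trabeculae are much thinner than the measured apparent
  thickness, report strong inflation instead.

A scan of a truth volume assigns bone/water intensities (arbitrary device
units — cone-beam CT provides no calibrated CT values), blurs with a
Gaussian PSF, block-averages to the clinical voxel size (detector
integration), and adds white noise. Beam hardening, scatter and ring
artefacts are not modelled.

## Segmentation

**Histogram threshold (fine data).** Otsu's maximum between-class-variance
threshold, upper class = bone. On noise-free two-intensity data it is exact.

**Automated region growing (clinical data).** Calibration-free, per the
published family of homogeneity-threshold region-growing methods:

1. *Seeds* are the upper class of a three-class between-class-variance
   (multi-Otsu) split of a 1-voxel-Gaussian-smoothed copy — this isolates
   the bone tail whether the histogram is bimodal or background-dominated —
   eroded by one voxel to interior seeds.
2. The *strictest homogeneity threshold* is the SD of the raw intensities
   over the uneroded seed class. This spread carries both noise and
   partial-volume scale; the *most permissive* threshold is 1.6x it, and 50
   thresholds are swept linearly (both endpoints included).
3. *Growth* from the seeds admits, one at a time, the face-connected
   frontier voxel whose intensity is closest to the running region mean,
   as long as that deviation is within the threshold. The greedy order does
   not depend on the threshold, so all 50 masks are prefixes of one pass —
   exactly nested, and computed in a single sweep.
4. The *assessment function* selects the final iteration. The published
   form is not reproduced in the source study, so a surrogate is used:
   the volume's histogram is split into background / partial-volume / bone
   classes (three-class split of the smoothed copy) and the score is
   `w_leak * (background-class fraction inside the region) +
   w_miss * (bone-class fraction left outside)`, minimized over iterations,
   ties resolved to the strictest. Partial-volume voxels are free to join
   the region — which is precisely why segmentation of thin, blurred
   trabeculae counts the halo as bone and overestimates BV/TV, the behavior
   reported for clinical-resolution scanners.

This surrogate was chosen after measuring two more conventional scores
(mean boundary-gradient and boundary step contrast) on simulated clinical
scans: for blurred thin structures every intensity level set is an "edge",
the gradient peaks on the flank of the blurred bump rather than at the
halo boundary, and both scores monotonically prefer under-segmentation.
The class-disagreement score is the only form tried whose minimum tracks
the intended boundary in all three regimes (noise-free: exact recovery;
noisy fine-resolution at CNR ~8: Dice ≈ 0.91; blurred clinical: halo
included). The weights are exposed (`assessment_weights`, default (1, 1)).

CNR is |mean(bone ROI) − mean(background ROI)| / SD(background ROI). In
trabecular-only simulated volumes there are few pure-bone voxels at
clinical resolution, so measured CNR (~3 in the smoke study) is lower than
the nominal contrast/noise ratio of the scanner model (~6–7).

## Histomorphometry

Skeletonization is topology-preserving 3D thinning to voxel-wide lines
(Lee's method, scikit-image). The census counts junction voxels (≥3
skeleton neighbours in 26-connectivity) merged into 26-connected clusters —
so a thick crossing is one node — and free ends (exactly 1 neighbour),
excluding ends on the volume border (a cut trabecula is not a terminus).
Local thickness is model-independent sphere fitting: the diameter of the
largest inscribed sphere covering each voxel, with sphere radius D − ½ voxel
(D the Euclidean distance transform), computed per radius level as a
morphological opening; radius levels beyond 32 are quantized, bounding the
error well under one voxel. The seven parameters: Tb.Th (mean bone-phase
thickness, mm), Tb.Sp (mean marrow-phase thickness, mm), Tb.Sc (mean
thickness of the skeleton's complement — the spacing between trabecular
midlines, mm), Tb.N = 1/Tb.Sc (1/mm), Tb.Nd and Tb.Tm (nodes and termini
per mm³), BV/TV (exact voxel-count ratio).

Because the skeleton is a *curve* skeleton, Tb.Sc is meaningful for rod-like
networks (on a cubic rod lattice of spacing `s` it measures the cell
clearance ≈ √2·s) but degenerates for plate stacks, whose midplanes thin to
curves; the slab phantoms in the tests therefore validate Tb.Th/Tb.Sp/BV/TV
only. Tb.N is reported in 1/mm, the unit consistent with its definition as
trabeculae per unit length.

## Micro-FE homogenization

Each bone voxel becomes one 8-node trilinear hexahedral element (2×2×2
Gauss quadrature, exact for the cubic element), tissue E = 12 GPa,
ν = 0.3, linear isotropic. Only the largest face-connected component is
meshed: edge/corner contacts transmit no well-posed hexahedral stiffness
and floating fragments make the system singular (the removed fraction is
logged). Six canonical load cases (three uniaxial strains, three
engineering shears) are applied as kinematic uniform boundary conditions —
all nodes on the bounding-cube surface displaced by `eps @ x` — and the
interior is solved by conjugate gradients with Jacobi preconditioning and
an affine initial guess, to relative residual 1e-8 (Jacobi rather than
incomplete-LU preconditioning because an ILU preconditioner is
nonsymmetric, which breaks CG). The macroscopic stress of a case is the
element-stress average over the *total* cube volume (pores contribute
zero); the six stress vectors form the apparent stiffness C (Voigt,
engineering shears), which is symmetrized (asymmetry, a solver-tolerance
effect, is logged and ~1e-9 in practice). Engineering constants come from
the compliance S = C⁻¹: E_i = 1/S_ii relabelled so E3 is the maximum, and
Gmin is the smallest of the three shear moduli. KUBC gives an upper-bound
apparent stiffness; diagonal entries of C are non-increasing under material
removal, which the tests verify on nested random masks.

## Statistics

Pearson correlations with Fisher-z 95% intervals; ordinary least squares
for single-predictor regressions (R², two-tailed slope p); stepwise
multiple regression with probability-of-F entry 0.05 / removal 0.10 (the
defaults of the statistics package named by the emulated study), reporting
the single-predictor R² and the two-predictor adjusted R²
(1 − (1−R²)(n−1)/(n−k−1)); Bland–Altman bias and 1.96·SD limits of
agreement for test–retest scans, with a systematic-error flag when zero
lies outside the t-based CI of the bias. Formatted outputs print
"p < 0.001" below threshold; exact values are kept internally.

## The in-silico study and its scale

`RunConfig.smoke()` is the configuration the acceptance script runs: six
specimens, 7.68 mm cubes at 0.08 mm fine voxels (96³), clinical analogs at
0.16 mm with PSF 0.36–0.40 mm and noise 140–160 intensity units, FE cubes
of 3.84 mm (48³), one repeated clinical scan per specimen for
reproducibility analysis. These sizes keep a full run in minutes on one
CPU while preserving the regimes of the emulated full-scale design:
trabeculae ~2 clinical voxels thick, PSF ~2.5 clinical voxels, and a
specimen population spanning true volume fractions 0.05–0.20 (the sparse
range the gold-standard modality reports for distal-radius specimens, mean
≈ 0.10). Under these conditions the study reproduces the qualitative
findings the design is known for: clinical-analog BV/TV overestimates the
fine-reference value for every specimen, BV/TV strongly predicts micro-FE
E3 and Gmin, DXA-like areal BMD of small cubes predicts neither, and
repeated scans show no systematic error in Bland–Altman analysis.

A simulated DXA column is included so the regression table has the
full-design shape: areal BMD = 0.12 · BV/TV · depth(cm) g/cm² plus
detector noise (SD 0.003 g/cm²), clamped at zero — values near the
detection limit, hence the poor predictive value.

What passing tests show — and do not. The pipeline demonstrates internal
consistency (exact closed forms, oracle agreement, bound properties,
determinism) and the qualitative cross-resolution behavior above. It does
not demonstrate agreement with any particular scanner's point-spread or
noise statistics, nor the absolute parameter levels of real distal-radius
bone: synthetic phantoms differ from real trabecular architecture in
connectivity at low volume fraction, plate/rod balance, and the absence of
cortical remnants and imaging artefacts.

## Numerical conventions

0-based voxel indices; physical position = index × voxel size
(voxel-centred); centered crops round the offset half-down so crops are
reproducible; axis 3 is the last array axis. One master seed spawns
per-specimen and per-scan substreams (`numpy` SeedSequence), so studies
are deterministic end to end and scans of different modalities see
independent noise. Degenerate inputs: constant volumes are rejected by
seed selection and thresholding; empty/full masks raise a degenerate-mask
error that still carries the (always defined) BV/TV; a zero seed-intensity
spread is floored to a relative epsilon so the threshold schedule stays
well defined; component-size ties in meshing break to the component
containing the lowest lexicographic voxel.
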