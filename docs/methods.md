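# Methods

`ybremdose` implements a three-stage pipeline for quantitative 90Y
bremsstrahlung SPECT dosimetry after radioembolization, together with the
physics simulators and synthetic phantoms needed to train and evaluate it on
a single CPU. This note describes the models, their assumptions, the
numerical choices, and what the desk-scale experiments do and do not show.

## The problem

90Y is a pure beta emitter (endpoint 2.28 MeV, mean energy ~0.94 MeV, mean
soft-tissue penetration ~2.5 mm, CSDA endpoint range ~10.9 mm). Post-therapy
imaging relies on the continuous bremsstrahlung X-ray spectrum, which makes
scatter dominant inside the 105–195 keV acquisition window and forces
medium/high-energy collimation with poor spatial resolution. The pipeline
addresses both: a CNN estimates the scatter mean in projection space so
OS-EM can model y ~ Poisson(Ax + r̄), and a residual network converts the
reconstructed activity plus CT density into a dose-rate map while undoing
reconstruction blur, having been trained against dose maps computed from
*true* activity maps (never from reconstructions).

## Virtual patients and the torso phantom

Phantoms are generated on a desk grid of 128×128×64 voxels at 2 mm (a
512×512×194 @ 0.98×0.98×2 mm full-scale preset exists but is not exercised
by the tests). The liver is a union of random ellipsoids; lesions are
ellipsoids whose voxel counts match the requested mL volumes exactly (the
mask takes the n smallest normalized-radius voxels, so realized volume is
within one voxel of the request). Liver activity is
base concentration × lesion uptake ratio × a multiplicative log-normal
texture (σ = 0.35, correlation length 12 mm, normalized to mean 1);
uniform (XCAT-like) activity is known to train dose networks poorly, so the
texture is on by default. The map is rescaled so total activity equals the
configured value exactly (2 GBq by default). Densities: air 0.0012, lung
0.30, soft tissue 1.00, bone 1.40 g/cm³. Everything is deterministic given
the config seed.

The torso-phantom preset is a 1200 mL liver with 29/16/8 mL hot inserts at
6.4–7.8 MBq/mL over a 1.3 MBq/mL background, lung and spine compartments at
their densities. The printed concentrations integrate to ~1.9 GBq, so a
single global factor brings the total to 2.0 GBq (ratios are unchanged).

CT-to-density is a two-segment piecewise-linear curve anchored at
(−1000 HU, 0.0012), (0 HU, 1.0) and (+1000 HU, 1.60 g/cm³), constant below
−1000 and linearly continued above +1000; the experimentally calibrated
clinical curve is not public, so this Schneider-type stand-in is the
documented default. Attenuation maps use the tabulated water mass
attenuation coefficient (log-log interpolated, 50–2300 keV) times density,
evaluated at 150 keV — the middle of the acquisition window.

## System model (projector)

The projector is rotation-based: per view the volume is rotated into the
detector frame, attenuated along rays (midpoint rule: half the voxel's own
plane plus all planes between it and the detector), blurred per depth plane
with a Gaussian collimator-detector response of FWHM(d) = c0 + c1·d
(defaults c0 = 2 mm, c1 = 0.05, a broad high-energy-collimator-like
response; the clinical parameterization is not public), and summed along
rays. The in-plane rotation is a cached sparse bilinear *splat* matrix, so

- the backprojector is literally the transposed matrix: adjointness holds to
  machine precision (the gating property for OS-EM correctness), and
- counts are conserved exactly for objects strictly inside the field of
  view.

The attenuation map is rotated with the row-normalized (value-interpolating)
variant of the same matrix. View angles are equally spaced over 360°,
counter-clockwise from 0°. Grids must match the detector sampling (square
in-plane voxels equal to the bin pitch); no silent resampling.

## Photon Monte Carlo (scatter ground truth)

Photons are emitted isotropically from decay sites sampled from the
activity map with energies from a thick-target bremsstrahlung shape
I(E) ∝ (Emax − E)/E on [50, 2280] keV tabulated at 1 keV. Transport is
Woodcock (delta) tracking through the density map with water cross sections
scaled by density: Klein–Nishina Compton scattering (rejection sampling
against the forward maximum; outgoing energy follows the Compton relation
exactly) and a coarse photoelectric table; coherent scattering is neglected
(small above 105 keV). Detection: a photon escaping toward a view within a
2° acceptance cone is scored into the geometrically mapped bin if its
Gaussian-blurred energy (FWHM fraction 0.095 at 140 keV, scaling as 1/√E)
falls inside the window; ≥1 interaction scores to scatter, 0 to primary.
Scoring is analog with no variance reduction, so the estimator is simple
and auditable. Desk default: 2×10⁵ histories per view set, scatter labels
smoothed with a 1-bin-FWHM Gaussian. Outputs are normalized to counts per
decay and scaled by total activity, hence linear in activity.

## Measurement composition (desk study condition)

Measured projections are composed as y ~ Poisson(Ax + r̄) at ~10⁷ total
counts: the primary Ax comes from the deterministic projector evaluated at
*half* the detector pitch and 2×2-binned, so the reconstruction model is a
deliberately coarser approximation of the data generator (inverse-crime
avoidance — the clinical analogue pairs Monte Carlo data with an analytic
reconstruction model); r̄ is the photon-MC scatter mean rescaled so the
scatter-to-primary ratio matches the MC simulation (~1.5–2, scatter
dominates, as expected for bremsstrahlung imaging). The desk acquisition
uses 64 views of 64×32 bins at 4.8 mm with a 250 mm orbit; the paper-scale
128-view 128×80 geometry is the `ProjectionGeometry` default.

## Scatter CNN (stage I)

Two branches of three 3×3 conv + ReLU layers (one for the scaled total
projection, one for the projected attenuation map), channel concatenation,
a three-layer conv trunk, then a pointwise convolution and a terminal ReLU:
spatial size is preserved everywhere and the output is non-negative by
construction. Scaling: the total projection and the scatter labels are
divided by (study total counts × 10⁻⁴); attenuation line integrals by 10.
Constants live in the checkpoint sidecar and are inverted at the output.
The pointwise head's bias starts at +0.1 so the terminal ReLU is alive at
initialization (a dead output head cannot recover under backprop).
Training: pixel-wise MSE, Adam. The paper-scale recipe (lr 1e-4,
800 epochs) is the `TrainConfig.paper_scatter()` preset; the desk recipe is
lr 3e-4, 20 epochs, batch 16, channels 8/16, one phantom held out for
best-checkpoint validation. On the packaged fixtures this reaches a
held-out scatter NRMSE of ~11–12% (the labels themselves carry desk-scale
MC noise; the clinical-scale analogue with 10⁹-history labels reports ~4%).

## OS-EM (stage II)

Classic multiplicative OS-EM over interleaved view subsets (maximal angular
spacing, bit-reversal subset order), attenuation and CDR inside the system
model, scatter as an additive mean, denominator floored at 1e-12, voxels
with zero sensitivity excluded, uniform start inside the attenuation
support, no post-filter, fixed 4 subsets × 16 iterations. With one subset
the update is exactly MLEM and the Poisson log-likelihood is non-decreasing
(verified per iteration). Reconstructions are trilinearly resampled to the
CT grid with an exact global rescale so total activity is preserved.

## Beta dosimetry (stage III physics)

The 90Y spectrum is the allowed Fermi shape
N(E) ∝ p·E_tot·(Q−E)²·F(Z=40, E) with a nonrelativistic Coulomb factor,
tabulated at 10 keV (sampled mean 0.948 MeV). Electron transport is
condensed-history CSDA: steps of 1/20 of the residual Katz–Penfold range
R(E) = 0.412·E^(1.265−0.0954 ln E) g/cm², continuous deposition at step
midpoints, Highland-width Gaussian multiple scattering per step, terminal
local deposit below 100 keV (residual range 0.14 mm, far below any voxel
size used here), bremsstrahlung losses in the beta transport neglected.
Energy bookkeeping is exact: deposits plus the escaped-energy tally equal
the sampled emission energy.

Dose voxel kernels are generated in water with electrons starting uniformly
in the central voxel; kernel dimensions are the smallest odd counts
covering ±11 mm (2·round(11/pitch)+1 per axis, half away from zero), which
reproduces 23×23×13 at 0.98×0.98×2 mm voxels. Units are nGy/s per MBq via
10⁶ decays/s per MBq and the voxel mass. DVK dosimetry is zero-padded FFT
convolution of the activity map with the kernel, divided voxel-wise by
density, with voxels below the density cutoff set to zero. The cutoff is
1.0 g/cm³ as printed in the reference protocol — note this zeroes lung and
fat; the threshold is a config parameter because that behaviour is
surprising, but the default follows the printed rule, and the direct MC
applies the same rule so the two routes agree. `mc_dose_rate` uses the same
transport with geometric steps scaled by local density and batch-based
per-voxel standard errors. In uniform water the central dose rate matches
the analytic charged-particle-equilibrium value C·10⁶·Ē(J)/(10⁻³ kg) to
well within 2%.

Maximum penetration: the deepest simulated deposit approaches the CSDA
endpoint (10.94 mm) from below, ~10 mm at 10⁶ histories — multiple
scattering keeps electrons short of the straight-line range, consistent
with measured extrapolated ranges. The radius enclosing 99.9% of deposited
energy is ~8.3 mm; published EGS-type 90Y point kernels place that
percentile similarly far inside the extreme range. Dose-rate to dose is a
single factor T½/ln 2 (in seconds): microspheres do not redistribute, so
the only kinetics is physical decay.

## Residual dose network (stage III, DblurDoseNet-style)

Input: 11-slice packs of per-study-scaled activity (scaled so voxels sum to
the normalizing constant 10⁶) and density, concatenated along channels; a
3-layer 3-D conv extractor (in-plane kernel 7, axial depths 5, 5, 3 by
default — a 5, 3, 3 variant is selectable; channels 32/32/32 at full scale,
4/4/8 in the desk preset) collapses the pack to the middle slice; a 2-D
U-Net (4 levels, widths 32–256 at full scale; 3 levels, widths 8–32 desk)
produces a residual that is divided by density, scaled by an internal
residual scale (the RMS of the needed correction on the training set, for
Adam conditioning), and added to the DVK dose-rate slice; the inverse
activity scaling is applied at the end. The residual head is
zero-initialized, so the untrained network reproduces DVK dosimetry
*exactly*. Because dose is linear in activity, the DVK input and MC labels
are scaled by the same per-study factor during training. Training labels
always come from MC on the true activity/density. End slices use replicate
padding; negative outputs are clamped at inference with the clamped
fraction logged. The two networks are always trained separately and
sequentially — never jointly through OS-EM.

The single-stage ablation shares the architecture, takes the no-SC
reconstruction and its DVK map, and carries a `single_stage` checkpoint tag;
inference guards against mixing variants.

## Desk-scale training limits (what the tests show)

The desk recipe (two training phantoms plus one for validation,
1.2×10⁶-history labels, 64×64 training crops, every other slice,
30 epochs) reliably (i) leaves the
untrained network identical to DVK dosimetry, (ii) reduces validation MSE
below the DVK baseline, and (iii) corrects the healthy-liver mean bias
(typically +10% → ~1%). Recovering *lesion* means beyond the MC-on-
reconstruction baseline — the clinical-scale headline — is a much harder
target at desk scale: the per-voxel MC label noise (~20% at 2×10⁶
histories vs <0.1% at the reference 10⁹) and the unlearnable log-normal
activity texture dominate the voxel residuals, and in-sample experiments
show the MSE objective spends its capacity on the large liver-rim spill
before sharpening lesion cores. The acceptance suite asserts the
directional lesion criterion anyway and reports it honestly; a failure
there reflects the desk-scale training regime, not the physics stages,
which are verified by exact oracles.

## Evaluation

NMAE is implemented exactly as printed in the field's tables: the absolute
difference of VOI means over the GT mean, in percent — a bias of means. A
voxel-wise MAE variant exists under a distinct name and is never used for
acceptance. NRMSE is RMSE over the GT root-mean-square. DRVH curves are
cumulative (fraction of VOI receiving ≥ threshold) with
D(f) = the largest threshold whose coverage is ≥ f (step-function
convention), so D10 ≥ D90 always. Background VOIs for lesion-to-background
ratios are shape-identical translated copies of the lesion mask, searched
nearest-first over integer offsets within 50 mm, feasible placements fully
inside the liver and disjoint from every lesion, ranked by local
coefficient of variation (evaluation bounded to the 2000 nearest feasible
candidates).

## Numerical choices and limitations

- float64 throughout, except the 3-D convolution kernels which compute in
  float32 (relative error ~1e-7, verified against a float64 im2col
  implementation in the tests).
- All randomness flows through explicit integer seeds; reruns are
  bit-identical.
- The projector requires grid pitch = bin pitch; resampling is explicit.
- Septal penetration tails, camera backscatter, 90Y internal-pair photons,
  bremsstrahlung dose, and regularized reconstruction are out of scope.
- The photon MC scores object scatter only (no collimator/detector
  scatter).
- Synthetic phantoms do not reproduce real patient anatomy, respiratory
  motion, or deformable registration effects; conclusions from the packaged
  fixtures are about the pipeline's correctness and directional behaviour,
  not clinical accuracy.
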