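# Methods

This note documents the models, defaults and numerical choices behind
`duospect`, and what the in-silico experiments do and do not show.

## Scene and phantom

The phantom emulates a ¹⁶⁶Ho radioembolization procedure imaged together
with ⁹⁹ᵐTc-colloid. All organs are ellipsoids (body, liver, one or more
tumors, two lungs) on a 64×64×48 grid at 4.8 mm isotropic voxels — the
clinical pixel pitch on a desk-scale matrix; the clinical 128×128 matrix
is accepted through the phantom and protocol configuration. Voxel indices are 0-based, world
coordinates are `index · spacing + origin`, and rotations act about the
volume center in x→y→z order; these conventions are used everywhere.

Activity defaults are the protocol's scan-time values: 250 MBq ¹⁶⁶Ho over
the liver and 50 MBq ⁹⁹ᵐTc in healthy liver only (the adopted 5:1 ratio).
The tumor-to-normal ¹⁶⁶Ho concentration ratio defaults to 4, a typical
microsphere hot-spot contrast; a 2% lung shunt is included so lung
dosimetry is non-degenerate (clinically shunts of a few percent are
common). Activity is piecewise constant per compartment and normalized
against the voxelized organ volumes, so prescribed totals are reproduced
to float precision for any grid. Untargeted-tissue activity outside the
liver defaults to zero.

Attenuation maps are organ-wise constants at the two photopeak energies:
0.18 cm⁻¹ (81 keV) and 0.15 cm⁻¹ (140 keV) for soft tissue, lungs at 0.3×
soft tissue, air zero. Densities are 1.06 g/ml (soft tissue) and 0.3 g/ml
(lung); voxels outside the body carry unit density purely to keep the
dose map defined there — no VOI ever includes them.

## Acquisition model

The projector is parallel-beam: the camera rotates about the patient axis
and, per angle, the volume is rotated so rays run along one grid axis,
weighted by the attenuation survival factor (half-voxel self-attenuation
convention), summed, and blurred with a distance-independent Gaussian
detector response (FWHM 10 mm default). The in-plane rotation is a sparse
bilinear matrix applied as a *splat* (the transpose of the backward-map
interpolation matrix), which conserves counts exactly; the backprojector
is the literal matrix transpose, so ⟨Px, y⟩ = ⟨x, Pᵀy⟩ holds to machine
precision — a unit-tested invariant that OSEM correctness rests on. A
circular orbit replaces the clinical non-circular orbit: with a
distance-independent PSF the orbit radius does not enter the model.

Windows follow the clinical layout: 81 keV (15%), 118 keV (12%), 140 keV
(15%), 170 keV (12%). Per window the expectation is the sum of a primary
term (fully attenuated projection at the photopeak energy) and
downscatter terms (projection with 0.7× attenuation, blurred by a 40 mm
FWHM Gaussian — a standard Monte-Carlo-free surrogate for object
scatter). Photopeak self-scatter of the 81 keV line is deliberately not
modeled, mirroring the clinical reconstruction. Default sensitivities
(counts per Bq·s) give clinically plausible totals of a few million
counts per window; each isotope's downscatter sensitivity into the 81 keV
window is 1.15× its sensitivity into the 118 keV window (likewise 140 vs
170 keV for ¹⁶⁶Ho), which realizes the single combined k-factor of 1.15
*identically*, independent of how activity is distributed. The k-factor
calibration routine fits k by least squares between estimation-window
expectations and the simulator's known contamination, and is exposed so
users can recalibrate after changing the crosstalk model. Poisson noise
uses one substream per window derived from the master seed, so identical
expectations produce identical counts regardless of which isotopes are
present.

## Reconstruction

OSEM with multiplicative updates, 10 iterations × 8 subsets (angles
assigned round-robin by index stride), uniform positive initialization
inside the body support, and a fixed iteration count (no convergence
stopping). The window-based scatter estimate — k times the optionally
smoothed estimation-window counts — enters the update denominator
additively rather than being subtracted from the data, preserving Poisson
statistics. The estimate is smoothed with a 20 mm FWHM Gaussian by
default (window estimates are noisy; standard triple-energy-window
practice), renormalized per angle so smoothing never changes the total
estimate. The reconstruction grid equals the phantom grid; the system
model mirrors the simulator's primary term (same PSF, same attenuation
map), which is the matched-model idealization of calibrating a clinical
reconstructor. Reconstructed volumes are therefore in calibrated Bq/ml;
the dosimetry stage nevertheless rescales totals to the administered
activity, as the clinical protocol does.

## Registration

Motion between the two acquisition arms is rigid (the patient stays on
the table). Alignment is estimated on the attenuation maps with
normalized mutual information (32 bins over the joint support), via an
exhaustive integer-voxel translation scan (±3 voxels) crossed with a
small in-plane rotation scan, then Nelder–Mead refinement of all six
parameters. Both inputs are presmoothed by a one-voxel Gaussian: without
it, interpolation artifacts pin intensity metrics to grid-aligned poses
and sub-voxel motion is never recovered. The procedure is fully
deterministic — a deliberate replacement for stochastic-gradient
optimizers, so tests and experiments are bit-reproducible. Recovery
accuracy on the standard phantom is ~0.03 voxel and ~0.05°.

## Dosimetry and VOIs

Dose assumes local beta deposition: `D = 15.87 mJ/MBq · C·10⁻⁶ / ρ`,
valid because the mean ¹⁶⁶Ho beta range (2.5 mm) is below the voxel size;
the ~4% gamma energy is ignored. VOI rules: an ellipsoidal healthy-liver
VOI of 27.57 ml placed at the healthy-liver centroid and shifted away
from the tumor until disjoint (the clinical volumes were all 27.57 ml
with unstated radii; radii here use a fixed 1.3:1:0.8 anisotropy);
the tumor VOI (ground-truth mask in the experiment, standing in for
manual segmentation); lungs thresholded from the attenuation map at
5–60% of soft-tissue μ and shrunk by 2 cm via the Euclidean distance
transform (equivalent to ball erosion, spacing-aware); and a 25 ml
minimum VOI volume. Automatic segmentation thresholds default to 0.35 of
the image maximum for healthy liver (⁹⁹ᵐTc image) and 0.4 for tumor
(¹⁶⁶Ho image), keeping the largest connected component.

## Statistics

Bland–Altman uses sample (n−1) SDs; CRP = 1.96·SD; LoA = mean ± CRP.
Pearson r and the paired t test follow the standard formulas (p from the
t distribution with n−1 df). Cohen's κ is computed from observed and
marginal-product expected agreement and is cross-checked against an
independent implementation in the tests. Quantile summaries use
linear-interpolation quantiles. No multiple-testing correction is
applied.

## Paired experiment

Per seed: build phantom → simulate the Ho-only arm (Tc zeroed) → apply a
small rigid motion (default: half-voxel translation) and simulate the DI
arm → reconstruct ¹⁶⁶Ho with the correction on and off → register the DI
attenuation map to the Ho-only frame and resample the reconstructions →
build VOIs in the Ho-only frame → rescale to the administered therapy
activity and compute mean VOI doses → pool pairs over seeds into the
agreement battery. Both arms share the per-window noise substreams, so
removing ⁹⁹ᵐTc and motion makes the arms voxel-identical — a pipeline
identity the acceptance tests assert exactly. The default experiment is
10 seeds on the 64³-scale grid, minutes on one CPU.

## What the phantom does and does not show

The generator reproduces the features the window-based correction
interacts with — activity ratios, window contamination with the correct
k structure, attenuation, Poisson statistics, rigid inter-scan motion —
but not anthropomorphic anatomy, respiratory or intra-scan motion,
depth-dependent collimator response, septal penetration, photopeak
self-scatter, or Monte-Carlo photon transport. Passing tests therefore
demonstrate the correctness and internal consistency of the correction
and dosimetry chain under the stated model, not clinical image quality.
Because the simulator's downscatter model realizes k = 1.15 by
construction, the corrected-arm residuals measure noise, registration and
convergence effects rather than k-miscalibration; users studying
k-sensitivity should perturb the crosstalk model and recalibrate.

Known limitations: tumor-dose recovery at the fixed 10×8 OSEM schedule is
convergence-limited (≈ −10% for the default 34 ml tumor at 4:1 contrast;
more iterations recover more), which is the in-silico analogue of the
clinical minimum-VOI-volume rule; the parallel-beam projector ignores
orbit radius; and registration assumes overlapping fields of view.
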