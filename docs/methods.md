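# Methods

`lair` implements a two-step limited-angle (LA) micro-CT reconstruction
workflow on fully synthetic data: (1) the missing angular band of an LA
sinogram is inpainted by a context-encoder GAN trained on randomized digital
phantoms, and (2) the completed sinogram is reconstructed analytically (FBP)
or iteratively (EM-TV, ASD-POCS) with an image-quality-based stopping rule.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Geometry and projection model

A rotating source-detector pair scans a fixed object; angles are degrees,
counter-clockwise, 0 along +x. At view angle 0 the source sits at
`(0, -SOD)` and the flat detector line at `y = SID - SOD`. The natural
reconstructed voxel is the detector pitch demagnified to the isocenter,
`pitch x SOD/SID`: 69.00 um for the 75-um panel at SOD 299 mm / SID 325 mm,
17.4088 um at SOD 49 mm / SID 211.1 mm. Three acquisition protocols are
built in: LA (1 deg/view, 90 deg), DSFC (1 deg/view, 360 deg) and LSFC
(5 deg/view, 360 deg).

Forward projection is the linear model `p = A f`, where `a_ij` is the exact
intersection length (mm) of ray `j` with pixel `i`, computed by Siddon-style
parametric traversal (numba). Backprojection is the matched transpose, so
adjointness holds to machine precision by construction and is tested rather
than assumed. Matrices are cached per (geometry, angle grid, image grid)
within a session because their construction dominates iterative studies.
Cone-beam data are treated slice-by-slice as fan beam (central-slice
approximation); full 3D cone weighting is out of scope.

## Analytic reconstruction

FBP is the 2D central-slice specialisation of the Feldkamp algorithm:
cosine pre-weighting of each row (fan mode, detector rescaled to the
isocenter), convolution with the band-limited discrete ramp kernel
(`g(0) = 1/(4h^2)`, odd lags `-1/(pi^2 n^2 h^2)`, frequency-domain with
>= 2x zero padding), then distance-weighted (`1/U^2`) backprojection with
linear detector interpolation.  The truncated kernel's tiny positive DC
gain is deliberately kept: it compensates the finite kernel support, and
forcing it to zero biases reconstructed attenuation several percent low. Negative
values are retained; clipping is the caller's choice. Kernel windows
(Shepp-Logan, Hann) and a Nyquist-fraction cutoff are available; the
default is Ram-Lak at full cutoff since the studies are noiseless.

A sampling choice that matters: the quality-study geometry samples the
detector at **half** the reconstruction voxel (384 bins at 271.7 um for
0.5-mm voxels on a 128 px grid). At 1:1 sampling the Shepp-Logan DSFC-FBP
PSNR is ~27.8 dB; at 2x it is ~32.9 dB, because ramp-filter aliasing at
the sharp skull edge dominates the error. The completion-pipeline geometry
instead fixes 176 detector bins (the network's radial dimension) at 380 um
pitch around a 96 px / 0.4 mm grid, so no radial resampling is needed.

## Iterative reconstruction

Both solvers address `argmin_f U(f) + lambda V(f)` subject to `f >= 0`,
with V the isotropic TV norm (forward differences, zero-gradient boundary;
the z term drops in 2D). The smoothed surrogate
`sum sqrt(|grad f|^2 + eps^2)` (eps = 1e-6) supplies descent directions.

* **EM-TV**: multiplicative MLEM fidelity steps
  `f' = f . A^T(p/(Af)) / A^T 1` (0/0 := 0) alternated with `tv_steps`
  normalised TV-gradient steps of length
  `lambda x tv_step_size x ||EM update||`, so regularisation strength
  tracks fidelity progress and `lambda = 0` is plain MLEM.
* **ASD-POCS**: a relaxed SART pass (`beta`, decayed by `beta_red` each
  iteration) plus nonnegativity projection, then adaptive TV descent with
  step `alpha_frac x ||POCS update||`, `alpha` decayed by `alpha_red`
  whenever the TV stage moves farther than `r_max` times the POCS update.

Defaults (`lambda` 0.2, tv_steps 10, tv_step_size 0.1, beta 1.0,
beta_red 0.995, alpha_frac 0.2, alpha_red 0.95, r_max 0.95, 50 iterations)
follow the common settings of the ASD-POCS literature family; none are
fitted to data. Both solvers can be initialised from an image; the pipeline
initialises them from the clipped FBP of the same data. That choice is
load-bearing: from a flat or zero start, SART-type fidelity needs far more
than 30 iterations to pass the FBP baseline on a 72-view scan, while
FBP-initialised runs of either solver roughly halve the FBP RMSE within
30 iterations. EM-TV additionally floors its initial image at a small
positive value because multiplicative updates cannot leave zero.

Rays that miss the reconstruction grid (all-zero matrix rows) are excluded
from the EM consistency check: an inpainted sinogram may place small
nonzero values there, and such rays carry no information either way.

### Image-quality stopping rule

Instead of thresholding the unknowable pixel error, iteration stops on
image quality against a reference `f`: among iterates with
`PSNR(f*, f) > k` (k = 35 dB), the score `s = UIQI - rTV` is tracked and
the argmax-s iterate is returned once `s` has not improved for `patience`
(default 3) iterations. If the gate is never met the last iterate is
returned with reason `psnr-gate-unmet`. In simulation the reference is the
ground-truth phantom; in an LA pipeline it is the FBP of the completed
sinogram — both selectable. Note that `s` is typically negative (rTV sits
near 1 while UIQI < 1); the score is used only ordinally, so this is
harmless. Because rTV's ideal value is 1 rather than 0, a variant score
`UIQI - |rTV - 1|` is available behind `use_rtv_distance`; the default
keeps the literal difference.

## Figures of merit

PSNR uses the joint maximum pixel value of the two images as the peak and
returns an `inf` sentinel for identical images. UIQI is computed on global
statistics; when both means are exactly zero the luminance factor is 0/0
and the index reduces to its structure-contrast part `2cov/(v1+v2)`
(identical zero-mean images still score 1, sign-inverted ones -1). SSIM
uses `c1 = (0.01L)^2`, `c2 = (0.03L)^2`; the default mode is the
conventional 11x11 Gaussian window (sigma 1.5, mean-pooled, via
scikit-image), and a `global` mode evaluates the expression once on
whole-image statistics. rTV is the TV-norm ratio and is deliberately
asymmetric. CNR and SNR follow the usual ROI definitions with 3 x 3 mm^2
boxes; FWHM comes from a least-squares Gaussian + constant-baseline fit
(`FWHM = 2 sqrt(2 ln 2) sigma`); HA linearity is the Pearson correlation of
insert ROI means against nominal densities (0-800 mg/cm^3).

## Synthetic data

The generator emulates the statistical variety of a training corpus rather
than any particular animal: 1-4 filled discs with radii uniform in
10-20 px, uniformly placed subject to containment, values uniform in
0.01-0.05 mm^-1 (soft-tissue range at micro-CT voltages); the classical
Shepp-Logan slice/volume; and thick-stroke "digit-like" images standing in
for handwritten-digit data so nothing is downloaded. Pose augmentation
applies a random rotation (bilinear, zero fill), optional left-right
reflection, and a reversed-rotation flag realised as reversed angular
ordering of the sinogram rows (row *i* holds the view at `-i * step`;
since scanning at negated angles equals scanning the mirrored object, the
stored ground-truth image is the vertically flipped phantom, keeping every
sample consistent with its sinogram in the reconstruction frame).
Everything is reproducible from a master seed via spawned per-sample
seeds.

The LA manipulation chain follows the fan-beam periodicity trick: a 360 deg
sinogram is extended to 450 deg by copying its first 90 deg of rows, the
[90, 360) band is zeroed (the missing flag is carried separately from the
data, so a measured zero is never confused with a missing row), and the
result is resampled bilinearly to the network profile. After completion the
sinogram is resampled back to native dims, measured rows are restored
bit-exactly, and the duplicated band is folded onto [0, 90) by averaging
(`keep-first` preserves the alternative); averaging is exact on consistent
data and halves completion noise in the band.

What the generator does **not** model: polychromatic spectra, scatter,
detector gain/dark nonuniformity, ring artifacts, beam hardening, or
anatomical texture. A Poisson/Gaussian noise switch exists but defaults to
off. Green tests therefore demonstrate the pipeline's internal correctness
and the completion network's capacity on piecewise-constant objects, not
performance on animal data.

## Context-encoder completion

The generator encodes the full masked sinogram through four stride-2 3x3
conv stages (depths 2, 4, 8, 16; leaky rectifier slope 0.2; batch-norm
momentum 0.8, i.e. running = 0.8 running + 0.2 batch; dropout 0.5 on the
last stage), maps features to the decoder seed through a channel-wise
fully-connected layer (per-channel dense, no channel mixing), and decodes
through four conv + nearest-2x-upsample stages (depths 16, 8, 4, 2) into a
final tanh conv that emits only the masked band. For the full-size profile
(544 bins x 448 angles) the bottleneck is 34 x 28, the seed 34 x 17 and
the band 544 x 272. The discriminator is three 3x3 conv stages (first two
stride 2) over the band, flattened into one sigmoid unit.

Band height is the missing-row count rounded **up** to a multiple of 16
(the four decoder upsamplings): 272 rows for the 448-angle profile
(~269 missing rows after resampling), 80 rows for the desk profile
(67 missing of 112). The band therefore extends one or two rows into known
territory; compositing overwrites those rows from the measured input, so
training never alters known values at inference.

Sinogram values are mapped affinely onto tanh's (-1, 1) range; the
reference gray range is 0-80, and the desk pipeline derives the range from
the training-set maximum with a 15% margin so the frequent zero-background
level sits away from tanh's saturated -1, where regression gradients
vanish. The loss is `0.999 x masked-region L2 + 0.001 x adversarial BCE`
(the balance is configurable; the sources state both terms but not their
weights, and a strongly L2-dominant mix is the stable choice for
regression-style inpainting). Each epoch draws one random 32-sinogram
training batch and a 16-sinogram validation draw from the pool —
discriminator update on a concatenated real/fake batch, then a generator
update — with per-epoch losses and periodic validation PSNR/UIQI/SSIM
logged.  Batches cycle a reshuffled permutation of the pool, so every
sinogram gets equal exposure over the run; the discriminator trains on a
half-real/half-fake batch and the generator reuses its forward pass for
both updates.

Three further details matter at this scale and were kept after
measurement. First, the output conv's bias is initialised to the mean
normalised band value, saving the early epochs otherwise spent drifting
from tanh's mid-range. Second, after training the batch-norm running
statistics are replaced by population statistics computed in one pass over
the pool (dropout off): with the prescribed momentum 0.8 the running
averages remember only ~5 batches, which makes inference-mode outputs
swing by several dB between epochs. Third, inpainted values are clipped to
nonnegative line integrals, a projection onto the physical range that can
only shrink the pointwise error. Variants that measured no better or worse
at this scale — Polyak/EMA weights, best-validation snapshot selection,
learning-rate step decay, tail weight averaging, beta1 = 0.9, prediction
ensembles — are not used.

The network core is a compact, self-contained CPU implementation (float32
NCHW; convolutions as nine shifted batched matmuls, which profiled faster
on one CPU than both im2col and direct numba loops at these channel
counts; Adam with bias correction). Gradients are verified against central
differences in the test suite.

**Desk profile.** The CPU study uses 176 x 112 sinograms, an 80-row band,
and discriminator widths 8/16/16 (the full-size profile with the printed
widths 64/128/128 is a preset; at the desk scale the wide discriminator
dominates CPU cost while the 0.001 adversarial weight makes it nearly
irrelevant to the L2-driven inpainting). Training runs 800 one-batch
epochs at lr 3e-3, beta1 0.5. The conventional GAN rate of 2e-4 is the
package default, but at a few hundred total gradient steps it demonstrably
undertrains (roughly 7 versus 11 dB held-out region-PSNR gain at equal
epochs); the desk preset's higher rate is a CPU-budget choice, not a tuned
constant. With it, desk training completes in ~4.5 minutes per seed; over
three seeds the inpainted band gains >= 10 dB median region PSNR over zero
filling on held-out slices, and the completed-sinogram FBP beats the LA
FBP on PSNR and UIQI on essentially all of them.

Known limitations: the architecture is size-locked (a different missing-band
geometry needs retraining at matching dims); the adversarial term is nearly
inert at the default weights; batch-norm inference statistics lag early in
training; and the desk-profile numbers quantify recovery of piecewise-
constant phantoms, not anatomy.

## Problem sizes

Studies are sized for a single CPU: 128 px grids with 384 detector bins for
reconstruction-quality numbers (seconds per FBP, ~5 s per 50-iteration
EM-TV run), 96 px grids with 176 bins for the completion pipeline, and
200-sinogram training sets. `scripts/acceptance.py --seed <int> --out
<path>` recomputes every headline quantity from scratch — geometry
arithmetic, projector error bounds, metric closed forms, protocol PSNR/RMSE
orderings, the stopping-rule optimality fraction, and a full desk training
run — in roughly ten minutes.
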