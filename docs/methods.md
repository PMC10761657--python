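# Methods

`petrestore` studies a restoration problem from pediatric total-body
PET/CT: a full-dose tracer injection (3.7 MBq/kg FDG) with an ultrashort
acquisition (6-150 s instead of 600 s) yields images whose count statistics
are too poor for conventional reconstruction alone, and a learned mapping is
asked to recover full-time image quality. The package implements the whole
experimental loop on synthetic phantoms: paired activity/CT generation,
count-limited scan emulation, a multimodal restoration network with a CT
feature-fusion branch (p3DNet) plus its single-modality ablation (3DNet), a
non-local means (NLM) baseline, and the quantitative/semiquantitative
evaluation used to compare them.

## Phantoms and acquisition model

A phantom is a list of axis-aligned ellipsoidal "organs" and spherical
"lesions" painted into a background, in order, later descriptors
overwriting earlier ones where they overlap (a deterministic last-wins
rule). Each descriptor carries an activity in SUV and a CT level in HU, so
the activity and attenuation volumes are generated perfectly co-registered
on the same grid — registration of clinical data is out of scope. The
stock torso phantom (body, liver, lung, spine, two avid lesions above
SUV 5) scales its geometry with the grid; the randomized generator used for
training draws organ/lesion placement, size and uptake (lesions 5-10 SUV)
per seed so the networks see varied anatomy. Default grid: 96 x 96 x 24
voxels of 2.34 x 2.34 x 2.89 mm (in-plane 256 x 256 in the clinical
protocol; smaller grids keep desk runs fast while preserving the geometry
of the problem).

A t-second scan is emulated statistically rather than through list-mode
reconstruction: per-voxel expected counts are
`lambda = activity * counts_per_suv_second * t`, one Poisson draw is
converted back to SUV by dividing by `counts_per_suv_second * t`, and a
3 mm-FWHM Gaussian postfilter (sigma = FWHM/2.3548 per axis, in voxel
units) stands in for the smoothing of the clinical reconstruction chain.
This preserves exactly the two moments that define the problem: the
pre-filter image is unbiased (`E[x_t] = truth`) and its variance is
`truth / (counts_per_suv_second * t)`, i.e. proportional to 1/t, so the 6 s
image is 100x noisier (in variance) than the 600 s image. The calibration
`counts_per_suv_second = 2.0` was chosen once so that relative noise spans
~30% at 6 s to ~3% at 600 s for SUV-1 tissue — the regime in which
denoising is hard but the reference is trustworthy. What the emulation does
*not* model: reconstruction artifacts, spatially correlated noise,
attenuation/scatter residuals, motion. Conclusions from passing tests are
therefore about count-limited noise, not about those effects.

The simulated 600 s scan — not the noiseless truth — is the training target
and evaluation reference, exactly as a clinical study would use its
full-time reconstruction; the noiseless truth is retained only to validate
the simulator itself.

## Preprocessing

PET volumes are normalized to [0, 1] by the maximum SUV over the training
collection, CT by the maximum HU; both constants are embedded in any saved
checkpoint and reused verbatim at inference. Values of unseen volumes may
exceed 1 (or be negative, for CT): nothing is clipped. CT volumes are
resampled to the PET grid by trilinear interpolation on corner-aligned
grids, filling outside the CT extent with the CT minimum. Networks consume
H x W x 5 slabs; extraction tiles the depth axis with a final slab flush
with the last slice when the depth is not divisible, training uses stride 2
(denser sampling), inference stride 5, and reassembly averages overlapping
slabs, which inverts extraction exactly. Volumes shallower than 5 slices
are front-padded by edge replication and cropped after reassembly.

## Networks

Both networks are residual U-Nets over slabs, built from 3 x 3 x 3
convolutions with LeakyReLU (slope 0.01). Down- and upsampling act
in-plane only (stride-2 convolution; zero-stuffing + convolution), keeping
the 5-slice depth intact, since a depth of 5 cannot survive repeated
halving. Residual modules are two convolutions with an identity shortcut.
p3DNet fuses the CT prior at low and high dimensions: the raw CT slab
enters the PET stem as a second input channel, and a CT encoder's features
are injected into the PET encoder at every scale by channel concatenation
followed by a 1 x 1 x 1 projection back to the branch width —
concatenation being the least lossy fusion when the exact operator is not
prescribed. All CT entry points are gated at initialisation (the CT
weights start at zero and the per-scale fusion projections start as
identities on the PET half), so the multimodal network begins as exactly
the single-modality mapping and admits the anatomical prior only as
training finds it useful; without this, random fusion weights inject CT
interference that short schedules never learn to cancel. Symmetric encoder-decoder skip
connections concatenate features. A global input-to-output residual (the
network predicts a correction to the noisy slab, and the final convolution
is zero-initialised so training starts exactly at the identity) is the
package's own design choice: standard in restoration CNNs, and at desk
scale it is what makes ~30-epoch convergence possible.

The default configuration — base width 32 doubling over 3 scales, 2
residual modules per encoder scale, 1 per decoder scale — lands at
~4.33 M trainable parameters, inside the ~4 M budget that distinguishes
this lightweight design from a standard ~30 M 3D U-Net; the matched 3DNet
has ~3.43 M. Exact per-scale widths and block counts are free parameters
bounded by that budget.

Because no deep-learning framework is assumed, the networks run on a small
reverse-mode autodiff engine inside the package (`petrestore.grad`):
channels-last ndarrays, im2col + GEMM convolutions, and an Adam optimizer.
Gradient correctness is held to finite differences in the test suite.

## Training

Loss: `w_l2 * MSE + w_perc * MSE(F(pred), F(target))` with `w_l2 = 1`,
`w_perc = 0.1` (defaults; the weighting is not prescribed). The perceptual
extractor `F` is a frozen, seed-determined random 3-layer convolutional
network: random fixed features penalise structural discrepancies (edges,
texture) rather than per-voxel intensity and keep the package free of
downloaded weights; a differently configured extractor is a config option.

One model is trained on slab pairs pooled over *all* short durations
against the 600 s target — no duration conditioning — with Adam, batch
size 5, initial learning rate 3e-4 annealed by a cosine schedule (no
restarts) from full value at epoch 0 to 0 at the last epoch, 400 epochs at
full scale. Cross-validation folds are drawn at patient level (K = 10),
pairwise disjoint with sizes differing by at most one, so no patient's
slabs appear on both sides of a fold.

The desk profile used by the tests and the acceptance script scales the
problem to one CPU: 32 x 32 x 5 slabs, 24 training + 6 validation
phantoms, 40 epochs, and a small network (base width 8, 2 scales, 1
residual module per scale). These sizes are the package's study
conditions for the qualitative claims (restoration beats raw input;
CT fusion helps most at 6-15 s); they do not reproduce clinical-scale
metric values.

## NLM baseline

Slice-wise 2D non-local means with a 27 x 27 search window and 3 x 3
patches (the printed parameters are 2D). Each output pixel is the
`exp(-d2/h^2)`-weighted average of its search window, `d2` the patch-mean
squared difference, borders edge-replicated. The filtering strength `h`
defaults to 0.8x a robust per-slice noise estimate (wavelet-domain median
absolute deviation), since no strength is prescribed. The sweep-by-offset
implementation is held pixel-exact to a direct quadruple-loop oracle.

## Evaluation

PSNR uses `10 log10(V^2 / MSE)` with V the maximum of the *evaluated*
image (a reference-max option exists for cross-tool comparison); identical
images return an infinite-PSNR flag. SSIM is computed from global volume
moments with stabilizers `a1 = 1e-6`, `a2 = 3e-6` — the global form, not
the sliding-window variant (offered as an option), and on the [0, 1]
normalized scale where those stabilizers are meaningful. The 2D
correlation is the per-axial-slice Pearson coefficient averaged over
slices, skipping (and counting) degenerate constant slices.

Semiquantitative reading uses 2 cm circular ROIs whose membership is
decided by voxel-center distance in millimetres (~57 voxels at 2.34 mm
pitch); SD is the population SD; ROI objects are geometric descriptors, so
the ROI drawn on the reference transfers unchanged to every group. LBR is
lesion SUVmax over liver SUVmean. Lesion masks threshold the reference at
SUV >= 5 (inclusive); voxel-wise SUV differences inside the mask give the
distribution samples. Bland-Altman agreement is bias +/- 1.96 sample-SD.
Group reports carry descriptive paired-difference summaries only —
inferential testing (paired t, Kruskal-Wallis, post hoc corrections) is
deliberately out of scope.

## Numerical choices and degenerate inputs

FWHM-to-sigma 2.3548 (exact Gaussian identity); Poisson draws from numpy's
PCG64 with per-stage sub-seeds (CRC32 of the stage name mixed with the
global seed, kept below 2^31); descriptors outside the grid, non-positive
durations, even NLM windows, empty training sets, all-zero normalization
collections and sub-5-slice inputs all fail loudly with specific errors.
Identical seeds give bit-identical volumes and training histories on one
machine.

## Known limitations

- The noise model is voxel-independent before the postfilter; real
  reconstructed PET noise is spatially correlated and object-dependent.
- Phantom anatomy is piecewise-constant ellipsoids/spheres; there is no
  texture, breathing motion or tracer heterogeneity.
- The perceptual loss uses random features, not a pretrained perception
  network; its weighting was fixed a priori, not tuned.
- Desk-scale results are qualitative orderings, not clinical effect sizes;
  full-scale (256 x 256, 400-epoch) training is configured but not exercised
  by the test suite.
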