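# Methods

`orthosyn` reconstructs a volumetric synthetic CBCT (sCBCT) of the male
pelvis from two orthogonal 2-D projections (DRRs at gantry 0° and 270°)
plus the patient's planning CT (pCT), trained with an anatomically
informed loss. This note records the models, the assumptions behind them,
the tunable parameters, and the design decisions taken where the design
was genuinely open.

## The reconstruction problem

In image-guided radiotherapy the daily anatomy (bladder filling, rectal
gas, small prostate shifts) must be verified before each fraction.
Volumetric CBCT gives that information but is slow and adds imaging dose;
a pair of orthogonal kV projections is fast and cheap but only 2-D. The
framework treats daily-volume synthesis as conditional image translation:
the pCT supplies the patient-specific 3-D prior, the two projections
supply the daily state, and an encoder-decoder network fuses them into a
volume on the pCT grid.

## Network family

One implementation realises four variants by switching flags:

| variant          | 3-D encoder | skip connections | residual decoder |
|------------------|-------------|------------------|------------------|
| `drrs_only`      | –           | –                | –                |
| `fusion`         | ✓           | –                | –                |
| `fusion_skip`    | ✓           | ✓                | –                |
| `fusion_skip_res`| ✓           | ✓                | ✓                |

Encoders stack `Enconv` blocks (stride-2 3×3(×3) conv → instance norm →
ReLU → stride-1 conv), doubling channels per level from `base_channels`.
The 2-D branch consumes the two DRRs as a 2-channel image. At the
bottleneck the 2-D latent's channel axis is split into (channels, depth)
to match the 3-D latent grid — a pure reshape that conserves every
element — the two latents are concatenated and mixed by a 1×1×1
"transform" convolution. The decoder mirrors the encoder with trilinear
×2 upsampling blocks; skip variants concatenate the matching encoder
level, and the residual variant adds an identity path around each conv
stack (1×1×1 projection when channel counts differ). A 1-channel 1×1×1
conv with a sigmoid bounds the output to the normalised [0, 1] intensity
domain. Open details of the reference architecture (output activation,
exact channel schedule, residual projection) were resolved to these
standard choices.

The networks, the differentiable projector and the losses run on a
compact reverse-mode autodiff engine written for this package
(`orthosyn.grad`/`orthosyn.nn`): float64 numpy throughout, so every
forward/backward pass is deterministic bit-for-bit on CPU, which the
determinism contracts of training and evaluation rely on. Every operator
carries a finite-difference test.

## Losses

The anatomically informed loss is

    L = α·MAE + β·PL + γ·PL_DRR + ω·PL_structures

with flagship weights (α, β, γ, ω) = (1, 0.05, 0.01, 0.04) and the
ablation presets onlyMAE (1,0,0,0), onlyPL (0,1,0,0), MAE&PL (1,0.02,0,0)
— pure weight settings, no separate code paths.

* **MAE** — voxel mean absolute error on the normalised volumes.
* **PL** — "2.5-D" perceptual loss: all axial and all sagittal slices are
  triplicated to pseudo-RGB and passed through a VGG19-topology feature
  extractor; the feature-space MSE at layer taps 3, 8, 15, 22 is averaged
  over slices, layers, and elements. Layers are weighted equally and the
  two orientations average with equal weight (per-slice weighting was an
  open choice; equal weights are the least-informative default).
* **PL_DRR** — the synthesised volume is re-projected through the
  differentiable DRR operator and its two views are compared to the input
  DRRs with the same perceptual distance, tying the output back to the
  daily projections.
* **PL_structures** — PL after multiplying both volumes by the
  *unified mask*: the union of PTV, bladder and rectum dilated 3 voxels
  with a 26-connected 3×3×3 element (the dilation depth is in voxels; an
  isotropic-mm alternative was considered and rejected as the grids here
  are near-isotropic).

The feature backbone is pluggable. The default is a *seeded random-weight*
CNN with the VGG19 feature-stage topology, width-scaled (channel schedule
scaled by `width/64`, default width 8): random-feature perceptual losses
are a recognised deterministic choice, need no downloaded weights, and
every structural property (non-negativity, zero at identity, symmetry of
the feature MSE) holds for any backbone. A pretrained VGG19 can be
plugged in where torchvision is available; its ImageNet input statistics
are then applied, whereas the seeded backbone takes [0, 1] inputs
unchanged.

## DRR operator

Parallel projection: the *mean* of voxel values along the ray axis
(0° = anterior, rays along y; 270° = left lateral, rays along x; IEC
gantry convention for a supine patient). The mean rather than the sum
keeps DRR magnitudes comparable across grid sizes, and since each view is
min-max normalised afterwards the two conventions are observationally
equivalent downstream. Views are bilinearly resized to the raster
(half-pixel-centred sampling; an exact identity at native raster) and
normalised last, so network inputs span exactly [0, 1]. The operator is
linear before normalisation and conserves mass (mean × ray length = volume
sum); both laws are asserted in tests, as is agreement of the plain and
differentiable paths bit-for-float.

## Preprocessing

HU volumes are clipped to [−1000, 2000] and min-max normalised per
volume; the clipped (min, max) pair stays attached to the volume so
HU-domain metrics can invert the mapping. A constant volume normalises to
zeros with a warning rather than NaN — degenerate inputs must not poison
a training run. Augmentation draws integer translations (≤ 5 voxels per
axis) and axial rotations (≤ 4°), applied identically to the CBCT
(linear interpolation, air fill) and its masks (nearest neighbour,
re-binarised); rotation is about the slice normal only, the standard
setup-error analogue. The ±5-voxel envelope is defined at the reference
1.98 mm raster (≈ ±10 mm of anatomy); on coarser desk grids the draw
range is reduced accordingly (±1 voxel at 8 mm spacing) so the physical
augmentation magnitude — not the voxel count — is preserved. Without
this scaling, ±5 voxels at 8 mm is a ±40 mm shift, and miniature
training runs collapse to the constant-background prediction (the MAE
median of a mostly-air target) and cannot escape it. DRRs are rendered from the *augmented* CBCT, before
the central-region masking. The central-region mask keeps the centred
(X, Y/2, Z) box (the treatment region); the pCT/CBCT working volumes are
multiplied by it, and evaluation masks are intersected with it so scored
voxels are exactly the voxels the model is trained on. Coordinates are
0-based (x, y, z) = (left-right, anterior-posterior, superior-inferior);
crop windows are half-open with odd margins floored.

## Synthetic phantom cohort

Clinical pCT/CBCT cohorts are not shareable, so the generator builds
analytic pelvic phantoms: an elliptical body cylinder, a pelvic bone
ring, and ellipsoidal bladder, prostate (PTV) and rectum (a tube along
z), rasterised on the voxel grid with per-patient size/position jitter.
Organ masks are derived from the same primitives with priority
PTV > bladder > rectum > bone, so every mask is exactly consistent with
the painted HU (bladder 10, prostate 45, rectal content 25, soft tissue
40, bone 700, gas −950, air −1000) and organ volumes are analytically
checkable — doubling the commanded bladder volume doubles the voxel count
to within discretisation.

Per-fraction variation replays the dominant pelvic changes: bladder axes
scaled by `scale^(1/3)` (volume × scale, log-normal draw clipped to
[0.5, 2]), a rectal gas pocket occupying the anterior fraction of the
lumen (present in ~60 % of fractions, up to 60 % of the lumen), rectum
radius ±25 %, and prostate shifts of a few mm. The CBCT domain gap is
additive Gaussian noise inside the body (default σ = 20 HU) plus an
optional global intensity offset. Fractions come pre-aligned (rigid
registration is assumed done upstream). The literature gives no
quantitative inter-fraction variability distribution for this setting;
these ranges were chosen once as clinically plausible magnitudes and are
not tuned thereafter.

What the phantoms do **not** emulate: CT physics (beam hardening,
scatter, cone-beam artifacts), deformable organ interaction, couch and
immobilisation hardware, real kV projection noise. Passing tests
therefore demonstrate that the pipeline's operators, contracts and
statistics are correct and that the network can learn the synthetic
mapping — not clinical image quality.

## Training protocol

AdamW (β₁ = 0.9, β₂ = 0.999, ε = 1e−8, weight decay 1e−2), initial
learning rate 1e−3, batch size one, Kaiming-He-uniform initialisation
(seeded; bound √2·√(3/fan_in)), 40 epochs by default. The output head's
draw is damped by 0.01 so the sigmoid starts near 0.5: most of the masked
target volume is air at normalised 0, the L1 term's optimal *constant*
is therefore 0, and a head that saturates there before spatial structure
is learned has vanishing sigmoid gradients and never recovers — observed
as an unrecoverable all-background collapse without the damped
initialisation. The learning rate
divides by 10 after 5 consecutive epochs without relative
validation-loss improvement above 1e−4 ("improvement" is relative —
the absolute/relative choice was open — and the reduction fires on the
epoch that *reaches* the patience count), floored at 1e−6. The
checkpoint with the lowest validation loss is kept. An epoch is one
shuffled pass over all (fraction, pCT) training pairs with augmentation
resampled online; validation is un-augmented. A non-finite loss aborts
with the offending component named — reproducibility is preferred to
robustness at this scale. Runs are a pure function of (config, seed).

## Evaluation

mMAE, mSSIM and mPSNR are computed in HU (inverting the stored
normalisation record) and averaged over the body-contour voxels
(intersected with the central-region box when that masking is active).
mSSIM uses 7×7×7 uniform windows, c₁ = (0.01·L)², c₂ = (0.03·L)² with L
the ground-truth dynamic range — the only self-consistent reading of the
constant conventions — reflection padding at boundaries, and attributes
each window to its centre voxel. mPSNR uses the ground-truth maximum;
identical inputs return an `inf` sentinel. cLPIPS is a perceptual patch
distance on the extracted central core of the normalised volumes: axial
slices, pseudo-RGB, channel-unit-normalised features at the same taps,
equal layer weights (no learned calibration), averaged over slices.
Every metric is validated against an independent brute-force masked
implementation on small random volumes.

Ablation comparisons use Shapiro-Wilk screening, Kruskal-Wallis, and
Dunn's post-hoc z-test (pooled tie-corrected rank variance) with
Bonferroni adjustment, starred *p < 0.05, **p < 0.01, ***p < 0.001.
Note an intrinsic limit of rank tests: with four groups the maximal
adjacent rank separation bounds the adjacent-pair z-statistic, so
adjacent pairs cannot reach p < 0.001 at n = 30 regardless of effect
size.

## Desk-scale defaults and known limitations

The package's default problem sizes are chosen so the entire pipeline —
cohort generation, four-way loss ablation, evaluation, statistics — runs
on one CPU in minutes: 32×32×16 voxels at 8 mm (64×64×32 at 4 mm for the
mid-scale), DRR raster equal to the axial grid, `base_channels` 8, and a
width-8 feature backbone. The reference-scale configuration
(128×128×64 grid, 128×128 raster, `base_channels` 64) is reachable purely
through configuration; nothing in the code is specific to the small
grids.

Early in training the model passes through an "all-background" basin
(most of the masked target volume is air at normalised 0), so very short
runs produce near-constant outputs; single-case overfitting escapes it
within a few hundred steps. Other known limitations: the DRR model is
parallel-beam without noise or scatter, so real kV projections are out of
scope; the DRR raster must currently equal the first two volume axes so
the latent grids align; and the seeded random backbone, while a valid
perceptual metric family, is not calibrated to human judgements the way
a pretrained LPIPS network is.
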