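# Methods

## The phantom model

The simulator emulates the *output* of a standard resting-state preprocessing
chain rather than raw scanner data: voxel time series are mean-centered,
band-limited, and optionally globally regressed. Its generative model:

- Each of K networks owns one latent time course: white Gaussian noise,
  brick-wall low-pass filtered below `lowpass_hz` (default 0.1 Hz at the
  scan's TR, default 2.2 s), standardized to unit variance. Latents are
  correlated across networks according to `cross_network_corr` (default
  identity, i.e. independent networks); the factor is taken from an
  eigendecomposition so rank-deficient correlation matrices (exact duplicate
  networks, used to exercise tie handling) are reproduced exactly.
- ROI voxels carry `within_network_weight` × their network's latent (default
  1). Background in-mask voxels carry a random unit-norm mixture of all
  latents at 0.3 × that amplitude — real gray matter is never signal-free, and
  this makes label confirmation and background classification non-trivial.
- Every in-mask voxel receives independent 1/f^`pink_exponent` noise
  (default exponent 1, SD `noise_sd` = 1), generated by spectral shaping, so
  the default per-voxel SNR is 1 and the within-network voxel-pair
  correlation is w²/(w²+σ²) = 0.5.
- Subjects differ by an amplitude factor 1 + `subject_jitter`·ε (default
  jitter 0.1) and by independent noise; per-subject generator substreams are
  derived from the master seed by name, so subject i's scan is invariant to
  cohort size.

Defaults were chosen once as plausible desk-scale study conditions: 16³ grids
with an ellipsoidal "gray-matter" mask (~1,700 voxels), 4 networks × 3
spherical ROIs of radius 1, 8 subjects, 300 frames at TR 2.2 s. The
`global_signal_regression` flag defaults to off so that independent networks
correlate at exactly zero in expectation; switching it on reproduces the
negative between-network correlations characteristic of globally regressed
data and is used by the connectivity analyses.

What the phantom does **not** emulate: spatial autocorrelation (no smoothing
kernel), head motion, scanner drift, physiological confounds, anatomical
geometry, or demographic structure. Passing tests therefore demonstrate the
pipeline's correctness and its robustness behavior under planted covariance
with independent voxel noise — not performance on real brains.

## Similarity samples

Both channels are deliberately scale-free so that truncated scans produce
in-distribution inputs: Pearson correlation is length-normalized by
construction, and the Euclidean channel is computed between sample-SD
(ddof = 1) z-scored series and divided by √T. Under this convention the two
channels are linked by the exact identity ‖z_a − z_b‖ = √(2(T−1)(1−r));
`similarity_map()` computes the norm directly while the all-voxel inference
path uses the identity, and a test pins their agreement at 1e−10.
Zero-variance series get r = 0 and are compared against the zero vector for
the distance; a zero-variance *seed* is an error.

Label confirmation re-derives the seed's network as the argmax correlation
with each network's mean ROI signal; a disagreeing draw is discarded and
redrawn (never relabeled), and an exact tie is an error. Augmentation is
applied once, in place, to training-split samples at set construction;
validation samples stay clean. The affine is composed as
Rx·Ry·Rz·Shear about the volume center with trilinear interpolation and zero
fill, followed by intensity scaling, additive Gaussian noise (SD 0.01),
re-clipping of the correlation channel to [−1, 1] and the distance channel to
≥ 0, and re-masking.

## Classifier

The architecture is a parameterized template; the default desk configuration
is 3 dense blocks × 2 units, growth 8, in 2 → 50 feature channels. One unit
is a 1³ bottleneck (concatenated state → growth channels) followed by 3³ and
7³ residual convolutions at constant width, each convolution preceded by
batch normalization and followed by a leaky ReLU (slope 0.01). Between
blocks, max- and average-pooled (2³, stride 2) maps are averaged element-wise
— a channel-preserving, parameter-free way to combine the two. Each block
feeds an auxiliary head (global average pooling → 20% dropout → linear →
softmax); a final 1³ feature layer (32 channels) feeds the main head, giving
blocks + 1 = 4 loss terms. The deep-supervision loss is the unweighted sum
over heads of class-weighted cross entropy with w_c = N/(K·n_c). Only the
final head is read at inference.

Numerical implementation: a compact reverse-mode autodiff over numpy in
channels-last layout. Small kernels use a direct per-offset matrix-product
convolution; kernels of width ≥ 5 use a spectral path (FFT cross-correlation
with gradients through the matching convolution/correlation theorems), which
is mathematically identical — a test pins the two paths to 1e−10 — and an
order of magnitude cheaper for 7³ kernels on 16³ grids. Training uses Adam
(lr 3e−3, batch 32, optional decoupled weight decay), float32 parameters,
and is fully reproducible given the schedule seed; a float64 switch exists
for finite-difference gradient checks.

Two training-loop details matter on small phantoms:

- **Batch-norm recalibration.** With few steps and fast-moving weights, the
  exponential running statistics lag the population statistics and the drift
  compounds across layers, collapsing evaluation-mode accuracy. Before every
  validation the running statistics are replaced by population statistics
  from one forward pass over a fixed, evenly spaced calibration subset of the
  training split (≤ 128 samples) with momentum forced to 1 — self-consistent
  because each layer is then normalized by the very statistics that become
  its evaluation statistics.
- **Checkpoint tie-breaking.** Early stopping follows the strict rule — stop
  after `patience` = 3 consecutive validations without improvement in
  held-out accuracy — but on easy phantoms accuracy saturates at 1.0 within
  two epochs, and the *first* saturated checkpoint is poorly converged.
  Among checkpoints of equal accuracy the one with the lower validation loss
  is kept; this selects better-calibrated models and markedly stabilizes the
  downstream probability maps.

## Inference and group maps

Every in-mask voxel is its own seed; the all-pairs correlation and distance
matrices are computed once per scan and each voxel's 2-channel volume is
classified in batches. Zero-variance voxels receive the uniform vector 1/K.
Group maps use the sample SD (n−1); mean/SD is defined as 0 where the SD is
numerically zero (≤ 1e−12) so group maps stay finite. WTA assigns argmax + 1
where the peak probability reaches the threshold (default display threshold
0.2; area computations use threshold 0), with exact ties broken to the lowest
network index. Recovery of the planted structure is scored as per-network
Dice over the ROI support: background voxels carry deliberate latent mixtures
and have no planted label, so they are not counted against recovery.

## MS-SSIM

Volumes are compared at box-average downsamplings (default factors 2, 4, 8,
16, 32; a helper drops factors that do not leave at least 2 voxels per
dimension — on 16³ grids the usable set is 2, 4, 8). At each scale the
standard windowed luminance/contrast/structure statistics are computed under
a Gaussian window (width 7 clipped to the volume, SD 1.5) over all fully
contained windows, with stability constants c1 = (0.01 L)², c2 = (0.03 L)²
and L the joint max − min of the two volumes (so probability maps and raw
volumes use one convention, and joint positive rescaling leaves the score
invariant). Per-scale mean scores are combined by a **weighted arithmetic
mean** with Gaussian weights over the scale index (SD 1, peaked at the middle
factor, normalized). The more common product-of-powers combination is
ill-defined for negative per-scale scores; the weighted mean keeps the score
in [−1, 1], equal to 1 exactly for identical volumes, and symmetric.

## Robustness and connectivity protocols

Frame truncation keeps the first n frames. Noise injection follows the
interval-rescaling recipe: per voxel, the signal is affinely mapped so its
min/max hit ±(1−f), an independent pink-noise series is mapped to ±f, and the
two are summed — at f = 0.1 the signal spans exactly [−0.9, 0.9] and the
noise [−0.1, 0.1]. Robustness curves report the MS-SSIM between each
network's probability volume from the degraded scan and from the reference
scan, averaged over networks (per-network curves are kept alongside).
Connectivity matrices correlate softmax probability vectors (or BOLD series)
across ROI voxels or ROI means, ordered by network; voxel-level nodes are the
atlas ROI voxels, which carry a network identity — background voxels have
none and are excluded from block statistics.

## Known limitations

- Probability maps over the phantom *background* are intrinsically less
  stable than over ROI voxels: background similarity patterns resemble no
  training sample (training seeds are always network-ROI averages), so the
  classifier extrapolates confidently on ambiguous inputs, and shortening the
  scan can move a contiguous share of background voxels across a decision
  boundary. Real gray matter, which is tiled by networks, does not have this
  out-of-distribution population; the frame-truncation similarity on phantoms
  should be read with that caveat. Weight decay and the loss tie-break above
  mitigate but do not remove the effect.
- The architecture is a desk-scale template of the stated motifs, not a
  reproduction of any particular large instantiation; optimizer and schedule
  values are package defaults, logged with every run.
- MS-SSIM scale weights follow the standard Gaussian-peaked construction; the
  exact weight values used elsewhere are not public.
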