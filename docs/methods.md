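# Methods

## Problem and pipeline

Fissure integrity quantifies how much of a lobar boundary is an actual
pleural fissure. The package treats it as 3-class voxel labeling on the
*complete fissure* — the whole boundary surface between the lobes adjacent
to a fissure — followed by counting:

FI% = 100 · |intact| / |intact ∪ incomplete|.

The pipeline per case and fissure: isotropic resampling (1 mm default) →
HU clip to (−1024, 200) and affine rescale to [−1, 1] → per-lung bounding
box crop (2-voxel margin) → 2-channel input (CT, fissure probability) →
attention U-Net → argmax labeling → three-step cleanup → metrics. The
right-lung input is used twice, once for the right oblique and once for
the right horizontal fissure; each fissure has its own independently
trained network.

## Complete fissure extraction

The surface is the set of voxels of a designated *reference* lobe that are
face-adjacent (6-connectivity) to the partner lobe: LOBL uses LUL against
LLL; RHOR uses RUL against RML; ROBL takes the union of RML-against-RLL
and RUL-against-RLL (the right oblique fissure touches the lower lobe both
anteriorly and posteriorly). One-sidedness keeps the surface one voxel
thick; because FI% is a ratio over the same surface, the one- vs two-sided
choice largely cancels, and a `two_sided` flag provides the alternative.
6-adjacency is used because it yields the thinnest well-formed digital
surface; 26-adjacency would thicken corners. Voxels at the right-lung
triple junction may belong to both ROBL and RHOR surfaces; each fissure is
assessed independently, so they are retained in both.

## Network

A 3D attention U-Net: `levels` encoder steps (default 4), two 3×3×3
convolutions + instance normalization + ReLU per level, channels doubling
from `base_filters` (default 16), 2× max-pool down, nearest-neighbor up.
Skip connections pass through additive attention gates — 1×1×1 projections
of the skip features and of the coarser decoder features (upsampled),
added, ReLU, 1×1×1 projection to one channel, sigmoid — whose coefficient
map multiplies the skip features. A 1×1×1 head and channel softmax give
per-voxel probabilities for background / intact / incomplete. Inputs must
be divisible by 2^levels; prediction pads (CT channel with −1, probability
with 0) and strips the padding afterwards.

Instance rather than batch normalization: batches of 2 volumes give very
noisy batch statistics, and instance norm makes inference deterministic
and batch-size independent. Upsampling is nearest-neighbor for exact
gradient bookkeeping in the in-package autodiff. These internal choices
(as well as the exact filter counts) are this package's defaults, not
claims about any other implementation.

The compute core is a small tape-based reverse-mode autodiff over numpy
(im2col convolutions, float32), with Adam. Gradients of the full model are
verified against central finite differences in float64 in the test suite
(relative tolerance 1e-4; conv biases that feed instance norm have true
gradient 0 there, since the norm subtracts any constant shift).

## Loss

Tversky loss per class c:

TI_c = (Σ p_c g_c + s) / (Σ p_c g_c + α Σ p_c (1−g_c) + β Σ (1−p_c) g_c + s),
loss = Σ_c (1 − TI_c),

with α = 0.05, β = 1 − α = 0.95, stabilizer s = 1.0 so empty classes give
TI = 1 rather than 0/0. The background class is included in the sum with
uniform weight. At α = β = 0.5 each term reduces to soft Dice (asserted in
tests against an independent implementation). β ≫ α makes a missed
fissure voxel ~19× costlier than a spurious one, which is what a thin,
heavily outnumbered foreground needs.

## Training

Adam with a static learning rate (default 2e-4), batches of random
fixed-size crops (default (128, 128, 64)); crops smaller than the lung are
padded with the channel background (−1 / 0 / label 0). Because the surface
is a thin sheet, a purely uniform crop often contains no foreground, so
with probability `fg_crop_prob = 0.5` a crop is constrained to contain at
least one surface voxel (switchable). Per-epoch validation loss selects
the best epoch (ties to the earlier epoch); weights are restored to that
epoch after training. Splits are always at the subject level: a 0.75 /
0.15 / 0.10 train/test/validation partition by largest-remainder rounding,
and k-fold cross-validation (k = 8) in which each fold's training portion
carves out its own 0.10 validation share — the reading adopted for
combining a fixed split ratio with k-fold evaluation. The "best epoch"
criterion is minimum validation Tversky loss.

Crops per case per epoch defaults to 4 and batch size to 2; both are
configurable and the scaled study below uses smaller values.

## Post-processing

Three steps on the raw argmax labeling, all with 26-connectivity:

1. *Remove false positives*: voxels off the complete fissure → background.
2. *Fill false negatives*: background voxels on the surface take the
   majority class among their intact/incomplete neighbors; synchronous
   passes (all updates computed from the previous state) until the surface
   is fully labeled or `fill_max_iters` is reached. Ties → incomplete:
   for collateral-ventilation screening it is safer to flag possible
   incompleteness than to mask it. Surface voxels unreachable from any
   label are assigned by nearest labeled voxel, computed per class with
   two distance transforms so distance ties follow the same tie rule.
3. *Smooth*: one simultaneous majority pass; by default a voxel's own
   label is excluded from its vote and ties (or isolated voxels) keep the
   original label; a `smooth_include_center` flag includes it.

Single-pass smoothing is not exactly idempotent: at a convex corner of a
label patch the neighbor majority can flip the corner voxel, so a perfect
labeling is a fixed point only up to such corners (< 0.5 % of surface
voxels on phantoms, < 2 FI% points). This is inherent to any one-pass
majority filter and is documented rather than hidden behind iteration.

## Phantom generator

Each case: two ellipsoidal lungs in a 0 HU body, parenchyma −850 HU, and
smooth graph surfaces z = f(x, y) (tilted plane + two sinusoids, random
slope/phase/amplitude) splitting the left lung into two and the right lung
into three lobes; where the near-axial horizontal surface dips below the
right oblique surface the middle lobe pinches out, reproducing the double
adjacency of the right oblique fissure. On each boundary surface a
contiguous patch — grown geodesically from a peripheral seed, since real
incompleteness is typically peripheral and contiguous — is marked
incomplete: there the −650 HU fissure sheet is absent and the probability
map is low. The probability map is the blurred (σ = 1 voxel) indicator of
the visible sheet, rescaled so a planar sheet keeps a peak near 1, clipped
to [0, 1]. Gaussian CT noise (SD 30 HU) is drawn from a separate noise
seed so the same geometry can be regenerated under fresh noise. Default
gap fractions 0.10 / 0.08 / 0.32 (LOBL / ROBL / RHOR) follow the cohort
completeness reported in the fissure literature: oblique fissures mostly
complete, the right horizontal fissure the least complete and most
variable.

What the phantom does *not* emulate: airways and vessels, accessory
fissures, emphysema and other parenchymal disease, scanner/protocol
variation, segmentation errors of the upstream lobe pipeline, and motion
artifacts. Passing the phantom studies therefore demonstrates that the
pipeline's machinery — learning, cleanup, counting — recovers known truth
under controlled contrast and noise; it does not certify clinical
accuracy.

## Scaled study configuration

The reference end-to-end experiment (`recovery_study`, also run by
`scripts/acceptance.py`) is sized for minutes on one CPU: 40 phantoms on
64×64×32 grids with gap fractions uniform in [0, 0.8]; 30 training cases
(3 of them carved out for validation) and 10 test cases; per-fissure
networks with 3 levels and 8 base filters; 32×32×16 crops, one crop per
case per epoch, batch 4, 12 epochs, learning rate 1e-3 (the compact
network on a short schedule takes larger steps than the full-size 2e-4
default). The reproducibility arm regenerates the 10 test phantoms with
identical geometry seeds and fresh noise seeds and compares predicted FI%.
All randomness derives from the single study seed.

## Numerical conventions

- Sample (n−1) standard deviations everywhere; a single observation
  reports SD 0.
- FIS error aggregates as the mean of absolute values (signed mean also
  emitted); cases with ground-truth FI% = 0 are excluded from FIS-error
  aggregation and counted separately.
- AUC is the rank (Mann–Whitney) statistic with ties counted ½, predicted
  FI% as the score and the "complete" category as positive.
- Reproducibility differences are absolute FI% differences in percentage
  points, not relative errors (a relative variant is available).
- Category thresholds are closed on the left: FI% = 90 is complete,
  FI% = 10 is partial.
- Volumes are reoriented to canonical anatomical axes at load; all volumes
  of a case must share one grid within 1e-3 mm after resampling.

## Known limitations

- The numpy compute core is CPU-only and single-threaded; full-size
  (128, 128, 64) training at 16 base filters is feasible but slow — the
  package's studies use the scaled configuration above.
- Only the standard five-lobe anatomy is modeled; accessory fissures and
  anatomic variants are out of scope.
- DICOM ingestion and inter-volume registration are out of scope; inputs
  must already be aligned.
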