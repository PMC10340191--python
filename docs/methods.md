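# Methods

## Architecture

The network keeps a high-resolution representation alive end to end.  A stem
of two stride-2 3×3 convolutions (3→64→64 channels by default) reduces the
input to 1/4 scale.  Stage 1 applies `stage1_blocks` residual bottleneck
units (1×1 down, 3×3, 1×1 up).  Stages 2–4 each spawn one additional branch
from the lowest existing one via a stride-2 3×3 convolution — half the
resolution, twice the width — then run `modules_per_stage[s] ×
blocks_per_module` multi-scale attention blocks per branch, followed by a
dense fusion layer in which every stream receives additive contributions
from every other stream (repeated stride-2 convolutions downward; stride-2
3×3 transposed convolutions upward, with padding/output-padding chosen so an
upsampled map exactly doubles in side and lands on the target resolution).
Fusion performs no extra activation, so zeroing all cross-resolution paths
into a stream makes fusion the identity for it — a property the tests use
as an oracle.

A multi-scale attention block is: dynamic conv → BN → ReLU → dynamic conv →
BN → coordinate attention → add identity skip → ReLU.  Only these two 3×3
convolutions per block are dynamic; stem, transitions, fusion and head use
standard convolutions.  The head walks the pyramid from high to low
resolution: stride-2 downsample to a ladder width, concatenate with the next
stream, fuse with a 1×1 convolution back to the ladder width (for the
literal layer-table profile the ladder equals the branch widths 96/192/384);
then a 1×1 convolution to 2048 channels, global average pooling, 2048→512
and 512→N linear layers, and an elementwise logistic.  Outputs are N
independent probabilities; no softmax, because findings co-occur.

Where the published layer table is ambiguous we read it literally and make
the choice configurable: stage 1 keeps its stated output width (canonical
high-resolution networks expand it; the `stage1_width`/`stage1_out` fields
expose both readings), module counts are uniform per stage by default, and
cross-resolution exchange is dense (all pairs) as the architecture diagram
draws it.

## Dynamic convolution

Each dynamic layer holds `num_experts` = 3 kernels of standard shape and a
routing function sigmoid(FC(GAP(x))) with bias and no hidden layer, no
temperature, and no normalization across experts — mixtures need not sum to
one.  Aggregation builds the per-sample kernel Σᵢ αᵢWᵢ (a batched matmul on
im2col patches); by linearity of convolution this equals the α-weighted sum
of per-expert convolutions, and the test suite asserts that identity to
1e-5 as well as agreement with an explicit per-sample loop.

## Coordinate attention

Row means and column means per channel are concatenated along the spatial
axis, passed through a shared 1×1 convolution to `C/ca_reduction` channels
(floored at 1, with a warning when the division is not exact), batch norm,
hard-swish, then split and restored by two separate 1×1 convolutions (F_h,
F_w do not share parameters) whose sigmoid outputs gate the input.  Gates
are clamped to [1e-7, 1−1e-7] so they are numerically strict members of
(0,1) even under float32 saturation; the same clamp applies to all logistic
outputs in the package.  The default reduction is 32, the canonical
setting; the calibrated profile (below) sets 1.

## Weighted focal loss

Focal loss with class-balance α = 0.25 and focusing exponent γ = 2;
probabilities are clamped to [1e-7, 1−1e-7] before the logarithms.  Class
weights are wᵢ = (1/aᵢ)/Σⱼ(1/aⱼ) where aⱼ is class j's binary accuracy at
threshold 0.5 on the validation split in the previous epoch — validation
rather than training accuracy, to avoid a feedback loop with the quantity
being optimized.  Accuracies are floored at 0.05 so early rounds cannot
blow up a weight.  Weights are Σ-normalized (sum to one); an optional
`rescale_n` flag multiplies by N so the mean weight is 1, since the printed
form of the weighting is ambiguous between the two scalings.  Epoch 1 uses
uniform weights — there is no previous round.  With uniform weights the
weighted loss equals the plain summed focal loss divided by N exactly.

## Training loop

Adam (0.9, 0.999), initial learning rate 1e-3, constant by default; batch
size configurable (64/128 are the studied values); maximum 80 epochs.
"Stop when the validation loss is stable" is operationalized as: stop when
validation loss has not improved by more than 1e-4 for 10 consecutive
epochs.  The best-validation parameters are checkpointed together with the
full network configuration, and loading verifies configuration equality.
All randomness (init, shuffling, augmentation) derives from one integer
seed; a run is bit-reproducible on a fixed platform.

## Profiler and the calibrated profile

Parameters are counted by enumerating trainable arrays.  FLOPs are analytic
per-layer multiply–accumulate counts at a stated input size, with 1 FLOP =
1 MAC; batch norm, activations and elementwise gating are not charged.  For
dynamic convolutions the default convention charges each expert's
convolution separately plus the routing affine — the multi-branch view of
the layer, which is what the published compute budgets reflect; the
aggregated-kernel convention (one convolution + routing + kernel mixing) is
available as a switch and describes actual runtime work.

The literal layer-table widths (48/96/192/384 with 4×4 blocks per stage)
produce a network several times larger than the published 20.9 M-parameter
baseline budget, so the package ships a second, calibrated profile whose
widths and depths were fixed once against the three published budget rows
and then frozen: branch widths 11/22/44/88, modules per stage (5,1,1) with
4 blocks per module, stage-1 bottlenecks at internal width 144 expanding to
576, head ladder (320, 1920, 384), attention reduction 1.  This profile
reproduces 21.24/23.53/23.73 M parameters and 9.85/11.06/11.06 G FLOPs for
the baseline / +dynamic-convolution / full variants at 256×256.

One structural limit is worth stating: with dynamic convolution applied to
the two 3×3 convolutions of every multi-scale block and coordinate
attention in the same blocks, the two parameter increments are coupled —
the attention increment can be at most 1/12 of the dynamic-convolution
increment (three 1×1 convolutions of C·C/r parameters against 2×2 extra 9C²
kernels, maximized at r = 1).  The published increments (+1.2 M attention
vs +2.2 M dynamic convolution) exceed that ratio, so no width/depth profile
can land on all three parameter rows simultaneously; the calibrated profile
places the first two rows within 2% and the full-model row at −2.3%.

## Synthetic data generator

The generator emulates the properties the architecture is designed around:
findings of characteristic size and location.  Each image is a
low-frequency Gaussian-filtered noise background with a mild vertical
intensity gradient; each active class adds one Gaussian-profile ellipse
whose scale is drawn from a class-specific range, whose center follows the
class's location prior ("center", "border", "any", or an anchor point —
defaults give every class a distinct anchor), and whose amplitude is the
class contrast.  Labels are multi-hot draws from a skewed prevalence vector
(0.30 decaying to 0.02 across the 14 classes, mirroring the strong class
imbalance of real CXR collections), with a co-occurrence boost adding one
extra finding to 15% of positive images.  Bounding boxes (center ± 2σ) are
recorded per lesion, and labels are emitted in the pipe-separated CSV
dialect so the file readers are exercised end to end.

What the generator does **not** emulate: anatomy (ribs, mediastinum),
projection physics, inter-class appearance similarity, label noise, and
correlated pathologies.  Passing the end-to-end tests therefore shows that
the architecture, losses, metrics and plumbing interoperate and can learn
location/scale/contrast-coded classes from images — not that the model
reaches any particular performance on real radiographs.

## Study sizes used by the test suite

The end-to-end checks run a miniature configuration (branch widths
8/16/32/64, one block per stage, stem width 16) chosen so the whole suite
completes on one CPU: learnability uses n = 2000 images at 64×64 for 10
epochs and asks for validation mean AUC ≥ 0.85; the loss-reweighting
comparison uses n = 1000 images at 32×32 for 14 epochs over five paired
seeds, with one class at contrast 0.15 (prevalence 0.5) against 0.8
elsewhere, and compares the per-class accuracy spread averaged over the
last three epochs — the averaging damps the jitter that a 0.5 decision
threshold induces on small validation splits.  Heatmap localization is
evaluated on the learnability run's images as the fraction of heatmap mass
inside lesion boxes versus the boxes' area fraction.

## Activation heatmaps

The heatmap is the channel-wise maximum of absolute activations of a late
feature map, min-max normalized and bilinearly upsampled to the input size.
In a multi-branch network "the last convolutional layer" is ambiguous; the
package defaults to the final high-resolution stream (1/4 scale) — the
representation this architecture maintains precisely so that spatial detail
survives to the classifier — because the alternative (the 2048-channel head
convolution at 1/32 scale) is too coarse to localize at small input sizes.
Both are exposed (`layer="highres"`/`"head"`), and a gradient-weighted
variant is intentionally not provided: the implemented procedure is purely
activation-based.

## Other numerical choices

float32 arithmetic throughout; He-normal initialization; batch-norm
momentum 0.1 and epsilon 1e-5 with biased batch variance; convolutions
carry no bias (batch norm follows); ROC curves sweep all thresholds with
equal scores grouped and trapezoid integration (AUC equals the
pairwise-ranking statistic with ties counted one half); degenerate
confusion-metric denominators yield NaN and are excluded from macro
averages with a warning; a constant activation map yields an all-zero
heatmap.  The 7:2:1 split assigns 0.7/0.2/0.1 to train/test/validation in
that order, grouped by patient whenever patient identifiers exist so no
patient straddles splits; both patient-wise and image-wise modes are
available since the published description does not disambiguate.

## Known limitations

No GPU path and no multi-process data loading — the numpy implementation is
meant for desk-scale study, not for training on the full public datasets.
Uncertainty handling implements the two global policies (all-0 / all-1)
only.  Label-correlation modeling and label-noise handling are out of
scope.
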