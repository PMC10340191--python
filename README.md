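# hrcxr

Multi-label classification of chest radiographs with a high-resolution
multi-branch CNN that combines dynamic (conditionally parameterized)
convolution, coordinate attention, and a class-difficulty-weighted focal
loss.  The package targets researchers who study thoracic-disease
classifiers: it provides the full architecture, the two label-file dialects
used by the large public CXR datasets, an analytic compute profiler, a
synthetic lesion-image generator for controlled experiments, and a training
loop — all implemented on numpy with explicit forward/backward passes, so
every component is inspectable and runs on a plain CPU.

## The model

**Backbone.**  A stem of two stride-2 3×3 convolutions feeds a parallel
multi-resolution network: the high-resolution stream runs at 1/4 scale
throughout, and stages 2–4 each add a stream at half the resolution and
twice the width (for a 224×224 input the four streams sit at 56/28/14/7).
After each stage a dense fusion layer exchanges information between all
streams: stride-2 convolutions downward, stride-2 transposed convolutions
upward.  A progressive downsample–concatenate–fuse head collapses the
pyramid, and two linear layers emit N=14 independent logistic outputs (an
image may carry any subset of findings).

**Dynamic convolution.**  Each multi-scale block replaces its two 3×3
convolutions with an n-expert mixture (n = 3),

    y = (α₁W₁ + α₂W₂ + … + αₙWₙ) ∗ x,   αᵢ = sigmoid(FC(GAP(x))),

so the effective kernel adapts per sample while only one convolution's worth
of work is executed.  By linearity the aggregated-kernel output equals the
α-weighted sum of per-expert convolutions — an identity the test suite
checks to 1e-5 over random shapes.

**Coordinate attention.**  Features are mean-pooled along height and width
separately, passed through a shared 1×1 transform (batch norm + hard-swish),
split, and restored to two sigmoid gate maps g_h(i), g_w(j) that reweight the
input as y(c,i,j) = x(c,i,j)·g_h(c,i)·g_w(c,j) — attention that encodes both
channel importance and spatial position, matching how findings have
characteristic locations.

**Weighted focal loss.**  The focal loss
FL(p, y=1) = −α(1−p)^γ ln p, FL(p, y=0) = −(1−α)p^γ ln(1−p) (α = 0.25,
γ = 2) is weighted per class by the inverse of that class's accuracy from
the previous training round, normalized to sum to one, shifting capacity
toward the diseases the model currently classifies worst.

## Worked example

Profile the calibrated architecture (the profile whose widths and depths
were fixed against the published compute budgets; see `docs/methods.md`):

```
$ hrcxr profile
baseline              21.24 M params     9.85 G FLOPs @ 256
baseline+condconv     23.53 M params    11.06 G FLOPs @ 256
full                  23.73 M params    11.06 G FLOPs @ 256
```

The three rows are the plain multi-resolution backbone, the backbone with
3-expert dynamic convolutions in every multi-scale block (+2.29 M
parameters for the two extra kernel banks and routing affines per block),
and the full model with coordinate attention as well.  FLOPs are analytic
multiply–accumulate counts at 256×256×3 input, with each expert's
convolution charged separately for dynamic layers.

Train a miniature configuration on generated lesion images and evaluate it:

```python
from hrcxr.config import NetworkConfig
from hrcxr.data import SyntheticSpec, generate_synthetic_dataset
from hrcxr.train import train

cfg = NetworkConfig(branch_widths=(8, 16, 32, 64), modules_per_stage=(1, 1, 1),
                    blocks_per_module=1, stage1_blocks=1, stem_width=16,
                    ca_reduction=4, head_hidden=(128, 64), input_size=64)
ds = generate_synthetic_dataset(SyntheticSpec(), 2000, seed=42)
net, state = train(cfg, ds, max_epochs=10, batch_size=64, seed=0)
print([round(r["val_mean_auc"], 3) for r in state.log_rows])
```

prints the per-epoch validation mean AUC trajectory

```
[0.609, 0.749, 0.802, 0.832, 0.851, 0.862, 0.866, 0.872, 0.878, 0.879]
```

— the miniature network learns the 14 class-specific lesion signatures
(distinct locations, scales and contrasts) well past the 0.85 mark within
ten epochs on one CPU.  `hrcxr generate-data`, `hrcxr evaluate` and
`hrcxr cam` expose the generator, the ROC/AUC report and the activation
heatmap from the shell.

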