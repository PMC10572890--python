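# mincenet

Quantifying pork adulteration in minced mutton from RGB dish images with
lightweight attention CNNs and multi-part feature fusion.

## The problem

Minced pork — cheap, and often disguised with mutton-flavour essence and red
colorant — gets mixed into minced mutton at fractions that are hard to spot
by eye.  Given a top-down photograph of a compacted minced-meat sample in a
6 cm petri dish, the task is to regress the pork mass fraction
w ∈ {0.10, 0.20, 0.30, 0.40} g/g, for pork from three cuts (back, front
leg, hind leg) and for mixtures of cuts.  The audience is food-safety and
image-analysis researchers who want a fully reproducible, desk-scale
implementation of this pipeline: the original study's images are not
public, so the package ships a synthetic dish renderer that emulates them
(granular two-component speckle in a circular dish, cut-specific pork
colour, a tint knob for the essence/colorant masking, illumination noise).

## The models

Four backbone variants, built block by block with exact parameter
accounting (counts include batch-norm moving statistics, the framework
`summary()` convention):

| variant | structure | parameters |
|---|---|---|
| `resnet50` | bottleneck blocks, widths 256→2048, regression head | 23,589,761 |
| `invert_resnet50` | inverted residuals (expand→depthwise→project), widths 64→512 | 9,853,569 |
| `cbam_resnet50` | + one CBAM after every block | 26,122,337 |
| `cbam_invert_resnet50` | inverted residuals + CBAM | 10,016,349 |

The inverted residual swaps the bottleneck's narrow–wide channel plan: a 1×1
convolution expands to `4 × stage_width`, a 3×3 depthwise convolution
operates in the wide space, and a linear 1×1 projection comes back down —
58% fewer parameters than the plain backbone, while CBAM (sequential
channel + spatial attention, shared biased MLP at reduction 16, 7×7 spatial
kernel) adds under 2%.  For mixed-cut samples, the pooled last-layer
features of the three per-cut models are concatenated in series ("early"
fusion) and a small head is fine-tuned on mixed data with the
input-proximal stages frozen.

Everything runs on a compact NumPy forward/backward layer stack included in
the package (no deep-learning framework required); every layer is
gradient-checked in the test suite.

## A worked example

`python examples/04_parameter_accounting.py` prints:

```
resnet50               trainable   23,536,641   with statistics   23,589,761
invert_resnet50        trainable    9,783,553   with statistics    9,853,569
cbam_resnet50          trainable   26,069,217   with statistics   26,122,337
cbam_invert_resnet50   trainable    9,946,333   with statistics   10,016,349

inverted residuals cut the backbone by 58.23% (with CBAM: 61.66%)
CBAM adds only 1.65% to the inverted backbone

budget search over expansion 1-6 and three width ladders picks expansion 4,
widths (64, 128, 256, 512) (relative errors {'cbam_invert_resnet50': 0.00036,
'invert_resnet50': 0.00036})
```

The totals are recounted from the actual weight array shapes; the last line
is `resolve_invert_config` re-deriving the inverted-family configuration
purely from target parameter budgets.  The other examples walk the rest of
the pipeline: `01` renders the 96-dish synthetic study and shows the
pork-colour signal rising with the true fraction, `02` detects the dish ROI
(sub-pixel circle recovery) and augments it, `03` reproduces the split
arithmetic (1575/525/700 images per cut, 4725/1575/2100 mixed), `05` trains
a desk-scale attention regressor (validation R² 0.87 ratio-of-sums /
0.80 conventional, monotone mean predictions 0.105/0.183/0.286/0.347
across the four true ratios), `06` shows fusion +
transfer fine-tuning beating the best single-cut model on mixed samples,
and `07` demos the evaluation statistics (ratio-of-sums R², n−1 RMSE, 1×IQR
boxplot whiskers).

A thin CLI mirrors the library (`mincenet simulate/prepare/summary/train/
extract-features/fuse-train/evaluate`), each command a single library call.

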