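# Methods

## Problem and model

The package quantifies pork adulteration in minced mutton from a single RGB
photograph of a compacted minced-meat sample in a 6 cm petri dish.  The
regression target is the pork mass fraction (g/g); the adulterated pork is
assumed to have been treated with mutton-flavour essence and red colorant,
which shrinks the visible colour difference between the two meats.  Four CNN
backbones are implemented:

* **resnet50** — the standard bottleneck backbone (stage widths
  256/512/1024/2048, block counts 3/4/6/3) with global average pooling and a
  single linear output.
* **invert_resnet50** — the same skeleton with every bottleneck replaced by
  an inverted residual block (1×1 expand → 3×3 depthwise → 1×1 linear
  projection).  Stage output widths are 64/128/256/512 and the hidden width
  of each block is `expansion_factor × stage_width` (default 4), so the wide
  middle layer mirrors the 4×-expanded output width of the bottleneck it
  replaces.  The first block of every stage keeps the skeleton's 1×1
  projection shortcut; other blocks use identity skips when shapes match.
* **cbam_resnet50 / cbam_invert_resnet50** — one CBAM attention module after
  every block, sized to the block's output channels: channel attention
  pushes the spatial-average and spatial-max pooled descriptors through one
  shared biased bottleneck MLP (reduction 16) and sigmoid-gates channels;
  spatial attention convolves the channel-average/channel-max maps with a
  7×7 kernel and sigmoid-gates pixels.

### Parameter accounting

Counts follow the Keras `model.summary()` convention: pointwise and full
convolutions carry biases, depthwise convolutions do not, and each
batch-norm layer holds 2c trainable parameters plus 2c moving statistics.
The headline "parameter count" is the total of both (the number a framework
summary prints).  Under these conventions the four variants total
23,589,761 / 9,853,569 / 26,122,337 / 10,016,349 parameters; the inverted
family is found by `resolve_invert_config`, an exhaustive search over
expansion factors 1–6 and three stage-width ladders that minimises relative
error against target counts — the defaults are the search's own output, not
hard-coded trust.

The bounded rectifier (ReLU6) is used inside inverted residual blocks with a
linear projection; standard ReLU elsewhere.  The regression head is a single
linear unit on the pooled features with no output activation; predictions
are clipped to [0, 1] only at reporting time so training gradients stay
unsaturated.  CBAM sits after the skip-merge; parameter counts are
unaffected by that placement choice.

### Neural-network stack

The layer stack (convolution, depthwise convolution, batch normalisation,
max pooling, CBAM, Adam with optional decoupled weight decay) is implemented
in NumPy with explicit forward/backward passes.  Every layer is verified
against central-difference gradients in the test suite.  Batch normalisation
uses eps 1e-5 and momentum 0.9; frozen layers switch to their moving
statistics and stop updating them, which is what makes the bit-identical
freeze guarantee of transfer learning testable.

## Synthetic study

The real study images are not public, so a renderer emulates them.  Each
dish is a circle (85% of the frame half-width; 672 px frames by default) on
a dark background, filled with granules of 6–12 px radius (the 3–5 mm mince
particles on a 6 cm dish), placed by grid-accelerated dart throwing with an
overlap-rejection rule and clipped at the rim.  Each granule is pork with
probability equal to the sample's adulteration ratio, otherwise mutton;
granule colours are i.i.d. Gaussian around the component mean (std 8/6/6).
Pork means are cut-specific (back palest, hind leg darkest); the
essence/colorant treatment is a single `tint_strength` knob that moves the
pork mean toward the mutton mean.  A random-direction linear illumination
gradient (amplitude 0.08) and Gaussian pixel noise (std 3) emulate uneven
lighting.  The full design is 8 replicates × 4 ratios (0.10–0.40) × 3 cuts
= 96 dishes; all randomness flows from explicit seeds (default 42) through
`numpy.random.SeedSequence`.

The tint default (0.35) and granule colour spread were calibrated against an
*oracle*: a ridge regression on dish-mean colour/chromaticity reaches a
validation R² around 0.9–1.0 under these defaults, i.e. the task is solvable
but not trivial, and at `tint_strength = 1` the two components coincide and
no method can beat chance (the null control asserted in the tests).  Two
features of real data the renderer does not model: spatially correlated
texture within a granule (fat marbling, fibre direction) and camera optics
(vignetting, chromatic response).  Passing tests therefore demonstrate that
the pipeline recovers a colour/texture-coded mixture fraction under
controlled conditions, not field performance on real meat.

## Preprocessing and datasets

ROI extraction runs a circular Hough transform (scikit-image, Canny edges)
on an image downscaled to 160 px, then refines the top candidate circles at
full resolution: along 256 rays the rim is the steepest drop of the
(3-tap smoothed) radial intensity profile; rays that lock onto interior
crevices are discarded by a 3×MAD trim and a least-squares (Kasa) circle is
fitted through the surviving rim points, twice.  Candidates are ranked by
rim contrast (mean intensity just inside minus just outside).  On rendered
dishes this recovers the centre to well under 1 px and the radius to <1%.
Detection failure raises an error; callers may fall back to a centre crop.

Augmentation follows the acquisition protocol: two uniform draws gate a
rotation (rotate iff u1 > 0.3, by 360°·u2 about the centre, bilinear, black
fill; exact quarter-turns take a lossless path) and two more gate a
multiplicative brightness jitter (factor uniform in [0.7, 1.3], rounded and
clipped to 8 bit).  Mirroring picks a random axis.  Both uniforms are always
drawn so the random stream does not depend on outcomes.  Splits are
stratified by ratio: per ratio, round(n/3) dishes form the independent
validation set and the remainder split 3:1 with the test count rounded down;
augmentation then *fills* each split to a fixed image count (1575/525/700
per cut; exactly 3× that for the mixed union) at 224 px (area-average
resampling).  Count-driven filling is what makes those sizes reachable from
32 source dishes, since they are not integer multiples of any per-dish
expansion factor.  Augmented copies inherit their source dish's sample_id,
so validation independence is auditable from the manifest and asserted in
the tests.

## Training and fusion

Backbones are trained with Adam on mean squared error.  The mixed-part model
is built in two stages: per-cut backbones are trained on their own cut, then
a fusion model runs all three backbones on the same image, concatenates
their pooled features in fixed (back, front_leg, hind_leg) order, and maps
the fused vector through a 256-unit hidden layer to one output.
Fine-tuning freezes the stem and stages 1–2 of every backbone (the
input-proximal layers that carry generic low-level structure) and retrains
stages 3–4 plus the head on the mixed data; frozen parameters and their
batch-norm statistics are bit-identical before and after, which the tests
verify by checksum.  The freeze set must be an input-proximal prefix because
backpropagation stops at the deepest frozen stage.

## Evaluation statistics

Exactly as the study defines them, including two deliberate departures from
textbook forms:

* **R²** is the ratio-of-sums form Σ(x̂ᵢ − x̄)² / Σ(xᵢ − x̄)² with x̄ the mean
  of the actual values — not 1 − SSres/SStot.  It measures how much spread
  around the true mean the predictions reproduce; overdispersed predictions
  can exceed 1, so it is *not* order-compatible with accuracy.  Wherever a
  comparison or stopping rule needs "better", the package uses the
  conventional 1 − SSres/SStot alongside it and reports both.
* **RMSE** divides by n − 1.
* **Boxplots** use linear-interpolation quartiles with whiskers at 1×IQR
  beyond the quartiles (not the usual 1.5×); the multiplier is exposed.

## Desk-scale experiment sizes

The stochastic training properties are exercised at sizes chosen for a
single CPU core: dishes rendered at 224 px (same granule-to-dish scale),
study fill targets (1575/525/700 per cut), network inputs at 36 px, and a
tiny-width cbam_invert variant (widths 8/16/32/64, one block per stage,
reduction 4).  Training uses Adam at 3e-3 with 0.96/epoch decay, decoupled
weight decay 0.01, batch 32, at most 50 epochs with early stopping once the
validation R² clears 0.8 (ratio-of-sums) *and* 0.75 (conventional) — the
second condition exists because the ratio-of-sums form is satisfied by an
untrained overdispersed model.  Fusion fine-tuning uses a 1200-image
subsample of the mixed training split for 10 epochs at 1e-3.  Full-size
training (224 px inputs, 23M-parameter backbones) is supported by the same
code paths but is not exercised in the test suite.

## Known limitations

* The renderer's colour model is Gaussian-per-granule; real treated pork has
  correlated, textured colour, and real boxplot spreads (the study's IQR
  ranges) are therefore not reproducible here.
* The NumPy stack is single-threaded and CPU-bound; it is meant for
  correctness and desk-scale experiments, not production training.
* Hough ROI assumes exactly one dish per frame.
* The ratio-of-sums R² is reported because it is the study's metric; readers
  comparing models should look at the conventional R²/RMSE that every
  report also carries.
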