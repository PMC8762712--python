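# Methods

## The feature-product unit and block

A feature-product (FP) unit models an end-stopped visual neuron: instead of
one linear filter followed by a pointwise nonlinearity (the LN-unit of
ordinary CNNs), it multiplies the rectified, standardised responses of two
learned filters applied to the same input patch,

    T2[i,j,m] = ReLU(x'v - mu_v) * ReLU(g'x - mu_g) / (sigma_v * sigma_g),

where `x` is the vectorised 3x3 patch of feature map m at pixel (i,j),
`v = vect(V_m)` and `g = vect(G_m)` are the vectorised filter pair, and
`mu, sigma` are the spatial mean and standard deviation of the respective
filtered map (plain instance normalisation, no learned affine terms).  The
product is an AND-combination: the unit fires only where *both* features are
present, e.g. "horizontal edge AND vertical edge" fires at corners.

The FP-block wraps a bank of such units between two pointwise linear maps:

1. 1x1 combination of the `d_in` input maps to `e = round(q * d_out)` maps,
   followed by ReLU (`q` is the expansion factor);
2. per map, two depthwise 3x3 convolutions (stride `s` applied here),
   instance normalisation, ReLU, elementwise product;
3. 1x1 projection to `d_out` maps; identity residual `Tout = T0 + T3` only
   when input and output shapes match (stride 1 and `d_in = d_out`),
   omitted otherwise.

Parameter arithmetic per block: `e*d_in + 18*e + e*d_out` — no biases, no
normalisation parameters, no shortcut weights.  This layout is what makes
the published model sizes come out exactly (see below); a residual
*projection* on the shape-mismatched blocks would add ~2.8 M parameters to
the FP-net-50 and contradict its reported size, so it is deliberately
absent.  The standard deviation in the normaliser is the square root of the
spatial variance (the defining formula is reading-ambiguous between
variance and standard deviation; the accompanying prose says standard
deviation, and standardisation is what instance normalisation means), and
it is stabilised as `sigma + 1e-5` so constant maps divide safely.

## Architectures and the FP design rule

Networks are stacks of blocks; a stack processes one spatial scale and every
stack after the first is entered through a stride-2 block.  Builders cover:

* ResNet-(6N+2) for 32x32 inputs: 3 stacks of N basic blocks, widths
  16/32/64 (N = 3, 5, 7, 9 give ResNet-20/32/44/56);
* PyrBlockNet-(6N+2): same layout with pyramid blocks
  (BN-conv-BN-ReLU-conv-BN, no post-addition ReLU);
* ResNet-50: stem conv7x7/2 + max-pool, stacks of 3/4/6/3 bottlenecks,
  224x224 input, 1000 classes;
* MobileNet-V2 (width 1.0): inverted-residual schedule grouped into six
  stacks — {16}, {24}, {32}, {64+96}, {160}, {320}.  The 96-wide stage
  continues the 64-wide stack at 14x14; the final 160->320 width expansion
  is kept as its own stack even though it enters at stride 1 (the one
  deviation from the stride-2 stack rule, needed to make the six-stack
  grouping exact).

The FP transform replaces each stack's first block with an FP-block of
identical `d_in`, `d_out` and stride.  Since an FP-block has three
convolution layers where a pyramid/basic block has two, the Cifar FP-nets
gain one layer per stack: PyrBlockNet-20 -> FP-net-23, ..., -56 -> -59.
MobileNet FP-blocks use q=3; all six replaced MobileNet blocks change shape
and therefore carry no residual.

Parameter counting instantiates the network and sums all trainable scalars
(convolution weights, batch-norm affine pairs, classifier weight + bias);
counts are seed-independent.  Reproduced sizes: ResNet-50 25,557,032
(25.6 M), FP-net-50 q=1 25,959,208 (26.0 M), q=0.8 24,276,328 (24.3 M),
MobileNet-V2 3,504,872 (3.5 M), FP-MobileNet 3,484,536 (3.5 M).

For the Cifar baselines the shortcut on shape-changing basic/pyramid blocks
is a 1x1 projection + BN; their absolute sizes are not certified, only the
relative statement that FP transforms shrink the PyrBlockNet family.

## Implementation of the numerics

Everything runs on NumPy.  Convolutions are cross-correlations with
same-padding built on `sliding_window_view` + matmul; the backward pass is
the transposed convolution (stride-dilated output gradient, `k-1-p`
padding, spatially flipped kernels), verified layer-by-layer against
central finite differences at float64 (probes that straddle a rectifier
kink are detected by comparing two step sizes and skipped).  Training is
plain SGD with momentum 0.9.  Batch norm uses batch statistics in training
and running averages (momentum 0.1) at inference; instance norm divides by
`sigma + 1e-5` with no affine terms, exactly as in the FP-unit definition.
Forward passes are deterministic; checkpoints round-trip bit-exactly
through `.npz`.

## Hyperselectivity analysis

For a filter pair the angle is `gamma = arccos(v'g / |v||g|)` (inner
product clamped to [-1, 1]; zero-norm filters yield NaN, reported as
missing).  The simplified unit response used for contour analysis is
`F(x) = ReLU(x'v̂) ReLU(x'ĝ)` with unit-normalised filters.  The optimal
stimulus is the normalised bisector `v̂ + ĝ` (undefined at gamma = pi); the
second analysis axis is the in-span direction `v̂ - ĝ`, which is orthogonal
to the bisector, or a seeded Gram–Schmidt-orthogonalised random direction
when the pair is collinear.

Iso-response contours are extracted numerically: `F` is evaluated on a
(t, y) grid (y along the optimal axis, t orthogonal), and for each t the
smallest positive y reaching the requested level is located by linear
interpolation along the y column.  Curvature is the quadratic coefficient
of a least-squares parabola fitted over a window around t = 0 (defaults:
t-window 0.1 at level 0.25 of the unit-stimulus response, at least five
points spanning zero).  The window is kept small because the exact contour
branch is a hyperbola, `y(t) = sqrt(c + t^2 sin^2(g/2)) / cos(g/2)`, whose
quartic term would otherwise bias the quadratic fit; at these defaults the
fitted coefficient agrees with the small-t expansion
`sin^2(g/2) / (2 sqrt(c) cos(g/2))` to well under 1 %.

## Entropy and end-stopping protocols

These two measurements follow reconstructed protocols (the defining
appendix is not part of the source text); the concrete choices here are
normative for this package:

* **Entropy**: each unit's T2 values are pooled over a fixed batch of >= 256
  images, min–max normalised per unit, binned into 32 equal-width bins, and
  summarised by Shannon entropy in bits (0 for constant maps, at most
  log2 32 = 5).  Min–max binning makes the estimate invariant under
  positive rescaling of the activations.
* **End-stopping**: the probe is a centred axis-aligned square occupying
  half the input side, presented bright-on-dark and dark-on-bright at full
  contrast.  With Chebyshev receptive-field radius r, masks mark positions
  whose receptive field (a) lies fully inside the square (0D), (b) sees
  exactly one edge transition (1D: four 2r-wide bands along the edges,
  corner neighbourhoods excluded by construction), (c) sees two transitions
  (2D: four 2r x 2r corner patches).  Closed-form areas: (ss-2r)^2,
  8r(ss-2r), 16r^2 for square side ss.  Masks are downsampled to a block's
  grid by its cumulative stride; radius and stride come from the standard
  receptive-field recursion over all preceding layers.  For deep blocks
  whose receptive field outgrows the stimulus, the radius is clamped to
  (ss-1)//2 and recorded in the report — end-stopping numbers for such
  blocks are indicative only.
* **Classification**: bright/dark responses are pooled per region by the
  maximum.  Threshold: 1e-4 of the block's maximum stimulus response.  All
  three means at or below threshold -> non-responder; 0D mean above half
  the 2D mean -> 0D-responder; otherwise degree = 1 - 1D/2D (<= 1, exactly
  1 when the 1D mean vanishes).  The degenerate case of edge response
  without corner response cannot live in that three-way split and is
  classed separately as `edge_responder`.

The census walks every FP-block, records gamma, curvature, entropy, the
end-stopping fields and the unit's depth (convolution layers up to and
including its block's expansion; the FP-net-50's blocks sit at depths 2,
11, 23, 41 and the FP-net-59's at 2, 21, 40 under this count).  The
"near-zero gamma" threshold used when quoting fractions of linear units is
0.1 rad; the full gamma column is always reported so other cuts can be
read off.

## Attacks and robustness harness

FGSM perturbs by `eps * sign(grad)`; on a network the gradient is taken on
the cross-entropy loss at the true label (an open choice — predicted-label
gradients differ only on misclassified inputs), on a toy scorer on the
scorer itself.  Pixel-range clipping is off by default and flag-enabled.
CIGA iterates `eta <- clip(eta + tau * grad(x + eta), -eps, +eps)` and
asserts the box constraint at every iterate; the logged path and values
support the LN-vs-FP step-count comparison.  Robustness across classifiers
is summarised by the fraction of changed predictions under a perturbation,
which accuracy differences cannot confound.  JPEG test sets recompress
through Pillow's baseline codec (quality tables are encoder-specific, so
the codec identity is exposed as metadata); quality 100 denotes the
original images and short-circuits to an exact copy.

## Synthetic data and what the tests do (and do not) show

The generator emulates a small Cifar-like corpus: 32x32x3 images in [0, 1],
four balanced classes built from horizontal bars, vertical bars, L-corner
conjunctions and disks, rendered at random positions/intensities with a
per-image colour tint and additive Gaussian noise (sigma 0.05), all driven
by one seeded generator.  Corners versus bars is the minimal task where an
AND-unit has a real advantage.  Defaults: 512 images; smoke training runs
300 SGD steps at batch 32, lr 0.05, momentum 0.9 — a few minutes on one
CPU, enough to drive the training loss to ~0 on this small set.

What this does not emulate: natural image statistics, scale/viewpoint
variation, label noise, or dataset scale.  Trained-network results here are
therefore sign-level statements (most units hyperselective; entropy
decreases with gamma — Spearman rho about -0.4 on the standard seed), not
reproductions of benchmark error rates.  Benchmark accuracies, the
real-data robustness fractions, and the trained-on-ImageNet unit
distributions require GPU-scale training on Cifar-10/ImageNet and are out
of scope; the desk-scale counterparts (parameter counts, curvature law,
attack mechanics, end-stopping classifier, census signs) are what the test
suite certifies.

## Known limitations

* Pure-NumPy training is single-threaded-CPU bound; the smoke recipe is
  sized for minutes, not for convergence studies.
* The pyramid-block internals and the Cifar shortcut convention follow one
  reasonable reading of the referenced families (config-flagged in code);
  Cifar-family absolute parameter counts are not certified quantities.
* Entropy and end-stopping protocols are reconstructions (see above); the
  `edge_responder` class extends the published three-way partition for a
  degenerate case it cannot express.
* The iso-response analysis uses the simplified (un-normalised) product
  response; curvature therefore depends only on gamma and the level, not on
  the instance statistics of a particular input batch.
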