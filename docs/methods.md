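# Methods

## Problem setting

Stored wheat develops surface mold in distinguishable stages.  In THz
time-domain reflection imaging, each pixel of a scanned kernel records a
picosecond electric-field waveform; the Fourier magnitude of that waveform
carries both surface and sub-surface structure.  Kernels at four mold
degrees (normal, slight, moderate, serious) look nearly identical in
outline but differ in foreground signal strength (mold encapsulation damps
the reflected pulse) and in surface texture.  The task is fine-grained
four-way classification of single-kernel 0.3 THz slice images.

## Synthetic data model

No public moldy-wheat THz dataset exists, so the study conditions are
defined by a seeded generator (`mscfp.synthetic`) rather than a recording:

- **Geometry.** One kernel per image: an axis-aligned ellipse with
  semi-axes (55, 35) px at 180x180 (scaled with image size) and uniform
  center jitter of +-5 px.  The aspect ratio is a free constant chosen to
  resemble a wheat kernel in plan view, not a measured quantity.
- **Waveform.** Every foreground pixel carries the same single-cycle
  Gaussian-windowed cosine, amplitude-scaled per pixel: carrier 0.3 THz,
  envelope sigma_t = 1/(2 pi sigma_f) with sigma_f = 0.3/sqrt(2 ln 2) THz,
  so the spectral magnitude peaks at 0.3 THz and halves by 0.6 THz —
  matching the band where the instrument's wheat spectra peak and decay.
  Arrival time is fixed at 10 ps inside the 90 ps window.  Background
  pixels are pure Gaussian noise (exactly zero at `noise_sigma = 0`).
- **Mold-degree effect.** Class `c` multiplies the foreground by
  `foreground_level[c]` (0.90 / 0.75 / 0.60 / 0.45, strictly decreasing)
  and by a multiplicative texture field `1 + texture_sigma[c] * G` where
  `G` is a unit-variance Gaussian random field smoothed with a 3 px kernel
  (scaled with image size) and `texture_sigma` is 0.02 / 0.06 / 0.10 /
  0.15, strictly increasing.  The default separations are moderate;
  `GeneratorConfig.easy()` widens them for optimization sanity checks.
- **Seeding.** Every sample's random stream is keyed on
  `(seed, class, index)`, so any single sample can be regenerated
  independently of generation order, bitwise identically.

What the generator does **not** emulate: dispersion, Fresnel reflection at
internal interfaces, depth-dependent echoes, per-pixel arrival-time
jitter, detector drift, or any mycotoxin chemistry.  Tests passing on this
data show that the pipeline and optimizer behave correctly under the
stated statistical structure; they are not evidence about real wheat.

## Preprocessing

`time_to_frequency` takes the per-pixel DFT magnitude and keeps the lowest
300 non-negative-frequency bins: with a 90 ps window the bin spacing is
1/90 ps ~ 11.1 GHz, so 300 bins span ~3.33 THz, consistent with the
instrument band.  The transform is computed row-chunked with `scipy.fft`
(which preserves single precision; a full 180x180x9000 float32 cube is
~1.2 GB and must not be duplicated in double precision).
`select_frequency_slice` picks the bin nearest the requested frequency,
ties toward the lower bin; 0.3 THz falls on bin 27.  Phase is discarded —
the classifier consumes intensity images.

Background removal is Otsu's global threshold followed by the largest
connected component (8-connected) — the standard parameter-free choice
for isolating a single bright object; on noise-free synthetic images it
recovers the generating ellipse exactly.
A constant image yields an empty mask and a warning rather than an error.

The train/test split is stratified per class with
`round(ratio * n_class)` training images per class and a fixed seed:
1200 balanced images at 9:1 give exactly 1080/120.

## Network

**Backbone.** ResNeXt with the canonical 32x4d plan: depths (3, 4, 6, 3),
widths 64/256/512/1024/2048, 7x7 stride-2 stem + 3x3 stride-2 max-pool,
batch norm + ReLU inside blocks, stride 2 in the first block of stages
2-4.  Each bottleneck block is 1x1 compress -> 3x3 grouped (cardinality
32) -> 1x1 expand, plus a projected shortcut where shape changes.  The
grouped convolution is mathematically identical to 32 parallel 4-channel
branches summed position-wise, and is tested against that brute-force
form.  The stem is a single-channel variant: THz slices are grayscale and
no pretrained weights are involved, so no fake-RGB replication.  Striding
inside every block of a stage would collapse the resolution, so the
canonical first-block-only striding is used.

**Multi-scale context (MCFEM).** Six parallel branches on each stage
output: 1x1 conv, four 3x3 convs with dilations 1-4 ("same" zero padding),
and identity.  Receptive fields of the conv branches are 1, 3, 5, 7, 9 by
k + (k-1)(d-1).  Branch outputs (all C -> C, so they are summable) are
combined as a convex combination with softmax weights over six learnable
logits, then projected by a 1x1 conv (+ BN + ReLU).  The weighted *sum*
reading is forced by the convex-combination semantics of the softmax
weights; concatenation would make them redundant.  One MCFEM per stage,
after the stage's last block; a per-block placement would multiply the
module count several-fold with no consistent overall wiring, and is not
implemented.

**Coordinate attention.** Width-wise and height-wise global average pools
give C x H and C x W codes; concatenated on the spatial axis they pass a
shared 1x1 conv to max(8, C/r) channels (r = 32 default), batch norm and
hard-swish, then split back and expand per direction through 1x1 convs
with sigmoid gates; the input is multiplied by both broadcast gates.
Hard-swish/sigmoid follow the original coordinate-attention formulation;
pooling is the plain mean over the standard index ranges 0..H-1 and
0..W-1.  Placement is after MCFEM in each stage cascade.

**Bi-FPN.** All five per-stage maps (stem + 4 stages) are harmonized to a
common width (160 full-size, 40 scaled) by 1x1 conv + BN, then one
Bi-FPN layer runs top-down (nearest-neighbour upsampling to the exact
shallower shape) and bottom-up (3x3/stride-2 max-pool, which matches the
ceil(H/2) level geometry for any input size) passes.  Fusion nodes use
fast-normalized weights relu(w)/(sum relu(w) + 1e-4) and a
depthwise-separable 3x3 conv + BN + ReLU after fusion, both per the
original Bi-FPN design.  The head is global average pooling + a fully
connected layer on the deepest output level; `head_level: highest`
switches the head to the highest-resolution level instead.

With MCFEM, CA and Bi-FPN all disabled the model is exactly the plain
backbone + GAP/FC head, parameter for parameter — the ablation baseline.

## Implementation of the layers

The layers (grouped/dilated convolution via im2col + GEMM, batch norm,
pooling, SGD with momentum, explicit backward passes) are implemented in
`mscfp.nn` on numpy.  Correctness is enforced two ways: forward passes are
tested against independent oracles (`scipy.signal.correlate2d` for all
convolution variants, brute-force loops for pooling), and every layer and
composite module passes central-difference gradient checks at 1e-5
relative tolerance.  One analytic subtlety: the shift parameter (beta) of
a batch norm whose output reaches the loss only through a *following*
normalization layer receives an exactly zero gradient in exact
arithmetic; gradient-flow assertions therefore cover weights, fusion
logits and fusion weights, not shift parameters.

## Training protocol

Cross-entropy, SGD for 100 epochs by default.  The remaining
hyperparameters are fixed as package defaults: lr 0.01, momentum 0.9,
weight decay 1e-4, batch size 16, per-image min-max normalization to
[0, 1], no augmentation (THz slices are geometry-calibrated).  Metrics are
the 4x4 confusion matrix, overall accuracy, and macro-averaged precision,
recall and F1 in percent, with 0/0 defined as 0.  A per-class "accuracy"
has no standard definition consistent with per-class recall; the report
exposes one-vs-rest accuracy per class and leaves it at that.  The
ablation runner trains all eight on/off combinations of
(MCFEM, CA, Bi-FPN) with shared data, seed and hyperparameters.

Determinism: given a seed, parameter initialization, batch order and
therefore the entire run are reproducible bitwise (single-threaded BLAS
reductions permitting; in practice runs on the same machine reproduce
exactly and tests assert it).

## Problem sizes used by the test suite

A full-size run (1200 images at 180x180 through the ResNeXt-50-scale
network for 100 epochs) is far more than a routine test run should
spend, and absolute accuracies on real wheat cannot be checked without
real recordings in any case, so the suite exercises the full pipeline at
reduced scale as its own design choice: the learning check
uses depths (1, 1, 1, 1), quarter widths (16/64/128/256/512, pyramid
width 40), 64x64 images, 200 train / 40 test easy-set images, 15 epochs,
three seeds, asserting a median test accuracy of at least 85%.  Shape and
arithmetic contracts (180x180x9000 -> 180x180x300 -> 300 slices, the
1080/120 split, receptive fields, weight normalizations) are asserted at
full size, since they cost almost nothing.

## Known limitations

- Real THz recordings of moldy wheat are not available; every empirical
  number in the tests refers to the synthetic conditions above.
- The numpy implementation is CPU-bound and single-device; full-size
  100-epoch training is possible but slow (hours), which is why the CLI
  defaults are full-size but the tested configurations are reduced.
- Only coordinate attention is implemented in the attention slot; the
  interface accepts alternatives but none are shipped.
- Bi-FPN is single-layer by default; deeper stacks are configurable but
  untested beyond shape/gradient contracts.
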