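# Methods

## The model

`hffen` implements a single-image super-resolution network for plant imagery
whose distinguishing component is a plug-and-play **high-frequency feature
enhancement (HF-FE) branch**. Thin, branching, high-frequency structures —
leaf venation, lesion rims, serrated margins, frond edges — carry most of the
agronomic information in plant images, and generic SR backbones tend to
oversmooth exactly those structures. The network addresses this with an
explicit high-pass pathway.

With an LR input I_LR and N cascaded modules:

    F_0   = conv3x3(I_LR)                      shallow feature extraction
    F_n   = SR(F_{n-1}) + HF-FE(F_{n-1})       n = 1..N  (parallel branches,
                                               element-wise sum fusion)
    F_D   = conv3x3(F_N)                       aggregation
    I_SR  = upsample(F_D + F_0)                global skip + pixel shuffle

The HF-FE branch is the composition

    HF-FE(x) = HA( R( L * x ) )

* **L** — a fixed 3x3 Laplacian stencil (4-neighbour by default, 8-neighbour
  selectable), applied depthwise with reflect padding. Its zero DC response
  means constants vanish and only edge/texture structure passes. The kernel
  is stored outside the parameter set and is bit-identical before and after
  any amount of training.
* **R** — a stack of residual blocks (conv3x3 -> ReLU -> conv3x3, additive
  skip) refining the raw high-pass response.
* **HA** — hybrid attention: window multi-head self-attention and
  squeeze-and-excitation channel attention run *in parallel on the same
  input*, are summed, normalised channel-wise, and passed through a
  two-layer 1x1-conv MLP.

The SR branch is pluggable: anything satisfying the shape-preserving
`SRBranch` contract can be used. The shipped reference branch is a stack of
EDSR-style full-width residual blocks.

## Design choices where the architecture was open

* **Laplacian variant, padding, depthwise application.** The canonical
  4-neighbour stencil with reflect padding, applied per channel. Reflect
  padding avoids the dark halo a zero pad creates under an edge filter;
  depthwise application keeps the "fixed filter" semantics (cross-channel
  mixing would make it act like a learnable projection). Both the stencil
  (`hiem.kernel: lap4|lap8`) and padding (`hiem.padding`) are configurable.
* **HIEM residual blocks are bottlenecked** (C -> C/4 -> C at 3x3). The HF-FE
  branch is advertised as lightweight — under 10% of the backbone's
  multiply-adds. A constant-width refine stack of useful depth cannot meet
  that bound next to any reasonably sized backbone, so the refine blocks
  carry an internal 4x channel bottleneck; the branch still enters and
  leaves at full width, so the HA(R(L*x)) composition and every shape
  contract are unchanged.
* **Reference backbone depth: 16 residual blocks per module** (paper
  profile, N=4, C=64). This puts the baseline at ~181 G multiply-adds for a
  192x192 input — the scale of the published SR backbones the branch is
  meant to attach to — and makes the <10% overhead bound a meaningful test:
  the full branch adds 9.4% multiply-adds and 8.8% parameters.
* **Attention tokenisation.** Spatial positions are tokens of dimension C;
  maps larger than the 8x8 window are partitioned into non-overlapping
  windows (reflect-padded to a multiple, cropped afterwards) to bound the
  quadratic cost. No positional encoding; full attention is therefore
  exactly translation-equivariant, which the tests exploit.
* **Residual skip around the HA unit** (`ha.residual_skip`, default on).
  The attention equations alone have no skip, but a pre-norm-style skip is
  what makes such blocks trainable in practice; the toggle records the
  ambiguity.
* **Norm**: layer normalisation over the channel dimension at each spatial
  position — the convention of transformer-style restoration blocks.
* **Upsampler**: conv + pixel shuffle; x4 uses two x2 stages by default.
  Shuffle convs get ICNR initialisation (the r^2 sub-kernels of a group
  start identical), so upsampling begins as a clean nearest-neighbour
  interpolation instead of checkerboard noise. The final RGB conv starts
  with small weights and bias 0.5, i.e. the network's first output is
  near-constant mid-gray; both choices markedly shorten the unproductive
  early phase of short training runs.
* **Branch injection: ReZero gate + separate RNG stream.** The HF-FE
  branch output is scaled by a learnable scalar initialised to zero, and
  branch weights are drawn from a generator independent of the backbone's.
  Consequences: (i) the backbone initialisation is bit-identical with or
  without the branch, and (ii) at construction the full network computes
  exactly what the bare cascade computes, opening the high-frequency
  pathway only where it reduces the loss. This is the standard recipe for
  injecting a new branch into a working backbone without destabilising it,
  and it makes short-schedule baseline-vs-full comparisons properly
  paired. The fusion formula F_n = F_SR + F_HF is unchanged — the gate is
  simply the last stage of the branch. One side effect is pinned by a
  test: before the first optimisation step the gate blocks gradients into
  the branch, so gradient-reach is checked after one step.
* **Pixel normalisation**: divide by 255 into [0, 1], no mean shift.
  Outputs are clamped to the valid range at inference only, never inside
  the loss, keeping gradients clean.
* **Aggregation conv**: 3x3 (1x1 would also be defensible; 3x3 matches the
  other stages).

## Numerical substrate

The network, its reverse-mode autodiff (including im2col convolutions with
exact gradients), Adam, gradient clipping and pixel shuffle are implemented
directly on numpy, with JIT-compiled gather/scatter kernels on the
convolution hot path. Every differentiable operation is pinned against
central finite differences in the test suite. Training is single-threaded
and bit-deterministic: the batch at iteration t is drawn from a generator
seeded by (stream seed, t), so checkpoint resume reproduces an
uninterrupted run exactly.

## Data protocol

* 80/20 train/test split by a seeded shuffle (floor(0.8 n) training ids).
* Random HR patches (192x192 in the paper profile) with dihedral
  augmentation (8 symmetries of the square, drawn uniformly).
* LR inputs synthesised from HR patches by antialiased Catmull-Rom bicubic
  (a = -0.5) at x2/x3/x4 — never the reverse, and only from training
  images. An audit operation asserts over recorded provenance that no
  held-out image ever contributed a training patch.
* The resampler is separable, float64, with a symmetric weight matrix, so
  it commutes exactly with 90-degree rotations — used as a correctness
  cross-check.

## Training protocol

L1 loss in normalised units; Adam (beta1 = 0.9, beta2 = 0.999); learning
rate lr0 * 0.5^floor(t / halve_every); global gradient-norm clipping at 5;
separate models per scale; one iteration = one optimisation step on one
sampled batch. The paper profile mirrors the published protocol
(lr0 = 1e-4 halved every 100k, 400k iterations, 192px patches, batch 16).

## The desk profile

The published protocol is GPU-scale; the desk profile is the package's
CPU-scale working point, used by the tests and the acceptance experiment:

| parameter        | desk value | note |
|------------------|-----------|------|
| channels         | 24        | smallest width that still learns quickly |
| n_modules        | 1         | one HF-FE + SR module |
| backbone blocks  | 2         | reference branch depth |
| HIEM depth       | 1 (bottleneck 4) | |
| HA               | 2 heads, window 8, CA reduction 8 | |
| HR patch         | 48 px     | |
| batch            | 2         | best quality per CPU-second in our sweeps |
| lr0              | 2e-3      | standard for tiny SR nets on short schedules |
| halve_every      | 1500      | keeps the halving schedule meaningful |
| iterations       | 4500      | largest count fitting a quarter-hour run |

These sizes were chosen from measured convergence per wall-second on one
CPU core; the split protocol (200 images, 160/40, three seeds) is
untouched. Single-run PSNR gains over bicubic vary by several tenths of a
dB with the data split and the training seed at this scale, which is why
the reference experiment averages over three seeds.

## Synthetic data: what it does and does not show

The generator renders, deterministically per `SceneSpec`: a smooth
soil-toned background; a leaf silhouette with sinusoidal serration (the
boundary sharpens with serration amplitude and blends smoothly without
it); recursive binary-branching venation polylines (depth 5, per-branch
angle jitter, 1-2 px wide, count scaling with `venation_density`);
elliptical lesions with a sharp 1-px rim; mild Gaussian pixel noise
(sd 1.0 by default); and a green-dominant palette with per-image hue
jitter so the Y channel stays informative. Default scenes carry more than
10x the Laplacian energy of structure-free scenes — the property that
makes high-frequency enhancement measurable on this data.

What it does not emulate: photorealistic texture, species morphology,
illumination and shadow structure, sensor noise statistics, UAV motion
blur, water-surface reflections. Passing the desk-scale experiments shows
the training/evaluation machinery is sound and that the qualitative
ablation ordering is reproducible on structured synthetic data; it does
not certify gains on real plantation, aquatic or pathology imagery.

## Evaluation

PSNR and SSIM on the Y channel (ITU-R BT.601 studio range by default,
full range selectable), whole held-out images, a border of `scale` pixels
cropped on each side, peak 255. SSIM uses the 11x11 Gaussian window
(sd 1.5), C1 = (0.01*255)^2, C2 = (0.03*255)^2, population covariance.
Identical images produce an infinite PSNR sentinel which split averaging
skips with a logged count. FLOPs are analytic multiply-adds computed
symbolically from the architecture (convs, linears, attention matmuls;
normalisations and elementwise ops uncounted); an unknown layer type makes
the counter fail loudly rather than under-report.

## Known limitations

* The desk-scale ablation margin (full vs baseline) is a direction check
  at small scale, not an estimate of the published effect sizes.
* PSNR/SSIM conventions (Y standard, border crop, SSIM window) vary across
  the SR literature; reports embed the conventions used, and cross-paper
  numeric comparison is convention-limited.
* The x3 and x4 desk configurations train the same way but the acceptance
  experiment exercises x2 only, where the short-schedule signal is
  strongest.
* Whole-image evaluation pads attention windows at image borders; the
  border crop removes most, not provably all, boundary effects.
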