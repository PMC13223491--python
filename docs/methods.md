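# Methods

This note documents the models, algorithms and design choices behind
`vedicnn`, in the order data flows through the package.

## 1. Integer arithmetic emulation

**Representation.** Operands are `BitVector(width, value)` unsigned
integers; all kernels also exist as plain-integer fast paths that the
public operations wrap. The emulation is *functional* bit-accuracy: each
unit computes through the same intermediate structure as the hardware
(partial-product columns, carry-save rows, partial-sum/carry/final-sum
units), not through a host multiply.

**UT (vertical and crosswise).** Column sums `s_k = Σ_{i+j=k} a_i b_j`
over the AND partial products, with a single carry propagation across
columns. This is the recursion floor for all composite multipliers (4-bit
blocks).

**Nikhilam/Anurupyena (NAS).** The complement identity
`a·b = (a + b − W)·W + (W − a)(W − b)` is exact for *any* working base
`W`, so correctness never depends on base choice; base choice only
controls how small the complement product is. The working base `W = m·B^k`
(radix `B` = 10 for the classic decimal presentation, 2 in the datapath;
scale factors `m ∈ {1..9}` decimal, odd `m ∈ {1,3,5,7}` binary) minimises
`max(|a−W|, |b−W|)`. Since
`max(|a−W|, |b−W|) = |W − (a+b)/2| + |a−b|/2`, the optimum is the
candidate base nearest the operand midpoint; candidates are kept in a
sorted table and bisected. Ties break toward the smaller base,
deterministically. The complement product runs on UT; deficits (operands
below base) appear as signed intermediates, emulating the sutra's borrow
bookkeeping.

**CUTIN dispatch.** At width `n` (power of two ≥ 4): if both operands lie
within `2^(n−2)` of a shared binary working base, the NAS path is taken;
otherwise the operands split into high/low halves and four half-width
CUTIN sub-products combine crosswise. The four shifted sub-products reduce
through 3:2 carry-save stages and a final CSCGL addition. The closeness
threshold (`NAS_CLOSENESS_SHIFT = 2`) is a module constant; the routing
rule itself is a design choice of this package — it preserves NAS's
"close to a base" applicability condition while defaulting to UT
decomposition. Width-8 products are memoised (the full 8-bit space is only
64 Ki entries and is exercised exhaustively by the tests), which makes the
24×24 significand multiplies in the float layer fast without changing a
single computed bit.

**CSCGL.** Partial Sum Unit: half-adder layer `s0 = a⊕b`, `c0 = a∧b`.
Carry Unit: the selected carry chain `c_{i+1} = c0_i ∨ (s0_i ∧ c_i)`
derived combinationally from `(c0, cin)` — one chain, no duplicated adders
behind a multiplexer. Final Sum Unit: `sum = s0 ⊕ carries`, carry-out into
bit `n`. Result width is `n+1`.

**Carry-save convention.** `CarrySavePair` stores the carry vector
*unshifted*; the weight-2 factor lives in the invariant
`sum + 2·carry = value`. A finishing half-adder layer
(`x + y = (x⊕y) + 2(x∧y)`) guarantees the invariant even when the input
grid already has ≤ 2 rows.

## 2. Floating-point emulation

Profiles: fp32 (8-bit exponent, bias 127, 23-bit mantissa) and fp16
(5/15/10). The significand product (24×24 → 48 bits fp32; 11×11 → 22 bits
fp16) runs on the CUTIN datapath, zero-extended to the enclosing
power-of-two width.

Normalization follows the accelerator rule: if the MSB of the double-width
product is set, the mantissa window starts one bit below it and the
exponent increments; otherwise the window starts at the next lower bit and
the exponent is unchanged. (The increment condition depends on the product
MSB only; a stricter reading that would additionally require the next 23
bits set does not yield a consistent multiplier and is not used.)

Two rounding modes: **truncate** (drop the out-of-window bits — the most
literal reading of a hardware normalizer that "eliminates" the extra bits;
the default) and **round-nearest-even** for reference comparison. Measured
behaviour on sampled finite normal operands: RNE is bit-identical to host
IEEE-754; truncation is within 1 ulp.

Deliberate IEEE deviations, all flagged in `FpFlags`:

* subnormals flush to signed zero on input and output (the datapath
  handles biased exponents 1..254 / 1..30 only);
* exponent overflow saturates to the largest finite magnitude rather than
  producing an infinity;
* NaN/infinity inputs still propagate by the usual IEEE rules.

Addition (needed by the convolution adder tree) is the standard
align–add–normalize algorithm with three guard/round/sticky bits, with the
aligned significand addition (and two's-complement subtraction) on the
CSCGL unit. During post-subtraction left-normalization the sticky bit is
pinned at position 0, which is what makes the RNE path bit-exact.

## 3. Quantized convolution and the error bound

Feature maps are H×W×C float64 arrays. `conv2d` computes each output pixel
as an inner product of an im2col patch row with a filter column; backends:

* `exact` — host matmul (the oracle);
* `cutin_fp32` / `cutin_fp16` — every scalar product through `fp_multiply`
  and a balanced binary tree of `fp_add`.

Per-pixel deviation of an emulated inner product of `m` terms from the
exact value is bounded first-order by
`(1 + ⌈log2 m⌉) · u_op · Σ|x_i w_i| + m · FLT_MIN_NORMAL`, where `u_op` is
one relative ulp for truncation or half an ulp for RNE, the `1` covers the
multiplies, the `⌈log2 m⌉` the adder-tree depth, and the flush-to-zero
floor covers products below the smallest normal (relevant for fp16). A 5%
pad absorbs the second-order cross terms. The bound is asserted per pixel
on seeded random layers; measured worst deviations sit at roughly half the
bound.

Quantization is symmetric per tensor: `scale = max|t| / (2^(b−1) − 1)`,
zero point fixed at 0, levels clipped to the symmetric range; an all-zero
tensor takes scale 1 by convention. Per-channel granularity was not
adopted — nothing downstream needs it at desk scale.

Batch norm and ReLU are plain elementwise host operations: the accelerator
design keeps normalization and activation in floating point outside the
quantized MAC datapath, so emulating them bit-level adds nothing to what
the backends already exercise.

## 4. DnCNN

Structure (head `denoise` or `segment`): first layer conv+ReLU, `depth−2`
middle layers conv+BN+ReLU, last layer conv (denoise) or conv+sigmoid
(segment); 3×3 kernels, same-padding, stride 1, He initialization. The
denoise head is residual: the network predicts the noise map and the clean
estimate is `input − prediction`.

Training is host-float64 with manual backpropagation (im2col convolution
forward/backward, standard BN backward) and Adam (β₁ 0.9, β₂ 0.999).
Losses: MSE on the noise map for denoising; `(1−w)·BCE + w·Dice`
(default `w = 0.5`, Dice smoothing 1.0) on the sigmoid probabilities for
segmentation. Training is fully deterministic under the config seed
(`numpy` Generator for init and shuffling); a non-finite loss aborts with
a diagnostic rather than continuing to train garbage.

Training runs in host arithmetic only; the emulated backends are
inference-only. This mirrors the deployment split (training happens
off-device, the accelerator runs the forward pass) and avoids defining
gradients through bit-level truncation.

One consequence of mini-batch BN worth knowing: with learning rate 0 the
*parameters* are frozen, but per-epoch mean loss still fluctuates at the
third decimal because batch statistics depend on the shuffle; with
full-batch training the trace is exactly constant.

Post-processing is morphological closing (dilate then erode) with a disk
element; radius 0 is the identity, and closing is idempotent.

Desk-scale defaults: depth 5, width 16 (≈ 7.4 k parameters), 64×64
phantoms, 40 denoise / 25 segment epochs — sizes at which a seeded run
trains in tens of seconds on one CPU while still clearing +3 dB denoising
gain and 0.85 test DSC with a wide margin. The printed reference
architecture this emulates is far larger (512×512 inputs, hundreds of
channels); depth/width/size are configuration, not code.

## 5. Pelican Optimization Algorithm

Initialization `x_ij = l_j + rand_ij (u_j − l_j)`. Each iteration:

* **Exploration** ("moving towards prey"): prey is a randomly *selected*
  population position for the iteration. If the prey is fitter,
  `x ← x + r·(p − I·x)` with `I ∈ {1,2}` random; else
  `x ← x + r·(x − p)`. Greedy acceptance, clamp to bounds.
* **Exploitation** ("winging on the water surface"):
  `x ← x + R·(1 − t/T)·(2r − 1)·x` with `R = 0.2`; the neighborhood
  shrinks linearly to zero at `t = T`. Greedy, clamped.

Greedy acceptance makes the best-so-far trace monotone by construction;
NaN fitness values are rejected (the candidate keeps its position). Both
phases use per-dimension random vectors. Selecting the prey from the
population rather than uniformly from the search box is the one place the
published phase equations leave open; population prey couples exploration
to the current fitness landscape and is what reaches sphere medians ~1e-19
at `N=20, T=100` (a uniformly random prey point plateaus around 1e-1,
because late-stage "move away from worse prey" steps almost never improve).

Hyperparameter tuning searches `log10(lr) ∈ [−4, −1]`, depth 3..9, width
8..32, mask threshold [0.2, 0.8], post-processing radius 0..3; integers
round to the nearest valid value. Fitness is `1 − (½·DSC + ½·IoU)` on a
validation split after a short seeded training run. The default
configuration is warm-started into the initial population, so the tuned
result can only match or improve on it — tuning is then a bonus, never a
regression.

## 6. Phantom generator

Each phantom is built from its spec's own seed (datasets spawn
per-phantom child seeds from the master seed, so any element is
reproducible in isolation):

* background: base echo level ~0.55 plus smoothed Gaussian texture;
* **benign**: ellipse (eccentricity 0.6–0.95, random orientation), margin
  softened with σ = 1.2 px — smooth, well-defined;
* **malignant**: star polygon — low-order lobes plus 7–12 sharp spikes —
  with heterogeneous interior texture and a harder margin;
* both lesions hypoechoic, default contrast 0.40; outline radii are
  rescaled analytically (shoelace area) so the rasterized mask lands
  within a few percent of the requested area fraction (default 0.08);
* noise: multiplicative speckle `clean · (1 + s·(F − 1))` with `F` a
  unit-mean Rayleigh field (the first-order B-mode speckle model; `s` =
  0.5 default) plus additive Gaussian σ = 0.02, clipped to [0, 1].

The construction guarantees the properties the pipeline and classifier
rely on: malignant boundary-curvature variance exceeds benign in ≥ 95% of
seeded pairs, and clean-vs-noisy PSNR decreases monotonically in the
speckle scale.

What the generator does **not** emulate: anatomy (ducts, shadowing,
posterior enhancement), depth-dependent attenuation, operator variability,
multiple or subtle lesions, class overlap. Passing tests on phantoms
therefore demonstrate that the *pipeline machinery* (arithmetic, training,
tuning, metrics) works end to end — not clinical-grade segmentation or
diagnosis.

Splits are stratified by class with ratio 0.8; 312 phantoms split 250/62
(the exact 80:20 rounding; a 252/60 split would be 80.8:19.2).

## 7. Metrics and classifier

Pixel-level confusion counts feed accuracy, precision, specificity,
sensitivity, F-score, IoU and DSC; undefined ratios are NaN with a flag,
never silently 0. `dsc = 2·iou/(1+iou)` holds as an algebraic identity.
PSNR reports +inf for identical images. SSIM uses the canonical Gaussian
window (11×11, σ 1.5), stabilizers `C1 = (0.01·peak)²`,
`C2 = (0.03·peak)²`, population moments, border cropped — verified to
1e-6 against an independent reference implementation.

Lesion-level classification uses eight features of the largest connected
component: area fraction, circularity `4πA/P²` (Crofton perimeter — the
chain-code estimator overestimates smooth boundaries by ~3%, pushing disks
visibly below 1), solidity, boundary-curvature variance, interior
variance, local contrast, interior mean, interior/background contrast
ratio. The separator is a linear maximum-margin classifier (SVM) on
standardized features; the margin accompanies each 0/1 decision. Texture
is deliberately two summary statistics, not a co-occurrence suite — the
phantom classes are separable on geometry alone, and the feature list is
an extension point.

## 8. Pipeline and determinism

`run_pipeline` executes: phantoms → denoiser training → POA tuning (on a
small fitness split, default config warm-started) → segmenter training on
*denoised* images → segmentation + post-processing on the chosen
arithmetic backend → lesion classification (trained on ground-truth-mask
features, evaluated on predicted-mask features, falling back to the truth
mask when a prediction is empty, counted) → metrics. One master seed
derives every stage seed; the report contains no timestamps or wall times
(those go to stderr logging), so identical (config, seed) reproduces the
report byte for byte. The YAML config is schema-validated with unknown
keys rejected.

Problem sizes used by the shipped verification runs: exhaustive 8-bit
arithmetic plus 10^5 (tests) / 2·10^4 (acceptance script) sampled pairs at
16/32 bits; 100 (tests) / 20 (script) random 16×16 emulated-convolution
layers; 20-seed optimizer benchmarks; a 300-phantom 32×32 dataset (60-test
split) for the end-to-end run; a 10-phantom reduced configuration for the
byte-identity re-run check.

## 9. Known limitations

* Emulated backends run at Python speed (~10^4 scalar multiplies/s); they
  are for verification at small sizes, not throughput.
* fp16 inference flushes small activations to zero; on deep/wide networks
  the accumulated error can flip pixels near the mask threshold — the
  backend-agreement contract is ≥ 99% of pixels, not 100%.
* The CNN engine supports stride-1 same-padded 3×3 stacks (what the
  architecture uses); it is not a general conv framework.
* POA is a metaheuristic: benchmark medians are seeded and reproducible,
  but individual runs vary by orders of magnitude.
* Classifier features assume a single dominant lesion; multi-focal disease
  is out of scope.
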