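# Methods

## Problem and scope

`eggan` implements two trainable translators between 2-D grayscale medical
imaging domains (e.g. MRI ↔ CT, PD ↔ T2, motion-corrupted → clean):

1. **Paired translator** — an encoder-decoder network trained with an
   edge-sensitive composite loss on co-registered source/target slices.
2. **Unpaired translator (EGGAN)** — a two-generator, two-discriminator
   cycle-consistent GAN with least-squares adversarial objectives and an
   *edge-maintenance* penalty computed by a frozen, separately pretrained
   edge-detector U-Net.

Because real multi-modal clinical datasets cannot be bundled, the package
ships a seeded synthetic phantom generator that emulates the relevant
structure of such data: two co-registered renderings of one tissue geometry
with domain-specific intensity mappings, an unpaired variant obtained by
shuffling targets, and a motion-corrupted variant.

## Networks

**Generator.** The encoder uses a stem convolution followed by `levels`
stages of strided 3×3 convolution (stride 2 replaces pooling, so no level
loses more than half its resolution at once) and `res_blocks_per_level`
residual blocks (conv–instance-norm–ReLU ×2 with additive skip). With the
256-px default and 5 levels the bottleneck is 8×8. Fully connected layers
are absent; the network is fully convolutional.

Every encoder level's features pass through a **global-to-local fusion**
block on their skip pathway before entering the matching decoder level.
The block convolves its input with one 3×3 kernel per dilation rate
(default rates 3, 6, 12; padding `radius × rate` keeps the spatial size)
and aggregates from the largest rate inward: the most global branch is
computed first, then each more local branch is folded in. The fold `⊕` is
configurable:

* `concat_project` (default): channel concatenation followed by a 1×1
  projection back to the branch width — preserves all context levels;
* `sum`: plain addition — cheaper, offered for ablation.

The decoder doubles resolution with a **dual-branch interleaved
upsampler**: branch 1 applies four convolutions with 2×2, 3×2, 2×3 and 3×3
kernels, each producing an H×W map, and interleaves them into a 2H×2W map
at sub-pixel phases (even,even), (odd,even), (even,odd), (odd,odd); branch
2 does the same with four 5×5 convolutions; the branches are summed. The
rectangular kernels use trailing-edge (bottom/right) zero padding so all
four phase maps are exactly H×W. The phase assignment is fixed as listed;
any consistent assignment is equivalent up to learned weights. The output
head is a 3×3 convolution with tanh, so generator outputs live in [−1, 1].

**Discriminator.** A PatchGAN: `n_layers` stride-2 4×4 convolutions
(instance norm except the first, leaky ReLU 0.2), one stride-1 4×4
convolution, and a final 1-channel 4×4 convolution emitting a grid of raw
patch scores (no terminal sigmoid — the least-squares loss operates on raw
scores). With 3 layers a 256-px input yields a 30×30 score grid
(70-px receptive field per score).

**Edge detector.** A U-Net (`depth` levels, nearest-neighbour upsampling,
skip concatenation) producing single-channel logits; `edge_map` applies a
sigmoid to give per-pixel edge probability in [0, 1]. It is pretrained to
reproduce Canny edge maps (Gaussian sigma 1.0, hysteresis thresholds
0.1/0.3 of the normalised range — the detector itself is threshold-free
at inference) under binary cross-entropy, then frozen.

## Losses

All images enter the networks scaled from the canonical 12-bit range
[0, 4095] to [−1, 1]; losses are computed on the network scale, metrics
always on the de-normalised 12-bit scale.

Paired composite, with `g_e` the estimate and `g_r` the reference:

    e_L2 = mean (g_e − g_r)²
    e_G  = mean |∇x g_e − ∇x g_r| + |∇y g_e − ∇y g_r|
    e_N  = mean 1 − cos(n_e, n_r),   n = [∇x, ∇y, 1]
    e_T  = e_L2 + e_G + e_N          (unweighted)

∇x/∇y are forward differences with the last column/row set to zero
(replicate edge handling). Consequences worth knowing: a pure constant
shift has e_G = e_N = 0 by construction, and hand-computed values for
ramp images carry a boundary factor (n−1)/n from the zeroed last
column. The constant third component of the normals bounds each per-pixel
e_N term in [0, 2] and keeps the denominator ≥ 1.

Unpaired composite:

    e_CG = e_LSGAN1 + e_LSGAN2 + λ_Cyc·e_Cyc + λ_iden·e_iden
    e_T  = e_CG + λ_EM·e_EM

with defaults λ_Cyc = 10, λ_iden = 10, λ_EM = 5. The two LSGAN terms are
the two translation directions (per-direction discriminators D_B, D_A);
cycle and identity terms are L1, following the standard cycle-consistent
formulation. The edge-maintenance term is

    e_EM = mean |F(translated) − F(source)| + mean |F(cycled) − F(source)|

with F the frozen edge detector and the source's edge map treated as a
fixed reference (no gradient flows into it). It is applied symmetrically
in both cycle directions by default (`edge_maintenance_both_directions`);
a single-direction variant is a config switch, since either reading is
defensible. Each per-term toggle and weight lives in `LossWeights`.

## Training

Three loops (`eggan.train`), all pure functions of (data, config, seed):

* `train_edge_detector` — BCE against Canny maps; returns the net frozen.
* `train_paired` — minimises e_T on co-registered pairs.
* `train_eggan` — alternating updates: both discriminators first (on
  detached fakes), then both generators jointly on the full composite.
  No image-history buffer is used. The trainer sees only the
  (sources, targets) view of the sample set; the recorded pairing
  permutation is structurally withheld and used only by evaluation.

Reference hyperparameters for full-scale training: 100 epochs; batch 2,
learning rate 1e-4 (paired); batch 4, learning rate 5e-4 (unpaired);
first-moment decay ("momentum") 0.9. The optimizer is Adam with
β1 = momentum_beta by default — the momentum convention with no optimizer
named is interpreted as Adam's first moment, standard for this model
family; plain SGD with momentum is selectable (`optimizer:
"sgd_momentum"`). The learning rate is constant (no schedule).

Augmentation (paired transforms share the random draws between source and
target): horizontal and vertical flips with probability 0.5 each; random
crop to a 0.9 area fraction followed by bilinear resize back; rotation
uniform in [−5°, +5°]. Draws are per sample, not per batch.

## Phantom generator

Each sample draws a nested-ellipse "head": an outer skull ring (label 1),
an inner brain region (label 2), and interior structures (labels 3+),
Shepp-Logan-like, with the border ring guaranteed background. Both domains
are rendered from the same label map through per-tissue intensity lookup
tables on the 12-bit scale (domain A is MRI-like — bright soft tissue,
dark bone; domain B is CT-like — bright bone), followed by Gaussian
boundary smoothing (default sigma 1 px) and additive Gaussian noise
(default sigma 40 of 4095 per domain, a mid-single-digit-percent noise
level typical of clinical SNR). The map tissue → intensity must be
injective in domain B wherever it is in domain A, so a deterministic
tissue-wise lookup is a perfect A→B translator; with zero noise and zero
smoothing it achieves exactly zero error and serves as the floor any
trained model is compared against.

Unpaired sets shuffle targets with a recorded permutation (re-drawn
deterministically if more than 10% of indices map to themselves, so
"unpaired" is meaningful even at small n). Motion corruption replaces a
chosen number of rows of the image's 2-D DFT (k-space lines) with the
corresponding rows of a rigidly translated copy (shift uniform within
±max_shift px per axis) — the standard ghosting simulation for subject
motion during phase encoding; severity is parametric through the line
count and shift bound.

All randomness is keyed by `(seed, index, purpose)` through
`numpy.random.SeedSequence`, so datasets are bit-reproducible and
extending a dataset never perturbs earlier samples.

What the phantoms do *not* emulate: anatomical realism, MR physics (bias
fields, partial volume, multi-coil effects), inter-subject registration
error, 3-D structure. Passing tests therefore demonstrate correctness of
the algorithms and the expected qualitative behaviours (learning progress,
the effect of the edge term), not clinical-grade translation accuracy.

## Metrics

E_RMSE, E_MAE, E_PSNR = 20·log10(4095 / RMSE) and Gaussian-windowed E_SSIM
(window 11, sigma 1.5, k1 = 0.01, k2 = 0.03, L = 4095, valid windows
only), all computed on de-normalised 12-bit intensities — an explicit
scale guard rejects network-range images. Identical inputs report PSNR as
a documented 200 dB cap rather than infinity. Two formula variants that
circulate with inconsistent namings — an MAE with a nested square root and
a PSNR dividing by MSE rather than RMSE — are available behind
`as_printed=True` for exact-formula comparison; the standard textbook
forms are the defaults because reported magnitudes in this task family
(PSNR ≈ 17–23 dB) are only consistent with the standard definitions.

## Numerical core

The networks and training run on a compact reverse-mode automatic
differentiation engine (`eggan.autodiff`) over float64 numpy arrays:
broadcasting arithmetic, pointwise nonlinearities, reductions, im2col
2-D convolution with stride and dilation, sub-pixel interleaving,
forward-difference image gradients, a numerically stable BCE-with-logits,
and Adam / SGD-momentum optimizers. Gradients of every operation are
verified against central finite differences in the test suite, and the
dilated convolution against an independent double-loop evaluation.
Float64 keeps oracle comparisons tight (1e-6 absolute) and training
bit-reproducible for a fixed seed on one machine.

## Problem sizes used by the test suite and acceptance script

Training-based checks run at small scale on CPU, chosen once as the
smallest sizes at which the tested properties are stable:

* Edge detector: 64-px phantoms, 60 train / 12 held out, depth-3 U-Net
  (base 8 channels), 10 epochs, batch 4, lr 2e-3. Held-out Dice vs Canny
  reaches ≈ 0.75 (≥ 0.6 required; untrained ≈ 0.08–0.11).
* Paired translator: 64-px phantoms, 32 train / 8 validation, 3-level
  generator (base 8), 5 epochs, batch 2, lr 1e-3. Validation SSIM rises
  from ≈ 0.01 (random init) to ≈ 0.13–0.14.
* Unpaired EGGAN: 32-px phantoms (4 tissues, geometry scaled to fit),
  12 samples per side, 12 epochs, batch 4, lr 5e-4, seeds 0–2 for the
  λ_EM ∈ {5, 0} ablation. SSIM against the withheld true pairing improves
  over the initial weights, and λ_EM = 5 lowers the translated-vs-source
  edge-map discrepancy relative to λ_EM = 0 in the majority of seeds.

At these scales a full suite run plus the acceptance script completes in
a few minutes; the reference hyperparameters above remain the defaults
for real use.

## Known limitations

* GAN training at toy scale is noisy; individual seeds can show weak or
  reversed orderings, which is why the ablation is judged by majority
  over three seeds.
* The interleaved upsampler's zero padding makes border pixels of each
  doubled map depend on fewer taps; contracts about constant inputs hold
  in the interior.
* SSIM uses valid windows only, so images must be at least 11 px per side.
* Checkpoints store raw float64 weights; they are reconstructed from the
  embedded config and are not portable across architecture changes that
  alter parameter shapes.
* Only single-channel 2-D slices are supported; volumes are processed
  slice-wise through the NIfTI reader.
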