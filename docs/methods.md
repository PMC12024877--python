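# Methods

## Scope and intent

`sufseg` implements a conditional denoising-diffusion segmentation method at
desk scale: every component of the method — the diffusion algebra, the
two-encoder denoising network, the step-uncertainty fusion, the losses and
metrics — is present and tested, while the data are synthetic phantoms and
the default compute envelope is one CPU.  Nothing in the package depends on
GPU frameworks; the network runs on a purpose-built NumPy autodiff engine.

## Synthetic corpus: what it emulates, and what it does not

The generator emulates the *structure* of a simulated-defect skull corpus:

- 125 skulls × 21 defects = 2625 records at full count;
- 7 anatomical regions, 3 defects per region per skull;
- complexity tiers simple/moderate/complex in per-skull counts 9/7/5
  (corpus totals 1125/875/625).  The per-skull allocation is our exact
  reconstruction of the stated corpus totals — only totals are published;
- laterality left/right/bilateral, one of each per region triple;
- defect maximum diameter within 15–45 mm, enforced by construction
  (radius growth until ≥ 15 mm, clipping ball of diameter 45 mm);
- train/test split by skull (never by defect).  Every skull has an
  identical region/complexity composition, so any by-skull split is
  exactly stratified.

Phantom skulls are two fused ellipsoidal shells (calvarium + facial/
mandibular block) with zones assigned by geometric sector rules; axes are
jittered ±3 % per seed.  Defects are subtracted unions of spheres whose
radius is angularly modulated by a smooth random field (von Mises–Fisher
bumps), with complexity controlling sphere count (1 / 2–3 / 4–5) and
relative amplitude (≤ 0.12 / 0.15–0.30 / 0.30–0.45).

What a green test does **not** establish: anatomical realism, CT intensity
statistics, registration artefacts, or defect-shape distributions of real
trauma.  Bilateral defects in far-lateral regions (e.g. zygomatic arch) are
placed at the midline within the region's height/depth band — a geometric
convention, since such defects cannot cross the midline inside the region
itself.

Physical scale: at desk grids (32³ voxels, 1 mm) the upper half of the
15–45 mm size envelope cannot fit, so target diameters are drawn from
[15, min(45, 0.6·grid extent)] mm.  The envelope invariant holds at every
scale; the full range is only reachable on larger grids (e.g. 128³ at
0.5 mm).  Defect mean volume approaches the published ~1.7 cm³ only at
those larger scales; it is a soft calibration, not an invariant.

## Diffusion formulation

Linear β schedule from 1e-4 to 0.02 over T steps (T = 1000 full scale);
ᾱ_t by cumulative product with the sentinel ᾱ₀ = 1.  Timesteps are 1-based
in the API.  The forward kernel is the standard variance-preserving form
(the source text implies but never writes it; we adopt it).  The network
predicts x̂0 directly; ε̂ is derived algebraically, and DDIM stepping is
fully deterministic (η = 0) — stochasticity enters only through the initial
noise x_T (or optional MC dropout).  Inference uses K strided timesteps
(K = 5 default), the most-denoised step last.

One-hot convention: label k → channel k.  The source's listing suggests a
reversed channel order; we treat that as notational and use the standard
order throughout (encode/decode are exact inverses either way).

## Network

Two structurally identical encoder pyramids — the feature encoder (image
only) and the denoising encoder (image ⧺ x_t) — with per-level scale-wise
feature summation; decoder skips are concatenation + 1×1×1 reduction;
2-block bottleneck at the deepest level.  Residual blocks: two 3×3×3 convs,
instance norm, SiLU; the (time + condition) embedding is injected per block
as an adaptive-instance-norm scale/shift.  Downsampling is strided
convolution, upsampling nearest-neighbour + conv (the source names
neither; chosen for stability on binary targets).  The condition descriptor
is region one-hot (7) + laterality one-hot (3).

Full-scale widths are 4 levels × 3 blocks at 64/128/256/512 channels with
256-dim time and 128-dim condition embeddings.  We report the parameter
count from the build rather than targeting a printed figure: with the
stated widths alone our build exceeds the published ~14 M, and the decoder/
bottleneck widths are unspecified, so the count is profile-dependent.

Output: per-channel logistic squashing to [0,1] (not a cross-channel
softmax), because training couples BCE and MSE to x̂0 per channel; decoding
for metrics is threshold 0.5 on the foreground channel (argmax for N > 2).

### Numerical stability of training

Three measures keep gradients alive in float32:

1. BCE is evaluated in logit space during training (`bce_logits`), giving
   the exact gradient (σ(z) − t)/n at arbitrary saturation.  The
   probability-space BCE (with clipping) remains the reference form.
2. The final sigmoid computes its derivative in float64, so σ′ never
   rounds to exactly zero while logits are recoverable.
3. Soft Dice/Tversky on 5-D tensors reduce per (sample, channel) and
   average, so a small foreground channel is not drowned by background.

Without (1)–(2) the model reliably collapsed to the all-background minimum
with exactly-zero gradients within a few optimizer steps.

## Training protocol

Full-scale defaults follow the published protocol: Adam (β₁ = 0.9,
β₂ = 0.999) at 5e-5 halved every 50 epochs, batch 16, 200 epochs, weight
decay 1e-3, random left–right flip augmentation (the flip also swaps the
laterality condition).  The alternative published rate 3e-4 can be set per
run.  Two published loss recipes exist; the compound Dice + BCE + MSE is
the default (it is tied to the model equations), Tversky (α = 0.7,
β = 0.3) is selectable.  Per training step, t ~ U[1, T] per sample.

### Desk and micro profiles

The desk profile is the smallest configuration that visibly learns on one
CPU: 8 skulls × 7 defects (one per region, complexities 3/2/2), 32³ grid at
1 mm, 3 levels × 1 block at 8 base channels, T = 100, batch 2, 10 epochs,
K = 5, S = 4.  Its learning rate is 2e-3, fixed from step-count arithmetic:
a ~200-step Adam run moves parameters by roughly lr × steps, and 5e-5 would
leave a fresh network at its initialization.  The micro profile (4 skulls,
16³, 2 epochs, K = 3, S = 2) exists purely for determinism and smoke tests;
its scores are meaningless by design.

## Fusion

Both published weighting schemes are implemented behind `variant`:

- `softmax` (default): per-voxel variance over the S passes, tempered
  softmax across the K steps; λ = 5.0 is the published tuned value.
- `step-sigmoid`: entropy uncertainty −p̄ ln p̄ (natural log, so u ≤ 1/e
  and the (1 − u) factor is always valid) and step prior
  e^{σ(i/scale)}; `scale` defaults to K (no published value exists).
  The literal form is unnormalized; `normalize=True` (default) makes the
  fused map a probability.

Which variant produced the published results is not stated; softmax is the
default because it carries the tuned λ.  The K fused steps are the K DDIM
steps of the trajectory in prediction order (the source does not specify a
subset rule); pass count S defaults to 10 per the published M = 10.

## Metrics

DSC = 2|P∩G|/(|P|+|G|) (1.0 when both empty); RECALL = TP/(TP+FN),
undefined for empty G and excluded from aggregates; HD95 = 95th percentile
(linear interpolation) of the pooled symmetric surface-distance multiset in
mm.  Surfaces are mask voxels with ≥ 1 background face-neighbour; distances
use exact Euclidean distance transforms with anisotropic spacing.  The
published formula mixes max-Hausdorff notation with a percentile
description; the pooled-percentile reading is the common one and is what
the brute-force oracle in the tests implements independently.  Evaluation
targets the defect/implant mask (prediction vs simulated defect), matching
the repair-task framing; per-region means mirror the published table rows.

## Known limitations

- Phantoms are geometric stand-ins; no claim of anatomical validity.
- Desk-scale scores are far below published full-scale results by design;
  the acceptance checks are structural and relative (trained > untrained),
  not absolute.
- The autodiff engine is single-threaded and implements exactly the ops
  this architecture needs; it is not a general framework.
- Bit-for-bit reproducibility holds for fixed seed, config, and BLAS; the
  guarantee is within a machine/library build, as for any floating-point
  pipeline.
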