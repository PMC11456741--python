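# Methods

This note documents the models, numerical conventions and design choices in
`cvfreq`, and what the synthetic experiments do and do not demonstrate.

## Complex layers as paired real computations

A complex feature map is stored as two real arrays (real and imaginary parts
of identical shape). All complex layers are compositions of real operations
on this pair:

* **Complex convolution.** For input I = I_re + i·I_im and kernel
  K = K_re + i·K_im, the output is
  (I_re\*K_re − I_im\*K_im) + i(I_re\*K_im + I_im\*K_re) — four real
  convolutions. The implementation evaluates the equivalent block-matrix form
  (one real convolution of the stacked pair [I_re; I_im] with
  [[K_re, −K_im], [K_im, K_re]]), which is algebraically identical and does a
  single im2col pass. Kernels default to 3×3 with "same" zero padding; bias
  terms (one complex bias per output channel) are enabled by default.
* **Split activations.** CReLU applies ReLU to each part independently;
  CSigmoid (used only for attention weights) applies the logistic function to
  each part, so both output parts lie in (0, 1). Split activations are
  differentiable in each part separately, which is exactly the condition for
  backpropagation through the paired-real representation: the gradients
  computed here are the split (Wirtinger-equivalent) gradients, and no
  holomorphic machinery is needed or used.
* **Split max pooling.** Each part is max-pooled independently; the pooled
  real and imaginary values in one window may come from different pixels.
  Tie-breaking follows the underlying real argmax (first occurrence), which
  never affects pooled values. A max-by-magnitude variant
  (`cmaxpool(..., by_magnitude=True)`) that keeps real/imag pixel pairing is
  available for comparison; the split form is the default and is what the
  networks use.
* **Complex upsampling.** The same real interpolation (bilinear by default,
  half-pixel-centre convention; nearest available) applied to each part.
  Interpolation is a fixed linear operator, so its adjoint is exact.
* **Initialization.** Real and imaginary kernel parts are drawn independently
  from a zero-mean normal with per-part variance equal to half the Glorot
  variance 2/(fan_in + fan_out), so the expected squared complex magnitude
  matches the Glorot variance of an equivalent real layer. Biases start at
  zero, except attention-gate combining biases (below). All draws are
  deterministic given the architecture seed.

## Fourier encoding and decoding

The encoding layer (FTE) applies the unnormalized forward 2-D DFT per channel
and moves the DC coefficient to the centre pixel (row H//2, column W//2,
index map i → (i + ⌊n/2⌋) mod n — exact for odd and even sizes; the decoding
layer (FTD) inverts the shift, applies the 1/(HW)-normalized inverse DFT and
returns the real part. Under this convention ftd(fte(x)) = x to float
precision, and Parseval reads Σ|F|² = HW·Σ|I|²; the N² factor matters when
comparing loss magnitudes between the spatial and frequency domains (the
optional frequency-domain MSE divides by N² for this reason). FTD's discarded
imaginary residue is logged when it exceeds 1e-5 of the real norm; for a
trained complex network the mid-network spectra are generally not Hermitian,
and the real part is the defined output. Both layers are linear with exact
adjoints, so gradients flow through them like any other layer. Mid-network
FTE in CV-CAN transforms the multi-channel real feature maps channel-wise
without magnitude normalization; the following complex convolutions learn
their own scaling.

## Attention gates

The real gate follows the additive attention-U-Net construction: features x
(fine scale, F_l channels) are average-pooled to the gating signal's coarser
resolution; 1×1 convolutions project x and g to F_s intermediate channels
(default F_s = F_l/2, configurable); the sum passes ReLU, a 1×1 convolution
with bias, and a sigmoid; the weights β ∈ [0,1] are bilinearly upsampled back
to the feature resolution and multiply the features element-wise.

The complex gate rebuilds this chain from complex primitives (complex 1×1
convolutions, CReLU, CSigmoid, complex upsampling), giving complex weights α
with both parts in (0, 1). The gated output combines features with α by a
**per-pixel complex product** — the complex cross-term rule
(a_re·b_re − a_im·b_im) + i(a_re·b_im + a_im·b_re) applied pointwise, i.e.
the natural complex generalization of the real gate's element-wise product
(equivalently, a 1×1-support complex convolution). A whole-map "valid"
convolution combine is provided behind `combine="conv"` for ablation only; it
collapses the spatial dimensions and is not used by any architecture.

Two init details: the final gate bias b_s starts at 0 so gates start neutral
(β ≈ 0.5, trainable in both directions), and the combining bias b_g starts at
+0.1 so both split ReLU parts begin active even at very small intermediate
widths (at F_s = 1 a single dead unit would otherwise be possible at init).

## Architectures

All encoder blocks are Conv→ReLU→Conv→ReLU→MaxPool and all decoder blocks
Conv→ReLU→Conv→ReLU→Upsample (complex versions use the complex layers), with
channel widths doubling per scale from a configurable base (default 32;
desk-scale experiments use 8). Skip fusion follows the attention-U-Net
lineage: the gate's gating signal is the decoder's pre-upsampling
(coarser-scale) output, and the gated skip is concatenated with the upsampled
decoder features at the next block's input. There is no separate bottleneck
stack: the first decoder block's two convolutions act at the coarsest scale,
matching the literal n-encoder/n-decoder composition.

* **CV-Atten-UNet** (n = 4): FTE → complex encoders → complex decoders with
  complex gates → final block = FTD merged with a single real 3×3 convolution
  to one channel. Input dims must be divisible by 2⁴.
* **CV-CAN** (n = 2 real + 2 complex): real encoders → FTE → complex
  encoders → complex decoders (complex gates) → FTD → real decoders (real
  gates) → final 3×3 convolution. Divisibility 2⁴ (four poolings in total).
* **CV-DDAN** (n = 4): two weight-independent branches on the same image — a
  real-gated spatial U-Net body and a complex-gated frequency body (input
  through FTE, output through FTD) — each reduced to one channel by its own
  3×3 convolution, summed, and passed through a final 3×3 output convolution.
  Zeroing either branch's reduction isolates the other exactly.
* **CV-SRN**: the CV-Atten-UNet body on a half-size (square) input, FTD, then
  an upsampling block (bilinear ×2 + 3×3 convolution). A real input is passed
  through FTE first; an already-encoded frequency-domain input is accepted
  directly. 512×512 in → 1024×1024 out at full scale.
* **unet / attention_unet**: real four-scale baselines with the same block
  layout, skips plain or real-gated.

`count_parameters` counts each complex weight as two scalars; at equal base
width CV-DDAN carries ≈3.1× the parameters of the plain UNet.

## Training

MSE loss on the real spatial output against the reference, ADAM
(β₁ = 0.9, β₂ = 0.999, ε = 1e-8), default learning rate 1e-4, batch 4.
A frequency-domain MSE (`loss="fmse"`, Parseval-scaled) and a linear
learning-rate decay (`lr_schedule="linear"`) are available as options. Runs
are deterministic given the config: parameter init is seeded by the
architecture seed, batch order by the training seed, and there is no other
randomness. Checkpoints are single `.npz` files with the config JSON, named
parameter arrays and a format version. A non-finite loss aborts with a
diagnostic naming the first non-finite parameter (or reporting an activation
overflow if parameters are finite).

At inference, `restore()` normalizes 8/16-bit grayscale images to [0,1],
reflect-pads non-divisible sizes to the architecture's divisibility target,
crops back, and re-quantizes to the source bit depth. Evaluation metrics are
computed on predictions clipped to [0,1] — the displayable image that
`restore()` would write.

## Synthetic data

The phantom generator emulates the morphology of the real training
material — `filaments` (smooth random-walk curves with a Gaussian profile,
tubulin-like), `vesicles` (disks and rings of varied radius), `texture`
(band-limited random fields standing in for natural images) — with an
optional Gaussian PSF blur (σ = 1 px default) and normalization to [0, 1].
Noise models:

* **Mixed Poisson-Gaussian** (microscopy): y = Poisson(p·x)/p + N(0, σ²),
  variance x/p + σ² at signal level x; defaults p = 100 (low-SNR SIM-like
  shot noise) and read noise σ = 0.02.
* **AWGN** (natural images): N(0, (σ₈/255)²) in normalized units, σ₈ = 30 by
  default.

Corrupted images are clipped to [0, 1] (sensor saturation); the clip is part
of the noise model. Super-resolution pairs are Gaussian anti-aliased
(σ = 1 px) and decimated by exactly 2. Every pair in a dataset is a distinct
field of view (per-pair seeds spawned from the dataset seed), so train and
test sets generated from different seeds never share content.

What the phantoms do **not** model: reconstruction artifacts of SIM
algorithms, spatially correlated noise, illumination gradients, real
filament/vesicle density statistics. Passing tests demonstrate that the
pipeline learns and preserves spectra under the stated noise families at
small scale — not performance on real microscopy data.

## Metrics

PSNR = 10·log₁₀(max²/MSE) with max = 1.0 on normalized data (identical
images report an infinite sentinel rather than raising). SSIM is the
Gaussian-weighted Wang et al. form (11×11 window, σ = 1.5, K₁ = 0.01,
K₂ = 0.03, sample covariance), cross-checked against scikit-image in the
tests. The radial spectrum profile bins the centred log-magnitude spectrum
log(1+|F|) by integer radius from DC (log compression tames the DC-dominated
dynamic range); the spectral distance is the L2 distance between two such
profiles, optionally restricted to the upper half of the frequency bins. The
spectral distance to the reference is the package's operational statistic for
"preserves high-frequency content".

## Desk-scale experiments

Full-scale training (1024×1024 images, thousands of samples, GPU-class
budgets) is out of scope; `cvfreq.experiments` fixes two CPU-sized protocols:

* **Denoising**: CV-DDAN, base 8 channels, 64×64 filament phantoms with
  Poisson-Gaussian noise (p = 100, σ = 0.02), 200 training / 50 held-out
  pairs, 10 epochs, ADAM lr 2e-3 at batch 1 (the short schedule converges
  through many small steps; at larger batches the same epoch budget
  under-trains, and lr ≥ 4e-3 destabilizes). Reported against the noisy-input
  baseline (PSNR, SSIM, spectral distance) and against a plain UNet trained
  under the identical budget (SSIM non-inferiority).
* **Super-resolution**: CV-SRN, base 8, clean 32×32 → 64×64 filament pairs,
  10 epochs, lr 3e-3 at batch 2, against bicubic upsampling.

Typical outcomes (seed 1): the denoiser gains ≈ +4.8 dB PSNR over the noisy
input with a ≈5× smaller spectral distance, and CV-SRN exceeds bicubic by
≈ +4 dB. Run-to-run spread over seeds is a few dB at this scale.

## Known limitations

* The autodiff engine is minimal by design (no broadcasting beyond what the
  layers need, float64 only, single-threaded numpy); it is sized for
  desk-scale experiments, not for full-scale training.
* The split-sigmoid gate means a purely real input still acquires an
  imaginary attention component (sigmoid(0) = 0.5); this is a property of the
  split convention, made explicit in the tests.
* `cmaxpool` requires window/stride to tile the input exactly — no silent
  cropping.
* CV-SRN is a super-resolution network only; like the fully complex
  CV-Atten-UNet, it is not expected to handle joint denoising +
  super-resolution well, and the toolbox does not claim otherwise.
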