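# Methods

## Signal model and preprocessing

A CW radar at carrier f_c = 24.125 GHz (λ = c/f_c ≈ 12.4 mm) observing a
target closing at radial speed v returns a baseband tone at the Doppler
frequency f_d = 2v/λ ≈ 160.9 Hz per m/s. One classification event is a
frame of 1600 complex I/Q samples. At the default 2 kHz sampling rate a
frame spans 0.8 s.

The preprocessing unit computes a short-time Fourier transform: 24 windows
of 128 samples with hop 64 (50% overlap), each multiplied by a symmetric
Hamming window w[k] = 0.54 − 0.46·cos(2πk/127) and transformed by a
128-point FFT. Everything is fixed point:

- **Working format Q(16,11)** — 16-bit words, 11 fractional bits, real
  range ±16. Out-of-range values saturate (wraparound would corrupt
  magnitudes silently); multiplications truncate toward −∞ (an arithmetic
  right shift, which is what a bare datapath does). The hardware's actual
  rounding and overflow behaviour is not documented, so both are explicit,
  configurable decisions here.
- **ROMs** — window coefficients at Q(16,15), twiddle factors at Q(16,14),
  both rounded to nearest (ROM contents are computed offline, so there is
  no reason to accept truncation bias).
- **FFT** — decimation-in-time radix-2, bit-reversed input, seven butterfly
  stages, no per-stage scaling: headroom must come from the four integer
  bits of Q(16,11) plus input scaling. On in-range tones (amplitude ≤ 0.1,
  so the float DFT stays inside ±16) this achieves > 50 dB SQNR versus the
  float DFT; Q(16,14) saturates (range ±2) and degrades to a few dB, which
  reproduces the qualitative ordering that motivates choosing a format
  with more integer headroom than maximal precision.
- **Magnitude** — |X| ≈ |Re X| + |Im X|, which lies in [1, √2]× the
  Euclidean magnitude elementwise and avoids squaring/square roots.
- **Central 24 bins** — Doppler indices −12 … +11 around DC (natural-order
  FFT indices 116…127, 0…11), most-negative bin first. The symmetric
  choice with the extra bin on the negative side is isolated behind
  `select_center_bins`. At 2 kHz the kept band spans roughly ±1.17 m/s.
- **Binarization** — bit = 1 iff the raw integer magnitude ≥ 1140
  (≈ 0.557 in real units). The inclusive comparison follows the ≥ 0 branch
  of the folded batch-norm sign with positive γ. The threshold is a single
  scalar over the whole spectrogram, the reading consistent with a single
  deployed constant.

Rows of the resulting 24×24 bit map are Doppler (row 0 = most negative),
columns are time.

## Batch-norm folding

At inference, batch norm followed by sign is equivalent to one threshold
comparison: sign(γ(x−μ)/√(σ²+ε) + β) = +1 ⇔ γ·(x − T) ≥ 0 with
T = μ − (β/γ)·√(σ²+ε) and ε = 10⁻⁵. Inside the network the preactivation
is the integer 2p − N (p = popcount, N = fan-in), so T converts exactly to
an integer popcount threshold: for γ > 0, p ≥ ⌈(T+N)/2⌉; for γ < 0,
p ≤ ⌊(T+N)/2⌋. Channels whose threshold falls outside the reachable
popcount range are canonicalized to always-fire (γ-sign +1, threshold 0)
or never-fire (γ-sign +1, threshold N+1). Because the integer grid
conversion is exact, the folded model agrees with the pre-fold float
network on every sample — the tests assert zero mismatches, not a
tolerance.

## Network family and counting

Input 1×24×24 bits; first conv 5×5, later convs 3×3, all valid padding and
stride 1; a 2×2/2 pool after every conv; optionally one hidden FC; final FC
of width 2. No biases anywhere; two batch-norm parameters (γ, β) per
channel on every layer except the final FC. The spatial trace is
24→20→10→8→4(→2→1). This geometry is the unique member of the family
{first kernel 3/5/7} × {later kernel 3/5/7} × {same/valid} ×
{1/2/4 BN params} × {bias on/off} that reproduces all nine published
parameter totals, which a test verifies by brute-force enumeration. The
selected deployment network (conv 32,32,32; FC 32,2) has 20,576 parameters
and packs into 2572 bytes at one bit per parameter.

Tie-break at the output: equal scores classify as non-fall, minimizing
false alarms. Flattening before the first FC is channel-major then
row-major, and the ROM export preserves that order so hardware and
software agree bit-for-bit.

## Training

Latent real weights are kept in [−1, 1]; the forward pass uses
sign(w) (sign(0) = +1, matching the bit decoding), the backward pass
passes the gradient straight through the weight sign and windows the
activation gradient with 1{|y| ≤ 1} (hard-tanh STE). Optimizer: Adam,
cross-entropy loss, batch 32, stepped learning rate 0.005 / 0.001 / 0.0005
/ 0.0001 / 0.00005 / 0.00001 at epochs 0 / 60 / 100 / 120 / 140 / 160,
200 epochs by default, data shuffled then split 80/20. Batch-norm running
statistics use momentum 0.1.

One numerical choice matters: the final layer's scores are integers in
[−N, N], which saturates the softmax and can deadlock training on tiny
datasets (the two output rows receive exactly opposite gradients and can
lock sign-identical). Training logits are therefore scaled by 1/√N. This
affects only gradients; the deployed argmax is unchanged.

The trainer is written directly on numpy (explicit im2col forward/backward
passes, verified against numeric gradients); at ≤ ~10⁵ binary weights
these networks need nothing more.

`evaluate_kfold` wraps stratified k-fold and leave-one-subject-out splits
(scikit-learn) around the same fit loop.

## Synthetic data generator

Each activity class is a template of 1–3 point scatterers (torso plus
limbs) with a parametrized radial-velocity profile; the baseband signal is
s(t) = Σᵢ aᵢ·exp(j·(4π/λ)·rᵢ(t)) + circular Gaussian noise, with rᵢ the
integrated radial velocity. Default per-frame SNR is 20 dB. Frames are
cropped to 1600 samples centered on peak speed. Per-sample jitter
(kinematic parameters, direction, amplitudes, phases, noise) comes from
per-frame child seeds recorded in a manifest, so a corpus regenerates
bit-identically.

Kinematics:

- **Falls (a–e)**: speed ramps as sin² to a 2.0–3.3 m/s peak within
  0.3–0.55 s, then decays sharply at impact. Standing falls carry two limb
  scatterers at ~1.5× torso speed. Direction handling is deliberately not
  a pure cos(direction) projection: a falling body rotates and drops
  toward the waist-height radar, so falls project through a radial
  fraction drawn from ≈[0.55, 0.95], with the Doppler sign set by the
  nominal direction (randomly for lateral falls). Under a strict cosine
  projection lateral falls would have exactly zero Doppler and be
  undetectable in principle — unphysical for real geometry.
- **Gait (f, g)**: steady torso speed (≤ 0.8 m/s) with sinusoidal step
  modulation and, for fast walking, arm scatterers.
- **Other daily activities (h–l)**: smooth sin² start-stop bumps at
  ≤ 1.0 m/s (sign encodes sitting down versus standing up), with a
  double bump for lying-then-rising.
- Non-fall templates project with cos(direction ± a small spread), so the
  textbook cases (90° → no Doppler, 180° → mirrored spectrum) hold exactly
  for zero-spread templates.

Amplitudes (0.06–0.11 pre-quantization real units per torso scatterer) are
calibrated once so typical bin magnitudes straddle the 1140 threshold
rather than producing degenerate all-0/all-1 spectrograms.

What this emulates — and what it does not: superposed Doppler tones with
class-distinct velocity profiles, direction diversity, subject cycling for
LOSO splits. It does not model electromagnetic scattering, antenna
patterns, multipath, RF interference, range effects, clutter from other
movers, or realistic inter-subject variability. Consequently the synthetic
corpus is close to separable by construction (falls sweep past the
±1.17 m/s edge of the kept band; daily activities stay inside), and
passing accuracy tests demonstrates that the pipeline — preprocessing,
training, folding, integer inference — works end to end, not that the
classifier would reach comparable accuracy on real radar recordings.

## Problem sizes and defaults

The default corpus is 40 frames per class (480 total), which keeps a full
simulate → preprocess → train(60 epochs) → evaluate cycle around two
minutes on one CPU core; the composition of the original recordings
(170–340 per class) is available behind `table_proportional=True`.
Training for the published 200 epochs is the `TrainConfig` default; the
pipeline and tests use 60 epochs, past the point where held-out accuracy
on the synthetic corpus stops moving.

## Known limitations

- The fixed binarization threshold is a deployment constant; adaptive
  thresholding or AGC for varying range/environment is out of scope.
- The FFT model is behavioral: numerically bit-exact per the documented
  rounding/overflow decisions, but those decisions are this package's,
  not verified against the original RTL.
- CW radar has no range axis; nothing here handles multiple simultaneous
  movers.
- Hardware concerns — bus timing, ping-pong buffer scheduling, cycle
  counts, power — are intentionally not modeled.
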