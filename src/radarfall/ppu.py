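"""Bit-exact behavioral model of the preprocessing unit (PPU).

One classification event is a frame of 1600 complex baseband samples. The
PPU slides a 128-sample Hamming window with 50% overlap (hop 64) across the
frame, computes a 128-point fixed-point radix-2 FFT per window, approximates
each bin magnitude as |Re| + |Im|, keeps the central 24 Doppler bins
(indices -12 ... +11 around DC), and compares each magnitude against a fixed
integer threshold. The 24 windows x 24 bins of comparison bits form the
binary spectrogram fed to the classifier.

The model mirrors the hardware datapath: window and twiddle coefficients
come from quantized ROMs, every FFT intermediate saturates to the working
Q-format, and the threshold comparison happens in raw integer units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fixedpoint import (
    ROUND_HALF_UP,
    FixedArray,
    QFormat,
    fixed_mul,
    quantize,
)

__all__ = [
    "RawRadarFrame",
    "StftConfig",
    "BinarySpectrogram",
    "BnFoldParams",
    "hamming_rom",
    "twiddle_rom",
    "fft_fixed",
    "magnitude_approx",
    "select_center_bins",
    "binarize_column",
    "fold_bn_to_threshold",
    "stft_binary_spectrogram",
    "stft_binary_spectrogram_float",
]

# ROM formats: window coefficients live in [0, 1), twiddles in [-1, 1]
WINDOW_FMT = QFormat(16, 15)
TWIDDLE_FMT = QFormat(16, 14)


@dataclass
class RawRadarFrame:
    """One classification event: complex I/Q baseband samples.

    Default geometry: 128 + 23 * 64 = 1600 samples -> 24 STFT columns.
    """

    samples: np.ndarray
    sample_rate_hz: float = 2000.0
    label: Optional[str] = None
    subject_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.ndim != 1:
            raise ValueError("frame samples must be a 1-D complex array")


@dataclass
class StftConfig:
    """Geometry and quantization of the binary-spectrogram pipeline."""

    window_len: int = 128
    fft_points: int = 128
    hop: int = 64
    n_columns: int = 24
    n_kept_bins: int = 24
    fmt: QFormat = field(default_factory=lambda: QFormat(16, 11))
    threshold_raw: int = 1140

    def __post_init__(self) -> None:
        if self.hop != self.window_len // 2:
            raise ValueError("hop must be half the window length (50% overlap)")
        if self.fft_points != self.window_len:
            raise ValueError("fft_points must equal window_len")
        if self.n_kept_bins > self.fft_points:
            raise ValueError("cannot keep more bins than FFT points")
        if not (self.fmt.raw_min <= self.threshold_raw <= self.fmt.raw_max):
            raise ValueError("threshold_raw outside the Q-format range")

    @property
    def frame_len(self) -> int:
        return self.window_len + (self.n_columns - 1) * self.hop


@dataclass
class BinarySpectrogram:
    """24x24 single-bit time-frequency map.

    Row 0 is the most negative Doppler bin after centering (bin -12 for the
    default geometry); columns are window indices in increasing time.
    """

    bits: np.ndarray
    row_order: str = "doppler_ascending_from_most_negative"
    col_order: str = "time_ascending"

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2:
            raise ValueError("spectrogram bits must be 2-D")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("spectrogram elements must be 0 or 1")


@dataclass
class BnFoldParams:
    """Batch-norm parameters to fold into a threshold: gamma, beta, running
    mean mu, running variance sigma2, and the numerical-stability eps."""

    gamma: float
    beta: float
    mu: float
    sigma2: float
    eps: float = 1e-5

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("variance must be non-negative")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.gamma == 0:
            raise ValueError("gamma = 0 is not invertible")


def hamming_rom(n: int = 128, fmt: QFormat = WINDOW_FMT) -> FixedArray:
    """Quantized symmetric Hamming window ``0.54 - 0.46 cos(2 pi k/(n-1))``.

    Stored round-to-nearest: ROM contents are computed offline, so there is
    no reason to accept truncation bias.
    """
    if n < 2:
        raise ValueError("window needs at least 2 points")
    k = np.arange(n)
    w = 0.54 - 0.46 * np.cos(2.0 * np.pi * k / (n - 1))
    return quantize(w, fmt, rounding=ROUND_HALF_UP)


def twiddle_rom(n: int = 128, fmt: QFormat = TWIDDLE_FMT) -> FixedArray:
    """Quantized twiddle factors ``W_n^k = exp(-2 pi i k / n)``, k = 0..n/2-1."""
    k = np.arange(n // 2)
    w = np.exp(-2j * np.pi * k / n)
    return quantize(w, fmt, rounding=ROUND_HALF_UP)


def _bit_reverse_indices(n: int) -> np.ndarray:
    bits = int(np.log2(n))
    idx = np.arange(n)
    rev = np.zeros(n, dtype=np.int64)
    for _ in range(bits):
        rev = (rev << 1) | (idx & 1)
        idx >>= 1
    return rev


def _sat_add(a: np.ndarray, b: np.ndarray, fmt: QFormat) -> np.ndarray:
    return np.clip(a + b, fmt.raw_min, fmt.raw_max)


def fft_fixed(
    segment: FixedArray,
    fmt: QFormat | None = None,
    twiddles: FixedArray | None = None,
) -> FixedArray:
    """In-order DFT via decimation-in-time radix-2 stages, all fixed point.

    Input is bit-reverse permuted, then log2(n) butterfly stages run with
    quantized twiddles; every multiply truncates back to ``fmt`` and every
    add saturates. No per-stage scaling is applied: headroom must come from
    the format's integer bits and from input scaling.
    """
    if not segment.is_complex:
        segment = FixedArray(segment.raw, segment.fmt, imag=np.zeros_like(segment.raw))
    n = len(segment)
    if n < 2 or (n & (n - 1)) != 0:
        raise ValueError(f"FFT length must be a power of two >= 2, got {n}")
    fmt = fmt or segment.fmt
    if twiddles is None:
        twiddles = twiddle_rom(n)

    rev = _bit_reverse_indices(n)
    re = segment.raw[rev].copy()
    im = segment.imag[rev].copy()
    tw_re, tw_im = twiddles.raw, twiddles.imag
    shift = fmt.frac_bits + twiddles.fmt.frac_bits - fmt.frac_bits  # = tw frac bits

    size = 2
    while size <= n:
        half = size // 2
        stride = n // size
        # butterfly inputs: a = x[b + j], b = x[b + j + half] for each block b
        starts = np.arange(0, n, size)[:, None]
        j = np.arange(half)[None, :]
        ia = (starts + j).ravel()
        ib = ia + half
        k = np.tile(j * stride, (len(starts), 1)).ravel()
        wr, wi = tw_re[k], tw_im[k]

        # t = W * x[ib], truncated back to fmt then saturated
        prod_re = (re[ib] * wr - im[ib] * wi) >> shift
        prod_im = (re[ib] * wi + im[ib] * wr) >> shift
        prod_re = np.clip(prod_re, fmt.raw_min, fmt.raw_max)
        prod_im = np.clip(prod_im, fmt.raw_min, fmt.raw_max)

        ar, ai = re[ia], im[ia]
        re[ia] = _sat_add(ar, prod_re, fmt)
        im[ia] = _sat_add(ai, prod_im, fmt)
        re[ib] = _sat_add(ar, -prod_re, fmt)
        im[ib] = _sat_add(ai, -prod_im, fmt)
        size *= 2

    return FixedArray(re, fmt, imag=im)


def magnitude_approx(spectrum: FixedArray) -> FixedArray:
    """Approximate magnitude |Re| + |Im| with saturation.

    The approximation over-estimates: it lies in [1, sqrt(2)] times the
    exact Euclidean magnitude elementwise.
    """
    if not spectrum.is_complex:
        return FixedArray(np.abs(spectrum.raw), spectrum.fmt)
    return FixedArray(np.abs(spectrum.raw) + np.abs(spectrum.imag), spectrum.fmt)


def center_bin_indices(n: int, n_keep: int) -> np.ndarray:
    """Natural-order FFT indices of the central ``n_keep`` Doppler bins,
    ordered most-negative first (bins -n_keep/2 ... n_keep/2 - 1)."""
    if n_keep % 2 != 0:
        raise ValueError("n_keep must be even (symmetric Doppler band)")
    if n_keep > n:
        raise ValueError("n_keep exceeds spectrum length")
    return np.concatenate([np.arange(n - n_keep // 2, n), np.arange(n_keep // 2)])


def select_center_bins(spectrum: FixedArray, n_keep: int = 24) -> FixedArray:
    """Keep the central Doppler band: bins -n_keep/2 ... +n_keep/2 - 1 in
    zero-frequency-centered order (for n_keep = n this is an fftshift)."""
    idx = center_bin_indices(len(spectrum), n_keep)
    return spectrum[idx]


def binarize_column(magnitudes: FixedArray, threshold_raw: int) -> np.ndarray:
    """One spectrogram column: bit = 1 iff raw magnitude >= threshold.

    The comparison is inclusive, matching the >= 0 branch of the folded
    batch-norm sign with positive gamma.
    """
    return (magnitudes.raw >= threshold_raw).astype(np.uint8)


def fold_bn_to_threshold(p: BnFoldParams) -> tuple[float, int]:
    """Fold batch-norm + sign into a single threshold comparison.

    Returns ``(T, gamma_sign)`` with ``T = mu - (beta/gamma) sqrt(sigma2+eps)``
    such that ``sign(BN(x)) = +1  <=>  gamma_sign * (x - T) >= 0``.
    """
    t = p.mu - (p.beta / p.gamma) * np.sqrt(p.sigma2 + p.eps)
    return float(t), (1 if p.gamma > 0 else -1)


def stft_binary_spectrogram(frame: RawRadarFrame, cfg: StftConfig | None = None) -> BinarySpectrogram:
    """Full PPU pipeline: window -> fixed FFT -> |Re|+|Im| -> central bins ->
    threshold, repeated over the 24 hops. Fully deterministic."""
    cfg = cfg or StftConfig()
    if len(frame.samples) != cfg.frame_len:
        raise ValueError(
            f"frame length {len(frame.samples)} does not match config geometry {cfg.frame_len}"
        )
    window = hamming_rom(cfg.window_len)
    twiddles = twiddle_rom(cfg.fft_points)
    quantized = quantize(frame.samples, cfg.fmt)

    cols = np.empty((cfg.n_kept_bins, cfg.n_columns), dtype=np.uint8)
    for m in range(cfg.n_columns):
        seg = quantized[m * cfg.hop : m * cfg.hop + cfg.window_len]
        windowed = fixed_mul(seg, window, out_fmt=cfg.fmt)
        spectrum = fft_fixed(windowed, cfg.fmt, twiddles)
        mags = magnitude_approx(spectrum)
        kept = select_center_bins(mags, cfg.n_kept_bins)
        cols[:, m] = binarize_column(kept, cfg.threshold_raw)
    return BinarySpectrogram(cols)


def stft_binary_spectrogram_float(
    frame: RawRadarFrame, cfg: StftConfig | None = None
) -> BinarySpectrogram:
    """Float-precision reference of the same pipeline (exact DFT, exact
    window, |Re|+|Im| magnitude, threshold in real units). Used as the
    oracle for fixed/float consistency checks."""
    cfg = cfg or StftConfig()
    if len(frame.samples) != cfg.frame_len:
        raise ValueError("frame length does not match config geometry")
    k = np.arange(cfg.window_len)
    window = 0.54 - 0.46 * np.cos(2.0 * np.pi * k / (cfg.window_len - 1))
    thr_real = cfg.threshold_raw / cfg.fmt.scale
    idx = center_bin_indices(cfg.fft_points, cfg.n_kept_bins)

    cols = np.empty((cfg.n_kept_bins, cfg.n_columns), dtype=np.uint8)
    for m in range(cfg.n_columns):
        seg = frame.samples[m * cfg.hop : m * cfg.hop + cfg.window_len]
        spectrum = np.fft.fft(seg * window)
        mags = np.abs(spectrum.real) + np.abs(spectrum.imag)
        cols[:, m] = (mags[idx] >= thr_real).astype(np.uint8)
    return BinarySpectrogram(cols)
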