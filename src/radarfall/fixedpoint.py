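"""Signed fixed-point Q-format arithmetic with saturation.

Every intermediate of the preprocessing datapath is carried as a
:class:`FixedArray`: an integer array in raw units together with its
:class:`QFormat`.  A Q(W, F) number stores a real value ``v`` as the integer
``round(v * 2**F)`` clamped to the two's-complement range of ``W`` bits, so
the representable real range is ``[-2**(W-1-F), (2**(W-1)-1) / 2**F]``.

Overflow policy is saturation (wraparound would silently corrupt spectrogram
magnitudes); the default rounding is truncation toward negative infinity,
i.e. an arithmetic right shift, which is what a bare FPGA datapath does.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "QFormat",
    "FixedArray",
    "quantize",
    "dequantize",
    "fixed_mul",
    "sqnr_db",
    "Rounding",
]

# rounding mode names accepted throughout the package
TRUNCATE = "truncate"
ROUND_HALF_UP = "round_half_up"
Rounding = str

_QFMT_RE = re.compile(r"^Q\((\d+)[,.](\d+)\)$")


@dataclass(frozen=True)
class QFormat:
    """Signed fixed-point format: ``word_bits`` total, ``frac_bits`` fractional."""

    word_bits: int = 16
    frac_bits: int = 11

    def __post_init__(self) -> None:
        if not (0 < self.frac_bits < self.word_bits):
            raise ValueError(
                f"require 0 < frac_bits < word_bits, got Q({self.word_bits},{self.frac_bits})"
            )

    @property
    def scale(self) -> int:
        return 1 << self.frac_bits

    @property
    def raw_min(self) -> int:
        return -(1 << (self.word_bits - 1))

    @property
    def raw_max(self) -> int:
        return (1 << (self.word_bits - 1)) - 1

    @property
    def real_min(self) -> float:
        return self.raw_min / self.scale

    @property
    def real_max(self) -> float:
        return self.raw_max / self.scale

    @property
    def resolution(self) -> float:
        return 1.0 / self.scale

    @classmethod
    def parse(cls, text: str) -> "QFormat":
        """Parse ``"Q(16,11)"`` (comma or dot separator) into a QFormat."""
        m = _QFMT_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse Q-format string {text!r}")
        return cls(int(m.group(1)), int(m.group(2)))

    def __str__(self) -> str:
        return f"Q({self.word_bits},{self.frac_bits})"


def _saturate(raw: np.ndarray, fmt: QFormat) -> np.ndarray:
    return np.clip(raw, fmt.raw_min, fmt.raw_max)


class FixedArray:
    """Integer array in Q-format raw units; optionally complex.

    ``raw`` holds the real part (always present); ``imag`` holds the
    imaginary part's raw units when the array is complex, else ``None``.
    Raw values are saturated to the format's range at construction.
    """

    __slots__ = ("raw", "imag", "fmt")

    def __init__(self, raw, fmt: QFormat, imag=None):
        self.fmt = fmt
        self.raw = _saturate(np.asarray(raw, dtype=np.int64), fmt)
        self.imag = None if imag is None else _saturate(np.asarray(imag, dtype=np.int64), fmt)

    @property
    def is_complex(self) -> bool:
        return self.imag is not None

    @property
    def shape(self):
        return self.raw.shape

    def __len__(self) -> int:
        return len(self.raw)

    def __getitem__(self, idx) -> "FixedArray":
        return FixedArray(
            self.raw[idx], self.fmt, None if self.imag is None else self.imag[idx]
        )

    def to_float(self) -> np.ndarray:
        """Dequantize to float64 (complex128 when complex)."""
        re_part = self.raw / self.fmt.scale
        if self.imag is None:
            return re_part
        return re_part + 1j * (self.imag / self.fmt.scale)

    def __repr__(self) -> str:
        kind = "complex" if self.is_complex else "real"
        return f"FixedArray({kind}, shape={self.raw.shape}, fmt={self.fmt})"


def _round_raw(scaled: np.ndarray, rounding: Rounding) -> np.ndarray:
    if rounding == TRUNCATE:
        return np.floor(scaled).astype(np.int64)
    if rounding == ROUND_HALF_UP:
        return np.floor(scaled + 0.5).astype(np.int64)
    raise ValueError(f"unknown rounding mode {rounding!r}")


def quantize(values, fmt: QFormat, rounding: Rounding = TRUNCATE) -> FixedArray:
    """Quantize real (or complex) values into a saturating FixedArray.

    Out-of-range values saturate and never raise; for in-range values the
    round trip ``dequantize(quantize(x))`` errs by less than ``2**-frac_bits``.
    """
    values = np.asarray(values)
    if np.iscomplexobj(values):
        re_raw = _round_raw(values.real * fmt.scale, rounding)
        im_raw = _round_raw(values.imag * fmt.scale, rounding)
        return FixedArray(re_raw, fmt, imag=im_raw)
    return FixedArray(_round_raw(values * fmt.scale, rounding), fmt)


def dequantize(arr: FixedArray) -> np.ndarray:
    return arr.to_float()


def _shift_to(prod: np.ndarray, shift: int) -> np.ndarray:
    # arithmetic right shift == floor division by 2**shift (truncation
    # toward -inf, the datapath rounding convention)
    if shift >= 0:
        return prod >> shift
    return prod << (-shift)


def fixed_mul(a: FixedArray, b: FixedArray, out_fmt: QFormat | None = None) -> FixedArray:
    """Fixed-point multiply: full-precision integer product, then shift back
    into ``out_fmt`` with truncation and saturation.

    Complex x complex computes the four cross products at full precision,
    combines them, and shifts/saturates once per output component — the
    behaviour of a butterfly multiplier with a single output register.
    """
    if a.raw.shape != b.raw.shape and a.raw.size != 1 and b.raw.size != 1:
        raise ValueError(f"shape conflict in fixed_mul: {a.raw.shape} vs {b.raw.shape}")
    if out_fmt is None:
        out_fmt = a.fmt
    shift = a.fmt.frac_bits + b.fmt.frac_bits - out_fmt.frac_bits

    if a.is_complex and b.is_complex:
        re = _shift_to(a.raw * b.raw - a.imag * b.imag, shift)
        im = _shift_to(a.raw * b.imag + a.imag * b.raw, shift)
        return FixedArray(re, out_fmt, imag=im)
    if a.is_complex:
        return FixedArray(
            _shift_to(a.raw * b.raw, shift), out_fmt, imag=_shift_to(a.imag * b.raw, shift)
        )
    if b.is_complex:
        return FixedArray(
            _shift_to(a.raw * b.raw, shift), out_fmt, imag=_shift_to(a.raw * b.imag, shift)
        )
    return FixedArray(_shift_to(a.raw * b.raw, shift), out_fmt)


def sqnr_db(reference: np.ndarray, quantized: np.ndarray) -> float:
    """Signal-to-quantization-noise ratio, ``10 log10(sum|ref|^2 / sum|err|^2)`` dB."""
    reference = np.asarray(reference)
    quantized = np.asarray(quantized)
    if reference.shape != quantized.shape:
        raise ValueError("sqnr_db requires equal-length arrays")
    sig = float(np.sum(np.abs(reference) ** 2))
    if sig == 0.0:
        raise ValueError("reference has zero energy")
    noise = float(np.sum(np.abs(reference - quantized) ** 2))
    if noise == 0.0:
        raise ValueError("zero quantization noise: reference equals quantized signal")
    return 10.0 * np.log10(sig / noise)
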