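"""Binarized CNN: architecture grammar, parameter counting, and the
bit-exact XNOR/popcount inference engine.

Weights and activations are single bits (bit 1 <-> +1, bit 0 <-> -1). A
binary dot product over fan-in N is computed as ``2 p - N`` where ``p`` is
the popcount of the XNOR of the two bit vectors. Batch norm + sign collapses
to a per-channel integer popcount threshold, max-pooling on bits to a
logical OR, and the final fully connected layer emits raw integer scores —
the whole inference path is integer arithmetic.

Architecture family: input 1x24x24 binary spectrogram; first conv 5x5,
later convs 3x3, all valid padding, stride 1; 2x2/2 OR-pool after every
conv; optional hidden FC; final FC of size 2 (non-fall, fall). No biases
anywhere; two batch-norm parameters per channel on every layer except the
final FC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

__all__ = [
    "NetworkSpec",
    "BCNNModel",
    "TrainConfig",
    "NON_FALL",
    "FALL",
    "count_parameters",
    "weight_bit_count",
    "packed_size_bytes",
    "binary_conv2d",
    "binary_fc",
    "threshold_activate",
    "or_maxpool",
    "infer",
    "popcount_threshold_from_real",
]

NON_FALL = 0
FALL = 1
CLASS_NAMES = ("non-fall", "fall")


@dataclass(frozen=True)
class NetworkSpec:
    """Conv channel widths plus FC widths; everything else is fixed geometry."""

    conv_channels: Tuple[int, ...]
    fc_sizes: Tuple[int, ...]
    input_shape: Tuple[int, int, int] = (1, 24, 24)
    first_kernel: int = 5
    later_kernel: int = 3
    pool: int = 2

    def __post_init__(self):
        object.__setattr__(self, "conv_channels", tuple(int(c) for c in self.conv_channels))
        object.__setattr__(self, "fc_sizes", tuple(int(f) for f in self.fc_sizes))
        if len(self.fc_sizes) < 1 or self.fc_sizes[-1] != 2:
            raise ValueError("fc_sizes must end with the 2-way fall/non-fall output")
        if any(c < 1 for c in self.conv_channels) or any(f < 1 for f in self.fc_sizes):
            raise ValueError("layer widths must be positive")
        self.spatial_trace()  # validates geometry

    def kernel(self, i: int) -> int:
        return self.first_kernel if i == 0 else self.later_kernel

    def spatial_trace(self) -> List[int]:
        """Spatial side length after each conv and each pool; raises if the
        feature map collapses."""
        size = self.input_shape[1]
        trace = [size]
        for i in range(len(self.conv_channels)):
            size = size - self.kernel(i) + 1
            if size <= 0:
                raise ValueError(f"feature map collapsed at conv {i}: size {size}")
            trace.append(size)
            size = size // self.pool
            if size <= 0:
                raise ValueError(f"feature map collapsed at pool {i}")
            trace.append(size)
        return trace

    def flat_features(self) -> int:
        side = self.spatial_trace()[-1]
        chans = self.conv_channels[-1] if self.conv_channels else self.input_shape[0]
        if not self.conv_channels:
            side = self.input_shape[1]
        return chans * side * side

    def layer_fan_ins(self) -> List[int]:
        """Fan-in N per layer (conv: k^2 * C_in; fc: input features)."""
        fans = []
        c_in = self.input_shape[0]
        for i, c_out in enumerate(self.conv_channels):
            fans.append(self.kernel(i) ** 2 * c_in)
            c_in = c_out
        f_in = self.flat_features()
        for f_out in self.fc_sizes:
            fans.append(f_in)
            f_in = f_out
        return fans


def weight_bit_count(spec: NetworkSpec) -> int:
    """Number of binary weights (no batch-norm parameters)."""
    total = 0
    c_in = spec.input_shape[0]
    for i, c_out in enumerate(spec.conv_channels):
        total += spec.kernel(i) ** 2 * c_in * c_out
        c_in = c_out
    f_in = spec.flat_features()
    for f_out in spec.fc_sizes:
        total += f_in * f_out
        f_in = f_out
    return total


def count_parameters(spec: NetworkSpec) -> int:
    """Total parameters: binary weights plus two batch-norm parameters
    (gamma, beta) per output channel/unit on every layer except the final FC.
    There are no bias terms."""
    total = weight_bit_count(spec)
    for c_out in spec.conv_channels:
        total += 2 * c_out
    for f_out in spec.fc_sizes[:-1]:
        total += 2 * f_out
    return total


def packed_size_bytes(spec: NetworkSpec) -> int:
    """Bytes needed to store all parameters at 1 bit each."""
    count = count_parameters(spec)
    return -(-count // 8)  # ceil


# ---------------------------------------------------------------------------
# bit-domain primitives


def _check_bits(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only bits 0/1")
    return arr.astype(np.uint8)


def _xnor_popcount_matmul(w_bits: np.ndarray, x_bits: np.ndarray) -> np.ndarray:
    """Binary dot products via packed XNOR + popcount.

    ``w_bits``: (M, N) bit matrix, ``x_bits``: (N, P) bit matrix. Returns the
    (M, P) integer pre-activations ``2 p - N`` where p is the XNOR agreement
    count over the fan-in axis.
    """
    n = w_bits.shape[1]
    wp = np.packbits(w_bits, axis=1)  # (M, ceil(N/8))
    xp = np.packbits(x_bits.T, axis=1)  # (P, ceil(N/8))
    pad = 8 * wp.shape[1] - n  # zero padding agrees with itself -> subtract
    agree = np.bitwise_count(~np.bitwise_xor(wp[:, None, :], xp[None, :, :]))
    p = agree.sum(axis=2, dtype=np.int64) - pad
    return 2 * p - n


def _im2col(bits: np.ndarray, k: int) -> tuple[np.ndarray, int, int]:
    """(C, H, W) bits -> (C*k*k, H'*W') patch matrix, valid padding, stride 1."""
    c, h, w = bits.shape
    oh, ow = h - k + 1, w - k + 1
    windows = np.lib.stride_tricks.sliding_window_view(bits, (k, k), axis=(1, 2))
    # (C, OH, OW, k, k) -> (C, k, k, OH, OW) -> (C*k*k, OH*OW)
    cols = windows.transpose(0, 3, 4, 1, 2).reshape(c * k * k, oh * ow)
    return np.ascontiguousarray(cols), oh, ow


def binary_conv2d(input_bits: np.ndarray, weight_bits: np.ndarray) -> np.ndarray:
    """Valid, stride-1 binary convolution via XNOR/popcount.

    ``input_bits``: (C_in, H, W), ``weight_bits``: (C_out, C_in, k, k), both
    0/1. Returns integer pre-activations (C_out, H-k+1, W-k+1) equal to the
    float cross-correlation of the +/-1 decodings.
    """
    input_bits = _check_bits(input_bits, "input")
    weight_bits = _check_bits(weight_bits, "weights")
    if input_bits.ndim != 3 or weight_bits.ndim != 4:
        raise ValueError("expected input (C,H,W) and weights (C_out,C_in,k,k)")
    c_out, c_in, k, k2 = weight_bits.shape
    if k != k2:
        raise ValueError("kernels must be square")
    if input_bits.shape[0] != c_in:
        raise ValueError(
            f"channel mismatch: input has {input_bits.shape[0]}, weights expect {c_in}"
        )
    if input_bits.shape[1] < k or input_bits.shape[2] < k:
        raise ValueError("spatial size smaller than kernel")
    cols, oh, ow = _im2col(input_bits, k)
    preact = _xnor_popcount_matmul(weight_bits.reshape(c_out, -1), cols)
    return preact.reshape(c_out, oh, ow)


def binary_fc(input_bits: np.ndarray, weight_bits: np.ndarray) -> np.ndarray:
    """Fully connected binary layer: (F_in,) bits x (F_out, F_in) bits ->
    integer scores ``2 p - F_in``."""
    input_bits = _check_bits(input_bits, "input")
    weight_bits = _check_bits(weight_bits, "weights")
    if input_bits.ndim != 1 or weight_bits.ndim != 2:
        raise ValueError("expected input (F,) and weights (F_out, F)")
    if weight_bits.shape[1] != input_bits.shape[0]:
        raise ValueError("fan-in mismatch in binary_fc")
    return _xnor_popcount_matmul(weight_bits, input_bits[:, None])[:, 0]


def threshold_activate(
    preact: np.ndarray,
    gamma_sign: np.ndarray,
    popcount_threshold: np.ndarray,
    fan_in: int,
) -> np.ndarray:
    """Per-channel folded batch-norm activation, all integer.

    With raw popcount ``p = (preact + N) / 2`` and activation threshold
    ``T_a = 2 * popcount_threshold - N``: bit = 1 iff
    ``gamma_sign * (preact - T_a) >= 0`` (inclusive at equality).
    Channel axis is axis 0 of ``preact``.
    """
    preact = np.asarray(preact)
    gs = np.asarray(gamma_sign, dtype=np.int64)
    thr = np.asarray(popcount_threshold, dtype=np.int64)
    if np.any((gs != 1) & (gs != -1)):
        raise ValueError("gamma_sign entries must be +1 or -1")
    shape = (-1,) + (1,) * (preact.ndim - 1)
    t_a = (2 * thr - fan_in).reshape(shape)
    return (gs.reshape(shape) * (preact - t_a) >= 0).astype(np.uint8)


def or_maxpool(bits: np.ndarray, window: int = 2, stride: int = 2) -> np.ndarray:
    """2x2/2 max-pool as a logical OR on bit maps (floor semantics on odd
    spatial sizes). Equals float max-pooling of the +/-1 decoding."""
    bits = _check_bits(bits, "bits")
    if bits.ndim != 3:
        raise ValueError("expected (C, H, W) bit tensor")
    c, h, w = bits.shape
    oh, ow = h // stride, w // stride
    trimmed = bits[:, : oh * stride, : ow * stride]
    view = trimmed.reshape(c, oh, stride, ow, stride)
    return view.max(axis=(2, 4))


def popcount_threshold_from_real(t_real: float, fan_in: int, gamma_sign: int) -> tuple[int, int]:
    """Convert a real preactivation threshold T into an integer popcount
    threshold preserving exact decisions on the integer preactivation grid.

    Returns ``(gamma_sign, popcount_threshold)``; degenerate never-fire /
    always-fire channels are canonicalized to gamma_sign +1 with threshold
    fan_in + 1 / 0 respectively.
    """
    n = fan_in
    if gamma_sign > 0:
        # preact >= T  <=>  p >= ceil((T + N) / 2)
        p_thr = int(np.ceil((t_real + n) / 2.0))
        if p_thr <= 0:
            return 1, 0  # always fires
        if p_thr > n:
            return 1, n + 1  # never fires
        return 1, p_thr
    # gamma < 0: preact <= T  <=>  p <= floor((T + N) / 2)
    p_thr = int(np.floor((t_real + n) / 2.0))
    if p_thr >= n:
        return 1, 0  # always fires
    if p_thr < 0:
        return 1, n + 1  # never fires
    return -1, p_thr


@dataclass
class TrainConfig:
    """Training recipe: Adam + cross-entropy, stepwise decaying learning
    rate, 200 epochs, batch 32, 80/20 shuffled split."""

    epochs: int = 200
    batch_size: int = 32
    lr_schedule: Tuple[Tuple[int, float], ...] = (
        (0, 0.005),
        (60, 0.001),
        (100, 0.0005),
        (120, 0.0001),
        (140, 0.00005),
        (160, 0.00001),
    )
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        epochs = [e for e, _ in self.lr_schedule]
        rates = [r for _, r in self.lr_schedule]
        if epochs != sorted(set(epochs)):
            raise ValueError("lr schedule epochs must be strictly increasing")
        if any(r2 >= r1 for r1, r2 in zip(rates, rates[1:])):
            raise ValueError("lr schedule rates must be strictly decreasing")

    def lr_at(self, epoch: int) -> float:
        lr = self.lr_schedule[0][1]
        for e, r in self.lr_schedule:
            if epoch >= e:
                lr = r
        return lr


@dataclass
class BCNNModel:
    """Deployable artifact: bit-packed binary weights plus per-channel
    (gamma sign, integer popcount threshold) pairs for every layer except
    the final FC."""

    spec: NetworkSpec
    weights: List[np.ndarray]  # bits; conv (C_out,C_in,k,k), fc (F_out,F_in)
    bn: List[Tuple[np.ndarray, np.ndarray]]  # (gamma_sign, popcount_threshold)
    trained_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n_layers = len(self.spec.conv_channels) + len(self.spec.fc_sizes)
        if len(self.weights) != n_layers:
            raise ValueError("weight list does not match architecture depth")
        if len(self.bn) != n_layers - 1:
            raise ValueError("expected BN pairs for every layer but the last")
        fans = self.spec.layer_fan_ins()
        for i, (gs, thr) in enumerate(self.bn):
            if np.any(thr < 0) or np.any(thr > fans[i] + 1):
                raise ValueError(f"popcount threshold out of [0, fan_in+1] at layer {i}")

    def validate_counts(self) -> None:
        got = sum(int(w.size) for w in self.weights)
        expected = weight_bit_count(self.spec)
        if got != expected:
            raise ValueError(f"weight bit count {got} != expected {expected}")


def infer(model: BCNNModel, spectrogram) -> tuple[int, np.ndarray]:
    """Integer-only forward pass: conv -> threshold -> OR-pool blocks, then
    FC layers; returns (class index, integer score pair). Ties resolve to
    non-fall to minimize false alarms."""
    bits = spectrogram.bits if hasattr(spectrogram, "bits") else np.asarray(spectrogram)
    bits = _check_bits(bits, "spectrogram")
    if bits.ndim == 2:
        bits = bits[None, :, :]
    if bits.shape != model.spec.input_shape:
        raise ValueError(f"input shape {bits.shape} != spec {model.spec.input_shape}")

    fans = model.spec.layer_fan_ins()
    n_conv = len(model.spec.conv_channels)
    x = bits
    li = 0
    for _ in range(n_conv):
        preact = binary_conv2d(x, model.weights[li])
        gs, thr = model.bn[li]
        x = threshold_activate(preact, gs, thr, fans[li])
        x = or_maxpool(x)
        li += 1
    flat = x.reshape(-1)  # channel-major then row-major spatial
    for j in range(len(model.spec.fc_sizes)):
        scores = binary_fc(flat, model.weights[li])
        if li < len(model.weights) - 1:
            gs, thr = model.bn[li]
            flat = threshold_activate(scores, gs, thr, fans[li])
        li += 1
    label = FALL if scores[FALL] > scores[NON_FALL] else NON_FALL
    return label, scores
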