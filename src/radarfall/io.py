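"""Container formats: I/Q frame CSV, HDF5 corpus, PBM/PNG spectrograms,
JSON model descriptors with bit-packed weight blobs, and hex-text ROM
images mirroring the hardware's internal memories.

Every writer has a bit-exact reader; round-trip identity is part of the
contract and covered by tests.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Tuple

import h5py
import numpy as np

from .bcnn import BCNNModel, NetworkSpec
from .ppu import BinarySpectrogram, RawRadarFrame

__all__ = [
    "write_frame_csv",
    "read_frame_csv",
    "write_corpus_h5",
    "read_corpus_h5",
    "write_pbm",
    "read_pbm",
    "write_png",
    "save_model",
    "load_model",
    "export_rom",
    "import_rom",
]


# -- I/Q frames -------------------------------------------------------------


def write_frame_csv(path, frame: RawRadarFrame) -> None:
    """Write one frame as two-column CSV (I, Q) with a header."""
    data = np.column_stack([frame.samples.real, frame.samples.imag])
    header = "I,Q"
    np.savetxt(path, data, delimiter=",", header=header, comments="", fmt="%.17g")


def read_frame_csv(path, sample_rate_hz: float = 2000.0) -> RawRadarFrame:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns (I, Q), got {data.shape[1]}")
    return RawRadarFrame(samples=data[:, 0] + 1j * data[:, 1], sample_rate_hz=sample_rate_hz)


def write_corpus_h5(path, frames: List[RawRadarFrame], manifest: Optional[dict] = None) -> None:
    """Frame collection as HDF5 (complex dataset + label/subject arrays)
    with a JSON manifest sidecar."""
    path = Path(path)
    samples = np.stack([f.samples for f in frames])
    labels = np.array([(f.label or "") for f in frames], dtype="S2")
    subjects = np.array([f.subject_id or 0 for f in frames], dtype=np.int64)
    rates = np.array([f.sample_rate_hz for f in frames])
    with h5py.File(path, "w") as h5:
        h5.create_dataset("samples", data=samples)
        h5.create_dataset("labels", data=labels)
        h5.create_dataset("subject_ids", data=subjects)
        h5.create_dataset("sample_rate_hz", data=rates)
    if manifest is not None:
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def read_corpus_h5(path) -> Tuple[List[RawRadarFrame], Optional[dict]]:
    path = Path(path)
    with h5py.File(path, "r") as h5:
        samples = h5["samples"][...]
        labels = [s.decode() or None for s in h5["labels"][...]]
        subjects = h5["subject_ids"][...]
        rates = h5["sample_rate_hz"][...]
    frames = [
        RawRadarFrame(samples=s, sample_rate_hz=float(r), label=l,
                      subject_id=int(sid) if sid else None)
        for s, l, sid, r in zip(samples, labels, subjects, rates)
    ]
    sidecar = path.with_suffix(".json")
    manifest = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return frames, manifest


# -- spectrograms -----------------------------------------------------------


def write_pbm(path, spectrogram: BinarySpectrogram) -> None:
    """Plain (P1) portable bitmap; bit-exact and human-readable."""
    bits = spectrogram.bits
    lines = [f"P1", f"{bits.shape[1]} {bits.shape[0]}"]
    lines += [" ".join(str(int(b)) for b in row) for row in bits]
    Path(path).write_text("\n".join(lines) + "\n")


def read_pbm(path) -> BinarySpectrogram:
    tokens: List[str] = []
    for raw_line in Path(path).read_text().splitlines():
        line = raw_line.split("#", 1)[0]
        tokens.extend(line.split())
    if not tokens or tokens[0] != "P1":
        raise ValueError(f"{path}: not a plain PBM (P1) file")
    w, h = int(tokens[1]), int(tokens[2])
    bits = np.array(tokens[3 : 3 + w * h], dtype=np.uint8)
    if bits.size != w * h:
        raise ValueError(f"{path}: expected {w * h} bits, found {bits.size}")
    return BinarySpectrogram(bits.reshape(h, w))


def write_png(path, spectrogram: BinarySpectrogram, scale: int = 8) -> None:
    """Visualization PNG (white = bit set), upscaled for visibility."""
    from PIL import Image

    img = (spectrogram.bits * 255).astype(np.uint8)
    img = np.kron(img, np.ones((scale, scale), dtype=np.uint8))
    Image.fromarray(img, mode="L").save(path)


# -- model descriptor + weight blobs ---------------------------------------


def save_model(directory, model: BCNNModel) -> None:
    """JSON descriptor + per-layer bit-packed weight blobs + threshold table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    descriptor = {
        "spec": {
            "conv_channels": list(model.spec.conv_channels),
            "fc_sizes": list(model.spec.fc_sizes),
            "input_shape": list(model.spec.input_shape),
            "first_kernel": model.spec.first_kernel,
            "later_kernel": model.spec.later_kernel,
        },
        "trained_meta": model.trained_meta,
        "layers": [],
    }
    for i, w in enumerate(model.weights):
        blob = np.packbits(w.reshape(-1))
        (directory / f"layer{i}_weights.bin").write_bytes(blob.tobytes())
        entry = {"shape": list(w.shape), "weights": f"layer{i}_weights.bin"}
        if i < len(model.bn):
            gs, thr = model.bn[i]
            entry["gamma_sign"] = [int(g) for g in gs]
            entry["popcount_threshold"] = [int(t) for t in thr]
        descriptor["layers"].append(entry)
    (directory / "model.json").write_text(json.dumps(descriptor, indent=1, sort_keys=True))


def load_model(directory) -> BCNNModel:
    directory = Path(directory)
    descriptor = json.loads((directory / "model.json").read_text())
    spec = NetworkSpec(
        conv_channels=tuple(descriptor["spec"]["conv_channels"]),
        fc_sizes=tuple(descriptor["spec"]["fc_sizes"]),
        input_shape=tuple(descriptor["spec"]["input_shape"]),
        first_kernel=descriptor["spec"]["first_kernel"],
        later_kernel=descriptor["spec"]["later_kernel"],
    )
    weights, bn = [], []
    for entry in descriptor["layers"]:
        shape = tuple(entry["shape"])
        n = int(np.prod(shape))
        blob = np.frombuffer((directory / entry["weights"]).read_bytes(), dtype=np.uint8)
        weights.append(np.unpackbits(blob)[:n].reshape(shape))
        if "gamma_sign" in entry:
            bn.append(
                (np.array(entry["gamma_sign"], dtype=np.int64),
                 np.array(entry["popcount_threshold"], dtype=np.int64))
            )
    model = BCNNModel(spec=spec, weights=weights, bn=bn,
                      trained_meta=descriptor.get("trained_meta", {}))
    model.validate_counts()
    return model


# -- ROM hex export ---------------------------------------------------------
#
# One hex-text memory-initialization file per layer. Weight ROMs pack the
# layer's bits MSB-first into 16-bit words, one 4-digit hex word per line
# (zero-padded tail). Threshold ROMs hold one 16-bit word per channel:
# bit 15 = 1 when gamma is negative, bits 14..0 = popcount threshold.
# Line endings are "\n" on every platform.

_WORD_BITS = 16


def _pack_words(bits: np.ndarray) -> List[int]:
    flat = bits.reshape(-1)
    pad = (-len(flat)) % _WORD_BITS
    flat = np.concatenate([flat, np.zeros(pad, dtype=np.uint8)])
    words = []
    for i in range(0, len(flat), _WORD_BITS):
        word = 0
        for b in flat[i : i + _WORD_BITS]:  # MSB-first
            word = (word << 1) | int(b)
        words.append(word)
    return words


def _unpack_words(words: List[int], n_bits: int) -> np.ndarray:
    bits = []
    for word in words:
        for j in range(_WORD_BITS - 1, -1, -1):
            bits.append((word >> j) & 1)
    return np.array(bits[:n_bits], dtype=np.uint8)


def export_rom(directory, model: BCNNModel) -> None:
    """Write per-layer weight and batch-norm ROM images as hex text."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, w in enumerate(model.weights):
        lines = [f"{word:04x}" for word in _pack_words(w)]
        (directory / f"layer{i}_weights.hex").write_text("\n".join(lines) + "\n")
        if i < len(model.bn):
            gs, thr = model.bn[i]
            if np.any(thr >= (1 << 15)):
                raise ValueError("popcount threshold does not fit 15 bits")
            words = [
                ((1 << 15) if g < 0 else 0) | int(t) for g, t in zip(gs, thr)
            ]
            lines = [f"{word:04x}" for word in words]
            (directory / f"layer{i}_bn.hex").write_text("\n".join(lines) + "\n")


def _read_hex_words(path) -> List[int]:
    words = []
    for ln, raw_line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw_line.strip()
        if not line:
            continue
        try:
            word = int(line, 16)
        except ValueError as exc:
            raise ValueError(f"{path}: line {ln}: invalid hex word {line!r}") from exc
        if word >= (1 << _WORD_BITS):
            raise ValueError(f"{path}: line {ln}: word wider than {_WORD_BITS} bits")
        words.append(word)
    return words


def import_rom(directory, spec: NetworkSpec, trained_meta: Optional[dict] = None) -> BCNNModel:
    """Rebuild a model from ROM hex images (shapes come from the spec)."""
    directory = Path(directory)
    weights, bn = [], []
    shapes = []
    c_in = spec.input_shape[0]
    for i, c_out in enumerate(spec.conv_channels):
        shapes.append((c_out, c_in, spec.kernel(i), spec.kernel(i)))
        c_in = c_out
    f_in = spec.flat_features()
    for f_out in spec.fc_sizes:
        shapes.append((f_out, f_in))
        f_in = f_out

    for i, shape in enumerate(shapes):
        n_bits = int(np.prod(shape))
        path = directory / f"layer{i}_weights.hex"
        words = _read_hex_words(path)
        expected_words = -(-n_bits // _WORD_BITS)
        if len(words) != expected_words:
            raise ValueError(
                f"{path}: line {len(words) + 1}: expected {expected_words} words, got {len(words)}"
            )
        weights.append(_unpack_words(words, n_bits).reshape(shape))
        if i < len(shapes) - 1:
            bn_path = directory / f"layer{i}_bn.hex"
            bn_words = _read_hex_words(bn_path)
            if len(bn_words) != shape[0]:
                raise ValueError(
                    f"{bn_path}: line {len(bn_words) + 1}: expected {shape[0]} words"
                )
            gs = np.array([-1 if (word >> 15) & 1 else 1 for word in bn_words], dtype=np.int64)
            thr = np.array([word & 0x7FFF for word in bn_words], dtype=np.int64)
            bn.append((gs, thr))
    model = BCNNModel(spec=spec, weights=weights, bn=bn, trained_meta=trained_meta or {})
    model.validate_counts()
    return model
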