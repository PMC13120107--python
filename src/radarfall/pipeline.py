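"""End-to-end pipeline: simulate -> preprocess -> train -> evaluate -> export.

Mirrors the deployed dataflow (raw baseband -> preprocessing unit -> binary
spectrogram -> network unit -> class) and emits a JSON report with
accuracies, the parameter count, the packed model size, and a content
digest per stage so a rerun with the same config and seed can be verified
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from . import io as rfio
from .bcnn import NetworkSpec, TrainConfig, count_parameters, weight_bit_count
from .ppu import StftConfig
from .fixedpoint import QFormat
from .radarsim import SimConfig, SyntheticCorpus, generate_dataset
from .training import SpectrogramDataset, train_detailed
from .ppu import stft_binary_spectrogram

__all__ = ["RunConfig", "preprocess_corpus", "run_pipeline"]


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass
class RunConfig:
    """Everything needed to reproduce a full run; round-trips through YAML."""

    qformat: str = "Q(16,11)"
    threshold_raw: int = 1140
    conv_channels: tuple = (32, 32, 32)
    fc_sizes: tuple = (32, 2)
    epochs: int = 60
    batch_size: int = 32
    n_per_class: int = 40
    noise_snr_db: float = 20.0
    sample_rate_hz: float = 2000.0
    seed: int = 0
    out_dir: Optional[str] = None

    def network_spec(self) -> NetworkSpec:
        return NetworkSpec(tuple(self.conv_channels), tuple(self.fc_sizes))

    def stft_config(self) -> StftConfig:
        return StftConfig(fmt=QFormat.parse(self.qformat), threshold_raw=self.threshold_raw)

    def sim_config(self) -> SimConfig:
        from .radarsim import TEMPLATES

        return SimConfig(
            sample_rate_hz=self.sample_rate_hz,
            noise_snr_db=self.noise_snr_db,
            n_per_class={c: self.n_per_class for c in TEMPLATES},
            seed=self.seed,
        )

    def train_config(self) -> TrainConfig:
        return TrainConfig(epochs=self.epochs, batch_size=self.batch_size, seed=self.seed)

    def to_yaml(self, path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("conv_channels", "fc_sizes"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def preprocess_corpus(corpus: SyntheticCorpus, cfg: Optional[StftConfig] = None) -> SpectrogramDataset:
    """Run the fixed-point PPU over every frame of a corpus."""
    cfg = cfg or StftConfig()
    bits = np.stack([stft_binary_spectrogram(f, cfg).bits for f in corpus.frames])
    return SpectrogramDataset(
        x=bits[:, None, :, :],
        y=corpus.is_fall,
        codes=corpus.labels,
        subject_ids=corpus.subject_ids,
    )


def run_pipeline(cfg: RunConfig) -> Dict:
    """Execute the full flow and return (and optionally write) the report."""
    t0 = time.time()
    report: Dict = {"config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.__dict__.items()}}

    try:
        corpus = generate_dataset(cfg.sim_config())
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
    raw = np.stack([f.samples for f in corpus.frames])
    report["simulate"] = {"n_frames": len(corpus.frames), "digest": _digest(raw)}

    try:
        dataset = preprocess_corpus(corpus, cfg.stft_config())
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc
    report["preprocess"] = {"digest": _digest(dataset.x), "bit_density": float(dataset.x.mean())}

    spec = cfg.network_spec()
    try:
        result = train_detailed(dataset, spec, cfg.train_config())
    except Exception as exc:
        raise RuntimeError(f"stage 'train' failed: {exc}") from exc
    model = result.model
    n_params = count_parameters(spec)
    packed_bytes = -(-n_params // 8)
    report["train"] = dict(model.trained_meta)
    report["model"] = {
        "parameter_count": n_params,
        "weight_bits": weight_bit_count(spec),
        "packed_bytes": packed_bytes,
        "packed_kib": packed_bytes / 1024.0,
        "digest": _digest(np.concatenate([w.reshape(-1) for w in model.weights])),
    }

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        try:
            rfio.save_model(out / "model", model)
            rfio.export_rom(out / "rom", model)
            cfg_copy = RunConfig(**{**cfg.__dict__})
            cfg_copy.to_yaml(out / "config.yaml")
        except Exception as exc:
            raise RuntimeError(f"stage 'export' failed: {exc}") from exc
        report["export"] = {"dir": str(out)}

    report["elapsed_s"] = round(time.time() - t0, 2)
    if cfg.out_dir is not None:
        (Path(cfg.out_dir) / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
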