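"""Seeded synthetic CW-radar baseband generator.

A 24 GHz continuous-wave radar observing a moving person returns a
superposition of Doppler-shifted tones, one per effective point scatterer
(torso, limbs): ``s(t) = sum_i a_i exp(j (4 pi / lambda) r_i(t)) + noise``
with ``r_i(t) = integral of v_i(tau) cos(theta_i) dtau`` the radial range
and ``lambda = c / f_carrier``. Each of the 12 activity classes (a-e falls,
f-l non-falls) is a template of piecewise radial-velocity profiles:

* falls are impulsive — speed ramps to 2-3.3 m/s within half a second and
  stops abruptly at impact;
* gait is periodic — a steady torso velocity with limb oscillation;
* the remaining daily activities are smooth low-speed bumps (|v| <= 1 m/s).

Motion direction relative to the radar line of sight is drawn from each
template's direction set {0, +-90, 180 degrees}. Non-fall templates project
velocity with cos(direction), optionally jittered by
``direction_spread_deg``; templates with zero spread project exactly with
cos(direction). Falls instead draw a radial fraction from
``radial_fraction_range`` with the Doppler sign set by the nominal
direction — a falling body rotates and drops toward the waist-height
radar, so even a lateral fall keeps a substantial line-of-sight component.

Everything is deterministic under the configured seed, and the generated
frames are always 1600 samples, cropped/padded centered on peak speed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .ppu import RawRadarFrame

__all__ = [
    "ActivityTemplate",
    "SimConfig",
    "TEMPLATES",
    "FALL_CODES",
    "NON_FALL_CODES",
    "TABLE_COUNTS",
    "synthesize_activity",
    "generate_dataset",
    "doppler_hz",
]

SPEED_OF_LIGHT = 299_792_458.0
FALL_CODES = ("a", "b", "c", "d", "e")
NON_FALL_CODES = ("f", "g", "h", "i", "j", "k", "l")

# published dataset composition per activity code (used for proportional mode)
TABLE_COUNTS: Dict[str, int] = {
    "a": 170, "b": 340, "c": 170, "d": 150, "e": 300,
    "f": 145, "g": 145, "h": 265, "i": 190, "j": 190, "k": 240, "l": 265,
}


@dataclass(frozen=True)
class ActivityTemplate:
    """Kinematic recipe for one activity class."""

    code: str
    name: str
    kind: str  # "fall" | "gait" | "bump" | "double_bump" | "constant" | "static"
    peak_speed_range: Tuple[float, float]  # m/s, torso kinematic speed
    duration_range: Tuple[float, float]  # s, active-motion duration
    direction_set: Tuple[float, ...]  # degrees relative to radar LOS
    direction_spread_deg: float = 0.0
    n_limb_scatterers: int = 1
    limb_speed_factor: float = 1.5
    amplitude_range: Tuple[float, float] = (0.06, 0.11)
    sign: float = 1.0  # bump motion sign: +1 toward floor/radar convention
    # Falls project onto the line of sight through this fraction range rather
    # than cos(direction): the body pivots and drops toward a waist-height
    # radar, so even a lateral fall keeps a substantial radial component.
    # None -> pure cos(direction [+ spread]) projection.
    radial_fraction_range: Optional[Tuple[float, float]] = None

    @property
    def is_fall(self) -> bool:
        return self.code in FALL_CODES


def _fall_templates() -> List[ActivityTemplate]:
    standing = dict(radial_fraction_range=(0.55, 0.95), n_limb_scatterers=2)
    seated = dict(radial_fraction_range=(0.6, 0.95), n_limb_scatterers=1)
    return [
        ActivityTemplate("a", "standing fall forward", "fall", (2.4, 3.3), (0.35, 0.55),
                         (0.0, 180.0), **standing),
        ActivityTemplate("b", "standing fall left/right", "fall", (2.4, 3.3), (0.35, 0.55),
                         (90.0, -90.0), **standing),
        ActivityTemplate("c", "standing fall backward", "fall", (2.4, 3.2), (0.35, 0.55),
                         (180.0, 0.0), **standing),
        ActivityTemplate("d", "sitting fall forward", "fall", (2.0, 2.8), (0.3, 0.5),
                         (0.0,), **seated),
        ActivityTemplate("e", "sitting fall left/right", "fall", (2.0, 2.8), (0.3, 0.5),
                         (90.0, -90.0), **seated),
    ]


def _non_fall_templates() -> List[ActivityTemplate]:
    return [
        ActivityTemplate("f", "walking slowly, arms still", "gait", (0.45, 0.65), (0.8, 0.8),
                         (0.0, 180.0), 0.0, 1, limb_speed_factor=1.1),
        ActivityTemplate("g", "walking quickly, swinging arms", "gait", (0.55, 0.8), (0.8, 0.8),
                         (0.0, 180.0), 10.0, 2, limb_speed_factor=1.1),
        ActivityTemplate("h", "squatting", "bump", (0.55, 0.8), (0.8, 1.1),
                         (0.0, 90.0, -90.0, 180.0), 20.0, 1, sign=1.0),
        ActivityTemplate("i", "sitting on a chair", "bump", (0.5, 0.8), (0.7, 1.0),
                         (0.0, 90.0, -90.0), 20.0, 1, sign=1.0),
        ActivityTemplate("j", "standing up from a chair", "bump", (0.5, 0.8), (0.7, 1.0),
                         (0.0, 90.0, -90.0), 20.0, 1, sign=-1.0),
        ActivityTemplate("k", "lying down then lifting upper body", "double_bump", (0.45, 0.7),
                         (1.0, 1.3), (0.0, 90.0, -90.0, 180.0), 20.0, 1),
        ActivityTemplate("l", "lying down", "bump", (0.4, 0.65), (1.0, 1.4),
                         (0.0, 90.0, -90.0, 180.0), 20.0, 1, sign=1.0),
    ]


TEMPLATES: Dict[str, ActivityTemplate] = {
    t.code: t for t in _fall_templates() + _non_fall_templates()
}


@dataclass
class SimConfig:
    """Generator conditions: sampling, carrier, noise, corpus composition."""

    sample_rate_hz: float = 2000.0
    carrier_hz: float = 24.125e9
    noise_snr_db: float = 20.0
    frame_len: int = 1600
    n_per_class: Optional[Dict[str, int]] = None  # None -> 40 per class
    table_proportional: bool = False
    n_subjects: int = 5
    seed: int = 0

    @property
    def wavelength_m(self) -> float:
        return SPEED_OF_LIGHT / self.carrier_hz

    def class_counts(self) -> Dict[str, int]:
        if self.n_per_class is not None:
            if not self.n_per_class:
                raise ValueError("empty class map")
            bad = set(self.n_per_class) - set(TEMPLATES)
            if bad:
                raise ValueError(f"unknown activity codes: {sorted(bad)}")
            if any(n < 1 for n in self.n_per_class.values()):
                raise ValueError("per-class counts must be >= 1")
            return dict(self.n_per_class)
        if self.table_proportional:
            return dict(TABLE_COUNTS)
        return {code: 40 for code in TEMPLATES}


def doppler_hz(speed_mps: float, wavelength_m: float) -> float:
    """CW Doppler shift of a target closing at ``speed_mps``: 2 v / lambda."""
    return 2.0 * speed_mps / wavelength_m


# ---------------------------------------------------------------------------
# velocity profiles


def _fall_profile(t: np.ndarray, v_peak: float, t_fall: float) -> np.ndarray:
    """Accelerating drop reaching v_peak at t_fall, then impact decay."""
    v = np.zeros_like(t)
    rising = t < t_fall
    v[rising] = v_peak * np.sin(0.5 * np.pi * t[rising] / t_fall) ** 2
    after = ~rising
    v[after] = v_peak * np.exp(-(t[after] - t_fall) / 0.05)
    return v


def _bump_profile(t: np.ndarray, v_peak: float, duration: float) -> np.ndarray:
    """Smooth start-stop motion (sit, squat, stand, lie)."""
    v = np.zeros_like(t)
    active = (t >= 0) & (t <= duration)
    v[active] = v_peak * np.sin(np.pi * t[active] / duration) ** 2
    return v


def _gait_profile(t: np.ndarray, v_base: float, step_hz: float, swing: float) -> np.ndarray:
    return v_base + swing * np.sin(2.0 * np.pi * step_hz * t)


def _template_velocities(
    template: ActivityTemplate, rng: np.random.Generator, duration_total: float, fs: float
) -> List[Tuple[float, np.ndarray]]:
    """Per-scatterer (relative amplitude, kinematic speed series) pairs."""
    n = int(round(duration_total * fs))
    t = np.arange(n) / fs
    v_peak = rng.uniform(*template.peak_speed_range)
    dur = rng.uniform(*template.duration_range)
    start = 0.15 * duration_total + rng.uniform(0, 0.1 * duration_total)
    ts = t - start

    out: List[Tuple[float, np.ndarray]] = []
    if template.kind == "fall":
        torso = _fall_profile(ts, v_peak, dur)
        out.append((1.0, torso))
        for _ in range(template.n_limb_scatterers):
            f = template.limb_speed_factor * rng.uniform(0.85, 1.15)
            lag = rng.uniform(0.0, 0.08)
            out.append((rng.uniform(0.25, 0.45), _fall_profile(ts - lag, f * v_peak, dur)))
    elif template.kind == "gait":
        step_hz = rng.uniform(1.4, 2.0) if template.code == "g" else rng.uniform(0.8, 1.2)
        torso = _gait_profile(t, v_peak, step_hz, 0.12 * v_peak)
        out.append((1.0, torso))
        for _ in range(template.n_limb_scatterers):
            f = template.limb_speed_factor * rng.uniform(0.9, 1.1)
            phase = rng.uniform(0, 2 * np.pi)
            limb = v_peak + (f - 1.0) * v_peak * np.sin(2 * np.pi * step_hz * t + phase)
            out.append((rng.uniform(0.25, 0.45), limb))
    elif template.kind == "bump":
        torso = template.sign * _bump_profile(ts, v_peak, dur)
        out.append((1.0, torso))
        for _ in range(template.n_limb_scatterers):
            out.append((rng.uniform(0.2, 0.4),
                        template.sign * _bump_profile(ts - rng.uniform(0, 0.1), 1.2 * v_peak, dur)))
    elif template.kind == "double_bump":
        half = 0.45 * dur
        torso = _bump_profile(ts, v_peak, half) - _bump_profile(ts - 0.55 * dur, 0.8 * v_peak, half)
        out.append((1.0, torso))
        out.append((rng.uniform(0.2, 0.4), 1.2 * torso))
    elif template.kind == "constant":
        # steady radial speed: test/calibration probe, not a daily activity
        out.append((1.0, np.full(n, v_peak)))
    elif template.kind == "static":
        out.append((1.0, np.zeros(n)))
    else:  # pragma: no cover - template table is closed
        raise ValueError(f"unknown template kind {template.kind!r}")
    return out


def synthesize_activity(
    template: ActivityTemplate,
    direction_deg: float,
    cfg: SimConfig,
    seed: int,
) -> RawRadarFrame:
    """One synthetic frame: point-scatterer phase model plus complex
    Gaussian noise, cropped/padded to 1600 samples centered on peak speed."""
    if direction_deg not in template.direction_set:
        raise ValueError(
            f"direction {direction_deg} not in template {template.code}'s set {template.direction_set}"
        )
    rng = np.random.default_rng(seed)
    fs = cfg.sample_rate_hz
    duration_total = max(max(template.duration_range) * 1.6, cfg.frame_len / fs * 1.25)
    scatterers = _template_velocities(template, rng, duration_total, fs)

    # Nyquist guard on the kinematic peak (projection only reduces it)
    v_max = max(float(np.max(np.abs(v))) for _, v in scatterers)
    if doppler_hz(v_max, cfg.wavelength_m) >= fs / 2:
        raise ValueError(
            f"template {template.code!r} peak speed {v_max:.2f} m/s violates "
            f"Nyquist at fs={fs} Hz"
        )

    amp0 = rng.uniform(*template.amplitude_range)
    signal = np.zeros(len(scatterers[0][1]), dtype=np.complex128)
    combined_speed = np.zeros_like(scatterers[0][1])
    if template.radial_fraction_range is not None:
        # fall kinematics: sign of the Doppler follows the nominal direction,
        # magnitude of the LOS projection stays substantial (body rotation)
        if direction_deg == 0.0:
            radial_sign = 1.0
        elif direction_deg == 180.0:
            radial_sign = -1.0
        else:
            radial_sign = rng.choice((-1.0, 1.0))
    for rel_amp, v in scatterers:
        if template.radial_fraction_range is not None:
            projection = radial_sign * rng.uniform(*template.radial_fraction_range)
        elif template.direction_spread_deg > 0:
            theta = direction_deg + rng.uniform(
                -template.direction_spread_deg, template.direction_spread_deg
            )
            projection = np.cos(np.deg2rad(theta))
        else:
            projection = np.cos(np.deg2rad(direction_deg))
        v_radial = v * projection
        r = np.cumsum(v_radial) / fs
        phase = (4.0 * np.pi / cfg.wavelength_m) * r + rng.uniform(0, 2 * np.pi)
        signal += amp0 * rel_amp * np.exp(1j * phase)
        combined_speed += rel_amp * np.abs(v)

    # crop/pad to frame_len centered on the peak of combined kinematic speed
    peak = int(np.argmax(combined_speed))
    half = cfg.frame_len // 2
    lo = min(max(peak - half, 0), max(len(signal) - cfg.frame_len, 0))
    frame = signal[lo : lo + cfg.frame_len]
    if len(frame) < cfg.frame_len:
        frame = np.pad(frame, (0, cfg.frame_len - len(frame)))

    sig_power = float(np.mean(np.abs(frame) ** 2))
    if sig_power > 0 and np.isfinite(cfg.noise_snr_db):
        noise_power = sig_power / 10 ** (cfg.noise_snr_db / 10)
        sigma = np.sqrt(noise_power / 2)
        frame = frame + sigma * (
            rng.standard_normal(cfg.frame_len) + 1j * rng.standard_normal(cfg.frame_len)
        )
    return RawRadarFrame(samples=frame, sample_rate_hz=fs, label=template.code)


@dataclass
class SyntheticCorpus:
    frames: List[RawRadarFrame]
    labels: np.ndarray  # activity codes
    is_fall: np.ndarray  # 0/1
    subject_ids: np.ndarray
    manifest: dict


def generate_dataset(cfg: SimConfig) -> SyntheticCorpus:
    """Generate the labeled synthetic corpus.

    Per-sample jitter (direction, kinematics, amplitude, noise) comes from
    per-frame child seeds spawned deterministically from ``cfg.seed``; the
    manifest records every child seed and parameter, so the corpus can be
    regenerated bit-identically.
    """
    counts = cfg.class_counts()
    root = np.random.SeedSequence(cfg.seed)
    frames: List[RawRadarFrame] = []
    records = []
    subject_counter = 0
    for code in sorted(counts):
        template = TEMPLATES[code]
        for i in range(counts[code]):
            child = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(ord(code), i))
            child_seed = int(child.generate_state(1)[0])
            dir_rng = np.random.default_rng(child_seed ^ 0x5EED)
            direction = float(dir_rng.choice(template.direction_set))
            frame = synthesize_activity(template, direction, cfg, seed=child_seed)
            frame.subject_id = subject_counter % cfg.n_subjects + 1
            subject_counter += 1
            frames.append(frame)
            records.append(
                {
                    "code": code,
                    "index": i,
                    "seed": child_seed,
                    "direction_deg": direction,
                    "subject_id": frame.subject_id,
                }
            )
    labels = np.array([f.label for f in frames])
    manifest = {
        "seed": cfg.seed,
        "sample_rate_hz": cfg.sample_rate_hz,
        "carrier_hz": cfg.carrier_hz,
        "noise_snr_db": cfg.noise_snr_db,
        "frame_len": cfg.frame_len,
        "class_counts": counts,
        "n_subjects": cfg.n_subjects,
        "frames": records,
    }
    return SyntheticCorpus(
        frames=frames,
        labels=labels,
        is_fall=np.isin(labels, FALL_CODES).astype(np.int64),
        subject_ids=np.array([f.subject_id for f in frames]),
        manifest=manifest,
    )
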