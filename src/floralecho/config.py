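"""Shared configuration objects for simulation and processing.

All acoustic quantities are SI unless a field name says otherwise
(morphology is in mm, surface areas in mm**2, levels in dB).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass(frozen=True)
class SimConfig:
    """Geometry and sampling of a rotational echo scan.

    The default grid (-90deg..+90deg in 1.8deg steps) gives 101 ensonification
    angles per plane; scanning both azimuth and elevation yields 202 echoes
    per flower.
    """

    sample_rate: float = 500_000.0  # Hz
    speed_of_sound: float = 343.0  # m/s
    n_angles: int = 101
    angle_min: float = -90.0  # degrees
    angle_max: float = 90.0  # degrees
    seed: int = 0
    ir_length: int = 1024  # samples kept per simulated impulse response
    ir_onset: int = 128  # sample index of the rim reflection within the IR
    mls_order: int = 14
    duration_s: float = 2.0  # raw recording duration
    n_average: int = 50  # MLS periods averaged during deconvolution
    echo_delay_s: float = 2 * 0.20 / 343.0  # round trip over the 20 cm range

    def __post_init__(self) -> None:
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def angles(self):
        import numpy as np

        return np.linspace(self.angle_min, self.angle_max, self.n_angles)

    @property
    def angle_step(self) -> float:
        if self.n_angles == 1:
            return 0.0
        return (self.angle_max - self.angle_min) / (self.n_angles - 1)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class CallConfig:
    """Parameters of the synthetic downward-FM echolocation call.

    The defaults describe a short multi-harmonic sweep of the kind emitted by
    glossophagine nectar-feeding bats: a ~1.5 ms hyperbolic downward sweep
    whose fundamental runs 80->42 kHz with one overtone at twice the
    instantaneous frequency, so the two harmonics jointly cover roughly
    40-160 kHz. These are documented package constants, not measured values.
    """

    sample_rate: float = 500_000.0  # Hz
    duration_s: float = 0.0015  # s
    f_start: float = 80_000.0  # Hz, fundamental at call onset
    f_end: float = 42_000.0  # Hz, fundamental at call offset
    harmonic_amps: tuple = (1.0, 0.5)  # relative amplitude per harmonic
    highpass_hz: float = 5_000.0  # pre-convolution high-pass cutoff

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sample_rate))

    @property
    def f_max(self) -> float:
        return self.f_start * len(self.harmonic_amps)


@dataclass(frozen=True)
class SpectrogramConfig:
    """STFT settings for echo spectrograms (Hann 256, 90% overlap)."""

    window_len: int = 256
    hop: int = 26  # 256 * 0.1 = 25.6, rounded up; configurable
    floor_db: float = -80.0
    normalize: bool = True


DEFAULT_ECHO_LEN = 2048  # samples; fixed echo length fed to the classifier
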