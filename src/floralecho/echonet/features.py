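"""Echo synthesis and spectrogram features for the classifier.

An echo is the linear convolution of a (5 kHz high-passed) echolocation call
with a flower impulse response, trimmed or zero-padded to a fixed length so
every spectrogram in a dataset has the same shape. Spectrograms use a Hann
window of 256 samples with a hop of 26 samples (90% overlap, 256*0.1 = 25.6
rounded up), are converted to dB with an -80 dB floor relative to the frame
maximum and min-max normalized per spectrogram.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
from scipy import signal

from ..config import DEFAULT_ECHO_LEN, SpectrogramConfig

__all__ = ["highpass_call", "make_echo", "spectrogram", "spectrogram_shape", "EchoRenderer"]


def highpass_call(call: np.ndarray, sample_rate: float, cutoff: float = 5_000.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth high-pass (removes LF noise leakage)."""
    sos = signal.butter(4, cutoff, btype="highpass", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, call)


def make_echo(
    ir: np.ndarray,
    call: np.ndarray,
    length: int = DEFAULT_ECHO_LEN,
) -> np.ndarray:
    """Synthetic flower echo: filtered call convolved with the IR.

    ``call`` must already be high-passed (see :func:`highpass_call`). The
    result is trimmed/zero-padded to ``length`` samples.
    """
    ir = np.asarray(ir, dtype=float)
    if ir.size == 0:
        raise ValueError("empty impulse response")
    echo = np.convolve(np.asarray(call, dtype=float), ir)
    if echo.size >= length:
        return echo[:length]
    return np.pad(echo, (0, length - echo.size))


def frame_count(n_samples: int, cfg: SpectrogramConfig = SpectrogramConfig()) -> int:
    return (n_samples - cfg.window_len) // cfg.hop + 1


def spectrogram_shape(
    echo_len: int, cfg: SpectrogramConfig = SpectrogramConfig()
) -> Tuple[int, int]:
    return cfg.window_len // 2 + 1, frame_count(echo_len, cfg)


def spectrogram(
    echo: np.ndarray, cfg: SpectrogramConfig = SpectrogramConfig()
) -> np.ndarray:
    """Magnitude spectrogram (freq_bins, frames) on the classifier's scale.

    Frames are Hann-windowed; the magnitude is expressed in dB below the
    spectrogram maximum, floored at ``cfg.floor_db`` and min-max normalized to
    [0, 1] (an all-silent echo maps to all zeros).
    """
    echo = np.asarray(echo, dtype=float)
    n = echo.size
    if n < cfg.window_len:
        raise ValueError(f"echo of {n} samples shorter than window {cfg.window_len}")
    n_frames = frame_count(n, cfg)
    idx = np.arange(cfg.window_len)[None, :] + cfg.hop * np.arange(n_frames)[:, None]
    frames = echo[idx] * np.hanning(cfg.window_len)[None, :]
    mag = np.abs(np.fft.rfft(frames, axis=-1)).T  # (freq, frames)
    peak = mag.max()
    if peak == 0.0:
        return np.zeros_like(mag)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(mag / peak)
    db = np.maximum(db, cfg.floor_db)
    if not cfg.normalize:
        return db
    lo, hi = db.min(), db.max()
    if hi == lo:
        return np.zeros_like(db)
    return (db - lo) / (hi - lo)


class EchoRenderer:
    """Renders chunks of impulse responses into spectrogram tensors.

    Spectrograms are computed on demand from IR + call (so window/hop changes
    need no dataset rebuild) and memoized per (flower, plane, angle index),
    which is sound because the mapping is deterministic.
    """

    def __init__(
        self,
        scans_by_flower,
        call: np.ndarray,
        sample_rate: float,
        echo_len: int = DEFAULT_ECHO_LEN,
        spec_cfg: SpectrogramConfig = SpectrogramConfig(),
        highpass_hz: float = 5_000.0,
        cache: bool = True,
    ) -> None:
        self.scans = scans_by_flower
        self.call = highpass_call(np.asarray(call, dtype=float), sample_rate, highpass_hz)
        self.sample_rate = sample_rate
        self.echo_len = echo_len
        self.spec_cfg = spec_cfg
        self._cache: Optional[Dict] = {} if cache else None
        self.shape = spectrogram_shape(echo_len, spec_cfg)

    def spectrogram_for(self, flower_id: str, plane: str, angle_idx: int) -> np.ndarray:
        key = (flower_id, plane, angle_idx)
        if self._cache is not None and key in self._cache:
            return self._cache[key]
        ir = self.scans[flower_id][plane].irs[angle_idx]
        spec = spectrogram(make_echo(ir, self.call, self.echo_len), self.spec_cfg)
        if self._cache is not None:
            self._cache[key] = spec
        return spec

    def chunk_tensor(self, chunk) -> np.ndarray:
        """(k, freq_bins, frames) tensor for one echo chunk."""
        return np.stack(
            [self.spectrogram_for(chunk.flower_id, plane, idx)
             for plane, idx in chunk.ir_refs]
        )
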