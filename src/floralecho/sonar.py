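"""Echo-measurement signal chain.

A target is ensonified with a continuously repeated maximum length sequence
(MLS). Because the circular autocorrelation of an MLS is (almost) a Dirac
impulse, circular cross-correlation of the steady-state recording with the
sequence recovers the target's impulse response (IR). The chain implemented
here mirrors the measurement protocol end to end:

    recording -> period averaging -> deconvolution -> echo windowing
              -> power spectrum -> plate calibration -> band averaging

Target strength (TS) is expressed in dB relative to a reference reflector
(a flat plate) recorded with the identical chain, which cancels any common
loudspeaker/microphone coloration. All dB averaging is performed on linear
power ("after delog") and converted back to dB at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import max_len_seq

__all__ = [
    "MLSSequence",
    "ImpulseResponseScan",
    "TargetStrengthSpectrum",
    "BandDefinition",
    "DEFAULT_BANDS",
    "BROADBAND",
    "generate_mls",
    "deconvolve",
    "extract_echo",
    "power_spectrum",
    "calibrate_ts",
    "band_ts",
    "overall_ts",
    "directional_spectrum",
    "process_scan",
    "scan_band_ts",
]

ANALYSIS_BAND = (40_000.0, 160_000.0)


@dataclass(frozen=True)
class MLSSequence:
    """A maximal-length +/-1 sequence of length 2**order - 1."""

    order: int
    values: np.ndarray
    sample_rate: float = 500_000.0

    def __len__(self) -> int:
        return self.values.size

    @property
    def period_s(self) -> float:
        return len(self) / self.sample_rate

    def periods_in(self, duration_s: float) -> int:
        """Whole MLS periods contained in a recording of this duration."""
        return int(duration_s * self.sample_rate) // len(self)

    def usable_periods_in(self, duration_s: float) -> int:
        """Steady-state periods usable for averaging.

        The first period of the recording is transient (the target's impulse
        response has not fully built up), so one period fewer than the whole
        count is usable. A 2 s recording at 500 kHz with an order-14 sequence
        holds 61 whole periods of which 60 carry identical steady-state IRs.
        """
        return max(self.periods_in(duration_s) - 1, 0)


def generate_mls(order: int, sample_rate: float = 500_000.0) -> MLSSequence:
    """Maximal-length sequence from a fixed primitive LFSR polynomial per order.

    The binary sequence is mapped to +/-1 (bit 1 -> +1). Length is
    2**order - 1, e.g. 16 383 samples for the default order 14, which at
    500 kHz has a period of ~33 ms.
    """
    if not (2 <= order <= 24):
        raise ValueError(f"unsupported MLS order {order}; need 2 <= order <= 24")
    bits, _ = max_len_seq(order)
    values = 2.0 * bits.astype(np.float64) - 1.0
    return MLSSequence(order=order, values=values, sample_rate=sample_rate)


def circular_autocorrelation(x: np.ndarray) -> np.ndarray:
    """Circular (periodic) autocorrelation, exact up to FFT rounding."""
    X = np.fft.rfft(x)
    return np.fft.irfft(X * np.conj(X), n=x.size)


@dataclass
class ImpulseResponseScan:
    """Angle-indexed impulse responses of one flower in one scan plane."""

    flower_id: str
    plane: str  # "azimuth" or "elevation"
    angles: np.ndarray  # degrees, shape (n_angles,)
    irs: np.ndarray  # shape (n_angles, n_samples)
    sample_rate: float

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.irs = np.atleast_2d(np.asarray(self.irs, dtype=float))
        if self.irs.shape[0] != self.angles.size:
            raise ValueError("number of IRs must match the angle grid")
        if self.plane not in ("azimuth", "elevation"):
            raise ValueError(f"unknown scan plane {self.plane!r}")

    @property
    def n_angles(self) -> int:
        return self.angles.size


@dataclass(frozen=True)
class TargetStrengthSpectrum:
    """Calibrated per-frequency target strength for one ensonification angle."""

    frequencies: np.ndarray  # Hz
    ts_db: np.ndarray  # dB re reference plate at 10 cm
    angle: Optional[float] = None
    plane: Optional[str] = None


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValueError(f"invalid band {self.name}: [{self.f_low}, {self.f_high}]")


def _pm20(center: float) -> Tuple[float, float]:
    return 0.8 * center, 1.2 * center


BROADBAND = BandDefinition("broad", *ANALYSIS_BAND)
DEFAULT_BANDS = (
    BROADBAND,
    BandDefinition("45kHz", *_pm20(45_000.0)),
    BandDefinition("68kHz", *_pm20(68_000.0)),
    BandDefinition("102kHz", *_pm20(102_000.0)),
    BandDefinition("153kHz", *_pm20(153_000.0)),
)


# ---------------------------------------------------------------------------
# Deconvolution
# ---------------------------------------------------------------------------

def deconvolve(
    recording: np.ndarray,
    mls: MLSSequence,
    n_average: int = 50,
    discard: int = 1,
) -> np.ndarray:
    """Recover one period-length impulse response from an MLS recording.

    The recording is sliced into whole MLS periods; the first ``discard``
    periods are dropped as transient and the next ``n_average`` are averaged,
    boosting SNR by 10*log10(n_average) dB. The averaged period is then
    circularly cross-correlated with the sequence via FFT and normalized by
    the sequence length.
    """
    recording = np.asarray(recording, dtype=float)
    L = len(mls)
    n_whole = recording.size // L
    if n_whole < n_average + discard:
        raise ValueError(
            f"recording holds {n_whole} whole periods; "
            f"need {n_average + discard} (discard {discard} + average {n_average})"
        )
    periods = recording[: (discard + n_average) * L].reshape(-1, L)
    avg = periods[discard:].mean(axis=0)
    spec = np.fft.rfft(avg) * np.conj(np.fft.rfft(mls.values))
    return np.fft.irfft(spec, n=L) / L


# ---------------------------------------------------------------------------
# Echo windowing and spectra
# ---------------------------------------------------------------------------

def extract_echo(
    ir: np.ndarray,
    window_len: int = 1024,
    guard: int = 0,
    pre_peak: int = 128,
    noise_mult: float = 5.0,
    check_noise_floor: bool = False,
) -> np.ndarray:
    """Cut the flower echo out of an impulse response (rectangular window).

    The maximum-magnitude sample after the first ``guard`` samples (used to
    skip direct loudspeaker-microphone crosstalk; 0.8 ms is a sensible default
    for the 20 cm measurement geometry) marks the echo; a window of
    ``window_len`` samples starting ``pre_peak`` samples before it is
    returned. With ``check_noise_floor`` the peak must exceed ``noise_mult``
    times a robust noise-SD estimate, otherwise no echo is declared.
    """
    ir = np.asarray(ir, dtype=float)
    if ir.ndim != 1:
        raise ValueError("extract_echo expects a single impulse response")
    if ir.size < window_len:
        raise ValueError(f"IR of {ir.size} samples shorter than window {window_len}")
    mag = np.abs(ir)
    search = mag[guard:]
    peak = guard + int(np.argmax(search))
    if check_noise_floor:
        noise_sd = float(np.median(mag) / 0.6745)
        if mag[peak] < noise_mult * max(noise_sd, np.finfo(float).tiny):
            raise ValueError(
                f"no echo found: peak {mag[peak]:.3g} below "
                f"{noise_mult} x noise SD {noise_sd:.3g}"
            )
    start = int(np.clip(peak - pre_peak, 0, ir.size - window_len))
    return ir[start : start + window_len]


def power_spectrum(
    segment: np.ndarray, sample_rate: float = 500_000.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared FFT of a rectangular-windowed echo segment.

    Works on a single segment or a stack of segments (last axis = time).
    Returns the frequency grid (0..Nyquist, spacing fs/N) and the power.
    """
    segment = np.asarray(segment, dtype=float)
    n = segment.shape[-1]
    spec = np.fft.rfft(segment, axis=-1)
    power = spec.real**2 + spec.imag**2
    return _rfft_freqs(n, sample_rate), power


@lru_cache(maxsize=32)
def _rfft_freqs(n: int, sample_rate: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    freqs.setflags(write=False)
    return freqs


def calibrate_ts(
    flower_power: np.ndarray,
    plate_power: np.ndarray,
    freqs: Optional[np.ndarray] = None,
    band: Tuple[float, float] = ANALYSIS_BAND,
) -> np.ndarray:
    """Target strength spectrum: flower PSD over plate PSD, in dB.

    ts_db(f) = 10 log10 flower(f) - 10 log10 plate(f). Any common
    emitter/receiver coloration divides out. Zero plate power inside the
    analysis band is an error; outside the band the value is returned as-is
    (NaN/-inf where undefined) and should be treated as unreliable.
    """
    flower_power = np.asarray(flower_power, dtype=float)
    plate_power = np.asarray(plate_power, dtype=float)
    if flower_power.shape[-1] != plate_power.shape[-1]:
        raise ValueError("flower and plate spectra must share one frequency grid")
    if freqs is not None:
        in_band = (freqs >= band[0]) & (freqs <= band[1])
        if np.any(plate_power[..., in_band] <= 0):
            raise ValueError("zero plate power inside the analysis band")
    with np.errstate(divide="ignore", invalid="ignore"):
        return 10.0 * np.log10(flower_power / plate_power)


def band_ts(ts_db: np.ndarray, freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    """Band-average TS: delog to linear power, average bins, relog.

    Bin membership is by bin center within the closed interval
    [f_low, f_high]. Vectorized over any leading axes of ``ts_db``.
    """
    freqs = np.asarray(freqs, dtype=float)
    mask = (freqs >= band.f_low) & (freqs <= band.f_high)
    if not np.any(mask):
        raise ValueError(f"band {band.name} contains no frequency bins")
    lin = 10.0 ** (np.asarray(ts_db, dtype=float)[..., mask] / 10.0)
    return 10.0 * np.log10(lin.mean(axis=-1))


def overall_ts(per_plane_band_ts: Mapping[str, np.ndarray]) -> float:
    """Flower-level TS: delog-average angles within a plane, then planes.

    ``per_plane_band_ts`` maps plane name to the per-angle band TS values
    (dB). Each plane is averaged in linear power across its angles; the plane
    means are then averaged in linear power and reported in dB. Flowers
    scanned in a single plane use that plane alone.
    """
    if not per_plane_band_ts:
        raise ValueError("at least one scan plane is required")
    plane_means = [
        float(np.mean(10.0 ** (np.asarray(v, dtype=float) / 10.0)))
        for v in per_plane_band_ts.values()
    ]
    return 10.0 * float(np.log10(np.mean(plane_means)))


# ---------------------------------------------------------------------------
# Scan-level processing
# ---------------------------------------------------------------------------

def _window_rows(
    irs: np.ndarray, window_len: int, guard: int, pre_peak: int
) -> np.ndarray:
    """Rectangular echo windows for every row of an IR matrix (vectorized)."""
    n = irs.shape[-1]
    if n < window_len:
        raise ValueError("IRs shorter than the echo window")
    if n == window_len:
        return irs  # the IR is already exactly one echo window
    peaks = guard + np.argmax(np.abs(irs[:, guard:]), axis=1)
    starts = np.clip(peaks - pre_peak, 0, n - window_len)
    if np.all(starts == starts[0]):
        s = int(starts[0])
        return irs[:, s : s + window_len]
    idx = starts[:, None] + np.arange(window_len)[None, :]
    return np.take_along_axis(irs, idx, axis=1)


def directional_spectrum(
    scan: ImpulseResponseScan,
    plate_power: np.ndarray,
    window_len: int = 1024,
    guard: int = 0,
    pre_peak: int = 128,
) -> Tuple[np.ndarray, np.ndarray]:
    """Angle x frequency calibrated TS matrix for one scan plane.

    Returns ``(freqs, ts)`` with ``ts`` of shape (n_angles, n_freq); for the
    default 1024-sample window n_freq = 513. Angle 0 deg faces the flower
    opening, +/-90 deg the sides.
    """
    windows = _window_rows(scan.irs, window_len, guard, pre_peak)
    freqs, power = power_spectrum(windows, scan.sample_rate)
    ts = calibrate_ts(power, plate_power, freqs=freqs)
    return freqs, ts


def band_linear_ratio(
    irs: np.ndarray,
    plate_power: np.ndarray,
    bands: Sequence[BandDefinition],
    sample_rate: float,
    window_len: int = 1024,
    guard: int = 0,
    pre_peak: int = 128,
) -> Dict[str, np.ndarray]:
    """Per-IR band-averaged linear power ratio (flower over plate).

    This is the fused form of windowing -> PSD -> plate calibration -> delog
    band averaging: because the band average is defined on linear power, the
    intermediate dB conversion and its inverse cancel algebraically, so the
    linear band mean is computed directly. ``10*log10`` of the result equals
    the per-angle band TS to float rounding.
    """
    windows = _window_rows(np.atleast_2d(irs), window_len, guard, pre_peak)
    freqs, power = power_spectrum(windows, sample_rate)
    out: Dict[str, np.ndarray] = {}
    for b in bands:
        mask = (freqs >= b.f_low) & (freqs <= b.f_high)
        if not np.any(mask):
            raise ValueError(f"band {b.name} contains no frequency bins")
        plate_band = plate_power[..., mask]
        if np.any(plate_band <= 0):
            raise ValueError("zero plate power inside the analysis band")
        out[b.name] = (power[..., mask] / plate_band).mean(axis=-1)
    return out


def process_scan(
    scan: ImpulseResponseScan,
    plate_power: np.ndarray,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    window_len: int = 1024,
    guard: int = 0,
    pre_peak: int = 128,
) -> Dict[str, np.ndarray]:
    """Per-angle band TS values (dB) for each requested band."""
    lin = band_linear_ratio(
        scan.irs, plate_power, bands, scan.sample_rate, window_len, guard, pre_peak
    )
    return {name: 10.0 * np.log10(v) for name, v in lin.items()}


def scan_band_ts(
    scans: Iterable[ImpulseResponseScan],
    plate_power: np.ndarray,
    bands: Sequence[BandDefinition] = DEFAULT_BANDS,
    **kwargs,
) -> Dict[str, float]:
    """Flower-level band TS from one or two scan planes.

    Scans of equal shape are stacked so the whole flower goes through the
    windowing/PSD/calibration chain in one vectorized pass; the per-plane
    delog averaging is identical either way.
    """
    scans = list(scans)
    shapes = {s.irs.shape for s in scans}
    if len(scans) > 1 and len(shapes) == 1 and len({s.sample_rate for s in scans}) == 1:
        stacked = ImpulseResponseScan(
            flower_id=scans[0].flower_id,
            plane=scans[0].plane,
            angles=np.concatenate([s.angles for s in scans]),
            irs=np.vstack([s.irs for s in scans]),
            sample_rate=scans[0].sample_rate,
        )
        merged = process_scan(stacked, plate_power, bands, **kwargs)
        per_plane = {}
        offset = 0
        for s in scans:
            per_plane[s.plane] = {
                b.name: merged[b.name][offset : offset + s.n_angles] for b in bands
            }
            offset += s.n_angles
    else:
        per_plane = {
            s.plane: process_scan(s, plate_power, bands, **kwargs) for s in scans
        }
    return {
        b.name: overall_ts({plane: vals[b.name] for plane, vals in per_plane.items()})
        for b in bands
    }


def plate_reference_power(
    window_len: int = 1024,
    sample_rate: float = 500_000.0,
    onset: int = 128,
) -> np.ndarray:
    """Power spectrum of the ideal unit-reflector plate IR.

    The simulator's reference plate is a unit impulse processed through the
    identical windowing chain; its spectrum is flat at unit power. Real plate
    recordings are instead run through deconvolve/extract_echo/power_spectrum.
    """
    ir = np.zeros(window_len)
    ir[onset] = 1.0
    seg = extract_echo(ir, window_len=window_len, pre_peak=onset)
    _, power = power_spectrum(seg, sample_rate)
    return power
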