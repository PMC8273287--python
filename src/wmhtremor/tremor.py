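"""Polygraphic tremor analysis: spectral peak frequency and log total power.

Recordings follow the clinical polygraphy protocol: 30 s of postural tremor
sampled at 800 Hz from a bilateral accelerometer pair plus wrist
flexor/extensor surface EMG.  EMG is bandpass filtered 50–350 Hz and
full-wave rectified.  Spectra are Welch-averaged periodograms (4 s Hann
windows, 50 % overlap → 0.25 Hz resolution).  The frequency of the greatest
spectral peak within the tremor band (default 2–12 Hz) is the tremor
frequency; tremor amplitude is summarized as log10 of the band-integrated
accelerometer power.  Headline measures come from the accelerometer
channels only; EMG processing is provided but does not feed them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "CHANNEL_NAMES",
    "TremorRecording",
    "TremorSpectrum",
    "TremorMeasures",
    "preprocess_emg",
    "power_spectrum",
    "tremor_frequency",
    "log_total_power",
    "bilateral_mean",
    "tremor_measures",
]

CHANNEL_NAMES = (
    "acc_left",
    "acc_right",
    "emg_flex_left",
    "emg_ext_left",
    "emg_flex_right",
    "emg_ext_right",
)

DEFAULT_BAND_HZ = (2.0, 12.0)


@dataclass
class TremorRecording:
    """Multichannel tremor recording sampled at a common rate."""

    channels: dict[str, np.ndarray]
    fs: float = 800.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        lengths = {name: len(np.asarray(x)) for name, x in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channels differ in length: {lengths}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class TremorSpectrum:
    freqs: np.ndarray
    power: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(self.power < 0):
            raise ValueError("spectral power must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


@dataclass(frozen=True)
class TremorMeasures:
    """Per-side and bilateral-mean accelerometric tremor measures."""

    peak_frequency_left: float
    peak_frequency_right: float
    log_total_power_left: float
    log_total_power_right: float

    @property
    def mean_frequency(self) -> float:
        return bilateral_mean(self.peak_frequency_left, self.peak_frequency_right)

    @property
    def mean_log_total_power(self) -> float:
        return bilateral_mean(self.log_total_power_left, self.log_total_power_right)


def preprocess_emg(x, fs: float, band_hz=(50.0, 350.0), order: int = 4) -> np.ndarray:
    """Zero-phase bandpass (default 50–350 Hz) then full-wave rectification."""
    lo, hi = band_hz
    if fs <= 2 * hi:
        raise ValueError(f"sampling rate {fs} Hz too low for a {hi} Hz band edge")
    x = np.asarray(x, dtype=float)
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return np.abs(sps.sosfiltfilt(sos, x))


def power_spectrum(x, fs: float, window_s: float = 4.0, overlap: float = 0.5) -> TremorSpectrum:
    """Welch power spectral density (Hann windows, default 4 s, 50 % overlap).

    Density scaling, so ``sum(power) * resolution`` approximates the signal
    variance (Parseval).
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(window_s * fs))
    if nperseg < 64:
        raise ValueError("window too short: need window_s * fs >= 64 samples")
    if len(x) < nperseg:
        raise ValueError("signal shorter than one analysis window")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend=False,
        scaling="density",
    )
    return TremorSpectrum(freqs=freqs, power=psd, resolution=fs / nperseg)


def _band_slice(spec: TremorSpectrum, band_hz) -> np.ndarray:
    lo, hi = band_hz
    nyquist = spec.freqs[-1]
    if not (0.0 < lo < hi) or hi > nyquist:
        raise ValueError(f"band {band_hz} must lie within (0, {nyquist}] Hz")
    idx = np.flatnonzero((spec.freqs >= lo) & (spec.freqs <= hi))
    if idx.size == 0:
        raise ValueError(f"no spectral bins in band {band_hz}")
    return idx


def tremor_frequency(spec: TremorSpectrum, band_hz=DEFAULT_BAND_HZ) -> float:
    """Frequency of the greatest spectral peak within the tremor band.

    Ties break toward the lower frequency (argmax of the first maximum).
    """
    idx = _band_slice(spec, band_hz)
    return float(spec.freqs[idx[np.argmax(spec.power[idx])]])


def log_total_power(spec: TremorSpectrum, band_hz=DEFAULT_BAND_HZ) -> float:
    """log10 of the band-integrated power (Σ power × Δf over the band)."""
    idx = _band_slice(spec, band_hz)
    total = float(np.sum(spec.power[idx]) * spec.resolution)
    if total <= 0:
        raise ValueError("zero band power: log total power undefined")
    return float(np.log10(total))


def bilateral_mean(left: float, right: float) -> float:
    """Arithmetic mean of the left and right upper-extremity values."""
    if not (np.isfinite(left) and np.isfinite(right)):
        raise ValueError("bilateral mean requires finite values")
    return (left + right) / 2.0


def tremor_measures(
    rec: TremorRecording,
    band_hz=DEFAULT_BAND_HZ,
    window_s: float = 4.0,
    overlap: float = 0.5,
) -> TremorMeasures:
    """Accelerometric peak frequency and log total power, per side."""
    out = {}
    for side in ("left", "right"):
        spec = power_spectrum(rec.channels[f"acc_{side}"], rec.fs, window_s, overlap)
        out[f"peak_frequency_{side}"] = tremor_frequency(spec, band_hz)
        out[f"log_total_power_{side}"] = log_total_power(spec, band_hz)
    return TremorMeasures(**out)
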