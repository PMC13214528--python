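"""Acoustic feature extraction: waveform -> six 10 Hz feature channels.

The six channels summarise three perceptual attributes of a sound scene:

* loudness — the broadband ``envelope`` (magnitude of the analytic signal,
  low-pass filtered);
* pitch — a harmonic-template ``pitch`` track (log-Hz) plus the mean
  low-frequency spectrogram energy ``spec_low`` (resolved harmonics);
* timbre — the mean high-frequency spectrogram energy ``spec_high`` and the
  averaged spectral- (``scale``, cycles/octave) and temporal- (``rate``, Hz)
  modulation magnitudes of the spectrogram.

The auditory spectrogram uses a bank of 128 constant-Q bandpass filters
with log-spaced center frequencies spanning 5.3 octaves from 180 Hz,
half-wave rectification and short-window energy smoothing — a light-weight
stand-in for a cochlear model with the same channel geometry.  All channels
are mean-pooled onto a common 10 Hz grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.io import wavfile

FEATURE_ORDER = ("envelope", "pitch", "spec_low", "spec_high", "scale", "rate")

N_CHANNELS = 128
CF_LOW_HZ = 180.0
CF_OCTAVES = 5.3
BAND_SPLIT_HZ = 1120.0  # low/high spectral-summary boundary
INTERNAL_RATE = 16000
SPEC_FRAME_RATE = 100  # spectrogram frames per second, pooled later to 10 Hz
FEATURE_RATE = 10

__all__ = [
    "FEATURE_ORDER",
    "Waveform",
    "Spectrogram",
    "FeatureSet",
    "auditory_spectrogram",
    "extract_envelope",
    "extract_pitch",
    "band_energy_summaries",
    "modulation_summaries",
    "scale_filter_responses",
    "assemble_feature_set",
    "waveform_to_features",
    "center_frequencies",
]


@dataclass(frozen=True)
class Waveform:
    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("waveform must be non-empty and mono")
        if not np.all(np.isfinite(s)):
            raise ValueError("waveform contains non-finite samples")
        object.__setattr__(self, "samples", s)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    def resample(self, rate: int = INTERNAL_RATE) -> "Waveform":
        if rate == self.sample_rate:
            return self
        from math import gcd

        g = gcd(rate, self.sample_rate)
        out = signal.resample_poly(self.samples, rate // g, self.sample_rate // g)
        return Waveform(out, rate)

    @classmethod
    def from_wav(cls, path) -> "Waveform":
        rate, data = wavfile.read(path)
        data = np.asarray(data)
        if data.ndim > 1:
            data = data.mean(axis=1)
        if np.issubdtype(data.dtype, np.integer):
            data = data / float(np.iinfo(data.dtype).max)
        return cls(data.astype(float), int(rate))

    def to_wav(self, path) -> None:
        peak = np.max(np.abs(self.samples)) or 1.0
        wavfile.write(path, self.sample_rate,
                      (self.samples / peak * 0.9 * 32767).astype(np.int16))


@dataclass
class Spectrogram:
    values: np.ndarray  # (channels, frames), nonnegative energy
    center_freqs: np.ndarray  # Hz, strictly increasing
    frame_rate: float

    def __post_init__(self):
        if self.values.shape[0] != self.center_freqs.size:
            raise ValueError("channel count mismatch")
        if np.any(np.diff(self.center_freqs) <= 0):
            raise ValueError("center frequencies must be strictly increasing")


@dataclass
class FeatureSet:
    """Six time-aligned feature channels on the 10 Hz trial grid."""

    time: np.ndarray
    channels: dict[str, np.ndarray]

    def __post_init__(self):
        lengths = {k: len(v) for k, v in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channel length mismatch: {lengths}")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    def stack(self, order=FEATURE_ORDER) -> np.ndarray:
        return np.column_stack([self.channels[k] for k in order])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_s": self.time, **self.channels})

    @classmethod
    def from_frame(cls, df) -> "FeatureSet":
        chans = {k: df[k].to_numpy(dtype=float) for k in FEATURE_ORDER}
        return cls(time=df["time_s"].to_numpy(dtype=float), channels=chans)


def center_frequencies(n_channels: int = N_CHANNELS) -> np.ndarray:
    """Log-spaced CFs spanning ``CF_OCTAVES`` octaves upward from 180 Hz."""
    return CF_LOW_HZ * 2.0 ** (np.linspace(0.0, CF_OCTAVES, n_channels))


def auditory_spectrogram(wave: Waveform, frame_rate: float = SPEC_FRAME_RATE,
                         bandwidth_octaves: float = 0.25) -> Spectrogram:
    """Constant-Q filterbank energy representation of a 16 kHz waveform.

    Each channel is a 4-pole Butterworth bandpass (quarter-octave wide by
    default) followed by half-wave rectification and mean pooling into
    ``1/frame_rate`` windows.
    """
    wave = wave.resample(INTERNAL_RATE)
    fs, x = wave.sample_rate, wave.samples
    cfs = center_frequencies()
    hop = int(round(fs / frame_rate))
    n_frames = max(1, int(round(x.size / hop)))
    out = np.zeros((cfs.size, n_frames))
    half = 2.0 ** (bandwidth_octaves / 2.0)
    nyq = fs / 2.0
    for i, cf in enumerate(cfs):
        lo, hi = cf / half, min(cf * half, nyq * 0.999)
        sos = signal.butter(2, [lo / nyq, hi / nyq], btype="band", output="sos")
        y = np.maximum(signal.sosfilt(sos, x), 0.0)
        out[i] = _mean_pool(y, hop, n_frames)
    return Spectrogram(out, cfs, frame_rate)


def _mean_pool(x: np.ndarray, hop: int, n_frames: int) -> np.ndarray:
    n = n_frames * hop
    if x.size < n:
        x = np.pad(x, (0, n - x.size), mode="edge")
    return x[:n].reshape(n_frames, hop).mean(axis=1)


def extract_envelope(wave: Waveform, cutoff_hz: float = 40.0,
                     order: int = 6) -> np.ndarray:
    """Loudness channel: |analytic signal| low-passed (Butterworth, zero phase).

    Zero-phase forward-backward filtering keeps the envelope time-aligned
    with the spectrogram-derived channels.
    """
    wave = wave.resample(INTERNAL_RATE)
    env = np.abs(signal.hilbert(wave.samples))
    sos = signal.butter(order, cutoff_hz / (wave.sample_rate / 2),
                        btype="low", output="sos")
    return np.maximum(signal.sosfiltfilt(sos, env), 0.0)


# -- pitch -------------------------------------------------------------------

def _harmonic_templates(cfs: np.ndarray, f0_grid: np.ndarray,
                        n_harmonics: int = 8) -> np.ndarray:
    """(n_f0, n_channels) template bank: 1/k-weighted harmonic stacks.

    Each harmonic contributes weight 1/k, split linearly between the two
    channels bracketing k*f0 on the log-frequency axis, so template scores
    vary smoothly between grid points.
    """
    log_cfs = np.log2(cfs)
    step = log_cfs[1] - log_cfs[0]
    T = np.zeros((f0_grid.size, cfs.size))
    for gi, f0 in enumerate(f0_grid):
        for k in range(1, n_harmonics + 1):
            pos = (np.log2(k * f0) - log_cfs[0]) / step
            i0 = int(np.floor(pos))
            frac = pos - i0
            if 0 <= i0 < cfs.size:
                T[gi, i0] += (1.0 - frac) / k
            if 0 <= i0 + 1 < cfs.size:
                T[gi, i0 + 1] += frac / k
    return T


def extract_pitch(spec: Spectrogram, f0_min: float = 80.0, f0_max: float = 1200.0,
                  steps_per_octave: int = 24, median_window: int = 5,
                  energy_floor_frac: float = 0.01) -> np.ndarray:
    """Fundamental-frequency track (log2 Hz) by harmonic-template matching.

    Per frame the best-scoring f0 on a 1/24-octave grid is taken; the track
    is log-transformed, median filtered (window 5), and frames whose first
    derivative deviates from its mean by more than two standard deviations
    are replaced with the preceding estimate.  Low-energy frames (below 1%
    of the trial's maximum frame energy) hold the previous value.
    """
    n_steps = int(np.ceil(np.log2(f0_max / f0_min) * steps_per_octave)) + 1
    f0_grid = f0_min * 2.0 ** (np.arange(n_steps) / steps_per_octave)
    T = _harmonic_templates(spec.center_freqs, f0_grid)
    scores = T @ spec.values  # (n_f0, frames)
    track = np.log2(f0_grid[np.argmax(scores, axis=0)])

    frame_energy = spec.values.mean(axis=0)
    low = frame_energy < energy_floor_frac * max(frame_energy.max(), 1e-300)
    for t in range(track.size):
        if low[t]:
            track[t] = track[t - 1] if t else np.log2(f0_min)

    pad = median_window // 2
    padded = np.pad(track, pad, mode="reflect")
    track = signal.medfilt(padded, kernel_size=median_window)[pad:-pad]
    d = np.diff(track)
    if d.size and np.std(d) > 0:
        bad = np.abs(d - np.mean(d)) > 2.0 * np.std(d)
        for t in np.flatnonzero(bad) + 1:
            track[t] = track[t - 1]
    return track


def band_energy_summaries(spec: Spectrogram,
                          split_hz: float = BAND_SPLIT_HZ):
    """Mean spectrogram energy below / above the 1120 Hz boundary, per frame."""
    low = spec.center_freqs < split_hz
    return spec.values[low].mean(axis=0), spec.values[~low].mean(axis=0)


# -- modulation (scale / rate) ----------------------------------------------

def _gaussian_band_magnitude(data: np.ndarray, axis: int, sample_rate: float,
                             cfs: np.ndarray) -> np.ndarray:
    """Per-filter bandpass magnitude responses along one axis.

    Applies one-sided Gaussian bandpass filters (center cf, half-power width
    ~cf/2) in the FFT domain and returns the magnitude of the analytic
    reconstruction, stacked on a new leading axis (one slab per filter).
    """
    data = np.moveaxis(np.asarray(data, dtype=float), axis, -1)
    n = data.shape[-1]
    spec = np.fft.fft(data, axis=-1)
    freqs = np.fft.fftfreq(n, d=1.0 / sample_rate)
    out = np.empty((cfs.size,) + data.shape)
    for i, cf in enumerate(cfs):
        h = np.exp(-0.5 * ((freqs - cf) / (cf / 2.0)) ** 2)
        h[freqs <= 0] = 0.0  # analytic: positive frequencies only
        out[i] = np.abs(np.fft.ifft(spec * h, axis=-1))
    return np.moveaxis(out, -1, axis + 1)


def scale_filter_responses(spec: Spectrogram,
                           cfs_cyc_per_oct: np.ndarray | None = None) -> np.ndarray:
    """(n_filters, channels, frames) spectral-modulation magnitudes.

    Filter CFs default to 9 log-spaced values from 2^-4 to 2^4 cycles/octave;
    the channel axis is sampled at (n_channels-1)/octave-span channels per
    octave.
    """
    if cfs_cyc_per_oct is None:
        cfs_cyc_per_oct = 2.0 ** np.linspace(-4, 4, 9)
    chans_per_octave = (spec.center_freqs.size - 1) / CF_OCTAVES
    return _gaussian_band_magnitude(spec.values, axis=0,
                                    sample_rate=chans_per_octave,
                                    cfs=np.asarray(cfs_cyc_per_oct))


def modulation_summaries(spec: Spectrogram,
                         scale_cfs: np.ndarray | None = None,
                         rate_cfs: np.ndarray | None = None):
    """Averaged spectral (scale) and temporal (rate) modulation series.

    Scale: spectral-modulation filters (2^-4..2^4 cyc/oct) applied to each
    spectral slice, magnitudes averaged over filters and channels.  Rate:
    temporal-modulation filters (2-32 Hz, log-spaced) applied along time,
    likewise averaged.  Each returns one series per frame.
    """
    scale_resp = scale_filter_responses(spec, scale_cfs)
    scale_series = scale_resp.mean(axis=(0, 1))

    if rate_cfs is None:
        rate_cfs = 2.0 ** np.linspace(1, 5, 9)  # 2..32 Hz
    rate_resp = _gaussian_band_magnitude(spec.values, axis=1,
                                         sample_rate=spec.frame_rate,
                                         cfs=np.asarray(rate_cfs))
    rate_series = rate_resp.mean(axis=(0, 1))
    return scale_series, rate_series


def assemble_feature_set(envelope, pitch, spec_low, spec_high, scale, rate,
                         input_rates: dict[str, float],
                         out_rate: float = FEATURE_RATE) -> FeatureSet:
    """Mean-pool every channel into 100 ms frames on a common 10 Hz grid.

    ``input_rates`` maps channel name to its native sampling rate.  Frames
    are timestamped at bin centers.  Channels whose pooled lengths disagree
    by one frame (edge effects) are trimmed to the shortest.
    """
    raw = {"envelope": envelope, "pitch": pitch, "spec_low": spec_low,
           "spec_high": spec_high, "scale": scale, "rate": rate}
    pooled = {}
    for name, series in raw.items():
        series = np.asarray(series, dtype=float)
        hop = input_rates[name] / out_rate
        if abs(hop - round(hop)) > 1e-9:
            raise ValueError(f"{name}: rate {input_rates[name]} not a multiple "
                             f"of {out_rate}")
        hop = int(round(hop))
        n_frames = int(round(series.size / hop))
        pooled[name] = _mean_pool(series, hop, n_frames)
    lengths = sorted(len(v) for v in pooled.values())
    if lengths[-1] - lengths[0] > 1:
        raise ValueError(f"channel length mismatch beyond one frame: {lengths}")
    n = lengths[0]
    pooled = {k: v[:n] for k, v in pooled.items()}
    time = (np.arange(n) + 0.5) / out_rate
    return FeatureSet(time=time, channels=pooled)


def waveform_to_features(wave: Waveform) -> FeatureSet:
    """Full pipeline: waveform -> auditory spectrogram -> six 10 Hz channels."""
    wave = wave.resample(INTERNAL_RATE)
    spec = auditory_spectrogram(wave)
    env = extract_envelope(wave)
    pitch = extract_pitch(spec)
    lo, hi = band_energy_summaries(spec)
    scale, rate = modulation_summaries(spec)
    rates = {"envelope": float(wave.sample_rate), "pitch": spec.frame_rate,
             "spec_low": spec.frame_rate, "spec_high": spec.frame_rate,
             "scale": spec.frame_rate, "rate": spec.frame_rate}
    return assemble_feature_set(env, pitch, lo, hi, scale, rate, rates)
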