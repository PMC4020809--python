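"""Audio loading and calibrated log-amplitude spectrogram images.

The whole pipeline treats a recording as an image: a short-time Fourier
magnitude matrix, log-compressed and min-max rescaled to [0, 1], with row 0
the lowest frequency and columns advancing in time.  Frequency and time
calibration (Hz per pixel row, seconds per frame column) travel with the
image so that downstream band constraints can be expressed in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile
from scipy.signal import ShortTimeFFT, resample_poly
from scipy.signal.windows import get_window

__all__ = [
    "AudioClip",
    "Spectrogram",
    "StftParams",
    "load_wav",
    "write_wav",
    "normalize_amplitude",
    "compute_spectrogram",
]


@dataclass(frozen=True)
class AudioClip:
    """A mono recording: dimensionless samples plus its sample rate."""

    samples: np.ndarray
    sample_rate: int
    source_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("mono required: expected a 1-D sample array")
        if samples.size < 1:
            raise ValueError("empty clip: at least one sample required")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class StftParams:
    """Analysis parameters for the spectrogram image.

    Defaults give ~86 Hz x 5.8 ms pixels at 44.1 kHz (and ~43 Hz x 11.6 ms
    at 22.05 kHz), fine enough to keep band-limited callers as compact blobs
    while insect bands near Nyquist stay visible.
    """

    n_fft: int = 512
    hop: int = 256
    window: str = "hann"
    log_gain: float = 1000.0


@dataclass(frozen=True)
class Spectrogram:
    """Log-amplitude STFT image normalized to [0, 1].

    values[r, c] is the compressed magnitude at frequency row r (low to
    high) and time frame c.  ``freq_hz_per_pixel`` and ``sec_per_frame``
    calibrate pixel coordinates back to physical units.
    """

    values: np.ndarray
    freq_hz_per_pixel: float
    sec_per_frame: float
    stft_params: StftParams = field(default_factory=StftParams)
    source_id: str = ""

    @property
    def n_freq_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def pixel_to_hz(self, row: int) -> float:
        return row * self.freq_hz_per_pixel

    def hz_to_pixel(self, hz: float) -> int:
        return int(round(hz / self.freq_hz_per_pixel))


def load_wav(
    path,
    *,
    expected_rate: int | None = None,
    resample: bool = False,
    source_id: str | None = None,
) -> AudioClip:
    """Read a mono PCM/float WAV file into an :class:`AudioClip`.

    Integer PCM samples are rescaled to [-1, 1].  Multi-channel files are
    rejected outright — silently downmixing would change blob amplitudes.
    If ``expected_rate`` is given, a mismatching file is rejected unless
    ``resample=True``, which applies polyphase resampling.
    """
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"mono required: {path} has {data.shape[1]} channels")
    if data.size == 0:
        raise ValueError(f"zero-length recording: {path}")
    if np.issubdtype(data.dtype, np.integer):
        scale = float(max(abs(np.iinfo(data.dtype).min), np.iinfo(data.dtype).max))
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    if expected_rate is not None and rate != expected_rate:
        if not resample:
            raise ValueError(
                f"sample rate {rate} != expected {expected_rate} for {path}; "
                "pass resample=True to convert"
            )
        from math import gcd

        g = gcd(int(expected_rate), int(rate))
        samples = resample_poly(samples, expected_rate // g, rate // g)
        rate = expected_rate
    if source_id is None:
        import os

        source_id = os.path.splitext(os.path.basename(str(path)))[0]
    return AudioClip(samples=samples, sample_rate=int(rate), source_id=source_id)


def write_wav(path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV (values clipped to [-1, 1])."""
    pcm = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(path, clip.sample_rate, (pcm * 32767.0).astype(np.int16))


def normalize_amplitude(clip: AudioClip) -> AudioClip:
    """Scale the waveform so its peak absolute amplitude is 1.

    Pure gain change: the waveform shape is preserved.  Idempotent.
    """
    peak = float(np.max(np.abs(clip.samples)))
    if peak == 0.0:
        raise ValueError("silent recording: all samples are zero")
    if peak == 1.0:
        return clip
    return replace(clip, samples=clip.samples / peak)


def compute_spectrogram(clip: AudioClip, params: StftParams | None = None) -> Spectrogram:
    """Magnitude STFT -> log(1 + g*|X|) -> min-max rescale to [0, 1].

    The log compression bounds the dynamic range so that morphology and
    percentile thresholds operate on a contrast-compressed image; min-max
    rescaling makes the [0, 1] range a per-recording invariant.
    """
    params = params or StftParams()
    if clip.samples.size < params.n_fft:
        raise ValueError(
            f"clip of {clip.samples.size} samples shorter than one "
            f"analysis window ({params.n_fft})"
        )
    win = get_window(params.window, params.n_fft, fftbins=True)
    stft = ShortTimeFFT(win, hop=params.hop, fs=clip.sample_rate, fft_mode="onesided")
    mag = np.abs(stft.stft(clip.samples))
    values = np.log1p(params.log_gain * mag)
    lo, hi = float(values.min()), float(values.max())
    if hi > lo:
        values = (values - lo) / (hi - lo)
    else:
        values = np.zeros_like(values)
    return Spectrogram(
        values=values,
        freq_hz_per_pixel=clip.sample_rate / params.n_fft,
        sec_per_frame=params.hop / clip.sample_rate,
        stft_params=params,
        source_id=clip.source_id,
    )
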