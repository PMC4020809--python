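"""Synthetic annotated soundscapes for end-to-end pipeline testing.

The generator emulates the structure of multi-label field-recording
corpora from autonomous recording units: short mono clips, 0-6 band-
limited callers per clip that overlap freely in time but occupy distinct
frequency bands within a scene, per-source gains varying with distance,
plus abiotic interference — low-pass wind rumble, sparse broadband rain
or device-failure impulses, and slow anthropogenic siren tones.

Three call archetypes are synthesized: frequency-swept tonal chirps
(song-bird syllables), harmonic stacks (hooting night birds), and
pulse-modulated resonant combs (insect stridulation, which may run the
whole clip).  The default roster deliberately contains pairs of classes sharing
a frequency band but differing in call geometry — gross band occupancy
alone cannot separate them, mirroring real communities where species
overlap in frequency.

Everything is driven by one integer seed; the corpus annotation records
the ground-truth time-frequency box of every planted call so that
segmentation can be scored against it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfilt

from .audio import AudioClip, write_wav
from .classifier import make_label_matrix

__all__ = [
    "SpeciesSpec",
    "CallEvent",
    "SceneAnnotation",
    "Corpus",
    "default_roster",
    "disjoint_roster",
    "synth_call",
    "synth_noise",
    "synth_corpus",
]


@dataclass(frozen=True)
class SpeciesSpec:
    """Acoustic archetype of one synthetic class."""

    class_id: str
    call_kind: str  # tonal_chirp | harmonic_stack | broadband_stridulation
    band: tuple[float, float]  # Hz
    duration_range: tuple[float, float] = (0.4, 0.8)  # s per syllable
    repetition_rate: float = 60.0  # Hz, stridulation impulse rate
    gain_db_range: tuple[float, float] = (-9.0, 0.0)
    sweep_down: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("band must satisfy 0 < f_min < f_max")
        if self.duration_range[0] <= 0:
            raise ValueError("durations must be positive")


def default_roster(sample_rate: int = 22050) -> list[SpeciesSpec]:
    """Eight classes spanning the band, with same-band pairs.

    Classes 'chirp3k_up'/'chirp3k_down' and 'hoot5k'/'trill5k' share their
    bands, so band statistics confuse them while call geometry (sweep
    direction, harmonic structure) does not.
    """
    nyq = sample_rate / 2.0
    roster = [
        SpeciesSpec("hoot1k", "harmonic_stack", (500.0, 1100.0)),
        SpeciesSpec("chirp3k_up", "tonal_chirp", (2000.0, 3500.0)),
        SpeciesSpec("chirp3k_down", "tonal_chirp", (2000.0, 3500.0), sweep_down=True),
        SpeciesSpec("hoot5k", "harmonic_stack", (4200.0, 6000.0)),
        SpeciesSpec("trill5k", "tonal_chirp", (4200.0, 6000.0)),
        SpeciesSpec("whistle7k", "tonal_chirp", (6500.0, 7500.0)),
        SpeciesSpec(
            "cricket8k", "broadband_stridulation", (7800.0, 9200.0),
            repetition_rate=50.0,
        ),
        SpeciesSpec(
            "cicada10k", "broadband_stridulation", (9500.0, 10800.0),
            duration_range=(1.0, 3.0), repetition_rate=40.0,
        ),
    ]
    return [s for s in roster if s.band[1] <= nyq]


def disjoint_roster(sample_rate: int = 22050) -> list[SpeciesSpec]:
    """Variant with fully separated bands: separable by band occupancy alone."""
    return [
        SpeciesSpec("hoot1k", "harmonic_stack", (500.0, 1100.0)),
        SpeciesSpec("chirp2k", "tonal_chirp", (1600.0, 2600.0)),
        SpeciesSpec("chirp3k", "tonal_chirp", (3000.0, 4000.0), sweep_down=True),
        SpeciesSpec("hoot5k", "harmonic_stack", (4400.0, 5600.0)),
        SpeciesSpec("trill6k", "tonal_chirp", (6000.0, 6900.0)),
        SpeciesSpec("whistle7k", "tonal_chirp", (7200.0, 7900.0)),
        SpeciesSpec(
            "cricket8k", "broadband_stridulation", (8200.0, 9300.0),
            repetition_rate=50.0,
        ),
        SpeciesSpec(
            "cicada10k", "broadband_stridulation", (9600.0, 10800.0),
            duration_range=(1.0, 3.0), repetition_rate=40.0,
        ),
    ]


def synth_call(
    spec: SpeciesSpec,
    seed: int,
    sample_rate: int = 22050,
    duration: float | None = None,
) -> np.ndarray:
    """One syllable of the given archetype, peak-normalized.

    tonal_chirp: a frequency sweep across the band under a Hann envelope.
    harmonic_stack: fundamental at the band floor plus in-band harmonics
    with gentle vibrato.  broadband_stridulation: a stack of resonant
    carriers spanning the band, amplitude-modulated at the wing-stroke
    repetition rate — noise-like to the ear, a comb of fine spectral
    lines on the spectrogram.
    """
    rng = np.random.default_rng(seed)
    if spec.band[1] > sample_rate / 2:
        raise ValueError(f"band {spec.band} above Nyquist ({sample_rate / 2} Hz)")
    if duration is None:
        duration = float(rng.uniform(*spec.duration_range))
    n = max(int(duration * sample_rate), 2)
    t = np.arange(n) / sample_rate
    f_lo, f_hi = spec.band
    if spec.call_kind == "tonal_chirp":
        f0, f1 = (f_hi, f_lo) if spec.sweep_down else (f_lo, f_hi)
        # margin keeps the swept ridge inside the nominal band
        m = 0.08 * (f_hi - f_lo)
        f0, f1 = (f0 - m, f1 + m) if spec.sweep_down else (f0 + m, f1 - m)
        phase = 2 * np.pi * (f0 * t + 0.5 * (f1 - f0) / duration * t**2)
        wave = np.sin(phase)
    elif spec.call_kind == "harmonic_stack":
        f0 = f_lo * 1.05
        vibrato = 1.0 + 0.01 * np.sin(2 * np.pi * 5.0 * t + rng.uniform(0, 2 * np.pi))
        wave = np.zeros(n)
        k = 1
        while k * f0 <= f_hi:
            wave += (0.6 ** (k - 1)) * np.sin(2 * np.pi * k * f0 * vibrato * t)
            k += 1
    elif spec.call_kind == "broadband_stridulation":
        # pulse-modulated resonant comb: carriers spanning the band, each
        # amplitude-modulated at the wing-stroke repetition rate — noise-like
        # to the ear, a stack of fine spectral lines on the spectrogram
        n_lines = max(3, int((f_hi - f_lo) / 400.0))
        margin = 0.06 * (f_hi - f_lo)
        carriers = np.linspace(f_lo + margin, f_hi - margin, n_lines)
        carriers = carriers * (1.0 + rng.uniform(-0.004, 0.004, n_lines))
        wave = np.zeros(n)
        depth = 0.5
        for fc in carriers:
            pulse = np.sin(
                2 * np.pi * spec.repetition_rate * t + rng.uniform(0, 2 * np.pi)
            )
            amp = float(rng.uniform(0.6, 1.0))
            wave += amp * (1.0 - depth / 2 + (depth / 2) * pulse) * np.sin(
                2 * np.pi * fc * t + rng.uniform(0, 2 * np.pi)
            )
    else:
        raise ValueError(f"unknown call kind {spec.call_kind!r}")
    envelope = np.hanning(n) ** 0.5
    wave = wave * envelope
    peak = np.max(np.abs(wave))
    return wave / peak if peak > 0 else wave


def synth_noise(
    kind: str,
    level: float,
    seed: int,
    n_samples: int,
    sample_rate: int = 22050,
    click_rate: float = 20.0,
) -> np.ndarray:
    """Abiotic/anthropogenic interference of the given RMS level.

    wind_lowpass: low-pass filtered noise (cutoff well under 2 kHz);
    rain_impulses: sparse Poisson broadband clicks (also stands in for
    device-failure crackle); siren: a slowly frequency-modulated tone;
    none: silence.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    rng = np.random.default_rng(seed)
    if kind == "none" or level == 0.0:
        return np.zeros(n_samples)
    if kind == "wind_lowpass":
        sos = butter(4, 800.0, btype="lowpass", fs=sample_rate, output="sos")
        wave = sosfilt(sos, rng.standard_normal(n_samples))
    elif kind == "rain_impulses":
        wave = np.zeros(n_samples)
        n_clicks = rng.poisson(click_rate * n_samples / sample_rate)
        width = max(int(0.002 * sample_rate), 1)
        for pos in rng.integers(0, max(n_samples - width, 1), size=n_clicks):
            wave[pos : pos + width] += rng.standard_normal(width)
    elif kind == "siren":
        t = np.arange(n_samples) / sample_rate
        inst = 1000.0 + 300.0 * np.sin(2 * np.pi * 0.4 * t)
        wave = np.sin(2 * np.pi * np.cumsum(inst) / sample_rate)
    else:
        raise ValueError(f"unknown noise kind {kind!r}")
    rms = np.sqrt(np.mean(wave**2))
    return wave * (level / rms) if rms > 0 else wave


@dataclass(frozen=True)
class CallEvent:
    """Ground truth for one planted call."""

    class_id: str
    t_start: float
    t_end: float
    f_min: float
    f_max: float
    gain_db: float


@dataclass
class SceneAnnotation:
    recording_id: str
    present: list[str]
    events: list[CallEvent]
    noise_kinds: list[str]


@dataclass
class Corpus:
    clips: list[AudioClip]
    labels: pd.DataFrame
    annotations: list[SceneAnnotation]
    class_names: list[str]

    def write(self, out_dir) -> None:
        """WAV files + Table-style labels.csv + truth_boxes.csv."""
        os.makedirs(out_dir, exist_ok=True)
        for clip in self.clips:
            write_wav(os.path.join(out_dir, clip.source_id + ".wav"), clip)
        self.labels.to_csv(os.path.join(out_dir, "labels.csv"), index_label="#File")
        rows = [
            {
                "recording_id": ann.recording_id,
                "class_id": ev.class_id,
                "t_start": ev.t_start,
                "t_end": ev.t_end,
                "f_min": ev.f_min,
                "f_max": ev.f_max,
                "gain_db": ev.gain_db,
            }
            for ann in self.annotations
            for ev in ann.events
        ]
        pd.DataFrame(
            rows,
            columns=[
                "recording_id", "class_id", "t_start", "t_end",
                "f_min", "f_max", "gain_db",
            ],
        ).to_csv(os.path.join(out_dir, "truth_boxes.csv"), index=False)


def synth_corpus(
    specs: list[SpeciesSpec] | None = None,
    n_recordings: int = 100,
    species_per_recording: tuple[int, int] = (0, 3),
    snr_db: tuple[float, float] = (10.0, 30.0),
    seed: int = 0,
    sample_rate: int = 22050,
    duration_range: tuple[float, float] = (1.5, 3.0),
    p_structured_noise: float = 0.5,
    id_prefix: str = "rec",
    void_fraction: float | None = None,
    calls_per_species: tuple[int, int] = (1, 3),
) -> Corpus:
    """Generate a seeded corpus of annotated synthetic soundscapes.

    Each recording mixes 0-3 species (distinct classes, each contributing
    1-3 syllables at random times and a per-recording gain) over a white
    noise floor set by a per-recording SNR, optionally plus one structured
    interference source (wind, rain or siren).  Recordings with zero
    species get only noise and a noise-column-1 label row.
    ``void_fraction`` pins the exact share of empty recordings instead of
    leaving it to the species-count draw.
    """
    specs = specs if specs is not None else default_roster(sample_rate)
    rng = np.random.default_rng(seed)
    class_names = [s.class_id for s in specs]
    clips, annotations = [], []
    annotation_tags: dict[str, list[str]] = {}
    noise_kinds = ["wind_lowpass", "rain_impulses", "siren"]
    void_ids: set[int] = set()
    if void_fraction is not None:
        n_void = int(round(void_fraction * n_recordings))
        void_ids = set(rng.choice(n_recordings, size=n_void, replace=False).tolist())
    for i in range(n_recordings):
        rec_id = f"{id_prefix}{i:04d}"
        duration = float(rng.uniform(*duration_range))
        n = int(duration * sample_rate)
        mix = np.zeros(n)
        lo_sp, hi_sp = species_per_recording
        if void_fraction is not None:
            n_species = 0 if i in void_ids else int(rng.integers(max(1, lo_sp), hi_sp + 1))
        else:
            n_species = int(rng.integers(lo_sp, hi_sp + 1))
        chosen = rng.choice(len(specs), size=n_species, replace=False)
        events = []
        for s_idx in chosen:
            sp = specs[s_idx]
            gain_db = float(rng.uniform(*sp.gain_db_range))
            gain = 10.0 ** (gain_db / 20.0)
            if sp.call_kind == "broadband_stridulation":
                n_calls = 1
            else:
                n_calls = int(
                    rng.integers(calls_per_species[0], calls_per_species[1] + 1)
                )
            for _ in range(n_calls):
                call = synth_call(
                    sp, int(rng.integers(2**31)), sample_rate,
                    duration=min(float(rng.uniform(*sp.duration_range)), duration),
                )
                start = int(rng.integers(0, max(n - len(call), 1)))
                mix[start : start + len(call)] += gain * call[: n - start]
                events.append(
                    CallEvent(
                        class_id=sp.class_id,
                        t_start=start / sample_rate,
                        t_end=(start + len(call)) / sample_rate,
                        f_min=sp.band[0],
                        f_max=sp.band[1],
                        gain_db=gain_db,
                    )
                )
        # white noise floor pinned to the target SNR against the call mix
        target_snr = float(rng.uniform(*snr_db))
        signal_rms = np.sqrt(np.mean(mix**2)) if events else 0.0
        floor_rms = (
            signal_rms * 10.0 ** (-target_snr / 20.0) if events else 0.01
        )
        mix += floor_rms * rng.standard_normal(n)
        kinds = []
        if rng.uniform() < p_structured_noise or not events:
            kind = str(rng.choice(noise_kinds))
            level = max(floor_rms * 3.0, 0.02)
            mix += synth_noise(kind, level, int(rng.integers(2**31)), n, sample_rate)
            kinds.append(kind)
        peak = np.max(np.abs(mix))
        if peak > 0:
            mix = mix / peak * 0.9
        clips.append(AudioClip(samples=mix, sample_rate=sample_rate, source_id=rec_id))
        present = sorted({specs[s].class_id for s in chosen})
        annotation_tags[rec_id] = present
        annotations.append(
            SceneAnnotation(
                recording_id=rec_id, present=present, events=events, noise_kinds=kinds
            )
        )
    labels = make_label_matrix(annotation_tags, class_names)
    return Corpus(
        clips=clips, labels=labels, annotations=annotations, class_names=class_names
    )
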