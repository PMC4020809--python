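import numpy as np
import pytest

from wildscan.audio import AudioClip, Spectrogram, StftParams, compute_spectrogram
from wildscan.pipeline import PipelineConfig, extract_recording
from wildscan.simulator import default_roster, synth_call, synth_corpus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_spectrogram(values: np.ndarray, source_id: str = "fix") -> Spectrogram:
    """Wrap a raw matrix as a calibrated spectrogram for image-level tests."""
    return Spectrogram(
        values=np.asarray(values, dtype=np.float64),
        freq_hz_per_pixel=43.066,
        sec_per_frame=0.0116,
        stft_params=StftParams(),
        source_id=source_id,
    )


@pytest.fixture(scope="session")
def tiny_corpus():
    """12 short synthetic recordings with annotation, shared across tests."""
    return synth_corpus(n_recordings=12, seed=7)


@pytest.fixture(scope="session")
def tiny_extracted(tiny_corpus):
    cfg = PipelineConfig()
    return cfg, [extract_recording(c, cfg) for c in tiny_corpus.clips]


@pytest.fixture(scope="session")
def one_call_clip():
    """A single high-SNR chirp in light noise, with its ground-truth band."""
    sp = default_roster()[1]  # chirp3k_up, 2000-3500 Hz
    call = synth_call(sp, seed=5, duration=0.7)
    rng = np.random.default_rng(5)
    n = int(2.0 * 22050)
    mix = 0.005 * rng.standard_normal(n)
    start = int(0.6 * 22050)
    mix[start : start + len(call)] += call
    clip = AudioClip(mix / np.abs(mix).max(), 22050, "onecall")
    return clip, sp, (start / 22050, (start + len(call)) / 22050)
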