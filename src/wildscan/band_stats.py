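"""S1 block: marginal-over-time statistics on equal frequency bands.

The ROI-reconstructed spectrogram (original values under the ROI masks,
zero elsewhere) is partitioned into 16 equal, non-overlapping horizontal
bands — deliberately linear, not mel-spaced, because birds and insects
vocalise anywhere in the spectrum — and five descriptive statistics are
computed per band: mean, standard deviation, median, kurtosis, and the
90th percentile.  At the defaults this gives an 80-dimensional vector per
recording (16 bands x 5 stats), a coarse but surprisingly strong encoding
of which bands are occupied and how peaky their occupancy is.
"""

from __future__ import annotations

import numpy as np

from .audio import Spectrogram
from .segmentation import reconstruct_spectrogram

__all__ = [
    "STAT_NAMES",
    "partition_bands",
    "band_statistics",
    "s1_features",
    "s1_feature_names",
]

STAT_NAMES = ("mean", "std", "median", "kurtosis", "p90")


def partition_bands(n_freq_pixels: int, n_bands: int = 16) -> list[range]:
    """Contiguous, non-overlapping row ranges covering [0, n_freq_pixels).

    Band sizes differ by at most one pixel; larger bands come first.
    """
    if n_bands > n_freq_pixels:
        raise ValueError(
            f"cannot split {n_freq_pixels} rows into {n_bands} bands"
        )
    # first (n % n_bands) bands get the extra pixel, as np.array_split does
    base, extra = divmod(n_freq_pixels, n_bands)
    sizes = [base + 1] * extra + [base] * (n_bands - extra)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    return [range(int(bounds[i]), int(bounds[i + 1])) for i in range(n_bands)]


def band_statistics(band_pixels: np.ndarray) -> np.ndarray:
    """(mean, std, median, kurtosis, p90) of a flattened band.

    std is the population standard deviation.  Kurtosis is the fourth
    standardized central moment in the non-excess convention (a normal
    sample gives ~3); a constant band has kurtosis 0 by convention so the
    all-zero bands of sparse recordings stay finite.
    """
    x = np.asarray(band_pixels, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty band")
    mean = x.mean()
    m2 = np.mean((x - mean) ** 2)
    if m2 <= np.finfo(np.float64).tiny:
        kurt = 0.0
        std = 0.0
    else:
        std = np.sqrt(m2)
        kurt = np.mean((x - mean) ** 4) / m2**2
    return np.array([mean, std, np.median(x), kurt, np.quantile(x, 0.9)])


def s1_features(
    spec: Spectrogram,
    masks: list[np.ndarray],
    n_bands: int = 16,
    *,
    nonzero_only: bool = False,
) -> np.ndarray:
    """Per-recording S1 vector: reconstruct, partition, per-band stats.

    Statistics run over ALL pixels of each band of the reconstructed
    spectrogram — the zeros outside the ROIs are part of the enhanced
    spectrum and encode band occupancy.  ``nonzero_only=True`` restricts
    them to ROI pixels (empty bands then yield all-zero stats).  Output is
    band-major: band 0's five stats first, low to high frequency.
    """
    recon = reconstruct_spectrogram(spec, masks)
    bands = partition_bands(recon.n_freq_pixels, n_bands)
    out = np.empty(n_bands * len(STAT_NAMES))
    for b, rng in enumerate(bands):
        pixels = recon.values[rng.start : rng.stop, :].ravel()
        if nonzero_only:
            pixels = pixels[pixels != 0]
        stats = (
            band_statistics(pixels) if pixels.size else np.zeros(len(STAT_NAMES))
        )
        out[b * len(STAT_NAMES) : (b + 1) * len(STAT_NAMES)] = stats
    return out


def s1_feature_names(n_bands: int = 16) -> list[str]:
    return [f"S1:band{b}:{s}" for b in range(n_bands) for s in STAT_NAMES]
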