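"""S2 block: per-ROI shape descriptors quantized over multiple codebooks.

Each recording is a *bag of segments*: the set of its ROIs.  Every ROI is
summarized by a 22-dimensional descriptor — mask area, amplitude
statistics under the mask (mean, std, median, min, max), the frequency
pixel of the patch maximum, bandwidth and duration in pixels, and 13
mel-frequency cepstral coefficients averaged over the ROI's time frames.
Descriptors are pooled, whitened (per-dimension z-score) and clustered
with k-means into several codebooks of different granularity (default
sizes 25, 15 and 70).  A recording's S2 vector concatenates, per
codebook, the histogram of its ROIs' nearest-center indices — a
bag-of-words representation with a fixed length of sum(k) = 110 at the
defaults, whatever the number of ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct
from sklearn.cluster import KMeans

from .audio import Spectrogram
from .segmentation import ROI, ROICatalog

__all__ = [
    "DESCRIPTOR_NAMES",
    "Codebook",
    "describe_roi",
    "mel_filterbank",
    "mfcc_for_roi",
    "roi_descriptors",
    "whiten",
    "build_codebooks",
    "bag_histogram",
]

DESCRIPTOR_NAMES = (
    "area",
    "mean",
    "std",
    "median",
    "min",
    "max",
    "argmax_freq",
    "bandwidth",
    "duration",
) + tuple(f"mfcc{i}" for i in range(13))


def describe_roi(roi: ROI) -> np.ndarray:
    """Shape/amplitude descriptor of one ROI (without the MFCC part).

    Amplitude statistics are computed only over mask-true pixels; the
    argmax frequency is reported in absolute frequency pixels.  Apart from
    the duration, nothing depends on the ROI's time position.
    """
    vals = roi.patch[roi.mask]
    in_patch_row = np.unravel_index(np.argmax(roi.patch), roi.patch.shape)[0]
    return np.array(
        [
            roi.n_pixels,
            vals.mean(),
            vals.std(),
            np.median(vals),
            vals.min(),
            vals.max(),
            roi.freq_lo + in_patch_row,
            roi.bandwidth,
            roi.n_frames,
        ],
        dtype=np.float64,
    )


def mel_filterbank(n_filters: int, n_freq_pixels: int, sample_rate: float) -> np.ndarray:
    """Triangular mel-spaced filterbank over [0, Nyquist], unit-sum rows.

    Unit-sum normalization makes a spectrally flat frame map to a constant
    filterbank output, so its cepstrum is carried entirely by c0.
    """

    def hz_to_mel(f):
        return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)

    def mel_to_hz(m):
        return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)

    nyquist = sample_rate / 2.0
    mel_pts = np.linspace(0.0, hz_to_mel(nyquist), n_filters + 2)
    hz_pts = mel_to_hz(mel_pts)
    bin_freqs = np.linspace(0.0, nyquist, n_freq_pixels)
    fb = np.zeros((n_filters, n_freq_pixels))
    for i in range(n_filters):
        lo, mid, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (bin_freqs - lo) / (mid - lo)
        down = (hi - bin_freqs) / (hi - mid)
        fb[i] = np.clip(np.minimum(up, down), 0.0, None)
        s = fb[i].sum()
        if s > 0:
            fb[i] /= s
    return fb


def mfcc_for_roi(
    spec: Spectrogram,
    roi_frames: tuple[int, int],
    n_coeff: int = 13,
    n_filters: int = 26,
    sample_rate: float | None = None,
) -> np.ndarray:
    """MFCCs of the spectrogram image restricted to the ROI's frames.

    The image columns in [lo, hi) are multiplied with a mel filterbank,
    log is applied, the result is decorrelated with a DCT-II, and the
    first ``n_coeff`` coefficients are averaged over the frames.
    """
    lo, hi = roi_frames
    if hi <= lo:
        raise ValueError("empty frame set")
    if sample_rate is None:
        sample_rate = 2.0 * spec.freq_hz_per_pixel * (spec.n_freq_pixels - 1)
    frames = spec.values[:, lo:hi]
    fb = mel_filterbank(n_filters, spec.n_freq_pixels, sample_rate)
    energies = fb @ frames
    logs = np.log(energies + 1e-10)
    coeffs = dct(logs, type=2, axis=0, norm="ortho")[:n_coeff, :]
    return coeffs.mean(axis=1)


def roi_descriptors(spec: Spectrogram, catalog: ROICatalog) -> np.ndarray:
    """Full 22-dim descriptor matrix (one row per ROI) for one recording."""
    rows = []
    for roi in catalog:
        if roi.frames is None:
            raise ValueError("ROI lacks frame bounds needed for MFCCs")
        rows.append(np.concatenate([describe_roi(roi), mfcc_for_roi(spec, roi.frames)]))
    return (
        np.vstack(rows) if rows else np.empty((0, len(DESCRIPTOR_NAMES)))
    )


def whiten(descriptors: np.ndarray) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Per-dimension z-scoring over the ROI pool.

    Returns the whitened matrix and (mean, scale); zero-variance
    dimensions get scale 1 so they map to exact zeros.
    """
    mean = descriptors.mean(axis=0)
    scale = descriptors.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (descriptors - mean) / scale, (mean, scale)


@dataclass(frozen=True)
class Codebook:
    """k-means centers in whitened descriptor space."""

    k: int
    centers: np.ndarray
    whitening_mean: np.ndarray
    whitening_scale: np.ndarray

    def assign(self, descriptors: np.ndarray) -> np.ndarray:
        """Nearest-center index per descriptor row (Euclidean, whitened).

        Ties break to the lowest center index.
        """
        if descriptors.shape[0] == 0:
            return np.empty(0, dtype=int)
        white = (descriptors - self.whitening_mean) / self.whitening_scale
        d2 = ((white[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


def build_codebooks(
    descriptors: np.ndarray,
    ks: tuple[int, ...] = (25, 15, 70),
    seed: int = 0,
) -> list[Codebook]:
    """One seeded k-means run per codebook size on the whitened pool."""
    white, (mean, scale) = whiten(descriptors)
    books = []
    for k in ks:
        if descriptors.shape[0] < k:
            raise ValueError(
                f"codebook k={k} needs at least {k} ROIs, have {descriptors.shape[0]}"
            )
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
        km.fit(white)
        books.append(
            Codebook(
                k=k,
                centers=km.cluster_centers_,
                whitening_mean=mean,
                whitening_scale=scale,
            )
        )
    return books


def bag_histogram(
    recording_descriptors: np.ndarray, codebooks: list[Codebook]
) -> np.ndarray:
    """Concatenated per-codebook histograms of nearest-center counts.

    Each sub-histogram sums to the recording's ROI count; a recording
    without ROIs yields the all-zero vector.  Raw counts, not frequencies:
    the activity level of a recording is itself informative and forests
    are scale-free.
    """
    parts = []
    for book in codebooks:
        hist = np.zeros(book.k)
        for idx in book.assign(recording_descriptors):
            hist[idx] += 1
        parts.append(hist)
    return np.concatenate(parts)


def s2_feature_names(ks: tuple[int, ...] = (25, 15, 70)) -> list[str]:
    return [f"S2:cb{i}k{k}:bin{j}" for i, k in enumerate(ks) for j in range(k)]
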