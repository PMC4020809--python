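"""Spectrogram ROI segmentation by mathematical morphology.

A region of interest (ROI) is a connected high-amplitude blob in the
spectrogram image, assumed to be one call, syllable or phrase.  The chain
is: enhancement (subtract the morphological opening, which flattens
background illumination such as low-frequency wind glow), percentile
binarization, connected-component labeling, mask filtering (small blobs
and blobs touching the low-frequency border are discarded), and cropping
the surviving masks out of the *original* spectrogram.

Time positions are dropped from the catalogue: an animal can vocalise at
any time within a recording but only at the frequencies of its repertoire.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.measure import label as _sk_label
from skimage.morphology import opening

from .audio import Spectrogram

__all__ = [
    "ROI",
    "ROICatalog",
    "SegmentationConfig",
    "enhance_image",
    "binarize",
    "label_components",
    "filter_masks",
    "extract_rois",
    "reconstruct_spectrogram",
    "segment",
]


@dataclass(frozen=True)
class ROI:
    """One segmented spectral blob.

    ``patch`` is the bounding-box crop of the original spectrogram with
    non-mask pixels zeroed; ``mask`` is the boolean blob restricted to the
    same bounding box.  ``freq_lo``/``freq_hi`` are half-open frequency
    pixel bounds in the source image.  ``frames`` (the half-open time-frame
    bounds) is retained only so that per-ROI MFCCs can be computed within
    the source recording; it is never persisted nor used as a feature.
    """

    mask: np.ndarray
    patch: np.ndarray
    freq_lo: int
    freq_hi: int
    n_frames: int
    source_id: str
    roi_index: int
    frames: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.freq_lo >= self.freq_hi:
            raise ValueError("freq_lo must be < freq_hi")
        if self.mask.shape != self.patch.shape:
            raise ValueError("mask and patch shapes differ")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def bandwidth(self) -> int:
        return self.freq_hi - self.freq_lo


@dataclass
class ROICatalog:
    """Ordered ROI collection; ordering key (source_id, roi_index)."""

    rois: list[ROI] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def __getitem__(self, i: int) -> ROI:
        return self.rois[i]

    def extend(self, rois) -> None:
        self.rois.extend(rois)
        self.rois.sort(key=lambda r: (r.source_id, r.roi_index))

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source_id": r.source_id,
                    "roi_index": r.roi_index,
                    "freq_lo": r.freq_lo,
                    "freq_hi": r.freq_hi,
                    "n_pixels": r.n_pixels,
                    "n_frames": r.n_frames,
                }
                for r in self.rois
            ]
        )

    def save(self, out_dir) -> None:
        """Persist as a directory of .npy patch/mask pairs + CSV manifest."""
        os.makedirs(out_dir, exist_ok=True)
        self.manifest().to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
        for r in self.rois:
            stem = f"{r.source_id}_{r.roi_index:04d}"
            np.save(os.path.join(out_dir, stem + "_patch.npy"), r.patch)
            np.save(os.path.join(out_dir, stem + "_mask.npy"), r.mask)


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs of the segmentation chain.

    min_pixels=100 follows the convention of keeping only blobs at least as
    large as a short but perceptible call; border_rows drops blobs touching
    the lowest frequency rows, which are almost always low-pass (wind,
    running water) noise.
    """

    selem_size: int = 4
    percentile: float = 0.9
    connectivity: int = 8
    min_pixels: int = 100
    border_rows: int = 2
    enhancement: str = "opening"  # or "blur"
    blur_sigma: float = 6.0


def enhance_image(
    spec: Spectrogram,
    selem_size: int = 4,
    *,
    method: str = "opening",
    blur_sigma: float = 6.0,
) -> np.ndarray:
    """Background-flattened image: values minus their morphological opening.

    Opening (erosion then dilation) removes bright structures smaller than
    the structuring element while tracking smooth illumination; the
    difference keeps compact blobs and suppresses gradients.  ``method=
    "blur"`` subtracts a Gaussian-blurred copy instead.
    """
    img = spec.values
    if method == "opening":
        if selem_size > min(img.shape):
            raise ValueError(
                f"structuring element {selem_size} exceeds image {img.shape}"
            )
        background = opening(img, np.ones((selem_size, selem_size)))
    elif method == "blur":
        background = gaussian_filter(img, blur_sigma)
    else:
        raise ValueError(f"unknown enhancement method {method!r}")
    return np.clip(img - background, 0.0, None)


def binarize(image: np.ndarray, percentile: float = 0.9) -> np.ndarray:
    """Boolean mask of pixels strictly above the given quantile of all pixels.

    The quantile is taken over every pixel (zeros included); with a 0.9
    percentile roughly the top 10% of pixels survive.  A constant image
    yields an all-false mask.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must lie in (0, 1)")
    threshold = np.quantile(image, percentile)
    return image > threshold


def label_components(mask: np.ndarray, connectivity: int = 8) -> list[np.ndarray]:
    """Split a boolean mask into maximal connected components.

    Returns one full-shape boolean mask per component, ordered by the
    component's (min row, min col) so the ordering is deterministic.
    8-connectivity keeps diagonal chirp ridges as single blobs.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labeled = _sk_label(mask, connectivity=1 if connectivity == 4 else 2)
    components = []
    for lab in range(1, labeled.max() + 1):
        comp = labeled == lab
        rows, cols = np.nonzero(comp)
        components.append((rows.min(), cols.min(), comp))
    components.sort(key=lambda t: (t[0], t[1]))
    return [comp for _, _, comp in components]


def filter_masks(
    masks: list[np.ndarray], min_pixels: int = 100, border_rows: int = 2
) -> list[np.ndarray]:
    """Drop small masks and masks touching the bottom frequency rows.

    Keeps masks with at least ``min_pixels`` true pixels that do not
    intersect rows [0, border_rows) — the low-frequency border where
    low-pass noise blobs live.  Order is preserved.
    """
    if min_pixels < 1:
        raise ValueError("min_pixels must be >= 1")
    kept = []
    for m in masks:
        if m.sum() < min_pixels:
            continue
        if border_rows > 0 and m[:border_rows, :].any():
            continue
        kept.append(m)
    return kept


def extract_rois(
    spec: Spectrogram, masks: list[np.ndarray], *, masked: bool = True
) -> ROICatalog:
    """Crop each mask's bounding box out of the ORIGINAL spectrogram.

    Non-mask pixels inside the bounding box are zeroed so the patch carries
    the blob's geometry and nothing else (``masked=False`` keeps the raw
    rectangle instead).  Frequency bounds are recorded; absolute time
    position is dropped (``frames`` is kept only for MFCC extraction
    within this recording).
    """
    rois = []
    for idx, m in enumerate(masks):
        rows, cols = np.nonzero(m)
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        sub_mask = m[r0:r1, c0:c1]
        crop = spec.values[r0:r1, c0:c1]
        patch = np.where(sub_mask, crop, 0.0) if masked else crop.copy()
        rois.append(
            ROI(
                mask=sub_mask,
                patch=patch,
                freq_lo=int(r0),
                freq_hi=int(r1),
                n_frames=int(c1 - c0),
                source_id=spec.source_id,
                roi_index=idx,
                frames=(int(c0), int(c1)),
            )
        )
    return ROICatalog(rois)


def reconstruct_spectrogram(spec: Spectrogram, masks: list[np.ndarray]) -> Spectrogram:
    """Impose the ROIs of the original spectrum on an empty spectrogram.

    The output equals the original under the union of the masks and is
    zero elsewhere.  Idempotent (a projection).
    """
    union = np.zeros(spec.values.shape, dtype=bool)
    for m in masks:
        if m.shape != spec.values.shape:
            raise ValueError("mask shape does not match spectrogram")
        union |= m
    out = np.where(union, spec.values, 0.0)
    return Spectrogram(
        values=out,
        freq_hz_per_pixel=spec.freq_hz_per_pixel,
        sec_per_frame=spec.sec_per_frame,
        stft_params=spec.stft_params,
        source_id=spec.source_id,
    )


def segment(
    spec: Spectrogram, config: SegmentationConfig | None = None
) -> tuple[list[np.ndarray], ROICatalog]:
    """Full chain: enhance -> binarize -> label -> filter -> catalogue.

    Returns the surviving full-shape masks and the ROI catalogue.
    """
    config = config or SegmentationConfig()
    enhanced = enhance_image(
        spec,
        config.selem_size,
        method=config.enhancement,
        blur_sigma=config.blur_sigma,
    )
    mask = binarize(enhanced, config.percentile)
    components = label_components(mask, config.connectivity)
    kept = filter_masks(components, config.min_pixels, config.border_rows)
    return kept, extract_rois(spec, kept)
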