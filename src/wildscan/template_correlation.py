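"""S3 block: frequency-constrained normalized cross-correlation of ROIs.

Every training ROI, taken as a 2-D template (its masked patch), scans
every recording's spectrogram and the best normalized cross-correlation
it achieves becomes one feature of that recording.  The scan is
constrained in frequency to the template's own band enlarged by a few
pixels (default 4) — species often share call shapes and differ mainly in
where they sit in frequency — while time offsets are unrestricted, since
an animal can vocalise at any time within a recording.  Because the scan
never leaves the template's band, strong interference elsewhere in the
spectrum (an airplane at low frequency under a high-frequency cricket)
cannot disturb the score.

The NCC is the Pearson correlation between the template and an equally
sized image window: gain- and offset-invariant, bounded in [-1, 1], with
degenerate (zero-variance) windows scored 0.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import match_template

from .audio import Spectrogram
from .segmentation import ROI, ROICatalog

__all__ = ["ncc_at", "scan_template", "s3_features", "s3_feature_names"]


def ncc_at(template: np.ndarray, image: np.ndarray, offset: tuple[int, int]) -> float:
    """Normalized cross-correlation of a template at one image offset.

    Direct evaluation: covariance of the mean-subtracted template and the
    mean-subtracted image window, divided by the product of their root
    sums of squares.  The template mean is taken over its full bounding
    box (including any zeroed non-mask pixels).  Returns 0 when either
    factor has zero variance.
    """
    h, w = template.shape
    r, c = offset
    if r < 0 or c < 0 or r + h > image.shape[0] or c + w > image.shape[1]:
        raise ValueError(f"window {offset}+{template.shape} outside image")
    window = image[r : r + h, c : c + w]
    t = template - template.mean()
    f = window - window.mean()
    denom = np.sqrt((t**2).sum() * (f**2).sum())
    if denom == 0.0:
        return 0.0
    return float(np.clip((t * f).sum() / denom, -1.0, 1.0))


def scan_template(roi: ROI, spec: Spectrogram, freq_tolerance: int = 4) -> float:
    """Best NCC of a ROI template over its permissible frequency band.

    Row offsets keep the whole template inside
    [freq_lo - tol, freq_hi + tol) intersected with the image; all time
    offsets are allowed.  Returns 0 when no offset is feasible (template
    taller or longer than the allowed region).  The template is the ROI's
    stored patch — masked by default, a raw rectangle if the catalogue was
    extracted with ``masked=False``.
    """
    if freq_tolerance < 0:
        raise ValueError("freq_tolerance must be >= 0")
    template = roi.patch
    band_lo = max(0, roi.freq_lo - freq_tolerance)
    band_hi = min(spec.n_freq_pixels, roi.freq_hi + freq_tolerance)
    h, w = template.shape
    if band_hi - band_lo < h or spec.n_frames < w:
        return 0.0
    strip = spec.values[band_lo:band_hi, :]
    scores = match_template(strip, template)
    scores = np.nan_to_num(scores, nan=0.0, posinf=0.0, neginf=0.0)
    return float(np.clip(scores.max(), -1.0, 1.0))


def s3_features(
    templates: ROICatalog,
    spec: Spectrogram,
    freq_tolerance: int = 4,
) -> np.ndarray:
    """One max-NCC per training ROI, in catalogue order.

    The feature row has a fixed length (the size of the template swarm)
    for every recording, train or test alike.
    """
    return np.array(
        [scan_template(roi, spec, freq_tolerance) for roi in templates]
    )


def s3_feature_names(templates: ROICatalog) -> list[str]:
    return [f"S3:{r.source_id}:{r.roi_index}" for r in templates]
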