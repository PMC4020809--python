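"""End-to-end orchestration: clips -> ROI catalogues -> S1|S2|S3 blocks.

Feature fitting artifacts (codebooks, the template swarm) are learned on
training recordings only by default, so a fitted pipeline can be applied
to unseen data; ``transductive=True`` pools training and test ROIs for
codebook learning, the protocol appropriate when the full unlabeled test
corpus is in hand at fit time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio import AudioClip, Spectrogram, StftParams, compute_spectrogram, normalize_amplitude
from .band_stats import s1_feature_names, s1_features
from .bag_of_segments import (
    Codebook,
    bag_histogram,
    build_codebooks,
    roi_descriptors,
    s2_feature_names,
)
from .classifier import StackedFeatures
from .segmentation import ROICatalog, SegmentationConfig, segment
from .template_correlation import s3_feature_names, s3_features

__all__ = ["PipelineConfig", "ExtractedRecording", "extract_recording", "FeaturePipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    stft: StftParams = field(default_factory=StftParams)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    n_bands: int = 16
    codebook_ks: tuple[int, ...] = (25, 15, 70)
    freq_tolerance: int = 4
    max_templates: int | None = None
    transductive: bool = False
    blocks: tuple[str, ...] = ("S1", "S2", "S3")


@dataclass
class ExtractedRecording:
    """Per-recording artifacts shared by all three feature blocks."""

    spec: Spectrogram
    masks: list
    catalog: ROICatalog
    descriptors: np.ndarray
    s1: np.ndarray


def extract_recording(clip: AudioClip, config: PipelineConfig) -> ExtractedRecording:
    """Normalize, image, segment and describe one recording."""
    spec = compute_spectrogram(normalize_amplitude(clip), config.stft)
    masks, catalog = segment(spec, config.segmentation)
    return ExtractedRecording(
        spec=spec,
        masks=masks,
        catalog=catalog,
        descriptors=roi_descriptors(spec, catalog),
        s1=s1_features(spec, masks, config.n_bands),
    )


class FeaturePipeline:
    """Fits codebooks and the template swarm, then emits feature blocks.

    Typical use::

        pipe = FeaturePipeline(config)
        train_ex = [extract_recording(c, config) for c in train_clips]
        test_ex = [extract_recording(c, config) for c in test_clips]
        pipe.fit(train_ex, test_ex if config.transductive else None, seed=0)
        S_train = pipe.transform(train_ex)
        S_test = pipe.transform(test_ex)
    """

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        self.codebooks: list[Codebook] | None = None
        self.templates: ROICatalog | None = None

    def fit(
        self,
        train: list[ExtractedRecording],
        test: list[ExtractedRecording] | None = None,
        seed: int = 0,
    ) -> "FeaturePipeline":
        """Learn codebooks (train ROIs, plus test if transductive) and
        assemble the template swarm from training ROIs."""
        cfg = self.config
        pool = [ex.descriptors for ex in train]
        if cfg.transductive and test is not None:
            pool += [ex.descriptors for ex in test]
        descriptors = np.vstack([d for d in pool if d.size])
        if "S2" in cfg.blocks:
            self.codebooks = build_codebooks(descriptors, cfg.codebook_ks, seed=seed)
        swarm = ROICatalog()
        swarm.extend(roi for ex in train for roi in ex.catalog)
        if cfg.max_templates is not None and len(swarm) > cfg.max_templates:
            rng = np.random.default_rng(seed)
            keep = sorted(
                rng.choice(len(swarm), size=cfg.max_templates, replace=False)
            )
            swarm = ROICatalog([swarm[i] for i in keep])
        self.templates = swarm
        return self

    def block(self, extracted: list[ExtractedRecording], name: str) -> StackedFeatures:
        """One feature block (``"S1"``, ``"S2"`` or ``"S3"``) for a set of
        recordings, rows in the given order."""
        if name == "S1":
            return StackedFeatures(
                np.vstack([ex.s1 for ex in extracted]),
                s1_feature_names(self.config.n_bands),
            )
        if name == "S2":
            if self.codebooks is None:
                raise RuntimeError("pipeline not fitted (codebooks missing)")
            return StackedFeatures(
                np.vstack(
                    [bag_histogram(ex.descriptors, self.codebooks) for ex in extracted]
                ),
                s2_feature_names(self.config.codebook_ks),
            )
        if name == "S3":
            if self.templates is None:
                raise RuntimeError("pipeline not fitted (templates missing)")
            return StackedFeatures(
                np.vstack(
                    [
                        s3_features(self.templates, ex.spec, self.config.freq_tolerance)
                        for ex in extracted
                    ]
                ),
                s3_feature_names(self.templates),
            )
        raise ValueError(f"unknown block {name!r}")

    def blocks(
        self, extracted: list[ExtractedRecording]
    ) -> dict[str, StackedFeatures]:
        return {name: self.block(extracted, name) for name in self.config.blocks}
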