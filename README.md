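# wildscan

Multi-label classification of vocalizing species — birds, insects,
amphibians — in unprocessed field recordings from autonomous recording
units (ARUs). `wildscan` is aimed at bioacoustic monitoring work where a
single short recording may contain anywhere from zero to several
simultaneously calling species over wind, rain and anthropogenic noise,
and where the annotation available is a per-recording *tag list*, not
time-stamped, cleaned clips.

## The approach

The recording is treated as an image, not as a frame sequence:

1. **Spectrogram image.** The amplitude-normalized waveform becomes a
   log-amplitude STFT image `S[f, t]`, min-max rescaled to [0, 1]
   (default 512-point FFT, hop 256, Hann).
2. **ROI segmentation.** The image minus its morphological opening
   flattens background illumination (wind glow, water); thresholding at
   the 0.9 quantile and 8-connected component labeling yield binary
   masks. Masks under 100 pixels or touching the low-frequency border
   are dropped. The survivors, cropped from the *original* spectrogram,
   are the regions of interest (ROIs) — one blob ≈ one call or syllable.
   Each ROI keeps its frequency band; its time position is discarded.
3. **Three feature blocks per recording.**
   - **S1** (80 dims): mean, std, median, kurtosis and 90th percentile
     over each of 16 equal frequency bands of the ROI-reconstructed
     spectrogram.
   - **S2** (110 dims): each ROI is described by a 22-dim vector (mask
     area, amplitude statistics under the mask, argmax frequency,
     bandwidth, duration, 13 MFCCs over the ROI's frames); descriptors
     are whitened and quantized against k-means codebooks of sizes
     25/15/70, and the recording is the concatenated histogram of its
     ROIs' nearest-center indices (a bag of segments).
   - **S3** (one dim per training ROI): the maximum normalized 2-D
     cross-correlation of each training ROI template against the
     recording's spectrogram, scanned only within the template's own
     frequency band ±4 pixels. Out-of-band interference, however loud,
     cannot touch these scores.
4. **Classifier.** `S = [S1|S2|S3]` feeds an 80-tree random forest whose
   out-of-bag permutation importance selects features once (shared
   across labels); the final model is one 250-tree forest per label
   (binary relevance, one-vs-all; entropy criterion,
   `min_samples_split=4`, `min_samples_leaf=3`), replicated over 10
   seeds and averaged. Evaluation is per-label ROC AUC. A gradient
   boosting detector on the same features, trained on the label matrix's
   leading *noise* column, separates recordings with animal
   vocalisations from purely abiotic ones.

A seeded soundscape simulator generates annotated synthetic corpora —
band-limited chirps, harmonic stacks and insect stridulation over wind /
rain / siren interference — so the full pipeline is testable end to end
without any field data.

## Worked example

```python
import wildscan as ws
import wildscan.classifier as clf
from wildscan.pipeline import FeaturePipeline, PipelineConfig, extract_recording

train = ws.synth_corpus(n_recordings=60, seed=101, id_prefix="tr", void_fraction=0.3)
test = ws.synth_corpus(n_recordings=40, seed=102, id_prefix="te", void_fraction=0.3)

cfg = PipelineConfig()
tr = [extract_recording(c, cfg) for c in train.clips]
te = [extract_recording(c, cfg) for c in test.clips]
pipe = FeaturePipeline(cfg).fit(tr, seed=0)

S = clf.stack_features(*pipe.blocks(tr).values())
T = clf.stack_features(*pipe.blocks(te).values())
sel = clf.select_features_oob(S, train.labels, seed=0)
model = clf.train(S, train.labels, selected=sel)
per_label, macro = clf.evaluate_auc(clf.predict(model, T), test.labels)
print(f"kept {len(sel)}/{S.n_features} features, macro AUC {macro:.3f}")
```

prints

```
kept 163/359 features, macro AUC 1.000
```

i.e. the out-of-bag selection discards more than half of the stacked
features (mostly correlations against noise blobs, which have no
descriptive power), and the eight synthetic species are ranked
perfectly on the unseen recordings of this corpus: for every evaluable
label, every recording containing the species scores above every
recording without it. Block ablations on the same corpus stay slightly
behind the full stack (S1 alone ≈ 0.97 on a comparable corpus, S3
alone ≈ 0.99) — the band-constrained template correlations are the
strongest single block, and stacking adds the rest.

The same flow works from the shell on directories of WAV files:

```bash
wildscan simulate --out data/ --seed 4 --n-recordings 60
wildscan extract --in data/ --out catalog/ --min-pixels 100 --percentile 0.9
wildscan train --wavs data/ --labels data/labels.csv --out model.pkl
wildscan predict --model model.pkl --wavs data/ --out pred.csv
wildscan evaluate --pred pred.csv --truth data/labels.csv
```

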