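# Methods

## Problem setting

Given short mono field recordings and per-recording tag lists (which
acoustic classes occur, with no time stamps), learn to rank unseen
recordings by the probability that each class is present. The label
matrix is binary, `recordings × (1 + n_classes)`: the leading `noise`
column marks recordings void of animal vocalisation, and calls and
songs of one species may be distinct columns. Evaluation is per-label
ROC AUC; no decision thresholds are calibrated.

## Spectrogram image

- STFT: `n_fft=512`, `hop=256`, Hann, one-sided. At 44.1 kHz this gives
  ~86 Hz × 5.8 ms pixels; at the simulator's 22.05 kHz, ~43 Hz × 11.6 ms.
  These parameters are engineering defaults: fine enough that a syllable
  is a compact blob, coarse enough that a recording is a small image.
- Amplitude scale: `log(1 + 1000·|X|)`, then per-recording min-max to
  [0, 1]. Morphology and percentile thresholds need a bounded,
  contrast-compressed image; the gain of 1000 puts typical call energy
  well into the log regime. Row 0 is the lowest frequency everywhere.
- Recordings at an unexpected sample rate are rejected by default (an
  optional polyphase resample flag exists): pixel-denominated tolerances
  (±4 rows) are only meaningful if calibration is constant over a corpus.

## ROI segmentation

Enhancement subtracts the morphological opening (erosion then dilation,
square 4×4 structuring element) from the image and clips at zero — a
top-hat transform. It passes structures that are thin in at least one
dimension (call ridges) and removes smooth background illumination
(wind and water glow in the low rows). A Gaussian-blur-subtraction
variant is available behind a config switch.

Binarization keeps pixels strictly above the 0.9 quantile of *all*
pixels of the enhanced image (zeros included); a constant image yields
an empty mask rather than an error. Components are 8-connected by
default so diagonal chirp ridges stay single blobs. Masks with fewer
than 100 pixels are discarded (the size of a short but perceptible
call), as are masks touching the bottom 2 frequency rows, which are
almost always low-pass noise; the top and temporal borders are kept
(insects sing up to Nyquist, calls get clipped at recording edges).

A ROI stores the bounding-box crop of the **original** (pre-enhancement)
spectrogram with non-mask pixels zeroed, plus its half-open frequency
pixel bounds. Time position is dropped from the catalogue — an animal
can vocalise at any time, but only at the frequencies of its repertoire.
(The frame bounds are retained on the in-memory object solely so the
MFCC part of the ROI descriptor can be computed within the same
recording; they are not persisted and never become features.)

## Feature blocks

**S1 — band statistics (80 dims).** The ROI-reconstructed spectrogram
(original values under the mask union, zero elsewhere) is cut into 16
equal horizontal bands (linear spacing, deliberately not mel: insects
and birds occupy the whole axis), and each band contributes mean,
population std, median, kurtosis and the 0.9 quantile of *all* its
pixels. Including the zeros encodes band occupancy, which is the point
of the block; a config flag restricts to non-zero pixels. Kurtosis is
the non-excess fourth standardized moment (normal ≈ 3) with the
convention that a constant band scores 0, keeping sparse recordings
finite. Entropy and skewness are excluded by default (no added value
over the five above) but available behind config.

**S2 — bag of segments (110 dims).** Per-ROI descriptor (22 dims): mask
area, mean/std/median/min/max of the amplitude under the mask, argmax
frequency row (absolute pixels), bandwidth, duration, and 13 MFCCs.
MFCCs multiply the spectrogram image columns of the ROI's frames with a
26-triangle mel filterbank spanning 0–Nyquist, take log, decorrelate
with an orthonormal DCT-II, keep coefficients 0–12, and average over
the frames. Each triangle is normalized to unit sum so a spectrally
flat frame maps to a constant filterbank output (cepstrum carried by
c0 alone). Descriptors are pooled, z-scored per dimension
(zero-variance dimensions get scale 1), and clustered with seeded
k-means (k-means++, 10 restarts) into codebooks of 25, 15 and 70
centers — coarse to fine granularity. A recording's S2 vector
concatenates, per codebook, the raw-count histogram of its ROIs'
nearest centers (Euclidean in whitened space, ties to the lowest
index). Counts are not normalized: how *much* a recording vocalises is
itself informative, and forests are scale-free. By default codebooks
are fit on training ROIs only, so the fitted pipeline is deployable on
new data; a transductive mode pools training and test ROIs, appropriate
when the entire unlabeled test corpus is available at fit time.

**S3 — template correlations (one dim per training ROI).** Every
training ROI, as a 2-D template, scans every recording and contributes
its best normalized cross-correlation. The NCC at one offset is the
Pearson correlation between the template and the equally sized image
window; the template mean is taken over its full bounding box, zeros
included (the mask geometry is part of the template). Zero-variance
windows or templates score 0, never NaN. Row offsets are restricted so
the template stays within its own band enlarged by ±4 pixels — species
share call shapes and differ in frequency position, and the constraint
makes the score immune to out-of-band interference of any magnitude.
All time offsets are allowed; an infeasible scan (template taller or
longer than the allowed region) scores 0. The scan uses the standard
fast NCC (FFT-based `match_template`), which the tests pin against an
independent direct-summation implementation; scores are clipped to
[−1, 1]. A seeded `max_templates` subsample bounds the cost of the
swarm on large corpora, since S3 cost grows as templates × recordings.

## Classifier

Blocks are column-stacked with per-column provenance tags. Feature
selection: an 80-tree multi-output forest is fit once on all labels
jointly, and Breiman-style out-of-bag permutation importance is
computed per feature (per tree: accuracy on its out-of-bag samples
minus accuracy after permuting the feature among them, averaged over
trees; features a tree never splits on contribute exactly 0). Features
with importance ≤ 0 are removed, and the selection is shared by all
labels. The selection forest uses exhaustive split search
(`max_features=None`): with a random feature draw per split, trees are
forced to sometimes split on uninformative columns, whose importances
then straddle zero and survive at random; with exhaustive search,
columns that never win a split are dropped deterministically. The
out-of-bag sample of each tree is reconstructed from the tree's stored
integer seed with the same RNG recipe the forest used for its bootstrap
draw (verified against the library internals in the test suite).

Final model: per label, one binary one-vs-all 250-tree forest (entropy,
`min_samples_split=4`, `min_samples_leaf=3` — grid-search-tuned
defaults; a seeded 10-fold CV grid-search helper is included) per each
of 10 seeds; predictions are the arithmetic mean of the per-seed
positive-class probabilities, which provably cannot be more variable
across training replications than any single seed. Labels with fewer
than 2 positive or 2 negative training examples fall back to
constant-prevalence predictors. At recognition time the noise column is
dropped from the returned species matrix (it is available on request).
Labels whose truth is single-class are skipped (NaN) and excluded from
the macro average.

The void-recording detector is a binary classifier on the same stacked
features, with target = NOT(noise column); it reports per-class
precision/recall/F-score/support. Two variants are provided: gradient
boosting (the default, appropriate for corpora of several hundred
annotated recordings and up) and a 250-tree random forest. The
end-to-end checks use the forest variant: at a hundred training
recordings the boosting ensemble is data-starved — its staged fits on
the many weakly informative correlation columns generalize measurably
worse than bagged trees at that sample size.

## Soundscape simulator

The generator emulates the documented structure of ARU field corpora:
0–3 species per clip (configurable up to 6), clip durations 1.5–3 s,
per-recording source gains in [−9, 0] dB, a white-noise floor pinned to
a per-recording SNR drawn from [10, 30] dB, and with probability 0.5
one structured interferer — low-pass wind (≤ 800 Hz), sparse broadband
rain/device-failure clicks, or a slowly FM'd siren. A `void_fraction`
option pins the exact share of empty (noise-only) recordings.
Recordings are peak-normalized to 0.9 and written as 16-bit PCM at
22.05 kHz by default (configurable to 44.1 kHz); all randomness flows
from one integer seed and the annotation stores every planted call's
time-frequency box.

Call archetypes:

- `tonal_chirp`: a linear frequency sweep across the species band under
  a Hann envelope (up or down).
- `harmonic_stack`: fundamental near the band floor plus in-band
  harmonics at −4.4 dB/partial, with 1% vibrato at 5 Hz.
- `broadband_stridulation`: a comb of resonant carriers (~400 Hz
  spacing) spanning the band, each amplitude-modulated at the
  wing-stroke repetition rate (40–50 Hz, sinusoidal, depth 0.5). This
  is the physically appropriate model of stridulation — a carrier with
  repetition-rate sidebands — and, like real insect bands, it appears
  on the spectrogram as fine spectral lines rather than a smooth block
  (a smooth block is its own morphological opening and would be
  invisible to top-hat enhancement by definition).

The default 8-class roster deliberately contains same-band pairs
(up-chirp vs down-chirp at 2–3.5 kHz; hoot vs trill at 4.2–6 kHz): band
occupancy alone cannot separate those, which exercises the shape-aware
S2/S3 blocks. A `disjoint_roster` variant with fully separated bands is
separable by S1 alone and serves as a sanity configuration.

What the simulator does **not** model: reverberation and propagation
filtering, species-realistic repertoires and syntax, overlapping
conspecific choruses, diurnal/seasonal priors, microphone transfer
functions. Passing tests on this generator therefore demonstrate the
pipeline's mechanics — segmentation, invariances, feature wiring,
selection, multi-label ranking — not field-grade accuracy on real
communities.

## Problem sizes and numerical choices

The end-to-end checks use a 60-train / 40-test corpus with 30% void
recordings and seeded extraction, chosen as the smallest scale at which
all 8 classes are reliably represented and block ablations are
meaningful. Determinism: identical clip and parameters give
bit-identical spectrograms and catalogues; k-means, forests, the
template subsample and the corpus itself are all seed-driven.
Degenerate inputs are defined, not exceptional: constant images
binarize to empty masks, empty bands and constant bands yield zero
statistics, zero-ROI recordings get all-zero S2 rows, infeasible or
zero-variance correlations score 0. Ties break to the lowest index
throughout (component ordering, codebook assignment).

## Known limitations

- Box-IoU against ground truth is only a meaningful recovery measure
  for single syllables that fill their time-frequency box; harmonic
  stacks and stridulation intentionally segment into several blobs
  (per-partial ridges, comb lines).
- With masked templates (the default), a template correlated at its own
  source location scores slightly below 1 because the source window
  retains background where the template has zeros; raw-rectangle
  extraction (`masked=False`) restores the exact self-match.
- The out-of-bag sample reconstruction mirrors scikit-learn's internal
  bootstrap recipe and is pinned by a test; a change in that recipe in
  a future scikit-learn would surface there.
- Percentile binarization is relative per recording: in a recording
  dominated by one loud broadband source, faint calls can fall below
  the global threshold (also a property of the approach on real data).
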