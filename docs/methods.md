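# Methods

## Problem and approach

Scalp EEG is the standard instrument for detecting epileptic activity.
The three conditions of interest — healthy background activity, the
interictal state (between seizures, typically low-amplitude background
punctuated by sharp transients), and the ictal state (during a seizure,
large rhythmic slow oscillations) — differ in waveform morphology, and the
question is how to turn a raw single-channel recording into a small
feature vector a conventional classifier can use, entirely in the time
domain.

The approach is one-class reconstruction. A convolutional autoencoder is
trained to reproduce *only interictal* signals through a compressed latent
representation. Because the decoder only learns to emit waveforms from the
training distribution, signals from the other two conditions reconstruct
poorly, and the divergence between a signal `x` and its reconstruction
`x̂` is itself a discriminative feature. Three indicators quantify that
divergence per recording of length `n`:

* mean squared error, `MSE = (1/n) Σᵢ (xᵢ − x̂ᵢ)²`
* original-to-reconstructed signal ratio,
  `ORSR = 10·log₁₀(Σᵢ xᵢ² / Σᵢ x̂ᵢ²)` in dB (0 dB = equal energy)
* cosine similarity, `CS = Σᵢ xᵢx̂ᵢ / (‖x‖·‖x̂‖)` (1 = identical
  direction; higher means more similar)

The 3-vector `(MSE, ORSR, CS)` is the input to three ensemble classifiers
(random forest, AdaBoost, gradient boosting). A 10-component PCA on the
raw normalized signals is the comparison feature extractor. Permutation
importance and exact Shapley values explain what the fitted classifiers
use.

## Data model and normalization

Recordings follow the Bonn corpus conventions: single channel, one ASCII
sample per line, 4097 samples at 173.61 Hz (23.6 s), 100 recordings per
class directory. Every signal is trimmed to its first 4096 samples —
discarding one sample (~5.8 ms) lets three stride-2 layers halve the
length cleanly — and min-max normalized to [0, 1] *per record*. Features
are computed in this normalized space, the autoencoder's input/output
space, never on raw microvolts. One recording is one classification
sample; no windowing is applied, and no filtering or artifact rejection is
performed.

## Autoencoder

Architecture (lengths for the default L = 4096):

| layer | op | channels | length |
|---|---|---|---|
| E1 | conv k7 s2 + ReLU | 1 → 16 | 4096 → 2048 |
| E2 | conv k7 s2 + ReLU | 16 → 32 | 2048 → 1024 |
| E3 | conv k7 s2 + ReLU | 32 → 64 | 1024 → 512 |
| D1 | convᵀ k7 s2 + ReLU | 64 → 32 | 512 → 1024 |
| D2 | convᵀ k7 s2 + ReLU | 32 → 16 | 1024 → 2048 |
| D3 | convᵀ k7 s2 + sigmoid | 16 → 1 | 2048 → 4096 |

This is the smallest mirror-symmetric three-layer stack that trains on a
single CPU core in minutes; the channel widths are a design choice, not a
canonical prescription. The sigmoid output keeps reconstructions inside
[0, 1], matching the normalized inputs.

Training: Adam (lr 0.001, β = 0.9/0.999), elementwise MSE loss, batch
size 16, 200 epochs, all supplied reference-class records used (no inner
validation split — the protocol's feature quality is judged downstream by
the classifiers). Weights use fan-in-scaled uniform initialization. The
implementation is plain numpy: convolutions run as im2col patch extraction
plus a BLAS matrix multiply in float32, with hand-derived adjoint passes
(verified against finite differences in the test suite). Training is
deterministic given the seed and record order; a checkpoint stores config
and weights and round-trips bit-identically.

## Synthetic data generator

The generator produces the *contrast structure* the method exploits, not
physiological EEG. Per class (defaults; amplitudes in pre-normalization
units, all signals share a pink 1/f background and white noise sd 0.1):

* **healthy** — 8–12 Hz rhythm (frequency drawn per record), amplitude
  0.5 with 15 % slow amplitude modulation, background 0.25;
* **interictal** — background 0.3 plus Poisson-timed (0.8 events/s)
  biphasic spikes of width 60 ms and amplitude 2.0 (±30 % per event);
* **ictal** — 3–5 Hz rhythm, amplitude 3.0 with 20 % slow modulation,
  background 0.3.

Defaults: 100 records per class, 4096 samples, 173.61 Hz. A
reduced-contrast variant (rhythm/spike amplitudes compressed to 0.3/0.9/0.9
and noise sd doubled to 0.2) exists because at the default contrast all
classifiers saturate near ceiling on both feature sets; comparing feature
extractors requires a regime where errors occur. Per-record substreams are
derived from the master seed by a (class, index) counter, so any record is
reproducible in isolation.

What the generator does not emulate: multichannel correlation, real
spike-wave morphology variability, electrode artifacts, non-stationary
background. Passing tests therefore demonstrate that the pipeline's
machinery behaves as designed under the intended statistical contrast; they
do not certify accuracy on clinical recordings, for which the Bonn corpus
run described in the README is the relevant check.

## Classification protocol

Features are split 75 % / 25 % train/test, stratified by class (the
stratification keeps per-class test counts balanced at 25 of each with 300
records). Classifier hyperparameters are library defaults: random forest
with 100 trees, AdaBoost with 100 stumps (learning rate 1.0), gradient
boosting with 100 depth-3 trees (learning rate 0.1). No feature scaling is
applied before the trees — they are scale-invariant. Reports carry the
3×3 confusion matrix (rows true, columns predicted, class order healthy /
interictal / ictal), train/test accuracy, and per-class recall.

The PCA baseline is fit on all records of all three classes pooled — the
conventional unsupervised baseline — whereas the autoencoder sees only
interictal records; this asymmetry is the comparison's design. Classifiers
consume all 10 PC scores; min-max normalization of the first 3 PCs is a
plotting convenience only.

## Interpretability

Permutation importance: mean accuracy drop over 30 shuffling repeats of
each feature column, computed on the test split.

Shapley values are computed **exactly** by enumerating all 2³ feature
coalitions with the interventional value function — the value of
coalition S for sample z is the mean of `predict_proba` over background
rows with S's entries replaced by z's. With three features exactness is
cheap and removes the sampling-approximation knob of kernel-based
estimators. The background is the training split, subsampled to at most
100 seeded rows. Attribution is per class; the single-number-per-feature
summary is the class-averaged mean |φ|, and the feature ranking sorts by
it (ties alphabetically). Efficiency (Σφ = prediction − baseline) holds to
float precision by construction and is asserted in the tests.

## Numerical and design notes

* Tolerances: indicator formulas are checked to 1e-12 against loop
  oracles; Shapley exactness to 1e-10 against the permutation-average
  definition; PCA orthonormality to 1e-8. Float32 network arithmetic means
  reconstruction-level quantities are reproducible bit-for-bit on one
  platform but not across BLAS implementations.
* PCA component signs are fixed (largest-magnitude loading positive) to
  make fits deterministic.
* Degenerate inputs fail loudly: constant signals cannot be normalized,
  all-zero signals have no defined ORSR/CS, single-class feature tables
  cannot train a classifier, mixed-class data cannot train the
  one-class autoencoder.
* The master seed fans out to per-stage seeds by fixed offsets, so stages
  are individually reproducible and two identical runs write byte-identical
  JSON reports.
* Problem sizes in the automated checks — 100 records per class, a
  75-record 200-epoch training for the specificity check, 20 samples for
  the Shapley oracle comparison — are chosen so a full verification run
  completes in a few minutes on one CPU core while keeping every
  statistical margin wide.

## Known limitations

* Single-channel, whole-record classification only; no windowed or
  streaming inference.
* The autoencoder dimensions are a pragmatic choice; no architecture
  search was performed.
* Exact Shapley enumeration is limited to ≤ 10 features by design; larger
  representations would need a sampling estimator.
* Synthetic-data results bound what the implementation can show; clinical
  performance claims require the real Bonn recordings.
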