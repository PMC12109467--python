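# Methods

## Signal model and spectral features

An HVAD spinning at *r* rpm produces a fundamental acoustic line at
FF = *r*/60 Hz (42–47 Hz for the cohort's set speeds of 2540–2800 rpm)
with harmonics at *n*·FF; the four-bladed impeller accents multiples of
4·FF. A recording is modeled as a sum of such tones over a broadband
noise floor. Features are computed as:

- **PSD estimation.** The default feature estimator is the full-record
  periodogram (rectangular window, mean removed, no other detrending),
  giving a bin width of `fs/N` (1/60 Hz for a 60 s record). A Welch
  estimator (1 s Hann segments, 50% overlap, 1 Hz bins) is provided for
  visualization and for peak-contrast tests; it trades resolution for an
  estimator variance lower by roughly the segment count.
- **Harmonic power.** The area under the one-sided PSD in the closed
  1 Hz interval centered on each harmonic, by trapezoidal quadrature over
  the bins in the interval (a single-bin grid falls back to density ×
  width). On the fine periodogram grid the quadrature choice moves values
  by ≲0.01 dB.
- **Normalization.** Powers are converted to dB (linear floor 10⁻¹²
  guards against −∞) and shifted so the twelve linearized powers sum to
  exactly 1 (0 dB total). This removes the unknown amplitude calibration
  of the accelerometer chain; the operation is idempotent and invariant
  to any uniform gain, and both properties are asserted by tests.
- **Fundamental identification.** FF is taken from the recorded pump
  speed (rpm/60) when available. The fallback peak search scans 35–55 Hz,
  refines the peak bin by 3-point parabolic interpolation, and warns when
  the peak is < 3× the band's median PSD; that contrast threshold is
  meaningful on the low-variance Welch estimate (on a raw periodogram the
  maximum of hundreds of exponentially-distributed bins routinely exceeds
  3× the median even for pure noise).

Harmonic centers are exact multiples of FF with no per-harmonic
re-snapping; an optional window widening is available but the default
1 Hz matches the study definition.

## Cross-validation protocol

All models are scored by exhaustive CV over the 11 recordings:
leave-two-out (LTOCV; 55 splits enumerated lexicographically, 110 pooled
predictions — each recording is validated exactly 10 times) or
leave-one-out (LOOCV; 11 splits). Per split, every data-dependent step —
feature scaling, PCA, classifier fitting — is fitted on the 9 (or 10)
training rows only; a dedicated leakage test asserts that validation
coordinates from the fold transform differ from an all-rows transform.
Predictions are pooled into one confusion matrix with thrombosis YES
positive; metrics use the standard definitions, reported to 1 dp (half
away from zero) from exact integer counts, with precision/recall
reported as undefined when their denominator is zero. The ZeroR baseline
predicts each split's training-majority label (ties toward NO); with 8
NO / 3 YES outcomes every training majority is NO, giving 80/110 =
8/11 = 72.7% under both schemes.

The recordings HW-D1/D2 and HW-F1/F2 come from two patients recorded
twice; they are treated as independent rows, exactly as the protocol
enumerates them. This is a known leakage caveat of the original design,
not corrected here because reproducing that design is the point.

## KNN classifier and the frozen configuration

KNN is implemented directly: Euclidean distance, distance ties broken by
training-row order (stable sort), and a vote rule that predicts YES on a
strict majority, with even-k ties resolved either by the nearest
neighbor's label or toward NO. The latter ("tie → NO") amounts to
requiring more than half the neighbors to be thrombotic before calling a
recording thrombotic — a conservative decision threshold natural under
an 8:3 class imbalance.

The source models were fitted with auto-tuned hyperparameters per
training configuration, which are not recoverable; this package instead
freezes, per protocol, a single KNN setting calibrated once against the
printed result tables and records it in the run manifest:

| protocol | features | k | vote tie | scaling |
|---|---|---|---|---|
| LTOCV, plain variables | dB values | 2 | → NO | min-max (train) |
| LTOCV, PCA variables | 2 whitened PCs | 1 | — | none |
| LOOCV, plain variables | dB values | 1 | — | min-max (train) |
| LOOCV, PCA variables | 2 whitened PCs | 1 | — | none |

A sensitivity sweep (analysis script 03) shows why a single k cannot
cover every table: the plain-variable LTOCV confusion (tp=18, fp=2,
fn=12, tn=78) is produced only by the k=2 strict-majority rule, whereas
a zero-false-negative PCA confusion is impossible under that rule — when
the two thrombotic recordings HW-D1 and HW-D2 are held out together only
one thrombotic example remains in training, so no "both neighbors YES"
criterion can fire — forcing k=1 on the PCA route. Accuracy collapses
for k ≥ 3 because training sets contain at most three YES rows.

## PCA step

The fold-embedded dimension reduction centers each variable, scales it
to unit training variance, projects onto the top-2 right singular
vectors of the standardized training matrix, and whitens the component
scores to unit training variance. Whitening matters: without it the PCA
KNN model retains one false negative (97.3%); with it the classifier
sees equal-scale decorrelated coordinates and reaches the
zero-false-negative confusion (98.2%). Zero-variance variables fall back
to scale 1 with a warning. The PCA engine is a plain SVD, cross-checked
against scikit-learn's PCA in the tests.

## Synthetic data

The signal generator emulates the pump signature:
`x(t) = Σₙ √(2pₙ)·sin(2π n·FF·t + φₙ) + ε(t)` with the 12 linear powers
pₙ scaled to a target variance, seeded uniform phases, and white
Gaussian noise at a prescribed level relative to the harmonic power.
Defaults are 6 kHz / 10 s — the 12th harmonic of a 47 Hz fundamental
needs only ~1.2 kHz of bandwidth, and 10 s gives a 0.1 Hz grid — chosen
so each test synthesizes in well under a second; recovery tests that
probe harmonics near −50 dB use the clinical 60 s record length, where
rectangular-window leakage cross-terms (∝ 1/T) drop below the 0.5 dB
tolerance. What the generator does *not* model: the real decaying
(non-white) noise floor, heart sounds and motion artifacts, pump-speed
modulation, or any amplitude calibration — so passing recovery tests
demonstrate correctness of the feature chain, not robustness to clinical
interference.

The cohort generators draw labeled feature rows from per-class Gaussians
(shared covariance) for engine tests, storing the drawn values directly:
a per-row 0 dB renormalization would distort the prescribed class
geometry (when P_FF dominates, normalization nearly cancels its
variation), so unlike extracted profiles these rows are only
approximately unit-sum. `studylike_cohort` reproduces the clinical
geometry qualitatively — a tight 3-row thrombosis cluster, six distant
non-thrombotic rows, and two non-thrombotic "confusers" adjacent to the
cluster — so the engine demonstrably reproduces the study's
characteristic failure mode: the confuser pair held out together yields
the only false positives, while LOOCV stays perfect.

## Numerical and design choices

- Accuracies are computed from integer counts and rounded once, at
  display time.
- Stochastic classifiers (random forest, gradient-boosted trees) run
  with a fixed seed (20250502); an optional repeats mode reports the
  modal confusion matrix over reseeded passes. Non-KNN results use
  scikit-learn defaults and are interpreted qualitatively (algorithm
  ranking, direction of the PCA effect), since the original tool's
  defaults are not documented.
- The grid reproduction gates PCA runs on the plain run exceeding the
  ZeroR baseline, mirroring the study's table construction; gating is
  recorded via an `exceeds_baseline` flag on every run.
- Result tables are emitted as CSV/JSON data files rather than figures,
  each referenced by an append-only manifest carrying the configuration
  snapshot, seeds, software version and a cohort checksum.

## Known limitations

Eleven recordings from nine patients cannot support a predictive model
for new data; everything here characterizes *this* dataset. The
printed feature-table fixture is the ground truth for the ML chain — the
exact estimator and quadrature that produced the printed dB values are
not recoverable from the study, so the spectral chain is validated
against synthetic signals instead. Patient-level grouping, ROC analysis
and hyperparameter search are deliberately out of scope.
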