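# Methods

## Scope and data model

The package analyses scripted wearable-accelerometer studies: each subject
produces one continuous triaxial recording (50 Hz, units of g) containing a
known roster of events with inter-event rests, plus per-event annotations
(label and nominal time). The pipeline stages are simulation → segmentation
→ feature extraction → classification under leave-one-subject-out (LOSO)
cross-validation. All stages are deterministic given a configuration and a
seed.

## The synthetic study generator

The simulator emulates the statistical structure the downstream analysis
relies on, not biomechanics:

- **Baseline.** A resting upright wearer reads 1 g along the device's
  longitudinal axis, taken to be z. Rest periods are this baseline plus
  white Gaussian noise (default SD 0.03 g, a typical MEMS noise floor at
  this bandwidth).
- **Events.** Each event is an impulsive excursion of ≤ 2 s built from one
  of three waveform families: a damped ~7 Hz impact transient (falls), a
  windowed oscillatory burst (walking ~2 Hz, jumping ~4 Hz), or a smooth
  aperiodic bump with a transient gravity-orientation excursion (lying,
  bending, sitting, standing). Default peak magnitudes: postural ADLs
  1.4–1.8 g, jumping 3 g, falls 3.8–5.5 g with hard variants above soft
  ones. The deviation waveform is rescaled by a 1-D root find so the
  maximal Euclidean magnitude within the event equals the template's peak
  amplitude exactly in the noise-free signal; the annotation records the
  time of that peak. Templates whose peak does not exceed the gravity
  baseline are rejected as undetectable.
- **Orientation.** Postural events traverse an orientation excursion
  (upright → target → upright) within the event window, so rests between
  events always sit at the upright baseline. This is a deliberate
  simplification: a real subject who lies down stays lying; here the
  signature of the posture change lives in the event window itself.
- **Subject variability.** One multiplicative amplitude factor per subject,
  drawn uniformly from 1 ± 0.15. This is what makes LOSO evaluation
  non-trivial: the held-out subject's event amplitudes are systematically
  shifted relative to every training subject.
- **Rest gaps.** Uniform on [5, 6] s; the interval's lower bound must stay
  ≥ 2 s so event windows cannot overlap. Recordings are padded 3 s at both
  edges so every event is extractable.
- **Reproducibility.** The per-subject RNG stream is seeded with
  (study seed, subject index), so a single subject can be regenerated
  bit-identically without simulating the others.

What the simulator does **not** model: sensor bias and drift, packet loss,
non-scripted behaviour between events, posture-dependent baselines, or
realistic fall kinematics. Passing end-to-end tests on this generator
demonstrates that the pipeline's plumbing, conventions and estimators are
correct and that the feature set separates signals with the assumed
structure — it says nothing about performance on any recorded human data.

## Segmentation conventions

- The "highest peak" of an event is taken on the Euclidean magnitude of the
  three axes — an axis-invariant choice consistent with the sum-vector
  tradition in this literature. Ties are broken by the earliest sample.
- Windows are inclusive of both endpoints: [peak − fs, peak + fs] gives
  2·fs + 1 = 101 samples at 50 Hz, peak at the centre.
- Events whose peak lies within 1 s of a recording edge raise a boundary
  error and are dropped with a logged warning; padding would corrupt the
  moment and spectral features.
- The per-annotation search half-width defaults to 2.5 s — half the minimum
  rest gap — guaranteeing exactly one event per search window under the
  simulator's invariants.

## Feature extraction conventions

- **Moments** use the population divisor N (not N − 1); kurtosis is the raw
  fourth standardised moment (Gaussian → 3). A zero-variance channel gets
  skewness = kurtosis = 0 by convention.
- **Autocorrelation** is the biased sample autocovariance of the demeaned
  channel, normalised to 1 at lag 0, so constant channels are degenerate
  ((0, 0, 0) is returned). Peaks are selected greedily tallest-first. The
  nominal exclusion distance of 30 % of one sample period is below one lag,
  which would exclude nothing; the radius is therefore
  max(1 lag, round(0.3·T·fs)) and configurable. Lag 0 is always the main
  peak; the informative features are the second peak's position (seconds)
  and amplitude.
- **Welch PSD**: 8 sections with 50 % overlap (section length ⌊N/4.5⌋,
  forced even so the one-sided grid ends exactly at fs/2), Hamming window,
  no detrending, density scaling — the PSD integral approximates total
  signal power including the DC (gravity) component. For N = 101 the
  section length is 22, giving a grid spacing of ≈ 2.27 Hz.
- **Spectral peaks**: greedy tallest-local-maximum selection with exclusion
  radius max(0.3·fs/N, one grid bin) Hz; endpoints count as candidate
  maxima when they exceed their single neighbour. Fewer than 6 peaks are
  zero-padded so the vector length is fixed.
- **Band powers** integrate the density over 0.5–5, 5–10 and 10–20 Hz by
  trapezoid with the density linearly interpolated onto the exact band
  edges. Adjacent bands share an edge point but tile the axis without
  double counting in the integral sense; on a flat unit-density PSD the
  three powers are exactly 4.5, 5 and 10.
- **Ordering**: the 24 per-axis features are interleaved axis-fastest
  (`f1.x f1.y f1.z f2.x …`), 72 values total, with a fixed global name
  order. The 2-value total-acceleration baseline is (min |a|, max |a|).

## Classifiers

- kNN: Euclidean distance on standardised features; neighbour ties at the
  k-th distance broken by lowest training index, vote ties by the nearest
  neighbour's class. k ∈ {1, 3, 5, 7}.
- SVMs: C = 1; RBF kernel width 1/n_features on standardised inputs. No
  hyperparameter search is attempted — an uncalibrated RBF width on this
  feature set tends to collapse onto the majority class, and documenting
  that behaviour is more useful than hiding it behind tuning.
- LDA: scikit-learn's SVD solver, whose tolerance-based pseudoinverse
  tolerates the collinear pairs this feature set produces (σ vs rms on
  near-zero-mean channels); priors are empirical class frequencies.
- Decision tree: CART with Gini impurity, grown to purity (min leaf 1),
  empirical priors via sample weights.
- ECOC: one binary SVM per unordered class pair, each trained only on that
  pair's samples; decoding by pairwise majority vote, ties resolved by the
  largest sum of signed decision margins over the tied classes, then by
  class order. Deterministic by construction.
- Trained models serialise to a joblib container with a format-version
  field.

## Evaluation

- LOSO folds are one per subject, in sorted subject order; standardisation
  is per-fold with training statistics only (constant training features map
  to 0 in both sets).
- Per-class F1 is the harmonic mean of precision and recall, 0 when
  precision + recall = 0; a class absent from both truth and predictions in
  a fold is skipped in that fold's average (logged) — under the full study
  design every subject performs every event, so this cannot occur there.
  Class-averaged F1 and accuracy are averaged over folds; confusion
  matrices are pooled counts, so the pooled total equals the dataset size.
- Tree importance of feature j: Σ over branch nodes splitting on j of
  risk(node) − risk(left) − risk(right), divided by the number of branch
  nodes, with risk = node probability × Gini impurity. Selection keeps
  features with mean importance across folds strictly > 0.0002.
- A reference 13-feature subset (x/z moments, one y-axis autocorrelation
  position, two x-axis spectral-peak amplitudes, a z-axis spectral-peak
  position and two z-axis band powers) ships as a named preset
  (`REFERENCE_13_FEATURES`, CLI `--feature-set reference-13`) so the
  reduced-feature configuration can be evaluated directly, independent of
  what a user's own selection run returns.

## Problem sizes used in tests and the acceptance script

The acceptance script simulates and segments the full 35-subject design
(525 events; ~2 s on one CPU). The test suite exercises most properties on
4–12 subject studies, with one end-to-end 35-subject separability check;
the whole suite runs in a few seconds.

## Known limitations

- The feature count is 72 per event (24 per axis × 3 axes). Conventions in
  parts of this literature count per-axis features and axes multiplicatively
  and arrive at larger nominal totals for the same quantities; the name
  vocabulary here makes the accounting explicit.
- Performance numbers on synthetic studies are not comparable to numbers on
  recorded human data; the simulator's class separations are a design
  choice, and the 7-class task's difficulty profile (postural-activity
  confusions) is reproduced qualitatively, not quantitatively.
- The Welch geometry, exclusion radii and band-edge handling are exposed in
  code but fixed by convention here; alternative conventions change feature
  values, so feature tables produced under different settings must not be
  mixed.
- Peak-centred segmentation assumes annotations within ±(search half-width)
  of the true peak and exactly one event per search window; overlapping
  windows are rejected rather than resolved.
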