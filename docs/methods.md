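# Methods

This note documents the models, algorithms and design choices behind
`gazedecode`, in the order data flows through the package.

## Stimulus geometry and feature extraction

Stimuli are square grayscale images in `[0, 1]` inside a circular aperture
whose diameter equals the image width.  The canonical width is 200 px: it is
the grid on which the three HOG resolutions (10/20/40 px cells) produce
20×20, 10×10 and 5×5 cell grids, and images of other sizes are bilinearly
resampled to it before extraction.  On load, everything outside the aperture
is replaced by the mean in-aperture intensity, so background pixels are
constant and contribute no gradients.

**Fourier features.**  The magnitude of the 2-D DFT is accumulated into
24 spatial-frequency × 16 orientation bands (384 features).  Choices the
transform itself does not fix:

* SF bands are 24 equal-width *linear* bands over `(0, W/2]` cycles/image —
  the minimal assumption; custom (e.g. logarithmic) edges can be supplied
  in `FourierBinning`.
* Frequencies above the cardinal-axis Nyquist (`W/2` cpi) are excluded, as
  is the DC term; each conjugate pair is counted once (half-plane `fy > 0`,
  plus `fy = 0, fx > 0`).
* Orientation is the direction of the frequency vector modulo 180°, in
  16 bands of 11.25°.  Bands with no spectrum samples (possible at the very
  lowest SF band under fine orientation binning) are defined as 0.

Magnitude spectra discard phase, so the features are invariant to circular
translation of image content — asserted in the tests.

**HOG features.**  One histogram per non-overlapping cell, no block
normalization: per-cell histograms are the only variant consistent with the
canonical feature counts (2484/540/81 kept features).  Details: centered
difference gradients (`numpy.gradient`; one-sided at borders), unsigned
orientation over `[0°, 180°)` in 9 bins with bin centers at k·20°,
magnitude-weighted votes split bilinearly between the two nearest centers
(circular), per-cell L2 normalization with ε = 1e-12 under the square root.
A cell is kept iff its entire square extent lies inside the closed aperture
disc; this full-containment rule uniquely reproduces 276/60/9 kept cells at
the three resolutions (verified by per-quadrant enumeration in the tests).

**Trial differences.**  `d = right − left`, label 1 = right chosen.  The
opposite convention only flips weight signs; one is fixed and documented.

## Synthetic experiment generator

The generator exists so every downstream stage can be tested against known
ground truth; it emulates the *statistical structure* the analyses need,
not photorealism.

* **Faces.**  Parametric grayscale composites: skin oval, eyes, brows
  (oriented ridges), a curved mouth with an optional bright "teeth" band,
  and nasolabial folds.  Four expression classes (happy, angry, sad,
  neutral) differ in class-mean part parameters (brow angle, eye aperture,
  mouth curvature, mouth-open contrast, fold strength).  Identity-level
  variation has three components drawn once per identity and shared across
  its four expressions: face-geometry jitter, part-parameter jitter, and a
  smooth idiosyncratic texture field (Gaussian-filtered white noise,
  σ = 3 px, amplitude 0.10 in intensity units).  The texture term matters:
  without it the stimulus set has only ~11 latent dimensions, every feature
  subset spans the same manifold, and feature-recovery questions are
  ill-posed; real faces carry exactly this kind of high-dimensional
  identity-specific detail.  All identity components scale with one
  `identity_jitter` factor (0 ⇒ within-class images pixel-identical).
* **Trials.**  Every ordered expression pair is a condition (16), each
  repeated equally (default 56 ⇒ 896 main trials), so every unordered pair
  is automatically side-counterbalanced.  Identities always differ within
  a trial.  Catch trials (nonzero stimulus-onset offset, default 14 repeats
  per condition ⇒ 224, drawn from 34–134 ms) are generated for design
  completeness but not otherwise analysed.
* **Choices.**  P(right) = (1 − λ)·Φ((w·d − b)/σ) + λ/2 over the
  informative-feature subvector of d; a probit link (any monotone link
  would do).  `lateral_bias` is specified as the probability offset toward
  the left side at zero signal and converted internally to the latent
  offset b.  σ = 0 is the deterministic limit.  `calibrate_noise_sd` sets σ
  so the ideal observer (predict sign(w·d)) scores a target accuracy on the
  realized trials, making "effect size" a single interpretable number.
* **Planted readouts.**  `make_planted_model` draws k distinct informative
  features.  Defaults chosen for identifiability: indices are restricted to
  the upper half of the feature-variance distribution (a readout of
  near-constant features cannot be recovered by any method), optionally to
  one feature per group (e.g. per HOG cell) and to an eligibility mask;
  weights are equal-magnitude random-sign, or variance-balanced
  (w ∝ 1/sd, equal variance contribution per feature) in the recovery
  study.  `orthogonalize_to_classes` projects weights orthogonal to the
  class-mean structure restricted to the informative coordinates, making
  E[w·d | class pair] = 0 for every pair — choices then carry no
  emotion-content signal at all.

## Selection engine

* **Folds.**  Eight stratified folds; within each class, consecutive
  temporal blocks of eight trials scatter one trial into each fold
  (permuted per block), so folds sample the whole session and per-fold
  class counts differ by ≤ 1.
* **Balanced splits.**  Each wrapper step re-draws a class-balanced ~50%
  train set: per-class count = min(pool/4, minority size); the remainder
  validates.  Validation may be unbalanced, hence the F1 validation metric
  (positive class = label 1; macro-F1 for multi-class).
* **Ranking.**  Two-group (or multi-group) Kruskal–Wallis H per feature,
  midranks with tie correction, all-tied features score 0; ties in the
  ranking break toward the lower feature index.  The implementation is
  vectorized and is checked against `scipy.stats.kruskal` as an
  independent oracle.
* **Budget.**  M = smallest count of top-ranked features whose scores sum
  to ≥ 10% of the total — strong separability ⇒ small budgets.  If every
  score is zero (fully uninformative data) the pipeline falls back to
  M = ⌈0.10 · n_features⌉, the equal-scores value, so degenerate input
  still yields chance-level output rather than an error.
* **Wrapper.**  Stepwise additive: each iteration draws a fresh balanced
  split, evaluates the top-S unselected features by current priority (one
  linear SVM per candidate, trained on selected ∪ {candidate}) and includes
  the best validation F1.  Priorities start at the chi-squared scores
  scaled to [0, 1] and are replaced by observed F1 once tested, keeping the
  search inside the informative region of the ranking while the F1 updates
  reorder candidates within it by multivariate value.  (The alternative —
  raw-score priorities, which scan successive blocks of the ranking
  breadth-first — was implemented and rejected: forcing one inclusion per
  block fills the selection with features that add no validation value.)
  At the first time 25% of M has been included, each included feature is
  removed in turn and dropped if the selection scores at least as well
  without it (sequential, never below one feature).  S defaults to
  max(10, ⌈0.05·n⌉); the studies fix S = 20 to bound runtime on the
  2484-feature space.  Degenerate fits are skipped and logged.
* **Candidates and the final model.**  filter = top-M ranked; wrapper as
  above; random = M uniform draws; pseudo-random = M draws from outside
  filter ∪ wrapper (padded, with a log message, in the unlikely case fewer
  than M remain).  Each candidate trains a standardized linear SVM (C = 1;
  hyperparameters deliberately fixed, no inner tuning) on the full training
  pool and is scored by hold-out accuracy; ties resolve in the fixed order
  filter > wrapper > random > pseudo-random.  A model on all features is
  the reference.  Multi-class problems use a one-vs-one linear SVM with
  tie votes broken by aggregate decision values.

## Controls

* **Empirical chance.**  Each feature column is permuted independently
  across trials (marginals preserved, class linkage and within-trial
  coupling destroyed; a row-relabelling mode exists for the alternative
  reading) and the *identical* pipeline re-runs on the shuffled data.  The
  per-fold chance value is the maximum of the four candidate accuracies —
  identically the final-model accuracy, because the final selection is the
  argmax — so real and chance numbers share degrees of freedom exactly.
  A fixed-selection mode that reuses a reference run's candidate sets
  exists for smoke tests and is explicitly non-canonical.
* **Bias baseline.**  Per fold and unordered different-expression pair,
  the training bias is the proportion of trials choosing the
  canonically-earlier expression; test trials of that pair are predicted as
  "the side showing the majority expression", with an exact-0.5 tie going
  to the earlier expression (documented; measure-zero in practice).  Pairs
  absent from a training fold are skipped and logged.
* **Emotion decoding.**  Single-image features, 4 classes (chance 0.25),
  stratified eightfold over the 156 images (fold count for images is a
  package default, aligned with the behavioural analysis).  Transferred
  mode uses the top-n features by behavioural relevance with n matched per
  fold to the free-selection reference and the identical folding.
* **Relevance weights.**  weight_f = Σ over folds whose final selection
  contains f of max(0, hold-out accuracy − chance mean), normalized to
  100%.  This accuracy-above-chance attribution is the minimal reading of
  "contribution to performance"; selection frequency or SVM coefficient
  magnitude are reasonable alternatives and can be computed from the same
  fold results.  When several runs are aggregated, both orders (pool raw
  contributions, or normalize per run first) are available.  Projections
  (HOG cell heatmap; SF and orientation marginals) conserve the total.

## Study conditions and problem sizes

The pre-registered studies in `gazedecode.studies` fix: 39 identities
(156 images); 896 main trials (16 × 56) for the noise-calibration and
recovery studies; 20 replicate sessions/participants where distributions
are compared; wrapper subsample S = 20.  The recovery study runs two
independent replicate sessions, each planting k = 10 variance-balanced
features, one per HOG cell, restricted to features whose trial-difference
variance is at least 80% texture-driven (measured against a zero-texture
twin render of the same identities), with the ideal observer calibrated to
0.70; accuracies average over sessions and the precision test pools both
sessions' selected-feature draws into one binomial test against the
random-inclusion rate.  A single session's chi-squared ranks flutter enough
(each planted feature's score competes with correlated same-cell proxies
around the budget cutoff) that exact-index recovery is noisy; the
replicates provide the power.  The bias-dissociation study uses 288
different-expression trials per participant (12 × 24) and an ideal observer
of 0.75 with emotion-orthogonal readouts.  The acceptance script runs 12
noise sessions rather than 20.

## What the synthetic tests do and do not show

Passing studies demonstrate that the pipeline is internally correct: the
chance estimator matches the selection optimism it is built to match,
planted sparse signals are found and localized, and feature-driven
behaviour dissociates from content biases.  They do not show that human
gaze is feature-driven — the generator's faces are smooth composites whose
class structure, texture statistics and choice model are idealizations
(probit readout, no sequential dependencies, no oculomotor noise, no
reaction-time structure), and real photographic faces have far richer
feature correlations.  Conclusions about real observers require real data
through the same interfaces.

## Known limitations

* The wrapper's search order depends on the priority scale; very deep
  informative features (chi-squared rank beyond S × M) are never tested.
* Exact-index recovery is only meaningful when features are not perfectly
  collinear; with strongly correlated features the pipeline finds
  *predictive* proxies, which is correct behaviour but lowers measured
  precision against a specific planted truth.
* Budgets, and hence model sizes, derive from a 10% mass rule on
  chi-squared scores; heavy-tailed score distributions can make M very
  small on strongly separable data.
* `LinearSVC` (liblinear) and the one-vs-one `SVC` are deterministic given
  data, but standardization uses training statistics only — features
  constant in training are frozen to zero, not dropped.
* Transferred-feature expression decoding can fall *below* the nominal 0.25
  chance: every identity appears in all four classes, folds stratify by
  class rather than identity, and class-irrelevant (identity-texture)
  features then anti-predict the held-out class — a test image's identity
  was seen in training under the other three labels.  This identity
  confound is itself evidence that the transferred features carry identity
  rather than expression content.
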