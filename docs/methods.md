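# Methods

`depvox` implements a single learned dissimilarity between speech
spectrograms and reuses it for two clinical downstream tasks. This note
records the model, the choices that were genuinely open, the synthetic
cohort the package is exercised on, and what the shipped experiments do
and do not demonstrate.

## Front end

A recording is DC-centered, cut into fixed-length segments, and each
segment becomes a log-Mel spectrogram: Hann-windowed frames of 30 ms with
a 10 ms hop (30 ms windows overlapped by 20 ms), zero-padded to `n_fft`,
one-sided power spectrum pooled by a Slaney-style area-normalized
triangular filterbank with 64 bands spanning 0 to Nyquist, then
`log(energy + 1e-10)`. The frame count is exactly
`floor((N - W)/H) + 1`.

Two normalizations follow, in a fixed order recorded in the provenance
metadata of every persisted feature file:

1. **CMVN per segment** — each mel band is standardized over the segment's
   time axis (mean 0, variance 1, `+1e-8` in the divisor). This removes
   channel coloration; it also removes any *static* spectral cue, so
   whatever the network learns must live in temporal structure.
   A config switch (`cmvn_scope: recording`) pools the statistics over the
   whole recording instead; per-segment is the default reading.
2. **Global z-score** — per-band standardization with statistics fitted on
   the training fold only. Applied after CMVN it is nearly an identity,
   but it keeps the subject-independence contract explicit and auditable.

Segment length is not a front-end constant of the published pipeline and
is exposed as configuration: the full-scale profile uses 2.5 s segments
with a 1.25 s hop; the desk-scale profile uses 1.25 s non-overlapping
segments (64x123 spectrograms), chosen to keep a full leave-one-subject-out
run on one CPU within minutes.

## Siamese distance

Each twin is a four-layer valid-mode stride-1 CNN; layers 1–3 are followed
by ReLU and 2x2/stride-2 max pooling, layer 4 by neither; one fully
connected layer produces the embedding `e`. The twins share one parameter
store — sharing is structural, not synchronized. The endpoint scores a
pair as

    d(L_i, L_j) = sigmoid( w · |e_i − e_j| + b )  ∈ (0, 1),

trained with binary cross-entropy against similar = 0 / dissimilar = 1.
Because `|e_i − e_j|` is exactly symmetric in IEEE arithmetic, so is `d`,
bitwise; `d(A, A) = sigmoid(b)` is a constant, the model's *identity
constant*, which also fills the diagonal of distance matrices.

Target coding resolves an ambiguity the description leaves open: the
downstream classifier picks the class with *minimum* aggregated score, so
the sigmoid output must mean dissimilarity.

Open choices, fixed as follows:

- **Kernels/channels.** The published description fixes depth, stride and
  pooling but not filter counts or sizes. Full profile:
  10/7/5/3 kernels with 32/64/64/128 channels and a 256-wide embedding
  (shrinking-kernel convention); desk profile: 5/3/3/3 with 2/4/4/8 and a
  32-wide embedding. Nothing in the tests depends on these values.
- **Initialization.** The narrow-normal init N(0, 0.01²) for all weights
  and biases is the full-profile default. In the reduced desk network that
  σ leaves the forward signal many orders of magnitude below the input
  scale (four layers of tiny weights compound), so the desk profile uses
  fan-in-scaled init (He) with zero biases — a property of the reduced
  architecture, recorded in the config.
- **Optimizer.** Plain SGD (the traditional back-propagation form);
  momentum is configurable and the desk profile uses 0.9 with lr 0.01,
  batch 12, ≤350 iterations. Full profile: lr 6e-5, batch 50, ≤3000
  iterations, momentum 0.
- **Early stopping.** Validation BCE every `eval_every` iterations;
  stop after `patience` evaluations without a `min_delta` improvement;
  the best-validation parameters are restored.
- **Restarts.** Small-batch training from a random init occasionally never
  leaves the BCE ≈ ln 2 plateau. When the best validation BCE stays above
  `restart_threshold`, training restarts from a re-seeded init (up to
  `max_restarts` times, best attempt kept) — the usual multi-start rule.
  Two consecutive attempts stuck at the chance plateau abort further
  restarts, since they indicate an uninformative pair task rather than bad
  luck. Defaults: no restarts (full profile); 2 (desk profile).

## Pair construction

Similar pairs join two distinct segments of one recording; dissimilar
pairs join segments of different recordings, by default of *opposite
classes* (same-class/different-recording supervision is ambiguous for a
class-discriminative distance and is opt-in via `cross_class_only:
false`). Pair sets are balanced within one pair and sampled with
replacement across the pair population, seeded.

## Support-set classification

For each class, every training segment's summed distance to all other
same-class segments is computed (self excluded), sorted ascending, and
the `v` most central segments become exemplars; ties break to the lower
index. A test segment's per-class aggregate is the **mean** distance to
that class's exemplars — mean rather than sum because the published
operating point uses unequal sizes (12 healthy vs 1 depressed exemplar),
and sums over different counts are incomparable. Predicted class =
argmin; exact ties resolve to Depressed (a screening tool should not
resolve ambiguity toward health). Recording-level decisions average the
per-segment aggregates before the argmin, consistent with one mental
state per recording.

Support sizes are tuned per fold on a validation split (10% of training
subjects, at least one per class when possible): over a grid of
`(v_h, v_d)` the healthy and depressed recognition rates are computed,
`v_h` maximizes the healthy rate marginalized over `v_d` and vice versa,
ties to the smaller size.

## Severity regression

Pairwise distances over the training segments (computed once per
unordered pair, mirrored; diagonal = identity constant) feed a k-medoids
model fitted with PAM: greedy BUILD initialization, then best-improvement
SWAP passes until no single medoid/non-medoid exchange lowers the cost.
An item's distance to its own medoid counts as 0 (the model's self-score
is a nonzero constant, which would otherwise pollute every cost).
Single-swap local optima are rare but real even at n = 8, so `fit_pam`
is multi-start: BUILD plus seeded random initializations
(`n_starts = 5`), lowest cost wins. The cluster count defaults to
`max(k, ceil(sqrt(n_items)))` so at least `k` medoids always exist.

A new segment's HAMD is the arithmetic mean of the scores of its `k`
nearest medoids (ascending distance, ascending index on ties); the
printed summation with `1/k` in front is read as exactly this mean. `k`
is tuned on the validation fold by minimizing RMSE + MAE, ties to the
smaller `k`; the published operating point is k = 24, the desk profile
tunes k in 1..8 because its medoid inventory is far smaller. Recording-
level HAMD is the mean of its segments' predictions.

## Interpretation layer

Relevance localization has no published formula; the package's rule
(flagged as its own in all output): average a convolutional layer's
post-ReLU maps over channels as absolute values, upsample
nearest-neighbor to the input grid, threshold at the smallest level whose
super-level set carries the requested fraction of total activation
(default 0.5), and report that set's bounding box in seconds (frame hop x
index, plus one window) and Hz (mel band center frequencies). The rule is
monotone: more mass never shrinks the box. "Sonification" is time-cropping
of the underlying audio; the frequency bounds travel as metadata rather
than as a band-pass (optional by config), so the clinician hears the
segment as recorded. Neighbor queries rank support-set members first —
they are the most characteristic recordings per class — then the
remaining training segments, each stratum ordered by the same scores the
classifier uses.

## Synthetic cohort

The clinical corpus (218 speakers, one read-speech recording each, HAMD
0–52, roughly class-balanced) is not redistributable, so the package
generates a stand-in with the same *shape*: one recording per synthetic
subject, Healthy ⇒ HAMD ∈ [0, 7], Depressed ⇒ HAMD ∈ [8, 52] uniform.
A voice is a jittered harmonic source shaped by three formant resonators,
a spectral tilt, a 4 Hz syllabic amplitude modulation, Poisson pauses and
a noise floor; gender enters only as an f0-register preset (120/210 Hz,
female fraction 0.66). Severity `s` (HAMD/52 for depressed; ≤0.04 for
healthy — subclinical scores barely move a voice) drives the parameters
monotonically with a saturating response `g = effect · (1 − e^{−3s})`:
pitch variability, pause rate and syllabic rate fall; pause duration,
formant bandwidths and low-frequency tilt rise. `effect = 0` makes the
classes exchangeable, the null condition.

What the generator does *not* emulate: phonetic content, prosodic
phrasing, speaker idiosyncrasy beyond the f0 register, recording-channel
variation, and any dissociation between diagnosis and voice. Passing the
shipped experiments therefore shows the pipeline recovers a planted,
monotone voice–severity relationship at realistic SNR — not clinical
validity on real speech.

## Shipped experiments and problem sizes

The desk-scale study (`acceptance_profile`) uses 24 subjects, 12 s
recordings at 16 kHz, 512-point FFT, 1.25 s segments (9 per subject), 600
training and 96 validation pairs per fold, and the reduced network above;
the whole leave-one-subject-out experiment re-fits scaler, pairs, network,
support set and medoids inside every fold, so nothing from a fold's test
subject reaches any fitted component. Subject-level metrics: accuracy,
sensitivity, specificity (Depressed positive), RMSE and MAE in HAMD units
against a predict-the-training-mean null, Spearman rank correlation, and
a held-out pair AUC built from the test subject's within-recording pairs
versus its cross-class pairs. `n_repeats` re-runs the downstream chain
with fresh derived seeds on the same cohort and reports means with a
standard-deviation block; the shipped experiments use a single repeat to
stay within desk runtimes. The deterministic `tiny_profile` (6 subjects,
30 iterations) exists to assert byte-identical reports for identical
config and seed.

## Numerical conventions

Energy floor 1e-10 inside logs; 1e-8 in standard-deviation divisors; all
network arithmetic in float32; BCE clipped at 1e-7; stable sorts with
lowest-index tie-breaks everywhere a ranking feeds a decision. Degenerate
inputs (constant bands, all-zero audio, single-frame spectrograms,
empty classes) either normalize to zeros or raise a validation error — 
never NaN.

## Known limitations

- The synthetic task is far easier than clinical speech; absolute metric
  values on it say nothing about the published corpus numbers.
- CMVN-per-segment erases static spectral cues; a real-data deployment
  may prefer per-recording CMVN (config switch) to retain some.
- The reduced network's hyperparameters were chosen for one-CPU runtimes;
  the full profile is untested at scale here by construction.
- PAM multi-start lowers, but cannot eliminate, the probability of a
  suboptimal medoid set on adversarial instances.
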