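# Methods

This note documents the models, parameter choices and numerical decisions
behind `microdyn`, in the order the pipeline runs.

## Synthetic cohort model

The generator exists so that every downstream stage can be validated
against known ground truth. It emulates eyes-closed resting EEG under the
same structural assumptions the analysis makes — at any instant the scalp
field is one dominant topography whose amplitude fluctuates — without any
forward head modeling.

**State dynamics.** A semi-Markov chain over K = 4 states: dwell lengths
are drawn from a gamma distribution (shape 2 by default, minimum 1 sample,
rounded to integer samples), after which the chain jumps according to the
self-transition-free renormalized row of a configurable transition matrix
(uniform off-diagonal by default). A gamma dwell with mean 13 samples at
128 Hz (~100 ms, shape 2) produces the 60–120 ms dwell spread typical of
empirical microstate statistics; a fixed-dwell mode (`dwell_shape=None`)
exists for deterministic test constructions.

**Topographies.** K unit-norm random Gaussian maps over 54 channels,
redrawn until every pairwise |cosine| ≤ 0.6 so the states are
distinguishable but not orthogonal by construction. Channel names are the
first 54 labels of the standard Biosemi-64 montage so synthetic and real
data share a layout.

**Signal.** At sample t with active state k, the channel vector is
`amplitude · a(t) · μ_k` plus white sensor noise. The activation
`a(t)` sums five band-limited oscillations (white noise spectrally masked
to the canonical delta/theta/alpha/beta/gamma ranges, unit SD each)
weighted by per-state gains, plus 1/f background (spectral exponent 1.0,
flat below 1 Hz), plus an offset of 2 standard deviations of that mix.
The offset keeps the polarity of the rendered topography consistent about
97–98 % of the time; without it, signed back-fitting (see below) could not
recover planted labels even in principle. With all gains and the 1/f
amplitude zero the source is exactly silent. Defaults
(`amplitude=50 µV`, `noise_sd=5 µV`, alpha-dominant gains
[1.0, 0.8, 1.5, 0.6, 0.3]) give per-channel signals of realistic
amplitude with an SNR at which segmentation is good but not trivial.

**Planted group effects (the study conditions).** Group B differs from
group A by: delta-band gain raised from 1.0 to 1.6 in state 1 and to 2.0
in state 3, and dwell means shortened from 13 to 10 samples in every
state. These mirror the directions reported for autism-spectrum cohorts
(elevated state-specific delta power; faster state turnover, i.e. shorter
inter-transition intervals). Effects are applied exactly as configured
and recorded per subject in the returned ground truth.

**What the generator does not emulate.** Volume conduction and electrode
geometry (maps are random vectors, not dipolar fields), ocular/muscle
artifacts beyond additive noise, non-stationarity across the recording,
and inter-subject topographic variability (all subjects share one
template set). Passing recovery tests therefore demonstrates the
correctness of the pipeline's computations and its sensitivity to effects
of the planted size — not robustness to real-world artifact structure.

## Preprocessing

Order: band-pass → notch → common-average reference → resample → epoch →
reject. Filters are Hamming-window FIR designs applied forward-backward
(zero phase); the band-pass is 1–45 Hz with ~1 Hz transition width, the
notch a 2 Hz-wide band-stop at 50 Hz. Resampling is polyphase
(`scipy.signal.resample_poly`) to 128 Hz. Epochs are 2 s with 50 %
overlap, half-open sample windows with 0-based starts, giving
`(T − W)//(W/2) + 1` epochs (149 for 150 s at 128 Hz). Rejection flags an
epoch when any |sample| exceeds 100 µV or when the z-score of its
per-channel variance (standardized across epochs, maximum over channels)
exceeds 3; rejection updates a mask and never deletes data, and removing
every epoch is an explicit error. Channel standardization picks the modal
channel-name set across subjects (ties: lexicographically smallest
signature), zero-fills missing channels and drops extras; the
common-average reference is computed per subject on native channels
before standardization, so zero-filled placeholders never bias the
reference.

## Microstate segmentation

GFP uses the population convention (divide by N). Peaks are strict local
maxima (plateaus yield their leftmost sample), pruned to a minimum
separation of 2 samples (~16 ms at 128 Hz) keeping the higher peak.
Peak topographies are unit-normalized and pooled across all subjects and
epochs — template learning is group-blind — then clustered with standard
K-means (k-means++, 10 restarts, fixed seed). Centroids are renormalized
and ordered by descending cluster size, so learned state indices carry no
anatomical meaning; recovery tests match learned to planted states by
Hungarian assignment on |spatial correlation|.

Back-fitting uses the *signed* dot product between each unit-normalized
sample vector and the templates, with ties going to the lowest state
index and zero-norm samples carrying the previous label forward. Signed
similarity is deliberate: it matches a plain K-means segmentation rather
than the polarity-folded "modified K-means" family. Both clustering and
assignment can be switched to absolute similarity with
`ignore_polarity=True`. No label smoothing is applied.

## Feature definitions and conventions

All entropies are in nats (natural log) except the LZ76 normalization,
which is `c · log₂(n) / n` as the measure is conventionally defined.
Durations are reported in ms and occurrence rates in s⁻¹ (the sampling
rate is carried through). Temporal features are computed per 2-s epoch
(T = 256, which also bounds the O(T²) recurrence analysis) and averaged
across accepted epochs; sequence-level features (complexity,
higher-order) are computed once on the per-epoch label rows flattened
into a single continuous sequence.

- **Recurrence analysis**: `R[t,t'] = 1` iff the states match. The
  recurrence rate averages the full matrix including the main diagonal;
  determinism counts diagonal lines of length ≥ 2 off the main diagonal
  only and divides by the off-diagonal recurrence mass (with the main
  diagonal included, determinism would be ≈ 1 always).
- **Transition matrix**: consecutive ordered pairs including self-pairs;
  rows of unvisited states stay all-zero rather than being renormalized.
- **Dwell entropy**: Shannon entropy of a state's run-duration
  distribution, each run weighted by its share of that state's total time.
- **Sample entropy** (m = 2, r = 0.2·SD, Chebyshev distance, self-matches
  excluded, both template lengths counted over the same N−m windows):
  on integer-valued (symbolic) sequences with r below the smallest level
  gap, matching reduces *exactly* to m-gram equality, so the
  implementation counts matches by hashing windows in O(N) instead of
  comparing all pairs; the generic chunked pairwise path covers
  continuous inputs. Both paths are verified against a naive
  template-matching oracle.
- **Permutation entropy** (m = 3, delay 1): ordinal patterns via stable
  argsort, so ties resolve as earlier-index-smaller.
- **DFA**: profile = cumulative sum of the demeaned series;
  non-overlapping windows at ≥ 8 log-spaced sizes from 4 to N/4; linear
  detrend per window; the exponent is the least-squares slope of
  log F(n) vs log n. White noise gives α ≈ 0.5 (the acceptance
  benchmark), integrated noise ≈ 1.5.
- **LZ76**: exhaustive-history parse; each phrase is the shortest prefix
  of the remainder not reproducible from the past (self-overlapping
  copies allowed); a reproducible final tail counts as one phrase.
- **Hurst**: classical rescaled-range over log-spaced windows from 8 to
  N/2; slope of log E[R/S] vs log n. Known small-sample positive bias
  (~0.55–0.6 on white noise at these lengths) is accepted as part of the
  standard estimator.
- **Multiscale complexity**: the five metrics are evaluated at
  coarse-graining scales 1, 2 and 4 (keep every s-th label), yielding the
  15 complexity columns.
- **Higher-order block** (10 columns): row-conditional transition entropy
  summed over rows (an i.i.d. uniform 4-state sequence approaches
  4·ln 4); mean inter-transition interval in samples (NaN below two
  transitions); 3-gram entropy after remapping observed labels to
  contiguous integers (invariant to relabeling); phase-locking value of
  the demeaned label series' analytic signal (constant sequence → 1 by
  convention); fractional-occupancy first differences across state index
  (`dfo_state_1..3`); and density, mean degree and clustering of the
  transition graph (directed density over K(K−1); degree and clustering
  on the simple undirected projection). A mock cross-frequency-coupling
  scalar (seeded uniform per state) exists behind a flag but is excluded
  from the canonical 80, as a random placeholder cannot be a biomarker.
  A Higuchi fractal dimension implementation is likewise available as an
  optional extra outside the canonical schema.

**State-conditioned spectra.** Samples carrying each state's label are
pooled across all accepted epochs (discontiguous runs concatenated
without tapering, a deliberate simplification), and Welch PSD (128-sample
Hann segments, 50 % overlap — 1 Hz resolution at 128 Hz) is averaged over
each band's bins (half-open [lo, hi) so shared edges are counted once),
then over channels. A 1-s minimum pooled duration guards estimate
reliability; it is applied to the subject-level pool because individual
microstate runs (~60–120 ms) never reach 1 s, and with ~25 % coverage a
state essentially never accumulates 1 s within a single 2-s epoch either
— a per-epoch threshold would silently discard all spectral data on any
realistic input. States below the threshold yield NaN, never a silent 0.

## Screening

Two-sided Mann–Whitney U with mid-ranks; `U = min(U₁, U₂)`; exact
enumeration when `n₁·n₂ ≤ 400` and the data are tie-free, otherwise the
normal approximation with tie correction. Cohen's d uses the pooled
sample-variance formula; Cliff's delta is the exhaustive dominance
difference. The sign convention is case minus control throughout. Raw
p-values are reported by default (a Benjamini–Hochberg column is
optional) and the conventional magnitude cutoffs (0.2/0.5/0.8 for d,
0.147/0.33/0.474 for δ) are attached as annotations only. The screen
operates on whatever rows the table carries; with subject-level rows at
n = 28 + 28 the smallest attainable two-sided p is ~1e-16 of order
`2/ C(56,28)`, so extreme p-values always indicate epoch-level (not
subject-level) observations.

## Classification harness

Stratified 10-fold cross-validation; hyperparameter search (default
budget 50 randomized candidates, 3-fold inner CV) and feature scaling
are fit on training folds only. Tree models skip scaling (they are
scale-invariant and unscaled features keep attributions interpretable);
linear/kernel/network models are wrapped with a standard scaler inside
the pipeline. The evaluation unit is explicit: `unit="subject"` uses
grouped stratified folds so all rows of a subject share a fold (the
leakage-safe default when rows are epochs), `unit="epoch"` is a plain
stratified split; every result records its unit. The positive class is
the case group (group "B" under the default cohort labels "A"/"B").
Sensitivity is the positive-class recall; metrics are percentages
reported as mean ± SD over folds. ROC curve points are pooled over folds
for plotting, but the reported area is the mean of per-fold AUCs:
pooling scores from separately calibrated fold models can fabricate
ranking inversions that no individual model makes.

Attribution uses the boosters' built-in exact tree-path Shapley values
(`pred_contribs`); per-instance contributions plus the base value
reproduce the model margin to float32 accumulation accuracy (~1e-4 over
80 features). Non-tree models raise an explicit error, with a
permutation-importance fallback available behind a flag and labelled as
such in the result. The cumulative ablation runs the booster on the
growing column sets temporal → +spectral → +complexity → +higher-order
(35, 55, 70, 80 columns); the top-k retrain (default k = 20) re-evaluates
on the Shapley-ranked subset with a small grid search, preserving the
original column order so the identity subset reproduces the full run
bit-for-bit.

## Test and benchmark problem sizes

The suite validates each metric against naive loop oracles on sequences
up to ~500 samples, and runs the full pipeline on synthetic cohorts: a
3 + 3 × 30 s cohort for fast end-to-end checks and 28 + 28 × 60 s cohorts
for group-effect recovery, null calibration and ablation shape. One
minute per subject is ample for every planted effect while keeping the
whole suite around two minutes; the generator's scientific defaults
(150 s recordings) are unchanged. Determinism is end-to-end: a fixed
`GeneratorConfig` reproduces cohorts bit-for-bit (seed-sequence spawning
per subject), and fixed seeds make segmentation, search and folds
reproducible.

## Known limitations

- Learned state indices are cluster-size ranks; cross-cohort comparisons
  of per-state features require template matching first.
- Signed back-fitting is polarity-sensitive by design; on real EEG
  (where oscillatory polarity flips constantly) the conventional choice
  is polarity folding, available via `ignore_polarity=True`.
- The spectral pooling concatenates discontiguous runs, which smears
  spectral estimates at run boundaries; with ~1 Hz resolution and ≥ 1 s
  pools the bias is small but not zero.
- R/S Hurst and small-window DFA carry the standard small-sample biases;
  values are comparable within the pipeline, not bias-corrected
  estimates.
- Subject-level feature rows (the default) give honest but
  low-statistical-power classification at n = 56; epoch-level analysis
  raises apparent power at the cost of within-subject dependence, which
  is why the harness defaults to grouped folds and always reports the
  unit used.
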