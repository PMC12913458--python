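# microdyn

EEG microstate dynamics as candidate case-control biomarkers.

Resting-state EEG spends most of its time in a handful of quasi-stable
scalp topographies ("microstates", ~60–120 ms each). The sequence of these
states is a compact symbolic summary of large-scale network dynamics, and
its statistics — how long states last, how they switch, how complex the
sequence is, what oscillatory content each state carries — differ between
clinical groups. `microdyn` implements the full analysis path from raw
multichannel recordings to an interpretable classification report, for
researchers studying case-control EEG cohorts (the motivating application
is autism-spectrum vs neurotypical adults, 28 + 28 subjects at 128 Hz).

## What it computes

1. **Preprocessing** — zero-phase FIR band-pass (1–45 Hz), 50 Hz notch,
   common-average reference, polyphase resampling to 128 Hz, 2-s epochs
   with 50 % overlap, amplitude/variance epoch rejection, and cross-subject
   channel standardization (modal layout, zero-fill missing channels).
2. **Microstate segmentation** — global field power
   `GFP(t) = sqrt((1/N) Σ_i (V_i(t) − V̄(t))²)`; topographies at GFP peaks
   are unit-normalized and clustered with K-means (K = 4, k-means++, 10
   restarts) into templates `μ_k`; every sample is back-fitted to the
   template with the highest dot product against the normalized channel
   vector.
3. **An 80-column multidomain feature vector per subject**
   - *temporal* (35): per-state mean duration `D_k`, coverage `C_k`,
     occurrence rate `O_k`, dwell entropy `H_k`, the 4×4 transition matrix
     `P_{i→j}`, switching rate, recurrence rate and determinism of the
     symbolic recurrence plot;
   - *spectral* (20): Welch band power (δ, θ, α, β, γ) of each state's
     pooled samples;
   - *complexity* (15): sample entropy, permutation entropy, DFA exponent,
     LZ76 complexity and Hurst exponent at coarse-graining scales 1, 2, 4;
   - *higher-order* (10): transition entropy, mean inter-transition
     interval, 3-gram entropy, a Hilbert phase-locking value,
     fractional-occupancy derivatives, and transition-graph
     density/degree/clustering.
4. **Screening** — Mann–Whitney U (two-sided, mid-ranks, exact enumeration
   for small samples), Cohen's d and Cliff's delta per feature.
5. **Classification harness** — logistic regression, random forest, RBF
   SVM, a shallow neural network, XGBoost, LightGBM and a stacked ensemble
   under stratified 10-fold cross-validation with nested randomized
   hyperparameter search; cumulative-domain ablation; exact tree-path
   Shapley (TreeSHAP) feature ranking with top-20 retraining and ROC.
6. **Synthetic cohorts** — a semi-Markov generator (gamma dwell times,
   state-dependent band-limited oscillations on unit-norm topographies,
   1/f background, sensor noise) with configurable planted group effects,
   so the entire pipeline is testable without any data download. Cohorts
   round-trip through EEGLAB `.set`/`.fdt` or a plain binary+JSON fixture
   format.

## Worked example

```python
from microdyn import GeneratorConfig, generate_cohort, extract_features, schema
from microdyn.screening import feature_screen
from microdyn.harness import cross_validated_eval

cfg = GeneratorConfig(n_per_group=10, duration=60.0, seed=42)
recordings, groups, truth = generate_cohort(cfg)       # group B: higher state
table = extract_features(recordings, groups, seed=42)  # delta gain, shorter dwells
feats = table[schema.FEATURE_NAMES]

screen = feature_screen(feats, table["group"].to_numpy(), case_group="B")
print(screen.nsmallest(6, "p_value")[["p_value", "cohens_d", "cliffs_delta"]])

res = cross_validated_eval(feats, table["group"], classifiers=("xgb",),
                           folds=5, search_iters=10, seed=42)[0]
print(f"XGBoost accuracy {res.mean('accuracy'):.1f}% "
      f"(±{res.sd('accuracy'):.1f}), "
      f"sensitivity {res.mean('sensitivity'):.1f}%, "
      f"specificity {res.mean('specificity'):.1f}%, AUC {res.roc_auc:.3f}")
```

Output:

```
                       p_value  cohens_d  cliffs_delta
feature
state_3_mean_duration 1.08e-05     -3.88            -1
state_2_dwell_entropy 1.08e-05      3.01             1
state_3_dwell_entropy 1.08e-05      5.33             1
switching_rate        1.08e-05      6.05             1
delta_power_state0    1.08e-05      4.57             1
delta_power_state1    1.08e-05       4.3             1

XGBoost accuracy 75.0% (±15.8), sensitivity 90.0%, specificity 60.0%, AUC 0.900
```

The screen recovers exactly what was planted: group B dwells in each state
for less time (negative effect sizes on durations, positive on switching
rate and dwell entropy) and carries more delta-band power (positive effect
sizes, with `1.08e-05` the smallest two-sided p-value attainable at
n = 10 + 10 under complete separation, |Cliff's δ| = 1). The
cross-validated booster then separates the groups well above chance on
20 subjects; accuracy rises further at the default 28 + 28.

A thin CLI wraps the same flow (`microdyn simulate / preprocess / segment /
extract / screen / classify / ablate / explain`); see `microdyn --help`.

## Documentation

`docs/methods.md` describes the generative model, every feature
definition, the numerical choices and known limitations.
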