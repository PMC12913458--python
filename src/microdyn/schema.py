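"""Canonical feature schema.

The subject-level feature vector has exactly 80 named columns split over
four domains:

* temporal (35): per-state mean duration / coverage / occurrence / dwell
  entropy (4 x 4), the 4 x 4 transition-probability matrix, switching rate,
  recurrence rate and determinism;
* spectral (20): mean Welch band power (delta..gamma) conditioned on each
  of the 4 states;
* complexity (15): sample entropy, permutation entropy, DFA exponent,
  Lempel-Ziv complexity and Hurst exponent of the label sequence at
  coarse-graining scales 1, 2 and 4;
* higher-order (10): transition entropy, mean inter-transition interval,
  3-gram entropy, phase-locking value, the three fractional-occupancy
  first differences, and transition-graph density / average degree /
  clustering.
"""

from __future__ import annotations

N_STATES = 4
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}
BAND_NAMES = list(BANDS)
COMPLEXITY_METRICS = ["sampen", "permen", "dfa", "lzc", "hurst"]
COMPLEXITY_SCALES = [1, 2, 4]


def temporal_feature_names(K: int = N_STATES) -> list[str]:
    names: list[str] = []
    for stat in ("mean_duration", "coverage", "occurrence", "dwell_entropy"):
        names += [f"state_{k}_{stat}" for k in range(K)]
    names += [f"trans_prob_{i}_to_{j}" for i in range(K) for j in range(K)]
    names += ["switching_rate", "recurrence_rate", "determinism"]
    return names


def spectral_feature_names(K: int = N_STATES) -> list[str]:
    return [f"{band}_power_state{k}" for band in BAND_NAMES for k in range(K)]


def complexity_feature_names() -> list[str]:
    return [
        f"{metric}_s{scale}"
        for metric in COMPLEXITY_METRICS
        for scale in COMPLEXITY_SCALES
    ]


def higher_order_feature_names(K: int = N_STATES) -> list[str]:
    return (
        ["transition_entropy", "mean_inter_transition_interval", "ngram_entropy",
         "plv_sync"]
        + [f"dfo_state_{k}" for k in range(1, K)]
        + ["graph_density", "graph_avg_degree", "graph_clustering"]
    )


DOMAINS: dict[str, list[str]] = {
    "temporal": temporal_feature_names(),
    "spectral": spectral_feature_names(),
    "complexity": complexity_feature_names(),
    "higher_order": higher_order_feature_names(),
}

FEATURE_NAMES: list[str] = [n for cols in DOMAINS.values() for n in cols]
assert len(FEATURE_NAMES) == 80 and len(set(FEATURE_NAMES)) == 80

# default cumulative ablation order: temporal -> +spectral -> +complexity
# -> +higher_order (column counts 35, 55, 70, 80)
DOMAIN_ORDER = ["temporal", "spectral", "complexity", "higher_order"]


def cumulative_columns(order: list[str] | None = None) -> list[list[str]]:
    """Column subsets for the cumulative-domain ablation."""
    order = DOMAIN_ORDER if order is None else order
    stages: list[list[str]] = []
    acc: list[str] = []
    for dom in order:
        acc = acc + DOMAINS[dom]
        stages.append(list(acc))
    return stages
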