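"""Temporal microstate features (35 per epoch, averaged over epochs).

Per state k: mean dwell duration D_k (ms), coverage C_k (fraction of
samples), occurrence rate O_k (runs per second), and dwell entropy H_k
(Shannon entropy, natural log, of the distribution of that state's run
durations normalized by total time in the state).  Plus the 4 x 4
first-order transition-probability matrix (self-pairs included), switching
rate, and the two recurrence-plot statistics RR and DET on the symbolic
sequence.
"""

from __future__ import annotations

import numpy as np

from . import schema
from ._types import ConfigError, LabelSequence

__all__ = [
    "run_lengths",
    "per_state_stats",
    "transition_probabilities",
    "switching_rate",
    "rqa_measures",
    "temporal_vector",
]


def run_lengths(seq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode: (state per run, length per run)."""
    seq = np.asarray(seq)
    if seq.size == 0:
        return np.empty(0, dtype=seq.dtype), np.empty(0, dtype=int)
    change = np.flatnonzero(np.diff(seq) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [seq.size]))
    return seq[starts], ends - starts


def per_state_stats(seq: np.ndarray, K: int, fs: float) -> dict[str, float]:
    """D_k (ms), C_k, O_k (s^-1), H_k (nats) for every state k.

    States never visited get zeros throughout.
    """
    seq = np.asarray(seq)
    if seq.size == 0:
        raise ConfigError("empty label sequence")
    T = seq.size
    states, lengths = run_lengths(seq)
    out: dict[str, float] = {}
    for k in range(K):
        durs = lengths[states == k]
        if durs.size == 0:
            mean_ms = cov = occ = ent = 0.0
        else:
            mean_ms = durs.mean() / fs * 1000.0
            cov = durs.sum() / T
            occ = durs.size / T * fs  # runs per second
            p = durs / durs.sum()
            ent = float(-(p * np.log(p)).sum())
        out[f"state_{k}_mean_duration"] = float(mean_ms)
        out[f"state_{k}_coverage"] = float(cov)
        out[f"state_{k}_occurrence"] = float(occ)
        out[f"state_{k}_dwell_entropy"] = ent
    return out


def transition_probabilities(seq: np.ndarray, K: int) -> np.ndarray:
    """Row-normalized count matrix of consecutive ordered pairs.

    Self-pairs are counted; rows of states with no outgoing pair stay
    all-zero rather than being renormalized.
    """
    seq = np.asarray(seq)
    if seq.size < 2:
        raise ConfigError("need at least 2 samples for transitions")
    counts = np.zeros((K, K))
    np.add.at(counts, (seq[:-1], seq[1:]), 1.0)
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        P = np.where(sums > 0, counts / np.where(sums > 0, sums, 1.0), 0.0)
    return P


def switching_rate(seq: np.ndarray) -> float:
    """Fraction of consecutive sample pairs with a state change."""
    seq = np.asarray(seq)
    if seq.size < 2:
        raise ConfigError("need at least 2 samples for the switching rate")
    return float(np.mean(seq[:-1] != seq[1:]))


def rqa_measures(seq: np.ndarray, l_min: int = 2) -> tuple[float, float]:
    """Recurrence rate and determinism of the symbolic recurrence plot.

    R[t, t'] = 1 iff s_t = s_t'.  RR averages the full matrix including the
    main diagonal; DET is the fraction of off-diagonal recurrence points on
    diagonal lines of length >= ``l_min`` (main diagonal excluded, else DET
    would be trivially ~1).
    """
    seq = np.asarray(seq)
    T = seq.size
    if T < l_min:
        raise ConfigError(f"sequence shorter than l_min={l_min}")
    counts = np.bincount(seq)
    total_rec = float((counts.astype(float) ** 2).sum())  # includes diagonal
    rr = total_rec / T ** 2
    offdiag = total_rec - T
    if offdiag <= 0:
        return rr, 0.0
    det_points = 0.0
    for d in range(1, T):
        eq = seq[:-d] == seq[d:]
        if not eq.any():
            continue
        padded = np.concatenate(([False], eq, [False])).astype(np.int8)
        edges = np.diff(padded)
        lens = np.flatnonzero(edges == -1) - np.flatnonzero(edges == 1)
        det_points += 2.0 * lens[lens >= l_min].sum()  # both triangles
    return rr, det_points / offdiag


def temporal_vector(seqs: LabelSequence, K: int = schema.N_STATES,
                    fs: float | None = None, l_min: int = 2) -> dict[str, float]:
    """All 35 temporal features, computed per epoch and averaged."""
    if seqs.n_epochs == 0:
        raise ConfigError("no accepted epochs")
    fs = seqs.fs if fs is None else fs
    names = schema.temporal_feature_names(K)
    acc = {name: 0.0 for name in names}
    for epoch_seq in seqs.labels:
        vals = dict(per_state_stats(epoch_seq, K, fs))
        P = transition_probabilities(epoch_seq, K)
        for i in range(K):
            for j in range(K):
                vals[f"trans_prob_{i}_to_{j}"] = float(P[i, j])
        vals["switching_rate"] = switching_rate(epoch_seq)
        rr, det = rqa_measures(epoch_seq, l_min=l_min)
        vals["recurrence_rate"] = rr
        vals["determinism"] = det
        for name in names:
            acc[name] += vals[name]
    n = seqs.n_epochs
    return {name: acc[name] / n for name in names}
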