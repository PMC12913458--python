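"""Complexity and higher-order metrics of the microstate label sequence.

The complexity block applies five nonlinear metrics — sample entropy,
permutation entropy, DFA exponent, Lempel-Ziv (LZ76) complexity and the
rescaled-range Hurst exponent — to the flattened label sequence at
coarse-graining scales 1, 2 and 4 (scale s keeps every s-th label),
yielding 15 features.  The higher-order block summarizes transition
structure: transition entropy, mean inter-transition interval, 3-gram
entropy, a Hilbert phase-locking value, fractional-occupancy first
differences, and density / degree / clustering of the transition graph
(10 features).  All entropies use natural log except LZ76's log2
normalization.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import hilbert

from . import schema
from ._types import ConfigError, LabelSequence

__all__ = [
    "sample_entropy", "permutation_entropy", "dfa_exponent", "lz_complexity",
    "lz76_phrase_count", "hurst_exponent", "higuchi_fd", "complexity_vector",
    "transition_entropy", "mean_iti", "ngram_entropy", "plv_sync",
    "fo_derivatives", "graph_features", "higher_order_vector", "cfc_mock",
]

logger = logging.getLogger(__name__)


def _as_1d(x) -> np.ndarray:
    if isinstance(x, LabelSequence):
        return x.flat.astype(float)
    return np.asarray(x, dtype=float).ravel()


# ---------------------------------------------------------------------------
# complexity metrics
# ---------------------------------------------------------------------------

def _pair_matches_discrete(codes: np.ndarray, length: int,
                           n_templates: int) -> float:
    """Unordered matching-template pairs of ``length`` via m-gram hashing.

    Both the length-m and length-(m+1) counts use the same first N-m
    template start positions (the standard SampEn convention).
    """
    if n_templates < 2:
        return 0.0
    base = int(codes.max()) + 1
    words = sliding_window_view(codes, length)[:n_templates].astype(np.int64)
    enc = words @ (base ** np.arange(length, dtype=np.int64))
    _, counts = np.unique(enc, return_counts=True)
    return float((counts * (counts - 1)).sum() / 2.0)


def _pair_matches_chebyshev(x: np.ndarray, length: int, r: float,
                            n_templates: int) -> float:
    """Unordered matching-template pairs under Chebyshev distance <= r."""
    if n_templates < 2:
        return 0.0
    W = sliding_window_view(x, length)[:n_templates]
    total = 0.0
    chunk = 256
    for i0 in range(0, n_templates, chunk):
        block = W[i0:i0 + chunk]  # (b, m)
        d = np.abs(block[:, None, :] - W[None, :, :]).max(axis=2) <= r
        # count pairs (i, j) with j > i only
        for bi in range(block.shape[0]):
            total += d[bi, i0 + bi + 1:].sum()
    return total


def sample_entropy(x, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r) with Chebyshev distance and self-matches excluded.

    ``r`` defaults to 0.2 x SD of the series.  Integer-valued (symbolic)
    input with r below the smallest nonzero level gap is counted exactly by
    m-gram hashing, which is equivalent to the Chebyshev rule there;
    otherwise a chunked brute-force pair count is used.  Undefined ratios
    (no matches at either length) give NaN, not an infinity sentinel.
    """
    x = _as_1d(x)
    N = x.size
    if N <= m + 1:
        raise ConfigError(f"need more than m+1={m + 1} samples")
    if r is None:
        r = 0.2 * float(x.std())
    uniq = np.unique(x)
    is_discrete = np.all(x == np.round(x))
    min_gap = np.diff(uniq).min() if uniq.size > 1 else np.inf
    n_templates = N - m
    if is_discrete and r < min_gap:
        codes = np.searchsorted(uniq, x)
        B = _pair_matches_discrete(codes, m, n_templates)
        A = _pair_matches_discrete(codes, m + 1, n_templates)
    else:
        B = _pair_matches_chebyshev(x, m, r, n_templates)
        A = _pair_matches_chebyshev(x, m + 1, r, n_templates)
    if B == 0 or A == 0:
        logger.warning("sample entropy undefined (A=%s, B=%s); returning NaN",
                       A, B)
        return float("nan")
    return float(-np.log(A / B))


def permutation_entropy(x, m: int = 3, delay: int = 1) -> float:
    """Shannon entropy (nats) of ordinal patterns of order ``m``.

    Ties are broken by treating the earlier index as smaller (stable sort).
    """
    x = _as_1d(x)
    N = x.size
    span = (m - 1) * delay
    if N < m or N - span < 1:
        raise ConfigError(f"sequence too short for order {m}, delay {delay}")
    idx = np.arange(N - span)[:, None] + np.arange(0, span + 1, delay)[None, :]
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    enc = patterns @ (m ** np.arange(m, dtype=np.int64))
    _, counts = np.unique(enc, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _log_spaced_sizes(lo: int, hi: int, num: int = 16) -> np.ndarray:
    sizes = np.unique(np.round(np.exp(
        np.linspace(np.log(lo), np.log(hi), num))).astype(int))
    return sizes[(sizes >= lo) & (sizes <= hi)]


def dfa_exponent(x, n_min: int = 4, n_sizes: int = 16) -> float:
    """Detrended fluctuation analysis scaling exponent (linear detrending).

    The profile (cumulative sum of the demeaned series) is split into
    non-overlapping windows at log-spaced sizes from ``n_min`` to N/4; the
    RMS residual around a per-window linear fit gives F(n), and the slope
    of log F(n) vs log n is the exponent (0.5 for uncorrelated noise).
    """
    x = _as_1d(x)
    N = x.size
    if N < 64:
        raise ConfigError("DFA needs at least 64 samples")
    y = np.cumsum(x - x.mean())
    sizes = _log_spaced_sizes(n_min, N // 4, n_sizes)
    if sizes.size < 8:
        raise ConfigError("fewer than 8 distinct window sizes")
    F = np.empty(sizes.size)
    for si, n in enumerate(sizes):
        nseg = N // n
        segs = y[:nseg * n].reshape(nseg, n).T  # (n, nseg)
        t = np.arange(n, dtype=float)
        A = np.column_stack([t, np.ones(n)])
        coef, *_ = np.linalg.lstsq(A, segs, rcond=None)
        resid = segs - A @ coef
        F[si] = np.sqrt(np.mean(resid ** 2))
    good = F > 0
    if good.sum() < 2:
        logger.warning("fluctuation function vanishes (constant input); NaN")
        return float("nan")
    return float(np.polyfit(np.log(sizes[good]), np.log(F[good]), 1)[0])


def lz76_phrase_count(symbols) -> int:
    """Number of phrases in the exhaustive-history LZ76 parse.

    Each phrase is the shortest prefix of the remaining sequence that is not
    reproducible from the already-seen past (copies may self-overlap); a
    final reproducible tail still counts as one phrase.
    """
    arr = np.asarray(symbols).ravel()
    if arr.size == 0:
        raise ConfigError("empty sequence")
    uniq = {v: i for i, v in enumerate(dict.fromkeys(arr.tolist()))}
    s = "".join(chr(33 + uniq[v]) for v in arr.tolist())
    n = len(s)
    c = 0
    l = 0
    while l < n:
        k = 1
        while l + k <= n and s.find(s[l:l + k], 0, l + k - 1) != -1:
            k += 1
        c += 1
        l += k
    return c


def lz_complexity(symbols) -> float:
    """LZ76 phrase count normalized by n / log2(n)."""
    arr = np.asarray(symbols).ravel()
    c = lz76_phrase_count(arr)
    n = arr.size
    if n < 2:
        return float(c)
    return float(c * np.log2(n) / n)


def hurst_exponent(x, n_min: int = 8, n_sizes: int = 16) -> float:
    """Rescaled-range (R/S) Hurst exponent.

    Log-spaced window sizes from ``n_min`` to N/2; within each window the
    range of cumulative deviations is divided by the window SD, averaged
    over windows, and H is the slope of log E[R/S] vs log n.
    """
    x = _as_1d(x)
    N = x.size
    if N < 4 * n_min:
        raise ConfigError(f"R/S needs at least {4 * n_min} samples")
    if np.ptp(x) == 0:
        logger.warning("constant input: R/S undefined, returning NaN")
        return float("nan")
    sizes = _log_spaced_sizes(n_min, N // 2, n_sizes)
    log_n, log_rs = [], []
    for n in sizes:
        nseg = N // n
        segs = x[:nseg * n].reshape(nseg, n)
        z = segs - segs.mean(axis=1, keepdims=True)
        Y = np.cumsum(z, axis=1)
        R = Y.max(axis=1) - Y.min(axis=1)
        S = segs.std(axis=1)
        ok = S > 0
        if not ok.any():
            continue
        log_n.append(np.log(n))
        log_rs.append(np.log((R[ok] / S[ok]).mean()))
    if len(log_n) < 2:
        logger.warning("too few usable window sizes for R/S; returning NaN")
        return float("nan")
    return float(np.polyfit(log_n, log_rs, 1)[0])


def higuchi_fd(x, k_max: int = 8) -> float:
    """Higuchi fractal dimension (optional extra, outside the canonical 80)."""
    x = _as_1d(x)
    N = x.size
    if N < 2 * k_max:
        raise ConfigError("sequence too short for Higuchi's method")
    log_k, log_L = [], []
    for k in range(1, k_max + 1):
        Lk = []
        for m0 in range(k):
            idx = np.arange(m0, N, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            Lk.append(dist * (N - 1) / ((idx.size - 1) * k) / k)
        if Lk:
            log_k.append(np.log(1.0 / k))
            log_L.append(np.log(np.mean(Lk)))
    return float(np.polyfit(log_k, log_L, 1)[0])


def complexity_vector(seq: LabelSequence,
                      scales=tuple(schema.COMPLEXITY_SCALES)) -> dict[str, float]:
    """The 15 complexity features: 5 metrics x coarse-graining scales."""
    flat = seq.flat
    out: dict[str, float] = {}
    for scale in scales:
        sub = flat[::scale]
        out[f"sampen_s{scale}"] = sample_entropy(sub)
        out[f"permen_s{scale}"] = permutation_entropy(sub)
        out[f"dfa_s{scale}"] = dfa_exponent(sub)
        out[f"lzc_s{scale}"] = lz_complexity(sub)
        out[f"hurst_s{scale}"] = hurst_exponent(sub)
    order = [f"{metric}_s{scale}" for metric in schema.COMPLEXITY_METRICS
             for scale in scales]
    return {name: out[name] for name in order}


# ---------------------------------------------------------------------------
# higher-order sequence features
# ---------------------------------------------------------------------------

def transition_entropy(seq, K: int = schema.N_STATES) -> float:
    """Sum over rows of the entropy of the conditional transition law (nats)."""
    from .temporal import transition_probabilities

    flat = seq.flat if isinstance(seq, LabelSequence) else np.asarray(seq).ravel()
    P = transition_probabilities(flat, K)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    return float(-terms.sum())


def mean_iti(seq) -> float:
    """Mean interval between successive state-change times (samples)."""
    flat = seq.flat if isinstance(seq, LabelSequence) else np.asarray(seq).ravel()
    times = np.flatnonzero(np.diff(flat) != 0) + 1
    if times.size < 2:
        logger.warning("fewer than 2 transitions: mean ITI undefined (NaN)")
        return float("nan")
    return float(np.diff(times).mean())


def ngram_entropy(seq, n: int = 3) -> float:
    """Shannon entropy (nats) of length-n label subsequences.

    Observed labels are first remapped to contiguous integers (sorted
    ascending -> 0, 1, ...), so the result is invariant under any bijective
    relabeling of states.
    """
    flat = seq.flat if isinstance(seq, LabelSequence) else np.asarray(seq).ravel()
    if flat.size < n:
        raise ConfigError(f"sequence shorter than n={n}")
    uniq = np.unique(flat)
    codes = np.searchsorted(uniq, flat).astype(np.int64)
    base = max(int(uniq.size), 1)
    words = sliding_window_view(codes, n)
    enc = words @ (base ** np.arange(n, dtype=np.int64))
    _, counts = np.unique(enc, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def plv_sync(seq) -> float:
    """Phase-locking value of the demeaned label series' analytic signal.

    A constant sequence has zero analytic signal; its phase is taken as 0
    everywhere, giving PLV = 1 by convention.
    """
    flat = (seq.flat if isinstance(seq, LabelSequence)
            else np.asarray(seq).ravel()).astype(float)
    x = flat - flat.mean()
    if np.allclose(x, 0.0):
        logger.info("constant sequence: PLV = 1 by convention")
        return 1.0
    phase = np.angle(hilbert(x))
    return float(np.abs(np.exp(1j * phase).mean()))


def fo_derivatives(seq, K: int = schema.N_STATES) -> dict[str, float]:
    """First differences of fractional occupancy across state index."""
    flat = seq.flat if isinstance(seq, LabelSequence) else np.asarray(seq).ravel()
    fo = np.array([np.mean(flat == k) for k in range(K)])
    return {f"dfo_state_{k}": float(fo[k] - fo[k - 1]) for k in range(1, K)}


def graph_features(seq, K: int = schema.N_STATES) -> tuple[float, float, float]:
    """(density, average degree, clustering) of the transition graph.

    Directed edges i -> j (i != j) exist when at least one transition was
    observed; density uses K(K-1).  Average degree and clustering are taken
    on the simple undirected projection.
    """
    flat = seq.flat if isinstance(seq, LabelSequence) else np.asarray(seq).ravel()
    if flat.size < 2:
        raise ConfigError("need at least 2 samples to build the graph")
    G = nx.DiGraph()
    G.add_nodes_from(range(K))
    pairs = np.stack([flat[:-1], flat[1:]], axis=1)
    pairs = pairs[pairs[:, 0] != pairs[:, 1]]
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    for (i, j), w in zip(uniq, counts):
        G.add_edge(int(i), int(j), weight=int(w))
    density = G.number_of_edges() / (K * (K - 1)) if K > 1 else 0.0
    U = nx.Graph(G)
    avg_degree = sum(dict(U.degree()).values()) / K
    clustering = nx.average_clustering(U) if U.number_of_edges() else 0.0
    return float(density), float(avg_degree), float(clustering)


def cfc_mock(K: int = schema.N_STATES, seed: int = 42) -> dict[str, float]:
    """Seeded uniform mock cross-frequency-coupling scalars (off by default)."""
    rng = np.random.default_rng(seed)
    return {f"cfc_state_{k}": float(rng.uniform()) for k in range(K)}


def higher_order_vector(seq: LabelSequence, K: int = schema.N_STATES,
                        include_cfc: bool = False,
                        cfc_seed: int = 42) -> dict[str, float]:
    """The 10 canonical higher-order features (CFC mock behind a flag)."""
    out: dict[str, float] = {
        "transition_entropy": transition_entropy(seq, K),
        "mean_inter_transition_interval": mean_iti(seq),
        "ngram_entropy": ngram_entropy(seq, n=3),
        "plv_sync": plv_sync(seq),
    }
    out.update(fo_derivatives(seq, K))
    density, avg_degree, clustering = graph_features(seq, K)
    out["graph_density"] = density
    out["graph_avg_degree"] = avg_degree
    out["graph_clustering"] = clustering
    if include_cfc:
        out.update(cfc_mock(K, seed=cfc_seed))
    return out
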