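"""Independent brute-force reference implementations.

Everything here is written as plain loops straight from the defining
formulas, deliberately ignoring the vectorized/fast paths the library
uses, so the two routes can be compared on small inputs.
"""

from __future__ import annotations

import math

import numpy as np


def gfp_direct(epoch: np.ndarray) -> np.ndarray:
    """Spatial population SD per sample, element by element."""
    C, S = epoch.shape
    out = np.empty(S)
    for t in range(S):
        vbar = sum(epoch[i, t] for i in range(C)) / C
        out[t] = math.sqrt(sum((epoch[i, t] - vbar) ** 2 for i in range(C)) / C)
    return out


def transition_counts_direct(seq, K: int) -> np.ndarray:
    N = np.zeros((K, K))
    for a, b in zip(seq[:-1], seq[1:]):
        N[a, b] += 1
    return N


def transition_probs_direct(seq, K: int) -> np.ndarray:
    N = transition_counts_direct(seq, K)
    P = np.zeros_like(N)
    for i in range(K):
        s = N[i].sum()
        if s > 0:
            P[i] = N[i] / s
    return P


def rqa_direct(seq, l_min: int = 2) -> tuple[float, float]:
    """RR and DET from the explicit T x T recurrence matrix."""
    seq = list(seq)
    T = len(seq)
    R = np.zeros((T, T), dtype=int)
    for t in range(T):
        for u in range(T):
            R[t, u] = int(seq[t] == seq[u])
    rr = R.sum() / T ** 2
    # exhaustive diagonal-line scan, main diagonal excluded
    line_points = 0
    for d in range(-(T - 1), T):
        if d == 0:
            continue
        diag = [R[t, t + d] for t in range(max(0, -d), min(T, T - d))]
        run = 0
        for v in diag + [0]:
            if v:
                run += 1
            else:
                if run >= l_min:
                    line_points += run
                run = 0
    offdiag = R.sum() - T
    det = line_points / offdiag if offdiag > 0 else 0.0
    return rr, det


def sampen_direct(x, m: int = 2, r: float | None = None) -> float:
    """Template-matching SampEn with explicit pair loops."""
    x = np.asarray(x, dtype=float)
    N = x.size
    if r is None:
        r = 0.2 * x.std()
    nt = N - m

    def count(length: int) -> int:
        c = 0
        for i in range(nt):
            for j in range(i + 1, nt):
                if max(abs(x[i + k] - x[j + k]) for k in range(length)) <= r:
                    c += 1
        return c

    B = count(m)
    A = count(m + 1)
    if A == 0 or B == 0:
        return float("nan")
    return -math.log(A / B)


def permen_direct(x, m: int = 3, delay: int = 1) -> float:
    """Ordinal-pattern entropy by explicit enumeration (stable ties)."""
    x = np.asarray(x, dtype=float)
    patterns: dict[tuple, int] = {}
    n_win = x.size - (m - 1) * delay
    for i in range(n_win):
        window = [(x[i + k * delay], k) for k in range(m)]
        order = tuple(k for _, k in sorted(window))  # value, then index
        patterns[order] = patterns.get(order, 0) + 1
    total = sum(patterns.values())
    return -sum(c / total * math.log(c / total) for c in patterns.values())


def dfa_direct(x, sizes) -> float:
    """DFA with per-segment polyfit loops over the given window sizes."""
    x = np.asarray(x, dtype=float)
    y = np.cumsum(x - x.mean())
    log_n, log_f = [], []
    for n in sizes:
        nseg = len(y) // n
        sq = []
        for s in range(nseg):
            seg = y[s * n:(s + 1) * n]
            t = np.arange(n)
            a, b = np.polyfit(t, seg, 1)
            sq.extend((seg - (a * t + b)) ** 2)
        f = math.sqrt(np.mean(sq))
        if f > 0:
            log_n.append(math.log(n))
            log_f.append(math.log(f))
    return float(np.polyfit(log_n, log_f, 1)[0])


def lz76_direct(symbols) -> int:
    """Step-by-step exhaustive-history LZ76 parse.

    At each step the next phrase is grown one symbol at a time; a phrase is
    closed the first time it cannot be copied from any earlier starting
    position (overlap with the phrase itself allowed).
    """
    s = list(symbols)
    n = len(s)
    phrases = 0
    start = 0
    while start < n:
        length = 1
        while start + length <= n:
            sub = s[start:start + length]
            found = False
            for src in range(start):  # any earlier start, overlap allowed
                if s[src:src + length] == sub and src + length <= n:
                    # need the copy to stay inside the sequence
                    if all(s[src + k] == sub[k] for k in range(length)):
                        found = True
                        break
            if not found:
                break
            length += 1
        phrases += 1
        start += length
    return phrases


def hurst_rs_direct(x, sizes) -> float:
    """Naive rescaled-range estimate over the given window sizes."""
    x = np.asarray(x, dtype=float)
    log_n, log_rs = [], []
    for n in sizes:
        nseg = len(x) // n
        ratios = []
        for s in range(nseg):
            seg = x[s * n:(s + 1) * n]
            z = seg - seg.mean()
            Y = np.cumsum(z)
            R = Y.max() - Y.min()
            S = seg.std()
            if S > 0:
                ratios.append(R / S)
        if ratios:
            log_n.append(math.log(n))
            log_rs.append(math.log(np.mean(ratios)))
    return float(np.polyfit(log_n, log_rs, 1)[0])


def ngram_entropy_direct(seq, n: int = 3) -> float:
    """3-gram entropy with dictionary counting and contiguous remapping."""
    seq = list(seq)
    levels = sorted(set(seq))
    remap = {v: i for i, v in enumerate(levels)}
    seq = [remap[v] for v in seq]
    counts: dict[tuple, int] = {}
    for i in range(len(seq) - n + 1):
        g = tuple(seq[i:i + n])
        counts[g] = counts.get(g, 0) + 1
    total = sum(counts.values())
    return -sum(c / total * math.log(c / total) for c in counts.values())


def mwu_direct(x, y) -> float:
    """min(U1, U2) from explicit rank sums with mid-ranks."""
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    pooled = sorted((v, src) for src, vals in ((1, x), (2, y)) for v in vals)
    ranks: dict[int, float] = {}
    i = 0
    rank_sum_1 = 0.0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and pooled[j + 1][0] == pooled[i][0]:
            j += 1
        mid = (i + j) / 2 + 1  # mid-rank, 1-based
        for k in range(i, j + 1):
            if pooled[k][1] == 1:
                rank_sum_1 += mid
        i = j + 1
    u1 = n1 * n2 + n1 * (n1 + 1) / 2 - rank_sum_1
    u2 = n1 * n2 - u1
    return min(u1, u2)


def cohens_d_direct(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    return (x.mean() - y.mean()) / math.sqrt(s2)


def cliffs_delta_direct(x, y) -> float:
    gt = sum(1 for a in x for b in y if a > b)
    lt = sum(1 for a in x for b in y if a < b)
    return (gt - lt) / (len(x) * len(y))
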