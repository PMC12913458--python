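"""Microstate segmentation: GFP, peak-map extraction, K-means template
learning, and per-sample back-fitting.

Global field power (GFP) is the spatial standard deviation of the scalp
potential at each sample (population convention, divide by the channel
count N):

    GFP(t) = sqrt( (1/N) * sum_i (V_i(t) - Vbar(t))^2 )

Topographies at GFP peaks are unit-normalized and clustered with plain
K-means (k-means++ init, 10 restarts) into K templates.  Back-fitting
assigns each sample the template with the highest *signed* dot product
against the unit-normalized channel vector; polarity folding (clustering
and assignment on absolute similarity) is available via
``ignore_polarity=True`` but is off by default.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.cluster import KMeans

from ._types import ConfigError, DegenerateInputError, EpochSet, LabelSequence, TemplateSet

__all__ = [
    "gfp_curve",
    "find_gfp_peaks",
    "extract_peak_maps",
    "learn_templates",
    "assign_labels",
]

logger = logging.getLogger(__name__)


def gfp_curve(epoch: np.ndarray) -> np.ndarray:
    """Per-sample global field power of a (channels x samples) array."""
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2:
        raise ConfigError("epoch must be 2-D (channels x samples)")
    if epoch.shape[0] < 2:
        raise DegenerateInputError("GFP needs at least 2 channels")
    return epoch.std(axis=0)  # numpy std is the population convention


def find_gfp_peaks(gfp: np.ndarray, min_peak_distance: int = 2) -> np.ndarray:
    """Indices of local GFP maxima, at least ``min_peak_distance`` apart.

    A peak is strictly greater than both neighbors; a plateau (run of equal
    values above both flanks) yields its leftmost sample.  When two peaks
    violate the distance constraint the higher one is kept.
    """
    gfp = np.asarray(gfp, dtype=float)
    n = gfp.size
    candidates: list[int] = []
    i = 1
    while i < n - 1:
        if gfp[i] > gfp[i - 1]:
            j = i
            while j + 1 < n and gfp[j + 1] == gfp[i]:
                j += 1
            if j + 1 < n and gfp[j + 1] < gfp[i]:
                candidates.append(i)  # leftmost sample of the plateau
            i = j + 1
        else:
            i += 1
    if not candidates or min_peak_distance <= 1:
        return np.asarray(candidates, dtype=int)
    # greedy by descending height, as in standard peak pruning
    order = sorted(candidates, key=lambda idx: (-gfp[idx], idx))
    kept: list[int] = []
    for idx in order:
        if all(abs(idx - k) >= min_peak_distance for k in kept):
            kept.append(idx)
    return np.asarray(sorted(kept), dtype=int)


def extract_peak_maps(es: EpochSet, min_peak_distance: int = 2) -> np.ndarray:
    """Unit-norm topographies at GFP peaks of every accepted epoch."""
    maps: list[np.ndarray] = []
    for epoch in es.accepted:
        gfp = gfp_curve(epoch)
        for idx in find_gfp_peaks(gfp, min_peak_distance):
            v = epoch[:, idx]
            norm = np.linalg.norm(v)
            if norm > 0:
                maps.append(v / norm)
    if not maps:
        logger.warning("no GFP peaks found in %d epochs", es.n_epochs)
        return np.empty((0, es.n_channels))
    return np.asarray(maps)


def learn_templates(maps: np.ndarray, K: int = 4, seed: int = 42,
                    ignore_polarity: bool = False,
                    ch_names: list[str] | None = None) -> TemplateSet:
    """Cluster unit-norm peak maps into K microstate templates.

    Plain K-means (k-means++, 10 restarts, fixed seed); centroids are
    renormalized to unit norm and ordered by descending cluster size (ties
    by first occurrence).  With ``ignore_polarity`` each map's sign is
    aligned to the first principal direction before clustering.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 2 or maps.shape[0] < K:
        raise ConfigError(f"need at least K={K} maps, got {maps.shape}")
    if ignore_polarity:
        _, _, vt = np.linalg.svd(maps, full_matrices=False)
        signs = np.sign(maps @ vt[0])
        signs[signs == 0] = 1.0
        maps = maps * signs[:, None]
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    assignments = km.fit_predict(maps)
    centroids = km.cluster_centers_
    sizes = np.bincount(assignments, minlength=K)
    first_seen = np.array([
        np.argmax(assignments == k) if sizes[k] else maps.shape[0]
        for k in range(K)
    ])
    order = sorted(range(K), key=lambda k: (-sizes[k], first_seen[k]))
    centroids = centroids[order]
    norms = np.linalg.norm(centroids, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return TemplateSet(maps=centroids / norms, ch_names=ch_names)


def kmeans_objective(maps: np.ndarray, templates: TemplateSet) -> float:
    """Within-cluster sum of squared distances of maps to nearest template."""
    d2 = ((maps[:, None, :] - templates.maps[None, :, :]) ** 2).sum(axis=2)
    return float(d2.min(axis=1).sum())


def assign_labels(es: EpochSet, templates: TemplateSet,
                  ignore_polarity: bool = False) -> LabelSequence:
    """Back-fit templates to every sample of every accepted epoch.

    Each channel vector is unit-normalized and labeled with the template of
    highest dot product (signed by default; absolute value with
    ``ignore_polarity``).  Ties take the lowest state index; zero-norm
    samples carry the previous label forward (state 0 at the start).
    """
    if es.n_channels != templates.n_channels:
        raise ConfigError(
            f"epochs have {es.n_channels} channels, templates "
            f"{templates.n_channels}"
        )
    data = es.accepted  # (E, C, S)
    E, C, S = data.shape
    labels = np.zeros((E, S), dtype=np.int64)
    for e in range(E):
        X = data[e]  # (C, S)
        norms = np.linalg.norm(X, axis=0)
        ok = norms > 0
        sim = templates.maps @ (X[:, ok] / norms[ok])  # (K, n_ok)
        if ignore_polarity:
            sim = np.abs(sim)
        lab = np.zeros(S, dtype=np.int64)
        lab[ok] = np.argmax(sim, axis=0)  # argmax ties -> lowest index
        # zero-norm samples: carry previous label forward (state 0 if first)
        if not ok.all():
            prev = 0
            for t in range(S):
                if ok[t]:
                    prev = lab[t]
                else:
                    lab[t] = prev
        labels[e] = lab
    return LabelSequence(labels=labels, fs=es.fs, K=templates.K)
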