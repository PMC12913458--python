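"""State-conditioned Welch band power (20 features).

For every microstate the samples carrying its label are pooled across all
accepted epochs of the subject (discontiguous runs concatenated without
tapering, epochs in time order).  A state is retained only if its pooled
duration reaches 1 s (>= fs samples) — shorter pools make the spectral
estimate unreliable; individual ~60-120 ms runs never reach 1 s on their
own, so the reliability threshold is applied to the subject-level pool.
Welch PSD (128-sample Hann segments, 50 % overlap) is computed per channel
on the pooled series, averaged over each band's frequency bins (half-open
[lo, hi) so shared edges are not double counted), then over channels.  A
state that never reaches 1 s yields NaN for its five band powers, never a
silent 0.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from . import schema
from ._types import ConfigError, EpochSet, LabelSequence

__all__ = ["pooled_state_series", "welch_band_means", "state_band_powers",
           "spectral_vector"]

logger = logging.getLogger(__name__)


def pooled_state_series(es: EpochSet, labels: LabelSequence, state: int
                        ) -> np.ndarray:
    """(channels x pooled-samples) series of one state across all epochs."""
    data = es.accepted
    if data.shape[0] != labels.n_epochs or data.shape[2] != labels.labels.shape[1]:
        raise ConfigError("labels are not aligned sample-wise with the epochs")
    parts = [epoch[:, lab == state]
             for epoch, lab in zip(data, labels.labels)]
    parts = [p for p in parts if p.shape[1]]
    if not parts:
        return np.empty((es.n_channels, 0))
    return np.concatenate(parts, axis=1)


def welch_band_means(x: np.ndarray, fs: float,
                     bands: dict[str, tuple[float, float]] | None = None,
                     nperseg: int = 128) -> dict[str, float]:
    """Mean Welch PSD per band, averaged over bins then channels."""
    bands = schema.BANDS if bands is None else bands
    x = np.atleast_2d(np.asarray(x, dtype=float))
    nseg = min(nperseg, x.shape[1])
    freqs, psd = signal.welch(x, fs=fs, window="hann", nperseg=nseg,
                              noverlap=nseg // 2, axis=-1)
    out = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs < hi)
        out[name] = float(psd[:, sel].mean()) if sel.any() else float("nan")
    return out


def state_band_powers(es: EpochSet, labels: LabelSequence, state: int,
                      bands: dict[str, tuple[float, float]] | None = None,
                      min_duration: float = 1.0) -> dict[str, float]:
    """Band powers for one state's pooled series (NaN below ``min_duration``)."""
    bands = schema.BANDS if bands is None else bands
    pooled = pooled_state_series(es, labels, state)
    if pooled.shape[1] < int(round(min_duration * es.fs)):
        logger.warning("state %d pools %.2f s < %.2f s; spectral features NaN",
                       state, pooled.shape[1] / es.fs, min_duration)
        return {name: float("nan") for name in bands}
    return welch_band_means(pooled, es.fs, bands)


def spectral_vector(es: EpochSet, labels: LabelSequence,
                    K: int = schema.N_STATES) -> dict[str, float]:
    """All 20 spectral features (5 bands x K states)."""
    out: dict[str, float] = {}
    per_state = [state_band_powers(es, labels, k) for k in range(K)]
    for band in schema.BAND_NAMES:
        for k in range(K):
            out[f"{band}_power_state{k}"] = per_state[k][band]
    return out
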