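"""Preprocessing: filtering, re-referencing, resampling, epoching,
automated epoch rejection, and cross-subject channel standardization.

The pipeline order is band-pass -> notch -> common-average reference ->
polyphase resample -> epoch -> reject.  Filters are zero-phase FIR
(Hamming-windowed design, forward-backward application); the notch is a
2 Hz-wide zero-phase band-stop.  Sample indices are 0-based and epoch
windows are half-open ``[start, start + length)``.
"""

from __future__ import annotations

import logging
from collections import Counter
from fractions import Fraction

import numpy as np
from scipy import signal

from ._types import (AllEpochsRejectedError, ConfigError, EpochSet, Recording)

__all__ = [
    "preprocess_recording",
    "epoch_recording",
    "reject_epochs",
    "standardize_channels",
    "common_average_reference",
]

logger = logging.getLogger(__name__)


def _fir_taps(fs: float, transition_hz: float) -> int:
    # Hamming-window design: ~3.3 / (transition width) taps, forced odd
    n = int(np.ceil(3.3 * fs / transition_hz))
    return n + 1 if n % 2 == 0 else n


def _filtfilt(taps: np.ndarray, data: np.ndarray) -> np.ndarray:
    return signal.filtfilt(taps, [1.0], data, axis=-1)


def common_average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean across channels (idempotent)."""
    return data - data.mean(axis=0, keepdims=True)


def preprocess_recording(rec: Recording, band: tuple[float, float] = (1.0, 45.0),
                         notch: float | None = 50.0,
                         target_fs: float = 128.0,
                         transition_hz: float = 1.0,
                         notch_width: float = 2.0) -> Recording:
    """Zero-phase band-pass, notch, CAR and polyphase resample, in order."""
    lo, hi = band
    if not lo < hi:
        raise ConfigError("band low must be below band high")
    if rec.fs < 2 * hi:
        raise ConfigError(
            f"sampling rate {rec.fs} Hz below Nyquist for band high {hi} Hz"
        )
    data = rec.data
    taps = signal.firwin(_fir_taps(rec.fs, transition_hz), [lo, hi],
                         pass_zero=False, fs=rec.fs, window="hamming")
    data = _filtfilt(taps, data)
    if notch is not None and notch < rec.fs / 2:
        half = notch_width / 2.0
        stop = signal.firwin(_fir_taps(rec.fs, notch_width / 2.0),
                             [notch - half, notch + half], pass_zero=True,
                             fs=rec.fs, window="hamming")
        data = _filtfilt(stop, data)
    data = common_average_reference(data)
    if target_fs != rec.fs:
        frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=-1)
    return rec.copy_with(data=data, fs=target_fs)


def epoch_recording(rec: Recording, window: float = 2.0,
                    overlap: float = 0.5) -> EpochSet:
    """Cut a recording into fixed windows (default 2 s, 50 % overlap)."""
    if not 0 <= overlap < 1:
        raise ConfigError("overlap must be in [0, 1)")
    win = int(round(window * rec.fs))
    step = int(round(win * (1 - overlap)))
    if step < 1:
        raise ConfigError("window/overlap give a zero-sample step")
    if rec.n_samples < win:
        raise ConfigError(
            f"recording ({rec.n_samples} samples) shorter than one window ({win})"
        )
    n_epochs = (rec.n_samples - win) // step + 1
    starts = np.arange(n_epochs) * step
    epochs = np.stack([rec.data[:, s:s + win] for s in starts])
    return EpochSet(epochs=epochs, fs=rec.fs, ch_names=list(rec.ch_names),
                    starts=starts, subject=rec.subject, group=rec.group)


def reject_epochs(es: EpochSet, amp_limit: float = 100.0,
                  var_z_limit: float = 3.0) -> EpochSet:
    """Flag artifact epochs by amplitude and cross-epoch variance z-score.

    An epoch is rejected if any sample exceeds ``amp_limit`` (µV) in
    magnitude, or if the z-score of its per-channel variance (standardized
    across epochs, maximum over channels) exceeds ``var_z_limit``.  Data are
    retained; only the mask changes.
    """
    amp_bad = np.abs(es.epochs).max(axis=(1, 2)) > amp_limit
    var = es.epochs.var(axis=2)  # (n_epochs, n_channels)
    mu = var.mean(axis=0, keepdims=True)
    sd = var.std(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (var - mu) / sd, 0.0)
    var_bad = z.max(axis=1) > var_z_limit
    mask = ~(amp_bad | var_bad)
    if not mask.any():
        raise AllEpochsRejectedError(
            f"all {es.n_epochs} epochs rejected (amp_limit={amp_limit}, "
            f"var_z_limit={var_z_limit})"
        )
    return EpochSet(epochs=es.epochs, fs=es.fs, ch_names=list(es.ch_names),
                    mask=mask, starts=es.starts, subject=es.subject,
                    group=es.group)


def standardize_channels(recordings: list[Recording]
                         ) -> tuple[list[str], list[Recording]]:
    """Align all subjects onto the modal channel layout.

    The reference layout is the most frequent channel-name *set* across
    subjects (ties broken by the lexicographically smallest sorted-name
    signature), ordered as in the first subject that carries it.  Missing
    channels are inserted as all-zero series; extra channels are dropped.
    """
    if not recordings:
        raise ConfigError("standardize_channels needs at least one recording")
    signatures = [tuple(sorted(r.ch_names)) for r in recordings]
    counts = Counter(signatures)
    # modal set; ties -> lexicographically smallest sorted-name signature
    top = max(counts.values())
    best = min(sig for sig, c in counts.items() if c == top)
    ref_order = next(r.ch_names for r, sig in zip(recordings, signatures)
                     if sig == best)
    out: list[Recording] = []
    for rec in recordings:
        if rec.ch_names == ref_order:
            out.append(rec)
            continue
        data = np.zeros((len(ref_order), rec.n_samples))
        have = {name: i for i, name in enumerate(rec.ch_names)}
        missing = [n for n in ref_order if n not in have]
        for j, name in enumerate(ref_order):
            if name in have:
                data[j] = rec.data[have[name]]
        if missing:
            logger.info("subject %s: zero-filled channels %s", rec.subject, missing)
        out.append(rec.copy_with(data=data, ch_names=ref_order))
    return list(ref_order), out
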