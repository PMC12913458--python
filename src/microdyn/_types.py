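"""Core containers shared across the pipeline.

All data are plain numpy arrays wrapped in light dataclasses:

* :class:`Recording` — one subject's continuous multichannel EEG (µV).
* :class:`EpochSet` — fixed-length windows cut from one recording.
* :class:`TemplateSet` — K unit-norm microstate topographies.
* :class:`LabelSequence` — integer microstate labels, per epoch or continuous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Recording",
    "EpochSet",
    "TemplateSet",
    "LabelSequence",
    "ConfigError",
    "SimulationError",
    "AllEpochsRejectedError",
    "DegenerateInputError",
]


class ConfigError(ValueError):
    """Invalid configuration (inconsistent shapes, rates, bands ...)."""


class SimulationError(RuntimeError):
    """The generative model cannot continue (e.g. absorbing state)."""


class AllEpochsRejectedError(RuntimeError):
    """Artifact rejection removed every epoch of a recording."""


class DegenerateInputError(ValueError):
    """Input is formally valid but the quantity is undefined on it."""


@dataclass
class Recording:
    """Continuous multichannel EEG for one subject.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    ch_names : list of str
        Unique channel names, one per row of ``data``.
    subject : str
        Subject identifier.
    group : str or None
        Cohort group label (e.g. ``"A"`` / ``"B"``).
    """

    data: np.ndarray
    fs: float
    ch_names: list[str]
    subject: str = ""
    group: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConfigError("Recording data must be 2-D (channels x samples)")
        if len(self.ch_names) != self.data.shape[0]:
            raise ConfigError(
                f"{len(self.ch_names)} channel names for {self.data.shape[0]} rows"
            )
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ConfigError("channel names must be unique")
        if self.fs <= 0:
            raise ConfigError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray, fs: float | None = None,
                  ch_names: list[str] | None = None) -> "Recording":
        return Recording(
            data=data,
            fs=self.fs if fs is None else fs,
            ch_names=list(self.ch_names) if ch_names is None else list(ch_names),
            subject=self.subject,
            group=self.group,
        )


@dataclass
class EpochSet:
    """Stack of fixed-length windows from one recording.

    ``mask`` flags epochs retained after artifact rejection (True = keep);
    data for rejected epochs is kept so rejection is non-destructive.
    """

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples_per_epoch)
    fs: float
    ch_names: list[str]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    starts: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject: str = ""
    group: str | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ConfigError("epochs must be 3-D (epoch x channel x sample)")
        if self.mask is None:
            self.mask = np.ones(self.epochs.shape[0], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.epochs.shape[0],):
            raise ConfigError("mask must have one entry per epoch")
        if self.starts is None:
            self.starts = np.arange(self.epochs.shape[0], dtype=int)
        self.starts = np.asarray(self.starts, dtype=int)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def epoch_len(self) -> int:
        return self.epochs.shape[2]

    @property
    def accepted(self) -> np.ndarray:
        """Epoch data with the rejection mask applied."""
        return self.epochs[self.mask]


@dataclass
class TemplateSet:
    """K unit-norm microstate topographies (rows) over C channels."""

    maps: np.ndarray  # (K, C)
    ch_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ConfigError("template maps must be 2-D (K x channels)")
        norms = np.linalg.norm(self.maps, axis=1)
        if np.any(norms == 0):
            raise ConfigError("template rows must be nonzero")
        if not np.allclose(norms, 1.0, atol=1e-6):
            self.maps = self.maps / norms[:, None]

    @property
    def K(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class LabelSequence:
    """Integer microstate labels.

    ``labels`` is stored 2-D (n_epochs, n_samples); a 1-D input is treated
    as a single continuous sequence of shape (1, T).
    """

    labels: np.ndarray
    fs: float
    K: int | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.ndim != 2:
            raise ConfigError("labels must be 1-D or 2-D")
        arr = arr.astype(np.int64)
        if arr.size and arr.min() < 0:
            raise ConfigError("labels must be non-negative")
        if self.K is not None and arr.size and arr.max() >= self.K:
            raise ConfigError("label outside [0, K)")
        self.labels = arr

    @property
    def n_epochs(self) -> int:
        return self.labels.shape[0]

    @property
    def flat(self) -> np.ndarray:
        """Epoch sequences flattened into one continuous 1-D sequence."""
        return self.labels.reshape(-1)
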