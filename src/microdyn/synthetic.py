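"""Synthetic resting-state EEG cohorts with planted group effects.

The generative model mirrors the assumptions of the downstream analysis:
scalp activity at any instant is a single quasi-stable topography (one of K
unit-norm "microstate" maps) modulated by a state-dependent oscillatory
amplitude.  State occupancy follows a semi-Markov chain: dwell lengths are
drawn from a discretized gamma distribution per state, and jumps follow the
self-transition-free renormalized row of a transition matrix.  The amplitude
a(t) is a gain-weighted sum of band-limited oscillations (delta..gamma)
plus 1/f background, offset so the active topography keeps a consistent
polarity most of the time; white sensor noise is added per channel.

Group "B" differs from group "A" only through configured offsets
(state-specific band gains, dwell durations, transition rates), so every
planted effect has a known sign and location.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import schema
from ._types import ConfigError, LabelSequence, Recording, SimulationError, TemplateSet

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "make_templates",
    "simulate_labels",
    "synthesize_recording",
    "generate_cohort",
    "BIOSEMI64_NAMES",
]

# Standard Biosemi 64-electrode 10-10 montage labels; synthetic cohorts use
# the first n_channels so real and synthetic paths share a layout.
BIOSEMI64_NAMES = [
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz", "Fpz",
    "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8", "FC6",
    "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4",
    "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
]

GROUPS = ("A", "B")


def default_channel_names(n_channels: int) -> list[str]:
    if n_channels <= len(BIOSEMI64_NAMES):
        return BIOSEMI64_NAMES[:n_channels]
    return BIOSEMI64_NAMES + [f"EX{i}" for i in range(n_channels - len(BIOSEMI64_NAMES))]


def _uniform_offdiag(K: int) -> np.ndarray:
    P = np.full((K, K), 1.0 / (K - 1))
    np.fill_diagonal(P, 0.0)
    return P


def _default_transition() -> dict[str, np.ndarray]:
    return {g: _uniform_offdiag(4) for g in GROUPS}


def _default_dwell_mean() -> dict[str, np.ndarray]:
    # ~100 ms per state in group A, ~78 ms in group B (shorter dwell ->
    # shorter inter-transition intervals, the ASD-like direction)
    return {"A": np.full(4, 13.0), "B": np.full(4, 10.0)}


def _default_dwell_shape() -> dict[str, np.ndarray]:
    return {g: np.full(4, 2.0) for g in GROUPS}


def _baseline_gains() -> np.ndarray:
    # resting eyes-closed profile: alpha dominant, modest delta/theta,
    # weaker beta/gamma; identical across states unless offset
    return np.tile(np.array([1.0, 0.8, 1.5, 0.6, 0.3]), (4, 1))


def _default_band_gains() -> dict[str, np.ndarray]:
    gains = {g: _baseline_gains() for g in GROUPS}
    # planted spectral effect: elevated delta in states 1 and 3 of group B
    gains["B"][1, 0] = 1.6
    gains["B"][3, 0] = 2.0
    return gains


@dataclass
class GeneratorConfig:
    """Cohort-level configuration; the defaults define the study conditions.

    Per-group parameters are dictionaries keyed ``"A"`` / ``"B"``; dwell
    means are in samples, band gains are (K, 5) nonnegative arrays over
    delta/theta/alpha/beta/gamma, and ``noise_sd`` is the white sensor-noise
    amplitude in microvolts.
    """

    n_per_group: int = 28
    n_channels: int = 54
    fs: float = 128.0
    duration: float = 150.0
    K: int = 4
    transition: dict[str, np.ndarray] = field(default_factory=_default_transition)
    dwell_mean: dict[str, np.ndarray] = field(default_factory=_default_dwell_mean)
    dwell_shape: dict[str, np.ndarray] = field(default_factory=_default_dwell_shape)
    band_gains: dict[str, np.ndarray] = field(default_factory=_default_band_gains)
    noise_sd: float = 5.0
    pink_sd: float = 0.5
    activation_offset: float = 2.0
    amplitude: float = 50.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        if self.K < 1 or self.K > self.n_channels:
            raise ConfigError("need 1 <= K <= n_channels")
        for g in GROUPS:
            P = np.asarray(self.transition[g], dtype=float)
            if P.shape != (self.K, self.K):
                raise ConfigError(f"transition[{g}] must be {self.K}x{self.K}")
            if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
                raise ConfigError(f"transition[{g}] rows must sum to 1")
            self.transition[g] = P
            dm = np.broadcast_to(np.asarray(self.dwell_mean[g], float), (self.K,)).copy()
            if np.any(dm < 1):
                raise ConfigError("dwell_mean must be >= 1 sample")
            self.dwell_mean[g] = dm
            self.dwell_shape[g] = np.broadcast_to(
                np.asarray(self.dwell_shape[g], float), (self.K,)
            ).copy()
            gains = np.asarray(self.band_gains[g], dtype=float)
            if gains.shape != (self.K, len(schema.BANDS)):
                raise ConfigError(
                    f"band_gains[{g}] must be {self.K}x{len(schema.BANDS)}"
                )
            if np.any(gains < 0):
                raise ConfigError("band gains must be nonnegative")
            self.band_gains[g] = gains
        if self.noise_sd < 0 or self.pink_sd < 0 or self.amplitude < 0:
            raise ConfigError("amplitudes must be nonnegative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)


@dataclass
class GroundTruth:
    """Everything planted by the generator, for recovery checks."""

    templates: TemplateSet
    labels: list[LabelSequence]
    params: list[dict]


def make_templates(K: int, n_channels: int, seed: int = 42,
                   max_cosine: float = 0.6, max_tries: int = 1000) -> TemplateSet:
    """Draw K unit-norm random topographies with bounded mutual similarity.

    Rows are i.i.d. Gaussian vectors normalized to unit Euclidean norm,
    redrawn until every pairwise \\|cosine\\| is at most ``max_cosine``.
    """
    if K < 1:
        raise ConfigError("K must be >= 1")
    if K > n_channels:
        raise ConfigError(f"K={K} templates need at least {K} channels")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        maps = rng.standard_normal((K, n_channels))
        maps /= np.linalg.norm(maps, axis=1, keepdims=True)
        gram = maps @ maps.T
        np.fill_diagonal(gram, 0.0)
        if np.max(np.abs(gram)) <= max_cosine:
            return TemplateSet(maps=maps)
    raise SimulationError(
        f"could not draw {K} maps with |cos| <= {max_cosine} in {max_tries} tries"
    )


def _draw_dwell(rng: np.random.Generator, mean: float, shape: float | None) -> int:
    if shape is None or not np.isfinite(shape):
        return max(1, int(round(mean)))
    d = rng.gamma(shape, mean / shape)
    return max(1, int(round(d)))


def simulate_labels(transition_matrix: np.ndarray, dwell_mean, n_samples: int,
                    seed: int = 42, dwell_shape=2.0, start_state: int | None = None,
                    fs: float = 1.0) -> LabelSequence:
    """Simulate a semi-Markov microstate label sequence.

    A dwell length is drawn from a discretized gamma distribution (per-state
    mean in samples, ``dwell_shape=None`` for a deterministic dwell), then
    the chain jumps according to the self-transition-free renormalized row
    of ``transition_matrix``.  The output has exactly ``n_samples`` labels.
    """
    P = np.asarray(transition_matrix, dtype=float)
    K = P.shape[0]
    if P.shape != (K, K) or np.any(P < 0) or not np.allclose(P.sum(1), 1.0, atol=1e-9):
        raise ConfigError("transition matrix must be square and row-stochastic")
    if n_samples < 1:
        raise ConfigError("n_samples must be >= 1")
    means = np.broadcast_to(np.asarray(dwell_mean, float), (K,))
    shapes = np.broadcast_to(np.asarray(dwell_shape, float)
                             if dwell_shape is not None else np.full(K, np.inf), (K,))
    rng = np.random.default_rng(seed)
    state = int(rng.integers(K)) if start_state is None else int(start_state)
    if not 0 <= state < K:
        raise ConfigError("start_state outside [0, K)")
    out = np.empty(n_samples, dtype=np.int64)
    pos = 0
    while pos < n_samples:
        d = _draw_dwell(rng, means[state], shapes[state])
        out[pos:pos + d] = state
        pos += d
        if pos >= n_samples:
            break
        row = P[state].copy()
        row[state] = 0.0
        mass = row.sum()
        if mass <= 0:
            raise SimulationError(
                f"state {state} is absorbing (no off-diagonal mass) but the "
                f"sequence needs {n_samples - pos} more samples"
            )
        state = int(rng.choice(K, p=row / mass))
    return LabelSequence(labels=out, fs=fs, K=K)


def _band_limited_noise(rng: np.random.Generator, n: int, fs: float,
                        lo: float, hi: float) -> np.ndarray:
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[(f < lo) | (f >= hi)] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                      exponent: float = 1.0, f_min: float = 1.0) -> np.ndarray:
    """Spectrally shaped white noise with power ~ 1/f^exponent above f_min."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.zeros_like(f)
    above = f >= f_min
    scale[above] = f[above] ** (-exponent / 2.0)
    scale[(f > 0) & ~above] = f_min ** (-exponent / 2.0)
    spec *= scale
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def synthesize_recording(labels: LabelSequence, templates: TemplateSet,
                         band_gains: np.ndarray, noise_sd: float, fs: float,
                         seed: int = 42, *, pink_sd: float = 0.5,
                         activation_offset: float = 2.0, amplitude: float = 50.0,
                         duration: float | None = None,
                         ch_names: list[str] | None = None,
                         subject: str = "", group: str | None = None) -> Recording:
    """Render a label sequence into a multichannel recording.

    At sample t the channel vector is ``amplitude * a(t) * template[s_t]``
    plus white sensor noise, where a(t) sums gain-weighted band-limited
    oscillations and 1/f background over the active state's gains, offset by
    ``activation_offset`` standard deviations so polarity stays mostly
    consistent.  With all gains and ``pink_sd`` zero the source is silent.
    """
    seq = labels.flat
    n = seq.size
    if duration is not None and n > int(round(duration * fs)):
        raise ConfigError(
            f"label sequence ({n} samples) longer than requested duration "
            f"({duration} s at {fs} Hz)"
        )
    K, C = templates.maps.shape
    if seq.max() >= K:
        raise ConfigError("labels reference states beyond the template set")
    gains = np.asarray(band_gains, dtype=float)
    if gains.shape != (K, len(schema.BANDS)):
        raise ConfigError(f"band_gains must be {K}x{len(schema.BANDS)}")
    rng = np.random.default_rng(seed)
    osc = np.stack([_band_limited_noise(rng, n, fs, lo, hi)
                    for lo, hi in schema.BANDS.values()])  # (5, n)
    pink = _one_over_f_noise(rng, n, fs) if pink_sd > 0 else np.zeros(n)
    sigma = np.sqrt((gains ** 2).sum(axis=1) + pink_sd ** 2)  # per-state SD of a(t)
    act = (gains[seq] * osc.T).sum(axis=1) + pink_sd * pink
    act += activation_offset * sigma[seq]
    data = amplitude * act * templates.maps[seq].T  # (C, n)
    if noise_sd > 0:
        data = data + noise_sd * rng.standard_normal((C, n))
    names = default_channel_names(C) if ch_names is None else list(ch_names)
    return Recording(data=data, fs=fs, ch_names=names, subject=subject, group=group)


def generate_cohort(config: GeneratorConfig | None = None
                    ) -> tuple[list[Recording], list[str], GroundTruth]:
    """Generate a two-group cohort; fully reproducible given ``config.seed``."""
    cfg = GeneratorConfig() if config is None else config
    root = np.random.SeedSequence(cfg.seed)
    tmpl_seed, subj_root = root.spawn(2)
    templates = make_templates(cfg.K, cfg.n_channels,
                               seed=int(tmpl_seed.generate_state(1)[0] % (2 ** 31)))
    ch_names = default_channel_names(cfg.n_channels)
    recordings: list[Recording] = []
    groups: list[str] = []
    gt_labels: list[LabelSequence] = []
    params: list[dict] = []
    subj_seeds = subj_root.spawn(2 * cfg.n_per_group)
    idx = 0
    for g in GROUPS:
        for i in range(cfg.n_per_group):
            lab_seed, rec_seed = (
                int(s.generate_state(1)[0] % (2 ** 31))
                for s in subj_seeds[idx].spawn(2)
            )
            idx += 1
            labels = simulate_labels(cfg.transition[g], cfg.dwell_mean[g],
                                     cfg.n_samples, seed=lab_seed,
                                     dwell_shape=cfg.dwell_shape[g], fs=cfg.fs)
            subject = f"{g}{i:02d}"
            rec = synthesize_recording(
                labels, templates, cfg.band_gains[g], cfg.noise_sd, cfg.fs,
                seed=rec_seed, pink_sd=cfg.pink_sd,
                activation_offset=cfg.activation_offset, amplitude=cfg.amplitude,
                ch_names=ch_names, subject=subject, group=g,
            )
            recordings.append(rec)
            groups.append(g)
            gt_labels.append(labels)
            params.append({
                "subject": subject,
                "group": g,
                "dwell_mean": cfg.dwell_mean[g].tolist(),
                "dwell_shape": cfg.dwell_shape[g].tolist(),
                "band_gains": cfg.band_gains[g].tolist(),
                "transition": cfg.transition[g].tolist(),
            })
    return recordings, groups, GroundTruth(templates=templates, labels=gt_labels,
                                           params=params)
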