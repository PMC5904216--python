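"""Synthetic multivariate time series with controllable informative missingness.

The generator draws class-conditional signals (smooth per-class mean
trajectories plus AR(1) noise) and then hides observations with per-sample
Bernoulli masks whose rates depend on the label.  The informativeness knob
``rho`` scales how far each selected variable's missing rate moves with the
label, with the two classes displaced symmetrically so the *overall* missing
rate stays at its base value for every ``rho`` — the knob changes only how
much the missingness itself tells you about the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Dataset, TimeSeriesSample, build_mask

__all__ = [
    "SyntheticConfig",
    "GenerationReport",
    "generate",
    "missingness_label_correlation",
]


@dataclass
class SyntheticConfig:
    """Full recipe for one generated dataset.

    ``base_rates`` is the per-variable missing rate when ``rho = 0``;
    ``informative`` selects which variables' rates move with the label;
    ``amplitudes`` sets the maximum displacement (defaults to 90% of the
    headroom to the nearest probability boundary).  ``signal_strength``
    scales the class separation of the observed values themselves, and
    ``signal_onset`` (a fraction of T) optionally delays it so early
    observations are uninformative.
    """

    n_samples: int = 500
    D: int = 10
    T: int = 30
    n_classes: int = 2
    rho: float = 0.0
    base_rates: np.ndarray | float = 0.5
    informative: np.ndarray | None = None
    amplitudes: np.ndarray | None = None
    signal_strength: float = 1.0
    signal_onset: float | None = None
    ar_coef: float = 0.6
    noise_scale: float = 1.0
    label_balance: float = 0.5
    stamp_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [0, 1]")
        if self.T < 2:
            raise ValueError("T must be >= 2")
        self.base_rates = np.broadcast_to(
            np.asarray(self.base_rates, dtype=float), (self.D,)
        ).copy()
        if np.any((self.base_rates < 0) | (self.base_rates >= 1)):
            raise ValueError("base rates must lie in [0, 1)")
        if self.informative is None:
            self.informative = np.ones(self.D, dtype=bool)
        else:
            self.informative = np.asarray(self.informative, dtype=bool)
        if self.amplitudes is None:
            headroom = np.minimum(self.base_rates, 1.0 - self.base_rates)
            self.amplitudes = 0.9 * headroom
        else:
            self.amplitudes = np.broadcast_to(
                np.asarray(self.amplitudes, dtype=float), (self.D,)
            ).copy()
        if self.rho > 0 and self.n_classes != 2:
            raise ValueError("label-dependent missingness requires binary labels")

    def missing_prob(self, y: int) -> np.ndarray:
        """Per-variable missing probability for a sample with label y."""
        shift = self.rho * self.informative * self.amplitudes * (2 * (y == 1) - 1)
        return self.base_rates + shift


@dataclass
class GenerationReport:
    """Diagnostics of one generated dataset."""

    overall_missing_rate: float
    per_variable_missing_rate: np.ndarray
    missing_label_correlation: np.ndarray
    degenerate: np.ndarray
    class_counts: np.ndarray


def _class_trajectories(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    """Smooth per-class mean trajectories, shape (n_classes, T, D)."""
    t = np.arange(cfg.T) / cfg.T
    mu = np.zeros((cfg.n_classes, cfg.T, cfg.D))
    for c in range(cfg.n_classes):
        offset = rng.normal(size=cfg.D)
        amp = rng.normal(size=cfg.D)
        phase = rng.uniform(0, 2 * np.pi, size=cfg.D)
        mu[c] = offset + amp * np.sin(2 * np.pi * t[:, None] + phase)
    mu *= cfg.signal_strength
    if cfg.signal_onset is not None:
        gate = (t >= cfg.signal_onset).astype(float)
        shared = mu.mean(axis=0, keepdims=True)
        mu = shared + (mu - shared) * gate[None, :, None]
    return mu


def _ar1_noise(rng: np.random.Generator, cfg: SyntheticConfig, n: int) -> np.ndarray:
    phi, s = cfg.ar_coef, cfg.noise_scale
    e = np.empty((n, cfg.T, cfg.D))
    e[:, 0] = rng.normal(scale=s / np.sqrt(1 - phi**2), size=(n, cfg.D))
    for t in range(1, cfg.T):
        e[:, t] = phi * e[:, t - 1] + rng.normal(scale=s, size=(n, cfg.D))
    return e


def generate(config: SyntheticConfig) -> tuple[Dataset, GenerationReport]:
    """Draw one dataset and its diagnostics, deterministically from the seed."""
    cfg = config
    for y in range(cfg.n_classes) if cfg.rho > 0 else [0]:
        p = cfg.missing_prob(y)
        bad = np.flatnonzero((p < 0) | (p >= 1))
        if bad.size:
            raise ValueError(
                f"missing probability out of (0, 1) for class {y}, "
                f"variables {bad.tolist()}"
            )
    rng = np.random.default_rng(cfg.seed)

    n1 = int(round(cfg.n_samples * cfg.label_balance))
    if cfg.n_classes == 2:
        labels = np.array([1] * n1 + [0] * (cfg.n_samples - n1))
    else:
        labels = np.arange(cfg.n_samples) % cfg.n_classes
    labels = rng.permutation(labels)

    mu = _class_trajectories(rng, cfg)
    signals = mu[labels] + _ar1_noise(rng, cfg, cfg.n_samples)

    probs = np.stack([cfg.missing_prob(y) for y in range(cfg.n_classes)])
    miss = rng.random((cfg.n_samples, cfg.T, cfg.D)) < probs[labels][:, None, :]

    samples = []
    for i in range(cfg.n_samples):
        raw = np.where(miss[i], np.nan, signals[i])
        values, mask = build_mask(raw)
        gaps = np.ones(cfg.T - 1)
        if cfg.stamp_jitter > 0:
            gaps = gaps + rng.uniform(-cfg.stamp_jitter, cfg.stamp_jitter, cfg.T - 1)
        stamps = np.concatenate([[0.0], np.cumsum(gaps)])
        samples.append(
            TimeSeriesSample(values=values, mask=mask, stamps=stamps,
                             sample_id=f"s{i:05d}")
        )

    dataset = Dataset(samples=samples, labels=labels)
    corr, degenerate = missingness_label_correlation(dataset, return_flags=True) \
        if cfg.n_classes == 2 else (np.zeros(cfg.D), np.ones(cfg.D, dtype=bool))
    mask_all = np.stack([s.mask for s in samples])
    report = GenerationReport(
        overall_missing_rate=float(1.0 - mask_all.mean()),
        per_variable_missing_rate=1.0 - mask_all.mean(axis=(0, 1)),
        missing_label_correlation=corr,
        degenerate=degenerate,
        class_counts=np.bincount(labels, minlength=cfg.n_classes),
    )
    return dataset, report


def missingness_label_correlation(dataset: Dataset, return_flags: bool = False):
    """Pearson r between each variable's per-sample missing fraction and the label.

    Variables whose missing fraction has zero variance across samples get a
    correlation of 0 and are flagged as degenerate.
    """
    labels = np.asarray(dataset.labels, dtype=float)
    if labels.ndim != 1 or not set(np.unique(labels)) <= {0.0, 1.0}:
        raise ValueError("binary labels required")
    rates = np.stack([1.0 - s.mask.mean(axis=0) for s in dataset.samples])
    D = rates.shape[1]
    corr = np.zeros(D)
    degenerate = np.zeros(D, dtype=bool)
    ls = labels.std()
    for d in range(D):
        rs = rates[:, d].std()
        if rs == 0 or ls == 0:
            degenerate[d] = True
        else:
            corr[d] = np.corrcoef(rates[:, d], labels)[0, 1]
    return (corr, degenerate) if return_flags else corr
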