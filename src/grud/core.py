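"""Data model for irregularly sampled multivariate time series with missingness.

A sample is a ``T x D`` matrix of measurements together with a binary
observation mask, a shared vector of time stamps (first stamp is 0), and a
derived matrix of per-variable time intervals: the elapsed time since each
variable was last observed.  All downstream models consume this
representation; unobserved entries hold a zero placeholder that is only ever
read through an explicit imputation or decay rule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TimeSeriesSample",
    "Dataset",
    "NormalizationStats",
    "build_mask",
    "compute_time_interval",
    "compute_empirical_means",
    "compute_normalization_stats",
    "normalize",
    "denormalize",
]


class NeverObservedError(ValueError):
    """A variable has zero observations in the split it is summarized on."""


@dataclass
class TimeSeriesSample:
    """One subject's measurements, mask, stamps and derived intervals.

    Attributes
    ----------
    values : (T, D) float array
        Measurements; entries where ``mask == 0`` hold a 0 placeholder.
    mask : (T, D) float array of {0, 1}
        1 where the variable was observed at that step.
    stamps : (T,) float array
        Nondecreasing observation times, ``stamps[0] == 0``.
    intervals : (T, D) float array
        Time since each variable's previous observation (cached, derived).
    sample_id : opaque identifier.
    """

    values: np.ndarray
    mask: np.ndarray
    stamps: np.ndarray
    intervals: np.ndarray = None
    sample_id: object = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=float)
        self.stamps = np.asarray(self.stamps, dtype=float)
        if self.values.ndim != 2 or self.values.shape != self.mask.shape:
            raise ValueError("values and mask must be matching T x D matrices")
        if self.stamps.shape != (self.values.shape[0],):
            raise ValueError("stamps must have length T")
        if self.stamps.size and self.stamps[0] != 0.0:
            raise ValueError("first stamp must be 0")
        if np.any(np.diff(self.stamps) < 0):
            raise ValueError("stamps must be nondecreasing")
        if not np.all((self.mask == 0) | (self.mask == 1)):
            raise ValueError("mask entries must be 0 or 1")
        if not np.all(np.isfinite(self.values[self.mask == 1])):
            raise ValueError("observed values must be finite")
        if self.intervals is None:
            self.intervals = compute_time_interval(self.stamps, self.mask)
        else:
            self.intervals = np.asarray(self.intervals, dtype=float)

    @property
    def T(self) -> int:
        return self.values.shape[0]

    @property
    def D(self) -> int:
        return self.values.shape[1]

    def replace(self, **kw) -> "TimeSeriesSample":
        return dataclasses.replace(self, **kw)


@dataclass
class NormalizationStats:
    """Per-variable mean/std of observed entries, tagged with its source split."""

    mean: np.ndarray
    std: np.ndarray
    provenance: str = "train"

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if np.any(self.std <= 0):
            raise ValueError("std must be positive (degenerate stds are forced to 1)")


@dataclass
class Dataset:
    """A collection of samples plus labels and per-variable summaries.

    ``labels`` is either a length-N integer vector (binary / L-class) or an
    (N, n_tasks) binary matrix for multi-task problems.  ``empirical_means``
    and ``norm_stats`` are populated from the *training* split only and
    carried along so every split is transformed identically.
    """

    samples: list[TimeSeriesSample]
    labels: np.ndarray = None
    variable_names: Sequence[str] = None
    empirical_means: np.ndarray = None
    norm_stats: NormalizationStats = None

    def __post_init__(self):
        if self.samples:
            D = self.samples[0].D
            if any(s.D != D for s in self.samples):
                raise ValueError("all samples must share D")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.samples):
                raise ValueError("labels length must equal number of samples")
        if self.variable_names is None and self.samples:
            self.variable_names = [f"var{d}" for d in range(self.samples[0].D)]

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def D(self) -> int:
        return self.samples[0].D

    def subset(self, idx) -> "Dataset":
        idx = np.asarray(idx)
        return Dataset(
            samples=[self.samples[i] for i in idx],
            labels=None if self.labels is None else self.labels[idx],
            variable_names=self.variable_names,
            empirical_means=self.empirical_means,
            norm_stats=self.norm_stats,
        )


def build_mask(raw_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a matrix with non-finite sentinels into (values, mask).

    ``mask[t, d]`` is 1 iff ``raw_values[t, d]`` is finite; values equal the
    raw data where observed and 0 elsewhere.  The placeholder is never read
    except through an imputation or decay rule.
    """
    raw = np.asarray(raw_values, dtype=float)
    if raw.ndim != 2:
        raise ValueError(f"expected a rectangular T x D matrix, got ndim={raw.ndim}")
    mask = np.isfinite(raw).astype(float)
    values = np.where(mask == 1, raw, 0.0)
    return values, mask


def compute_time_interval(stamps: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Elapsed time since each variable's last observation.

    Row ``t`` of the result is ``s_t - s_{t-1}`` for variables observed at
    ``t-1`` and accumulates the previous interval otherwise; row 0 is 0.
    """
    stamps = np.asarray(stamps, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if np.any(np.diff(stamps) < 0):
        raise ValueError("stamps must be nondecreasing")
    T, D = mask.shape
    delta = np.zeros((T, D))
    for t in range(1, T):
        gap = stamps[t] - stamps[t - 1]
        delta[t] = gap + np.where(mask[t - 1] == 0, delta[t - 1], 0.0)
    return delta


def compute_empirical_means(train: Dataset) -> np.ndarray:
    """Mean of each variable over its observed entries in the training split."""
    if not train.samples:
        raise ValueError("empty training split")
    D = train.D
    num = np.zeros(D)
    den = np.zeros(D)
    for s in train.samples:
        num += (s.mask * s.values).sum(axis=0)
        den += s.mask.sum(axis=0)
    never = den == 0
    if np.any(never):
        names = [train.variable_names[d] for d in np.flatnonzero(never)]
        raise NeverObservedError(
            f"variables never observed in training split: {names}"
        )
    return num / den


def compute_normalization_stats(
    train: Dataset, provenance: str = "train"
) -> NormalizationStats:
    """Observed-entry mean and population std per variable; zero stds become 1."""
    mean = compute_empirical_means(train)
    D = train.D
    ssq = np.zeros(D)
    den = np.zeros(D)
    for s in train.samples:
        ssq += (s.mask * (s.values - mean) ** 2 * s.mask).sum(axis=0)
        den += s.mask.sum(axis=0)
    std = np.sqrt(ssq / den)
    std = np.where(std <= 0, 1.0, std)
    return NormalizationStats(mean=mean, std=std, provenance=provenance)


def _transform(dataset: Dataset, stats: NormalizationStats, sign: int) -> Dataset:
    samples = []
    for s in dataset.samples:
        if sign > 0:
            vals = (s.values - stats.mean) / stats.std
        else:
            vals = s.values * stats.std + stats.mean
        vals = np.where(s.mask == 1, vals, 0.0)
        samples.append(s.replace(values=vals))
    out = Dataset(
        samples=samples,
        labels=dataset.labels,
        variable_names=dataset.variable_names,
        norm_stats=stats if sign > 0 else None,
    )
    out.empirical_means = compute_empirical_means(out)
    return out


def normalize(dataset: Dataset, stats: NormalizationStats) -> Dataset:
    """Z-score observed entries; masks, stamps and intervals are untouched.

    Empirical means are recomputed on the normalized scale (so they are ~0 on
    the split that produced ``stats``) because the input-decay rule blends on
    the model's input scale.
    """
    return _transform(dataset, stats, +1)


def denormalize(dataset: Dataset, stats: NormalizationStats) -> Dataset:
    """Inverse of :func:`normalize` with the same stats."""
    return _transform(dataset, stats, -1)
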