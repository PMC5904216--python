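"""Non-architectural missing-value strategies producing model-ready inputs.

Three strategies: replace missing entries with the training mean, carry the
last observation forward, or keep a base imputation and concatenate the mask
and interval channels so the classifier sees the missingness itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TimeSeriesSample

__all__ = ["SimpleVariant", "mean_impute", "forward_impute", "simple_concat"]


@dataclass(frozen=True)
class SimpleVariant:
    """Which channels the concatenation strategy emits besides the values.

    The canonical form emits both; ``include_mask=False`` is the "w/o m"
    ablation, ``include_interval=False`` the "w/o delta" ablation.
    """

    include_mask: bool = True
    include_interval: bool = True

    @property
    def width_factor(self) -> int:
        return 1 + int(self.include_mask) + int(self.include_interval)


def _check_means(means: np.ndarray, D: int) -> np.ndarray:
    means = np.asarray(means, dtype=float)
    if means.shape != (D,):
        raise ValueError(f"means must have length D={D}, got shape {means.shape}")
    return means


def mean_impute(sample: TimeSeriesSample, means: np.ndarray) -> np.ndarray:
    """x <- m*x + (1-m)*mean, elementwise; observed entries untouched."""
    means = _check_means(means, sample.D)
    m = sample.mask
    return m * sample.values + (1 - m) * means


def forward_impute(sample: TimeSeriesSample, means: np.ndarray) -> np.ndarray:
    """Replace each missing entry with the variable's last observed value.

    Entries missing before any observation fall back to the training mean.
    """
    means = _check_means(means, sample.D)
    out = np.empty_like(sample.values)
    last = means.copy()
    for t in range(sample.T):
        m = sample.mask[t]
        last = np.where(m == 1, sample.values[t], last)
        out[t] = np.where(m == 1, sample.values[t], last)
    return out


def simple_concat(
    sample: TimeSeriesSample,
    base: np.ndarray,
    variant: SimpleVariant = SimpleVariant(),
) -> np.ndarray:
    """Per-step concatenation [x; m; delta] honoring the variant flags.

    ``base`` is an already-imputed T x D matrix (mean or forward).  Output
    width is D, 2D, or 3D; channels are recoverable by slicing.
    """
    base = np.asarray(base, dtype=float)
    if base.shape != sample.values.shape:
        raise ValueError("base must be T x D matching the sample")
    parts = [base]
    if variant.include_mask:
        parts.append(sample.mask)
    if variant.include_interval:
        parts.append(sample.intervals)
    return np.concatenate(parts, axis=1)
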