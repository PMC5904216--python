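"""Metrics and analysis procedures: AUC, online prediction, decay inspection."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .core import Dataset, TimeSeriesSample

__all__ = ["auc", "truncate_dataset", "online_prediction_curve", "decay_report"]


def auc(scores, labels) -> float:
    """Rank-based area under the ROC curve, ties counted half.

    Equals the probability that a uniformly drawn positive outranks a
    uniformly drawn negative.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def truncate_sample(sample: TimeSeriesSample, cutoff: float) -> TimeSeriesSample:
    """Keep only steps with stamp <= cutoff; intervals are recomputed.

    The interval recursion is causal, so the recomputed prefix intervals
    coincide with the full-sequence intervals restricted to the prefix.
    """
    keep = sample.stamps <= cutoff
    if not keep.any():
        raise ValueError(f"cutoff {cutoff} precedes the sample's first stamp")
    n = int(keep.sum())
    return TimeSeriesSample(
        values=sample.values[:n],
        mask=sample.mask[:n],
        stamps=sample.stamps[:n],
        sample_id=sample.sample_id,
    )


def truncate_dataset(dataset: Dataset, cutoff: float) -> Dataset:
    return Dataset(
        samples=[truncate_sample(s, cutoff) for s in dataset.samples],
        labels=dataset.labels,
        variable_names=dataset.variable_names,
        empirical_means=dataset.empirical_means,
        norm_stats=dataset.norm_stats,
    )


def default_cutoffs(dataset: Dataset, n: int = 10) -> list[float]:
    """Deciles of the observation window, in native stamp units."""
    horizon = max(float(s.stamps[-1]) for s in dataset.samples)
    return [horizon * k / n for k in range(1, n + 1)]


def online_prediction_curve(model, dataset: Dataset, cutoffs=None) -> dict[float, float]:
    """AUC at each observation cutoff, using only data observed by then.

    Every test sequence is truncated to stamps <= cutoff, intervals are
    recomputed on the prefix, and the model scores the partial sequence; no
    future information leaks into earlier predictions.
    """
    if cutoffs is None:
        cutoffs = default_cutoffs(dataset)
    curve = {}
    for c in sorted(cutoffs):
        truncated = truncate_dataset(dataset, c)
        scores = model.predict_scores(truncated)
        curve[float(c)] = auc(scores, dataset.labels)
    return curve


def decay_report(model, delta_grid=None) -> dict:
    """Inspect the learned decays of a decay-augmented model.

    Returns, per variable: the input-decay curve over ``delta_grid`` and the
    hidden-decay weight column with its mean absolute value.  The report is a
    pure function of the decay parameters.
    """
    if getattr(model.config, "mode", None) != "grud":
        raise ValueError("decay_report requires a model in 'grud' mode")
    p = model.params
    w, b = np.asarray(p["w_gamma_x"]), np.asarray(p["b_gamma_x"])
    W_h = np.asarray(p["W_gamma_h"])
    if delta_grid is None:
        delta_grid = np.linspace(0.0, 10.0, 101)
    delta_grid = np.asarray(delta_grid, dtype=float)
    curves = np.exp(-np.maximum(0.0, w[:, None] * delta_grid[None, :] + b[:, None]))
    return {
        "delta_grid": delta_grid,
        "gamma_x_curves": curves,                     # (D, len(grid))
        "input_decay_weight": w,
        "input_decay_bias": b,
        "hidden_decay_columns": W_h.T,                # (D, H)
        "hidden_decay_mean_abs": np.abs(W_h).mean(axis=0),  # (D,)
    }
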