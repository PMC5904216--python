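"""Model fitting: heads, losses, Adam with early stopping, and cross-validation.

Training runs on padded batch tensors.  Sequences of unequal length share a
batch through a *validity* mask that freezes the hidden state past each
sequence's end; this mask is distinct from the missingness mask and never
mixed with it.  All gradients are reverse-mode analytic gradients through
the fully unrolled recurrence.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.misc import flatten

from . import cell as cell_mod
from .cell import (
    MODES,
    SimpleVariant,
    count_parameters,
    init_gru_params,
    init_grud_params,
    input_width,
    match_hidden_size,
)
from .core import (
    Dataset,
    NormalizationStats,
    compute_normalization_stats,
    normalize,
)
from .evaluation import auc
from .imputation import forward_impute, mean_impute, simple_concat

__all__ = [
    "ModelConfig",
    "FittedModel",
    "predict_proba",
    "cooccurrence_prior",
    "prior_penalty",
    "fit",
    "evaluate_cv",
]

HEAD_KINDS = ("binary", "softmax", "multitask")
_BN_EPS = 1e-5


@dataclass
class ModelConfig:
    mode: str = "grud"
    variant: SimpleVariant = field(default_factory=SimpleVariant)
    hidden_size: int | None = 16
    reference_hidden: int | None = None  # parity-match against GRU-Mean at this H
    head: str = "binary"
    n_outputs: int = 1
    head_dropout: float = 0.5
    recurrent_dropout: float = 0.3
    batch_norm: bool = True
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int = 32
    max_epochs: int = 40
    patience: int = 8
    prior_lambda: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.head not in HEAD_KINDS:
            raise ValueError(f"unknown head {self.head!r}")
        if not (0 <= self.head_dropout < 1 and 0 <= self.recurrent_dropout < 1):
            raise ValueError("dropout rates must be in [0, 1)")
        if self.head == "binary":
            self.n_outputs = 1
        elif self.n_outputs < 2:
            raise ValueError(f"{self.head} head needs n_outputs >= 2")
        if isinstance(self.variant, dict):
            self.variant = SimpleVariant(**self.variant)

    def head_spec(self) -> dict:
        return {"n_out": self.n_outputs, "batch_norm": self.batch_norm}

    def resolve_hidden(self, D: int) -> int:
        if self.reference_hidden is not None:
            ref = count_parameters("gru_mean", D, self.reference_hidden,
                                   self.head_spec())
            return match_hidden_size(ref, self.mode, D, self.head_spec(),
                                     self.variant)
        if self.hidden_size is None:
            raise ValueError("set hidden_size or reference_hidden")
        return self.hidden_size


# ---------------------------------------------------------------------------
# batch packing

def pack_batch(dataset: Dataset, means: np.ndarray, mode: str,
               variant: SimpleVariant) -> dict:
    """Pad a dataset into the dense tensors one forward pass consumes.

    For the decayed cell: values, missingness mask, intervals and the
    last-observation carry (mean-filled before the first observation).  For
    baseline modes: the imputed/concatenated input stream.  ``valid`` marks
    real (non-padding) steps.
    """
    N = len(dataset.samples)
    T = max(s.T for s in dataset.samples)
    D = dataset.D
    valid = np.zeros((N, T))
    for i, s in enumerate(dataset.samples):
        valid[i, : s.T] = 1.0
    out = {"valid": valid, "lengths": np.array([s.T for s in dataset.samples])}
    if mode == "grud":
        X = np.zeros((N, T, D))
        M = np.zeros((N, T, D))
        Dl = np.zeros((N, T, D))
        X_last = np.tile(means, (N, T, 1))
        for i, s in enumerate(dataset.samples):
            X[i, : s.T] = s.values
            M[i, : s.T] = s.mask
            Dl[i, : s.T] = s.intervals
            carry = means.copy()
            for t in range(s.T):
                X_last[i, t] = carry
                carry = np.where(s.mask[t] == 1, s.values[t], carry)
        out.update(X=X, M=M, Delta=Dl, X_last=X_last)
    else:
        Din = input_width(mode, D, variant)
        inputs = np.zeros((N, T, Din))
        for i, s in enumerate(dataset.samples):
            if mode == "gru_mean":
                xi = mean_impute(s, means)
            elif mode == "gru_forward":
                xi = forward_impute(s, means)
            else:
                xi = simple_concat(s, mean_impute(s, means), variant)
            inputs[i, : s.T] = xi
        out.update(inputs=inputs)
    return out


def _forward_batch(p: dict, batch: dict, mode: str, means, dropout=None):
    """Hidden state at each sequence's last real step, shape (N, H)."""
    valid = batch["valid"]
    H = p["W_r"].shape[0]
    if mode == "grud":
        X, M, Dl, X_last = batch["X"], batch["M"], batch["Delta"], batch["X_last"]
        N, T, D = X.shape
        h = anp.zeros((N, H))
        for t in range(T):
            gamma_x = cell_mod.decay_rate(Dl[:, t], p["w_gamma_x"], p["b_gamma_x"])
            x_hat = M[:, t] * X[:, t] + (1 - M[:, t]) * (
                gamma_x * X_last[:, t] + (1 - gamma_x) * means
            )
            h_new = cell_mod._grud_core(x_hat, M[:, t], Dl[:, t], h, p, dropout)
            v = valid[:, t : t + 1]
            h = v * h_new + (1 - v) * h
    else:
        inputs = batch["inputs"]
        N, T, _ = inputs.shape
        h = anp.zeros((N, H))
        for t in range(T):
            x = inputs[:, t]
            if dropout is not None:
                x = x * dropout["dx"]
                hg = h * dropout["dh"]
            else:
                hg = h
            r = cell_mod._sigmoid(
                anp.dot(x, p["W_r"].T) + anp.dot(hg, p["U_r"].T) + p["b_r"]
            )
            z = cell_mod._sigmoid(
                anp.dot(x, p["W_z"].T) + anp.dot(hg, p["U_z"].T) + p["b_z"]
            )
            h_tilde = anp.tanh(
                anp.dot(x, p["W"].T) + anp.dot(r * hg, p["U"].T) + p["b"]
            )
            h_new = (1 - z) * h + z * h_tilde
            v = valid[:, t : t + 1]
            h = v * h_new + (1 - v) * h
    return h


# ---------------------------------------------------------------------------
# heads and losses

def _init_head(H: int, config: ModelConfig) -> dict:
    head = {"w": np.zeros((H, config.n_outputs)), "b": np.zeros(config.n_outputs)}
    if config.batch_norm:
        head["bn_gamma"] = np.ones(H)
        head["bn_beta"] = np.zeros(H)
    return head


def _head_logits(h, head: dict, config: ModelConfig, bn_stats=None,
                 dropout_mask=None):
    if config.batch_norm:
        if bn_stats is None:  # train mode: batch statistics
            mu = anp.mean(h, axis=0)
            var = anp.var(h, axis=0)
        else:
            mu, var = bn_stats
        h = (h - mu) / anp.sqrt(var + _BN_EPS)
        h = head["bn_gamma"] * h + head["bn_beta"]
    if dropout_mask is not None:
        h = h * dropout_mask
    return anp.dot(h, head["w"]) + head["b"]


def _softplus(x):
    return anp.logaddexp(0.0, x)


def _loss_from_logits(logits, labels, config: ModelConfig):
    if config.head == "binary":
        z = logits[:, 0]
        y = labels
        return anp.mean((1 - y) * z + _softplus(-z))
    if config.head == "softmax":
        lse = anp.log(anp.sum(anp.exp(logits - anp.max(logits, axis=1, keepdims=True)),
                              axis=1)) + anp.max(logits, axis=1)
        picked = logits[anp.arange(len(labels)), labels.astype(int)]
        return anp.mean(lse - picked)
    # multitask: mean binary cross-entropy over tasks
    y = labels
    return anp.mean((1 - y) * logits + _softplus(-logits))


def predict_proba(hidden, head: dict, config: ModelConfig, bn_stats=None):
    """Probabilities from hidden state(s): scalar/simplex/per-task sigmoids."""
    hidden = np.atleast_2d(np.asarray(hidden, dtype=float))
    logits = _head_logits(hidden, head, config, bn_stats=bn_stats)
    logits = np.asarray(logits)
    if config.head == "binary":
        return 1.0 / (1.0 + np.exp(-logits[:, 0]))
    if config.head == "softmax":
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)
    return 1.0 / (1.0 + np.exp(-logits))


def cooccurrence_prior(labels: np.ndarray) -> np.ndarray:
    """Symmetrized, row-normalized label co-occurrence counts (n x n).

    A task with zero positives gets a uniform row before symmetrization.
    """
    labels = np.asarray(labels, dtype=float)
    if labels.ndim != 2 or labels.shape[1] < 2:
        raise ValueError("need an N x n binary label matrix with n >= 2")
    C = labels.T @ labels
    n = C.shape[0]
    rowsum = C.sum(axis=1, keepdims=True)
    A = np.where(rowsum > 0, C / np.where(rowsum > 0, rowsum, 1.0), 1.0 / n)
    return (A + A.T) / 2.0


def prior_penalty(head_w, A: np.ndarray):
    """Graph-Laplacian quadratic sum_ij A_ij ||w_i - w_j||^2 on task weights.

    ``head_w`` is (H, n); task i's weight vector is column i.
    """
    n = A.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                diff = head_w[:, i] - head_w[:, j]
                total = total + A[i, j] * anp.sum(diff * diff)
    return total


# ---------------------------------------------------------------------------
# fitted model

@dataclass
class FittedModel:
    params: dict              # cell weights, keyed by symbol name
    head: dict
    config: ModelConfig
    norm_stats: NormalizationStats
    means: np.ndarray
    bn_stats: tuple | None
    history: list = field(default_factory=list)

    def _score_batch(self, batch: dict) -> np.ndarray:
        h = _forward_batch(self.params, batch, self.config.mode, self.means)
        probs = predict_proba(np.asarray(h), self.head, self.config,
                              bn_stats=self.bn_stats)
        return probs

    def predict_scores(self, dataset: Dataset) -> np.ndarray:
        """Class scores for a raw (unnormalized) dataset.

        Binary: (N,) positive-class probability.  Softmax: (N, L) simplex
        rows.  Multitask: (N, n) per-task probabilities.
        """
        ds = normalize(dataset, self.norm_stats)
        batch = pack_batch(ds, self.means, self.config.mode, self.config.variant)
        return self._score_batch(batch)

    def save(self, path) -> None:
        payload = {
            "config": {**asdict(self.config)},
            "params": cell_mod.params_to_jsonable(self.params),
            "head": cell_mod.params_to_jsonable(self.head),
            "norm_mean": self.norm_stats.mean.tolist(),
            "norm_std": self.norm_stats.std.tolist(),
            "norm_provenance": self.norm_stats.provenance,
            "means": np.asarray(self.means).tolist(),
            "bn_stats": None if self.bn_stats is None
            else [np.asarray(a).tolist() for a in self.bn_stats],
            "history": self.history,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "FittedModel":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = ModelConfig(**payload["config"])
        bn = payload["bn_stats"]
        return cls(
            params=cell_mod.params_from_jsonable(payload["params"]),
            head=cell_mod.params_from_jsonable(payload["head"]),
            config=cfg,
            norm_stats=NormalizationStats(
                mean=np.array(payload["norm_mean"]),
                std=np.array(payload["norm_std"]),
                provenance=payload["norm_provenance"],
            ),
            means=np.array(payload["means"]),
            bn_stats=None if bn is None else tuple(np.array(a) for a in bn),
            history=payload["history"],
        )


# ---------------------------------------------------------------------------
# fitting

def _labels_for_loss(labels: np.ndarray, config: ModelConfig) -> np.ndarray:
    labels = np.asarray(labels)
    if config.head == "multitask":
        if labels.ndim != 2:
            raise ValueError("multitask head needs an N x n label matrix")
        return labels.astype(float)
    if labels.ndim != 1:
        raise ValueError("binary/softmax heads need a label vector")
    return labels.astype(float if config.head == "binary" else int)


def _validation_metric(scores: np.ndarray, labels: np.ndarray,
                       config: ModelConfig) -> float:
    if config.head == "binary":
        return auc(scores, labels)
    if config.head == "softmax":
        vals = []
        for c in range(config.n_outputs):
            y = (labels == c).astype(int)
            if 0 < y.sum() < len(y):
                vals.append(auc(scores[:, c], y))
        return float(np.mean(vals))
    vals = []
    for j in range(config.n_outputs):
        y = labels[:, j]
        if 0 < y.sum() < len(y):
            vals.append(auc(scores[:, j], y))
    return float(np.mean(vals))


def _slice_batch(batch: dict, idx: np.ndarray) -> dict:
    return {k: v[idx] for k, v in batch.items()}


def fit(train: Dataset, valid: Dataset, config: ModelConfig) -> FittedModel:
    """Train one model with Adam, returning the best-validation checkpoint.

    Normalization statistics and empirical means come from ``train`` only.
    Recurrent dropout draws one keep-mask per sequence per update and reuses
    it at every time step on the input-side, recurrent-side and (for the
    decayed cell) mask-side gate contributions.
    """
    rng = np.random.default_rng(config.seed)
    stats = compute_normalization_stats(train)
    train_n = normalize(train, stats)
    valid_n = normalize(valid, stats)
    means = train_n.empirical_means
    D = train.D
    H = config.resolve_hidden(D)

    if config.mode == "grud":
        params = init_grud_params(rng, D, H)
        din = D
    else:
        din = input_width(config.mode, D, config.variant)
        params = init_gru_params(rng, din, H)
    head = _init_head(H, config)

    y_train = _labels_for_loss(train.labels, config)
    y_valid = np.asarray(valid.labels)
    train_batch = pack_batch(train_n, means, config.mode, config.variant)
    valid_batch = pack_batch(valid_n, means, config.mode, config.variant)

    A = None
    if config.head == "multitask" and config.prior_lambda > 0:
        A = cooccurrence_prior(y_train)

    def loss_fn(theta, batch, y, dropout, head_mask):
        logits = _head_logits(
            _forward_batch(theta["cell"], batch, config.mode, means, dropout),
            theta["head"], config, bn_stats=None, dropout_mask=head_mask,
        )
        loss = _loss_from_logits(logits, y, config)
        if A is not None:
            loss = loss + config.prior_lambda * prior_penalty(theta["head"]["w"], A)
        return loss

    loss_grad = value_and_grad(loss_fn)
    theta = {"cell": params, "head": head}
    flat, unflatten = flatten(theta)
    m_t = np.zeros_like(flat)
    v_t = np.zeros_like(flat)
    step = 0

    def eval_bn_stats(theta):
        if not config.batch_norm:
            return None
        h = np.asarray(
            _forward_batch(theta["cell"], train_batch, config.mode, means)
        )
        return h.mean(axis=0), h.var(axis=0)

    def valid_metric(theta, bn):
        h = np.asarray(
            _forward_batch(theta["cell"], valid_batch, config.mode, means)
        )
        scores = predict_proba(h, theta["head"], config, bn_stats=bn)
        return _validation_metric(scores, y_valid, config)

    n = len(train_n)
    best = {"metric": -np.inf, "flat": flat.copy(), "bn": eval_bn_stats(theta),
            "epoch": -1}
    history = []
    stall = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = _slice_batch(train_batch, idx)
            B = len(idx)
            dropout = None
            if config.recurrent_dropout > 0:
                keep = 1.0 - config.recurrent_dropout
                dropout = {
                    "dx": (rng.random((B, din)) < keep) / keep,
                    "dh": (rng.random((B, H)) < keep) / keep,
                    "dm": (rng.random((B, D)) < keep) / keep,
                }
            head_mask = None
            if config.head_dropout > 0:
                keep = 1.0 - config.head_dropout
                head_mask = (rng.random((B, H)) < keep) / keep
            theta = unflatten(flat)
            cur, g = loss_grad(theta, batch, y_train[idx], dropout, head_mask)
            g_flat, _ = flatten(g)
            if not (np.isfinite(cur) and np.all(np.isfinite(g_flat))):
                raise FloatingPointError(
                    f"divergent loss/gradient at epoch {epoch}; history={history}"
                )
            step += 1
            m_t = config.beta1 * m_t + (1 - config.beta1) * g_flat
            v_t = config.beta2 * v_t + (1 - config.beta2) * g_flat**2
            m_hat = m_t / (1 - config.beta1**step)
            v_hat = v_t / (1 - config.beta2**step)
            flat = flat - config.learning_rate * m_hat / (np.sqrt(v_hat) + config.adam_eps)
            epoch_loss += float(cur) * B
        theta = unflatten(flat)
        bn = eval_bn_stats(theta)
        metric = valid_metric(theta, bn)
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / n, "valid_metric": metric}
        )
        if metric > best["metric"]:
            best = {"metric": metric, "flat": flat.copy(), "bn": bn, "epoch": epoch}
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break

    theta = unflatten(best["flat"])
    return FittedModel(
        params={k: np.asarray(v) for k, v in theta["cell"].items()},
        head={k: np.asarray(v) for k, v in theta["head"].items()},
        config=config,
        norm_stats=stats,
        means=means,
        bn_stats=best["bn"],
        history=history,
    )


def _stratify_key(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    return labels[:, 0] if labels.ndim == 2 else labels


def split_train_valid(dataset: Dataset, frac: float, seed: int):
    """Stratified train/validation split used for early stopping."""
    key = _stratify_key(dataset.labels)
    rng = np.random.default_rng(seed)
    train_idx, valid_idx = [], []
    for c in np.unique(key):
        idx = rng.permutation(np.flatnonzero(key == c))
        n_valid = max(1, int(round(len(idx) * frac)))
        valid_idx.extend(idx[:n_valid])
        train_idx.extend(idx[n_valid:])
    return np.sort(train_idx), np.sort(valid_idx)


def evaluate_cv(dataset: Dataset, config: ModelConfig, k: int = 5,
                valid_frac: float = 0.2) -> dict:
    """Stratified k-fold cross-validated AUC (mean +/- std over folds).

    Normalization statistics and empirical means are recomputed inside each
    training fold; the held-out fold never contributes to them.
    """
    from sklearn.model_selection import StratifiedKFold

    if k < 2:
        raise ValueError("k must be >= 2")
    key = _stratify_key(dataset.labels)
    if len(np.unique(key)) < 2:
        raise ValueError("stratification requires both classes")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    fold_scores = []
    for fold, (fit_idx, test_idx) in enumerate(skf.split(np.zeros(len(key)), key)):
        fit_ds = dataset.subset(fit_idx)
        tr_idx, va_idx = split_train_valid(fit_ds, valid_frac, config.seed + fold)
        model = fit(fit_ds.subset(tr_idx), fit_ds.subset(va_idx), config)
        scores = model.predict_scores(dataset.subset(test_idx))
        labels = np.asarray(dataset.labels)[test_idx]
        fold_scores.append(_validation_metric(scores, labels, config))
    arr = np.array(fold_scores)
    return {"fold_auc": fold_scores, "mean_auc": float(arr.mean()),
            "std_auc": float(arr.std())}
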