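"""Gated recurrent cells: the standard GRU and the decay-augmented variant.

The decay-augmented cell ("grud" mode) keeps, for every variable, the time
since its last observation and learns two decay mechanisms from it:

* an *input decay* that pulls a stale last observation back toward the
  training mean (its weight is a per-variable diagonal so variables decay
  independently), and
* a *hidden decay* that attenuates the previous hidden state through a dense
  map from the full interval vector.

Both decays use the exponentiated negative rectifier
``gamma = exp(-max(0, W delta + b))``, which is monotone in each interval and
confined to (0, 1].  The mask vector is additionally fed to every gate
through dedicated matrices ``V_r, V_z, V``.

All step functions are written against ``autograd.numpy`` and are pure in
their parameters, so analytic gradients of any loss through a whole unrolled
sequence come from reverse-mode differentiation.  They accept either single
vectors or batches (leading batch axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import autograd.numpy as anp
import numpy as np

from .core import TimeSeriesSample
from .imputation import SimpleVariant, forward_impute, mean_impute, simple_concat

__all__ = [
    "GRUParameters",
    "GRUDParameters",
    "LastObservationState",
    "decay_rate",
    "apply_input_decay",
    "apply_hidden_decay",
    "gru_step",
    "grud_step",
    "forward_sequence",
    "count_parameters",
    "match_hidden_size",
    "init_gru_params",
    "init_grud_params",
    "MODES",
]

MODES = ("grud", "gru_mean", "gru_forward", "gru_simple")

_GRU_KEYS = ("W_r", "W_z", "W", "U_r", "U_z", "U", "b_r", "b_z", "b")
_GRUD_EXTRA_KEYS = ("V_r", "V_z", "V", "w_gamma_x", "b_gamma_x", "W_gamma_h", "b_gamma_h")


@dataclass
class GRUParameters:
    """Weights of a plain GRU: gate input/recurrent matrices and biases."""

    W_r: np.ndarray
    W_z: np.ndarray
    W: np.ndarray
    U_r: np.ndarray
    U_z: np.ndarray
    U: np.ndarray
    b_r: np.ndarray
    b_z: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        H, Din = self.W_r.shape
        for name in ("W_z", "W"):
            if getattr(self, name).shape != (H, Din):
                raise ValueError(f"{name} must be H x Din")
        for name in ("U_r", "U_z", "U"):
            if getattr(self, name).shape != (H, H):
                raise ValueError(f"{name} must be H x H")
        for name in ("b_r", "b_z", "b"):
            if getattr(self, name).shape != (H,):
                raise ValueError(f"{name} must have length H")

    @property
    def hidden_size(self) -> int:
        return self.W_r.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_r.shape[1]

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "GRUParameters":
        return cls(**{f.name: np.asarray(d[f.name]) for f in fields(cls)})


@dataclass
class GRUDParameters(GRUParameters):
    """GRU weights plus mask matrices and the two decay parameter sets.

    The input-decay weight is stored as a length-D vector — the diagonal of
    the full matrix — enforcing per-variable independence; the hidden-decay
    weight is a dense H x D matrix.
    """

    V_r: np.ndarray = None
    V_z: np.ndarray = None
    V: np.ndarray = None
    w_gamma_x: np.ndarray = None
    b_gamma_x: np.ndarray = None
    W_gamma_h: np.ndarray = None
    b_gamma_h: np.ndarray = None

    def __post_init__(self):
        super().__post_init__()
        H, D = self.W_r.shape
        for name in ("V_r", "V_z", "V"):
            if getattr(self, name).shape != (H, D):
                raise ValueError(f"{name} must be H x D")
        if self.w_gamma_x.shape != (D,) or self.b_gamma_x.shape != (D,):
            raise ValueError("input-decay parameters must have length D")
        if self.W_gamma_h.shape != (H, D):
            raise ValueError("W_gamma_h must be H x D")
        if self.b_gamma_h.shape != (H,):
            raise ValueError("b_gamma_h must have length H")


@dataclass
class LastObservationState:
    """Carry of each variable's most recent observation across steps."""

    last_values: np.ndarray
    seen: np.ndarray

    @classmethod
    def initial(cls, D: int) -> "LastObservationState":
        return cls(last_values=np.zeros(D), seen=np.zeros(D))

    def updated(self, x: np.ndarray, m: np.ndarray) -> "LastObservationState":
        return LastObservationState(
            last_values=np.where(m == 1, x, self.last_values),
            seen=np.maximum(self.seen, m),
        )


def _pdict(params) -> dict:
    return params.to_dict() if hasattr(params, "to_dict") else params


def decay_rate(delta, weight, bias):
    """gamma = exp(-max(0, W delta + b)), elementwise in (0, 1].

    ``weight`` is either a vector (diagonal / per-variable case, output has
    delta's length) or a dense matrix (output has the bias's length).
    """
    if not hasattr(delta, "_value"):  # plain (untraced) input: validate
        delta = np.asarray(delta, dtype=float)
        if np.any(delta < 0):
            raise ValueError("intervals must be nonnegative")
    if not hasattr(weight, "ndim"):
        weight = np.asarray(weight, dtype=float)
    if weight.ndim <= 1:
        pre = weight * delta + bias
    else:
        pre = anp.dot(delta, weight.T) + bias
    return anp.exp(-anp.maximum(0.0, pre))


def apply_input_decay(x, m, last: LastObservationState, means, gamma_x):
    """Blend stale last observations toward the mean where unobserved.

    Observed entries pass through.  Where nothing has been seen yet the
    output is the mean regardless of gamma.
    """
    base = np.where(last.seen == 1, last.last_values, means)
    fallback = anp.where(
        last.seen == 1, gamma_x * base + (1 - gamma_x) * means, means
    )
    return m * x + (1 - m) * fallback


def apply_hidden_decay(h_prev, gamma_h):
    """h_hat = gamma_h * h_prev, elementwise."""
    if h_prev.shape != gamma_h.shape:
        raise ValueError("gamma_h must match h_prev's shape")
    return gamma_h * h_prev


def _sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def gru_step(x, h_prev, params):
    """One plain-GRU update. Accepts (Din,)/(H,) vectors or (B, .) batches."""
    p = _pdict(params)
    if isinstance(x, np.ndarray) and not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite input to gru_step")
    if isinstance(h_prev, np.ndarray) and not np.all(np.isfinite(h_prev)):
        raise FloatingPointError("non-finite hidden state in gru_step")
    r = _sigmoid(anp.dot(x, p["W_r"].T) + anp.dot(h_prev, p["U_r"].T) + p["b_r"])
    z = _sigmoid(anp.dot(x, p["W_z"].T) + anp.dot(h_prev, p["U_z"].T) + p["b_z"])
    h_tilde = anp.tanh(
        anp.dot(x, p["W"].T) + anp.dot(r * h_prev, p["U"].T) + p["b"]
    )
    return (1 - z) * h_prev + z * h_tilde


def _grud_core(x_hat, m, delta, h_prev, p, dropout=None, trace=None):
    """Shared decayed-GRU math given an already input-decayed x_hat.

    ``dropout`` optionally holds per-sequence keep masks for the input-side
    (``dx``), recurrent-side (``dh``) and mask-side (``dm``) contributions.
    """
    gamma_h = decay_rate(delta, p["W_gamma_h"], p["b_gamma_h"])
    h_hat = gamma_h * h_prev
    xg, hg, mg = x_hat, h_hat, m
    if dropout is not None:
        xg = xg * dropout["dx"]
        hg = hg * dropout["dh"]
        mg = mg * dropout["dm"]
    r = _sigmoid(
        anp.dot(xg, p["W_r"].T) + anp.dot(hg, p["U_r"].T) + anp.dot(mg, p["V_r"].T) + p["b_r"]
    )
    z = _sigmoid(
        anp.dot(xg, p["W_z"].T) + anp.dot(hg, p["U_z"].T) + anp.dot(mg, p["V_z"].T) + p["b_z"]
    )
    h_tilde = anp.tanh(
        anp.dot(xg, p["W"].T) + anp.dot(r * hg, p["U"].T) + anp.dot(mg, p["V"].T) + p["b"]
    )
    h = (1 - z) * h_hat + z * h_tilde
    if trace is not None:
        trace.update(r=r, z=z, h_tilde=h_tilde, h_hat=h_hat, gamma_h=gamma_h)
    return h


def grud_step(x, m, delta, h_prev, last: LastObservationState, means, params,
              trace: dict | None = None):
    """One decayed-GRU update; returns (h, updated last-observation state).

    ``trace``, if given, is filled with the internal gate activations —
    test-only, not part of the public contract.
    """
    p = _pdict(params)
    gamma_x = decay_rate(delta, p["w_gamma_x"], p["b_gamma_x"])
    x_hat = apply_input_decay(x, m, last, means, gamma_x)
    h = _grud_core(x_hat, m, delta, h_prev, p, trace=trace)
    if trace is not None:
        trace.update(gamma_x=gamma_x, x_hat=x_hat)
    return h, last.updated(x, m)


def forward_sequence(sample: TimeSeriesSample, params, means, mode: str,
                     variant: SimpleVariant = SimpleVariant()):
    """Unroll one sample from h_0 = 0, returning all hidden states (T, H).

    For the baseline modes the sample is first pushed through the matching
    imputation pipeline and fed to a plain GRU; "grud" runs the decayed cell.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    p = _pdict(params)
    H = p["W_r"].shape[0]
    h = np.zeros(H)
    out = []
    if mode == "grud":
        last = LastObservationState.initial(sample.D)
        for t in range(sample.T):
            h, last = grud_step(
                sample.values[t], sample.mask[t], sample.intervals[t],
                h, last, means, p,
            )
            out.append(h)
    else:
        if mode == "gru_mean":
            inputs = mean_impute(sample, means)
        elif mode == "gru_forward":
            inputs = forward_impute(sample, means)
        else:
            inputs = simple_concat(sample, mean_impute(sample, means), variant)
        if inputs.shape[1] != p["W_r"].shape[1]:
            raise ValueError(
                f"mode {mode!r} needs input width {inputs.shape[1]}, "
                f"parameters expect {p['W_r'].shape[1]}"
            )
        for t in range(sample.T):
            h = gru_step(inputs[t], h, p)
            out.append(h)
    return np.stack(out)


def _head_count(head_spec, H: int) -> int:
    if head_spec is None:
        return 0
    n_out = head_spec["n_out"]
    n = n_out * (H + 1)
    if head_spec.get("batch_norm", False):
        n += 2 * H
    return n


def input_width(mode: str, D: int, variant: SimpleVariant = SimpleVariant()) -> int:
    if mode == "gru_simple":
        return variant.width_factor * D
    return D


def count_parameters(mode: str, D: int, H: int, head_spec: dict | None = None,
                     variant: SimpleVariant = SimpleVariant()) -> int:
    """Exact count of trainable scalars for one cell + optional head."""
    if mode == "grud":
        n = 3 * (H * D + H * H + H * D + H)  # gates: W, U, V, b
        n += 2 * D                           # input decay (diagonal w, b)
        n += H * D + H                       # hidden decay
    else:
        Din = input_width(mode, D, variant)
        n = 3 * (H * Din + H * H + H)
    return n + _head_count(head_spec, H)


def match_hidden_size(reference_count: int, mode: str, D: int,
                      head_spec: dict | None = None,
                      variant: SimpleVariant = SimpleVariant()) -> int:
    """Largest H whose parameter count does not exceed ``reference_count``."""
    if count_parameters(mode, D, 1, head_spec, variant) > reference_count:
        raise ValueError("no feasible hidden size >= 1 fits the reference count")
    H = 1
    while count_parameters(mode, D, H + 1, head_spec, variant) <= reference_count:
        H += 1
    return H


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    fan_out, fan_in = shape
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


def init_gru_params(rng: np.random.Generator, Din: int, H: int) -> dict:
    """Fan-based uniform gate weights, zero biases."""
    p = {}
    for k in ("W_r", "W_z", "W"):
        p[k] = _glorot(rng, (H, Din))
    for k in ("U_r", "U_z", "U"):
        p[k] = _glorot(rng, (H, H))
    for k in ("b_r", "b_z", "b"):
        p[k] = np.zeros(H)
    return p


def init_grud_params(rng: np.random.Generator, D: int, H: int) -> dict:
    """Gate weights as for the GRU; decay parameters start at 0 (gamma = 1)."""
    p = init_gru_params(rng, D, H)
    for k in ("V_r", "V_z", "V"):
        p[k] = _glorot(rng, (H, D))
    p["w_gamma_x"] = np.zeros(D)
    p["b_gamma_x"] = np.zeros(D)
    p["W_gamma_h"] = np.zeros((H, D))
    p["b_gamma_h"] = np.zeros(H)
    return p


def params_to_jsonable(p: dict) -> dict:
    """Named-array checkpoint payload (lists of lists, keyed by symbol)."""
    return {k: np.asarray(v).tolist() for k, v in _pdict(p).items()}


def params_from_jsonable(d: dict) -> dict:
    return {k: np.asarray(v, dtype=float) for k, v in d.items()}
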