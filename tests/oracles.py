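"""Independent scalar-loop reference implementations used by several tests.

Everything here is deliberately written with explicit per-unit Python loops
and no shared code with the package, so agreement is a genuine two-route
check.
"""

import math

import numpy as np


def sigmoid(v):
    return 1.0 / (1.0 + math.exp(-v))


def interval_oracle(stamps, mask):
    T, D = mask.shape
    out = np.zeros((T, D))
    for d in range(D):
        elapsed = 0.0
        for t in range(1, T):
            gap = stamps[t] - stamps[t - 1]
            elapsed = gap if mask[t - 1, d] == 1 else elapsed + gap
            out[t, d] = elapsed
    return out


def decay_oracle_diag(delta, w, b):
    return np.array(
        [math.exp(-max(0.0, w[d] * delta[d] + b[d])) for d in range(len(delta))]
    )


def decay_oracle_dense(delta, W, b):
    H, D = W.shape
    out = np.empty(H)
    for j in range(H):
        pre = b[j]
        for d in range(D):
            pre += W[j, d] * delta[d]
        out[j] = math.exp(-max(0.0, pre))
    return out


def gru_step_oracle(x, h_prev, p):
    H = p["U_r"].shape[0]
    Din = len(x)
    r = np.empty(H)
    z = np.empty(H)
    for j in range(H):
        ar = p["b_r"][j] + sum(p["W_r"][j, i] * x[i] for i in range(Din))
        az = p["b_z"][j] + sum(p["W_z"][j, i] * x[i] for i in range(Din))
        for k in range(H):
            ar += p["U_r"][j, k] * h_prev[k]
            az += p["U_z"][j, k] * h_prev[k]
        r[j] = sigmoid(ar)
        z[j] = sigmoid(az)
    h = np.empty(H)
    for j in range(H):
        a = p["b"][j] + sum(p["W"][j, i] * x[i] for i in range(Din))
        for k in range(H):
            a += p["U"][j, k] * r[k] * h_prev[k]
        h[j] = (1 - z[j]) * h_prev[j] + z[j] * math.tanh(a)
    return h


def grud_step_oracle(x, m, delta, h_prev, last_vals, seen, means, p):
    """One decayed-GRU step, fully scalar; returns (h, new_last, new_seen)."""
    D = len(x)
    H = p["U_r"].shape[0]
    gamma_x = decay_oracle_diag(delta, p["w_gamma_x"], p["b_gamma_x"])
    x_hat = np.empty(D)
    for d in range(D):
        if m[d] == 1:
            x_hat[d] = x[d]
        elif seen[d] == 1:
            x_hat[d] = gamma_x[d] * last_vals[d] + (1 - gamma_x[d]) * means[d]
        else:
            x_hat[d] = means[d]
    gamma_h = decay_oracle_dense(delta, p["W_gamma_h"], p["b_gamma_h"])
    h_hat = np.array([gamma_h[j] * h_prev[j] for j in range(H)])
    r = np.empty(H)
    z = np.empty(H)
    for j in range(H):
        ar = p["b_r"][j]
        az = p["b_z"][j]
        for d in range(D):
            ar += p["W_r"][j, d] * x_hat[d] + p["V_r"][j, d] * m[d]
            az += p["W_z"][j, d] * x_hat[d] + p["V_z"][j, d] * m[d]
        for k in range(H):
            ar += p["U_r"][j, k] * h_hat[k]
            az += p["U_z"][j, k] * h_hat[k]
        r[j] = sigmoid(ar)
        z[j] = sigmoid(az)
    h = np.empty(H)
    for j in range(H):
        a = p["b"][j]
        for d in range(D):
            a += p["W"][j, d] * x_hat[d] + p["V"][j, d] * m[d]
        for k in range(H):
            a += p["U"][j, k] * r[k] * h_hat[k]
        h[j] = (1 - z[j]) * h_hat[j] + z[j] * math.tanh(a)
    new_last = np.where(m == 1, x, last_vals)
    new_seen = np.maximum(seen, m)
    return h, new_last, new_seen


def auc_pair_oracle(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_grud_params(rng, D, H, scale=0.5, decay_scale=0.5):
    p = {}
    for k in ("W_r", "W_z", "W", "V_r", "V_z", "V"):
        p[k] = rng.normal(scale=scale, size=(H, D))
    for k in ("U_r", "U_z", "U"):
        p[k] = rng.normal(scale=scale, size=(H, H))
    for k in ("b_r", "b_z", "b"):
        p[k] = rng.normal(scale=scale, size=H)
    p["w_gamma_x"] = rng.normal(scale=decay_scale, size=D)
    p["b_gamma_x"] = rng.normal(scale=decay_scale, size=D)
    p["W_gamma_h"] = rng.normal(scale=decay_scale, size=(H, D))
    p["b_gamma_h"] = rng.normal(scale=decay_scale, size=H)
    return p


def random_gru_params(rng, Din, H, scale=0.5):
    p = {}
    for k in ("W_r", "W_z", "W"):
        p[k] = rng.normal(scale=scale, size=(H, Din))
    for k in ("U_r", "U_z", "U"):
        p[k] = rng.normal(scale=scale, size=(H, H))
    for k in ("b_r", "b_z", "b"):
        p[k] = rng.normal(scale=scale, size=H)
    return p
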