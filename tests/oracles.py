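"""Independent brute-force oracles used by the tests.

Everything here is written as plain loops, straight from the defining
formulas, deliberately sharing no code with the package implementation.
"""

import numpy as np


def naive_squash(s):
    s = np.asarray(s, dtype=float)
    a = np.sqrt((s * s).sum())
    if a == 0.0:
        return np.zeros_like(s)
    return (a * a / (1.0 + a * a)) * (s / a)


def naive_conv2d(x, w, b, stride):
    """x: (C, H, W); w: (F, C, k, k); valid convolution, no padding."""
    C, H, W = x.shape
    F, _, k, _ = w.shape
    h = (H - k) // stride + 1
    wd = (W - k) // stride + 1
    out = np.zeros((F, h, wd))
    for f in range(F):
        for i in range(h):
            for j in range(wd):
                patch = x[:, i * stride:i * stride + k, j * stride:j * stride + k]
                out[f, i, j] = (patch * w[f]).sum() + b[f]
    return out


def naive_routing(u_hat, r):
    """u_hat: (L, J, n). Returns (V, c) after r iterations."""
    L, J, n = u_hat.shape
    b = np.zeros((L, J))
    for t in range(r):
        c = np.zeros((L, J))
        for i in range(L):
            e = np.exp(b[i] - b[i].max())
            c[i] = e / e.sum()
        V = np.zeros((J, n))
        for j in range(J):
            S = np.zeros(n)
            for i in range(L):
                S += c[i, j] * u_hat[i, j]
            V[j] = naive_squash(S)
        if t < r - 1:
            for i in range(L):
                for j in range(J):
                    b[i, j] += u_hat[i, j] @ V[j]
    return V, c


def naive_capsnet_forward(x, params, cfg):
    """Single image (N, N) through conv -> primary capsules -> routing -> lengths,
    written as straight-line loops over the defining equations."""
    z1 = naive_conv2d(x[None], params["conv1_w"], params["conv1_b"], cfg.frontend_stride)
    a1 = np.maximum(z1, 0.0)
    z2 = naive_conv2d(a1, params["conv2_w"], params["conv2_b"], cfg.primary_stride)
    g = cfg.primary_grid
    u = []
    for i in range(g):              # grid-major capsule order, channel blocks of m
        for j in range(g):
            for ch in range(cfg.primary_channels):
                vec = np.array([z2[ch * cfg.m + d, i, j] for d in range(cfg.m)])
                u.append(naive_squash(vec))
    u = np.array(u)                 # (L, m)
    L = u.shape[0]
    J = cfg.num_classes
    u_hat = np.zeros((L, J, cfg.n))
    for i in range(L):
        for j in range(J):
            u_hat[i, j] = params["W"][i, j] @ u[i]
    V, c = naive_routing(u_hat, cfg.routing_iterations)
    p = np.array([np.sqrt((V[j] ** 2).sum()) for j in range(J)])
    return p, V, u


def naive_auc(scores, labels):
    """Pair-enumeration AUC with ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))
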