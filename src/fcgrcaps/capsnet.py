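"""Capsule network over FCGR images, in pure NumPy with reverse-mode gradients.

Architecture (both classification stages use the same shape):

    FCGR image -> Conv2D + ReLU (frontend)
               -> Conv2D, reshaped into L primary capsules of dimension m, squashed
               -> prediction vectors u_hat[j|i] = W[i,j] @ u[i]
               -> dynamic routing (r iterations) -> J type capsules V_j of dimension n
               -> class probabilities p_j = ||V_j||

The squash nonlinearity keeps a vector's direction and maps its norm ``a`` to
``a^2 / (1 + a^2) < 1``, so a capsule's length reads as a presence
probability.  Routing starts from uniform coupling coefficients (softmax of
zero logits) and sharpens them by the agreement ``u_hat . V`` between each
primary capsule's prediction and the current type capsule.

Training minimizes the margin loss on capsule lengths (the canonical capsule
objective): the true class is pushed above ``m_plus``, the other class below
``m_minus`` with down-weight ``lambda_down``; there is no reconstruction
decoder.  All gradients here are written by hand and checked against finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "CapsNetConfig",
    "ConfigurationError",
    "small_config",
    "full_scale_config",
    "tiny_config",
    "squash",
    "compute_prediction_vectors",
    "dynamic_routing",
    "capsule_lengths",
    "margin_loss",
    "scale_images",
    "init_capsnet_params",
    "init_densehead_params",
    "CapsNet",
    "DenseHeadNet",
    "Adam",
]


class ConfigurationError(ValueError):
    """Inconsistent architecture hyperparameters or tensor shapes."""


def _conv_out(size: int, kernel: int, stride: int) -> int:
    return (size - kernel) // stride + 1


@dataclass
class CapsNetConfig:
    """Architecture hyperparameters.

    ``m`` is the primary-capsule dimension, ``n`` the type-capsule dimension,
    ``routing_iterations`` the number r of routing passes.  The primary layer
    is a convolution with ``primary_channels * m`` output channels reshaped
    into ``L = h^2 * primary_channels`` capsules, where h is its output grid
    size.  ``num_classes`` (J) is 2: one positive and one negative capsule.
    """

    input_resolution: int = 64
    frontend_filters: int = 16
    frontend_kernel: int = 9
    frontend_stride: int = 2
    primary_channels: int = 4
    primary_kernel: int = 9
    primary_stride: int = 2
    m: int = 8
    n: int = 32
    num_classes: int = 2
    routing_iterations: int = 3
    m_plus: float = 0.9
    m_minus: float = 0.1
    lambda_down: float = 0.5
    input_scaling: str = "per_max"

    def __post_init__(self):
        if min(self.frontend_filters, self.primary_channels, self.m, self.n,
               self.routing_iterations, self.num_classes) < 1:
            raise ConfigurationError(
                f"all architecture sizes must be >= 1, got {asdict(self)}")
        if self.input_scaling not in ("per_max", "per_total", "none"):
            raise ConfigurationError(f"unknown input_scaling {self.input_scaling!r}")
        if self.frontend_grid < 1 or self.primary_grid < 1:
            raise ConfigurationError(
                f"conv geometry collapses: input {self.input_resolution} -> "
                f"frontend grid {self.frontend_grid} -> primary grid {self.primary_grid}")

    @property
    def frontend_grid(self) -> int:
        return _conv_out(self.input_resolution, self.frontend_kernel, self.frontend_stride)

    @property
    def primary_grid(self) -> int:
        return _conv_out(self.frontend_grid, self.primary_kernel, self.primary_stride)

    @property
    def num_primary_capsules(self) -> int:
        """L: capsule-grid positions times capsule channels."""
        return self.primary_grid ** 2 * self.primary_channels


def small_config(input_resolution: int = 64, **overrides) -> CapsNetConfig:
    """Default compact geometry for CPU training (the package default)."""
    return CapsNetConfig(input_resolution=input_resolution, **overrides)


def full_scale_config(input_resolution: int = 64, **overrides) -> CapsNetConfig:
    """Sabour-style geometry: stride-1 frontend with 32 filters, 8 capsule
    channels — much heavier; intended for full-scale training runs."""
    kw = dict(frontend_filters=32, frontend_stride=1, primary_channels=8)
    kw.update(overrides)
    return CapsNetConfig(input_resolution=input_resolution, **kw)


def tiny_config(**overrides) -> CapsNetConfig:
    """Minimal geometry for unit tests and gradient checks."""
    kw = dict(input_resolution=8, frontend_filters=2, frontend_kernel=3,
              frontend_stride=1, primary_channels=1, primary_kernel=3,
              primary_stride=2, m=2, n=3, routing_iterations=2)
    kw.update(overrides)
    return CapsNetConfig(**kw)


# ---------------------------------------------------------------------------
# capsule math (functional, batched along leading axes)
# ---------------------------------------------------------------------------

def squash(s: np.ndarray, axis: int = -1) -> np.ndarray:
    """v = (||s||^2 / (1 + ||s||^2)) * s / ||s||, with squash(0) = 0 exactly.

    Computed as ``s * ||s|| / (1 + ||s||^2)`` so no division by zero occurs.
    """
    s = np.asarray(s, dtype=np.float64)
    a2 = np.sum(s * s, axis=axis, keepdims=True)
    return s * (np.sqrt(a2) / (1.0 + a2))


def _squash_backward(dv: np.ndarray, s: np.ndarray, axis: int = -1) -> np.ndarray:
    # v = h(a) s with a = ||s||, h(a) = a/(1+a^2); h'(a) = (1-a^2)/(1+a^2)^2
    a2 = np.sum(s * s, axis=axis, keepdims=True)
    a = np.sqrt(a2)
    h = a / (1.0 + a2)
    hp = (1.0 - a2) / (1.0 + a2) ** 2
    dot = np.sum(dv * s, axis=axis, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = np.where(a > 1e-30, hp * dot / a, 0.0)
    return h * dv + coef * s


def compute_prediction_vectors(u: np.ndarray, W: np.ndarray) -> np.ndarray:
    """u_hat[j|i] = W[i, j] @ u[i] for every primary/type capsule pair.

    ``u``: (..., L, m); ``W``: (L, J, n, m); returns (..., L, J, n).
    """
    u = np.asarray(u, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if W.ndim != 4 or u.shape[-1] != W.shape[-1] or u.shape[-2] != W.shape[0]:
        raise ConfigurationError(
            f"shape mismatch: u {u.shape} vs W {W.shape} "
            f"(need u (..., L={W.shape[0] if W.ndim == 4 else '?'}, m={W.shape[-1] if W.ndim == 4 else '?'}))")
    return np.einsum("ljnm,...lm->...ljn", W, u)


def dynamic_routing(u_hat: np.ndarray, r: int, return_cache: bool = False):
    """Route prediction vectors to type capsules.

    ``u_hat``: (..., L, J, n).  Logits start at zero; each iteration computes
    coupling coefficients c = softmax_j(b), the weighted sum S_j, the squashed
    output V_j, and (on all but the last iteration) the agreement update
    ``b += u_hat . V``.  Returns ``(V, c)`` of shapes (..., J, n) and
    (..., L, J).
    """
    u_hat = np.asarray(u_hat, dtype=np.float64)
    if r < 1:
        raise ConfigurationError(f"routing_iterations must be >= 1, got {r}")
    if not np.all(np.isfinite(u_hat)):
        raise FloatingPointError("non-finite prediction vectors entering routing")
    b = np.zeros(u_hat.shape[:-1], dtype=np.float64)  # (..., L, J)
    cache = []
    V = c = None
    for t in range(r):
        bmax = b.max(axis=-1, keepdims=True)
        e = np.exp(b - bmax)
        c = e / e.sum(axis=-1, keepdims=True)
        S = np.einsum("...lj,...ljn->...jn", c, u_hat)
        V = squash(S)
        cache.append((c, S, V))
        if t < r - 1:
            b = b + np.einsum("...ljn,...jn->...lj", u_hat, V)
    if return_cache:
        return V, c, cache
    return V, c


def _routing_backward(dV_final: np.ndarray, u_hat: np.ndarray, cache) -> np.ndarray:
    """Gradient of the routing output w.r.t. u_hat, unrolled through all
    iterations (coupling coefficients are functions of u_hat too)."""
    r = len(cache)
    du_hat = np.zeros_like(u_hat)
    db = np.zeros(u_hat.shape[:-1], dtype=np.float64)
    for t in reversed(range(r)):
        c, S, V = cache[t]
        if t == r - 1:
            dV = np.array(dV_final, dtype=np.float64)
        else:
            # b_{t+1} = b_t + u_hat . V_t ; db holds dL/db_{t+1}
            du_hat += db[..., None] * V[..., None, :, :]
            dV = np.einsum("...lj,...ljn->...jn", db, u_hat)
        dS = _squash_backward(dV, S)
        dc = np.einsum("...jn,...ljn->...lj", dS, u_hat)
        du_hat += c[..., None] * dS[..., None, :, :]
        db_local = c * (dc - np.sum(c * dc, axis=-1, keepdims=True))
        db = db + db_local
    return du_hat


def capsule_lengths(V: np.ndarray, axis: int = -1) -> np.ndarray:
    """p_j = ||V_j||: the length of each type capsule as a class probability."""
    return np.linalg.norm(np.asarray(V, dtype=np.float64), axis=axis)


def margin_loss(p: np.ndarray, label, m_plus: float = 0.9, m_minus: float = 0.1,
                lambda_down: float = 0.5) -> float | np.ndarray:
    """Margin loss on capsule lengths.

    ``p``: (J,) or (B, J) lengths in [0, 1); ``label``: true class index
    (scalar or (B,)).  Returns the per-example loss (scalar for a single
    example, (B,) for a batch).
    """
    p = np.asarray(p, dtype=np.float64)
    single = p.ndim == 1
    pb = p[None, :] if single else p
    yb = np.atleast_1d(np.asarray(label, dtype=np.int64))
    T = np.zeros_like(pb)
    T[np.arange(pb.shape[0]), yb] = 1.0
    pos = np.maximum(0.0, m_plus - pb) ** 2
    neg = np.maximum(0.0, pb - m_minus) ** 2
    loss = np.sum(T * pos + lambda_down * (1.0 - T) * neg, axis=1)
    return float(loss[0]) if single else loss


def _margin_loss_grad(p, y, m_plus, m_minus, lambda_down):
    """dL/dp for the batch-mean margin loss."""
    B = p.shape[0]
    T = np.zeros_like(p)
    T[np.arange(B), y] = 1.0
    dp = (T * (-2.0 * np.maximum(0.0, m_plus - p))
          + lambda_down * (1.0 - T) * 2.0 * np.maximum(0.0, p - m_minus))
    return dp / B


def scale_images(X: np.ndarray, mode: str) -> np.ndarray:
    """Scale raw FCGR count images at the network input boundary."""
    X = np.asarray(X, dtype=np.float64)
    if mode == "none":
        return X
    if mode == "per_max":
        denom = X.max(axis=(-2, -1), keepdims=True)
    elif mode == "per_total":
        denom = X.sum(axis=(-2, -1), keepdims=True)
    else:
        raise ConfigurationError(f"unknown input scaling {mode!r}")
    return np.where(denom > 0, X / np.where(denom > 0, denom, 1.0), 0.0)


# ---------------------------------------------------------------------------
# conv plumbing (im2col)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, s: int) -> np.ndarray:
    # x: (B, C, H, W) -> (B, C*k*k, h*w)
    B, C = x.shape[:2]
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::s, ::s]                       # (B, C, h, w, k, k)
    h, w = win.shape[2], win.shape[3]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(B, C * k * k, h * w)
    return np.ascontiguousarray(cols)


def _conv_forward(x, w, b, s):
    B = x.shape[0]
    F, C, k, _ = w.shape
    cols = _im2col(x, k, s)
    out = w.reshape(F, -1) @ cols + b[:, None]      # (B, F, P) via broadcasting
    h = _conv_out(x.shape[2], k, s)
    wd = _conv_out(x.shape[3], k, s)
    return out.reshape(B, F, h, wd), cols


def _conv_backward(dout, cols, w, x_shape, s):
    B, F = dout.shape[:2]
    k = w.shape[2]
    dflat = dout.reshape(B, F, -1)
    dw = np.einsum("bfp,bcp->fc", dflat, cols).reshape(w.shape)
    db = dflat.sum(axis=(0, 2))
    dcols = np.einsum("fc,bfp->bcp", w.reshape(F, -1), dflat)
    # col2im scatter-add
    Bx, C, H, W = x_shape
    h = _conv_out(H, k, s)
    wd = _conv_out(W, k, s)
    dcols = dcols.reshape(B, C, k, k, h, wd)
    dx = np.zeros(x_shape, dtype=np.float64)
    for ki in range(k):
        for kj in range(k):
            dx[:, :, ki:ki + s * h:s, kj:kj + s * wd:s] += dcols[:, :, ki, kj]
    return dx, dw, db


def _he_init(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def init_capsnet_params(config: CapsNetConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """He-initialized conv kernels; routing weight matrices W ~ N(0, 0.1)."""
    c = config
    k1, k2 = c.frontend_kernel, c.primary_kernel
    c2_out = c.primary_channels * c.m
    return {
        "conv1_w": _he_init(rng, (c.frontend_filters, 1, k1, k1), k1 * k1),
        "conv1_b": np.zeros(c.frontend_filters),
        "conv2_w": _he_init(rng, (c2_out, c.frontend_filters, k2, k2),
                            c.frontend_filters * k2 * k2),
        "conv2_b": np.zeros(c2_out),
        "W": rng.normal(0.0, 0.1, size=(c.num_primary_capsules, c.num_classes, c.n, c.m)),
    }


class CapsNet:
    """Forward/backward of the full capsule classifier on image batches.

    Holds a config and a parameter dict; the sklearn estimator wraps this with
    a training loop.  ``forward`` exposes the primary-capsule activities u,
    the type capsules V and the coupling coefficients c for embedding export
    and diagnostics.
    """

    param_names = ("conv1_w", "conv1_b", "conv2_w", "conv2_b", "W")

    def __init__(self, config: CapsNetConfig, params: dict[str, np.ndarray] | None = None,
                 rng: np.random.Generator | None = None):
        self.config = config
        if params is None:
            params = init_capsnet_params(config, rng or np.random.default_rng())
        self.params = params
        L, J = config.num_primary_capsules, config.num_classes
        if params["W"].shape != (L, J, config.n, config.m):
            raise ConfigurationError(
                f"W shape {params['W'].shape} inconsistent with config "
                f"(L={L}, J={J}, n={config.n}, m={config.m})")

    def forward(self, X: np.ndarray, want_cache: bool = False) -> dict:
        """X: (B, N, N) scaled images -> dict with p, V, u, c (+ cache)."""
        c = self.config
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1] != c.input_resolution or X.shape[2] != c.input_resolution:
            raise ConfigurationError(
                f"image resolution {X.shape[1:]} does not match config N={c.input_resolution}")
        x = X[:, None, :, :]                                     # (B, 1, N, N)
        p = self.params
        z1, cols1 = _conv_forward(x, p["conv1_w"], p["conv1_b"], c.frontend_stride)
        a1 = np.maximum(z1, 0.0)
        z2, cols2 = _conv_forward(a1, p["conv2_w"], p["conv2_b"], c.primary_stride)
        B = X.shape[0]
        g = c.primary_grid
        # channels grouped as (capsule_channel, m); capsules ordered grid-major
        u_raw = (z2.reshape(B, c.primary_channels, c.m, g, g)
                 .transpose(0, 3, 4, 1, 2)
                 .reshape(B, c.num_primary_capsules, c.m))
        u = squash(u_raw)
        u_hat = compute_prediction_vectors(u, p["W"])
        V, coup, rcache = dynamic_routing(u_hat, c.routing_iterations, return_cache=True)
        lengths = capsule_lengths(V)
        out = {"p": lengths, "V": V, "u": u, "c": coup}
        if want_cache:
            out["cache"] = {"x": x, "cols1": cols1, "z1": z1, "a1": a1,
                            "cols2": cols2, "z2": z2, "u_raw": u_raw, "u": u,
                            "u_hat": u_hat, "rcache": rcache}
        return out

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        """Batch-mean margin loss and gradients for every parameter."""
        c = self.config
        out = self.forward(X, want_cache=True)
        cache = out["cache"]
        p_len, V = out["p"], out["V"]
        y = np.asarray(y, dtype=np.int64)
        loss = float(np.mean(margin_loss(p_len, y, c.m_plus, c.m_minus, c.lambda_down)))

        dp = _margin_loss_grad(p_len, y, c.m_plus, c.m_minus, c.lambda_down)
        with np.errstate(divide="ignore", invalid="ignore"):
            unit = np.where(p_len[..., None] > 1e-30, V / np.where(
                p_len[..., None] > 1e-30, p_len[..., None], 1.0), 0.0)
        dV = dp[..., None] * unit
        du_hat = _routing_backward(dV, cache["u_hat"], cache["rcache"])
        dW = np.einsum("bljn,blm->ljnm", du_hat, cache["u"])
        du = np.einsum("ljnm,bljn->blm", self.params["W"], du_hat)
        du_raw = _squash_backward(du, cache["u_raw"])
        B = X.shape[0]
        g = c.primary_grid
        dz2 = (du_raw.reshape(B, g, g, c.primary_channels, c.m)
               .transpose(0, 3, 4, 1, 2)
               .reshape(B, c.primary_channels * c.m, g, g))
        da1, dw2, db2 = _conv_backward(dz2, cache["cols2"], self.params["conv2_w"],
                                       cache["a1"].shape, c.primary_stride)
        dz1 = da1 * (cache["z1"] > 0)
        _, dw1, db1 = _conv_backward(dz1, cache["cols1"], self.params["conv1_w"],
                                     cache["x"].shape, c.frontend_stride)
        grads = {"conv1_w": dw1, "conv1_b": db1, "conv2_w": dw2, "conv2_b": db2, "W": dW}
        return loss, grads


# ---------------------------------------------------------------------------
# dense-head ablation network
# ---------------------------------------------------------------------------

def init_densehead_params(config: CapsNetConfig, rng: np.random.Generator,
                          hidden: int = 64) -> dict[str, np.ndarray]:
    c = config
    k1 = c.frontend_kernel
    D = c.frontend_filters * c.frontend_grid ** 2
    return {
        "conv1_w": _he_init(rng, (c.frontend_filters, 1, k1, k1), k1 * k1),
        "conv1_b": np.zeros(c.frontend_filters),
        "fc1_w": _he_init(rng, (hidden, D), D),
        "fc1_b": np.zeros(hidden),
        "fc2_w": _he_init(rng, (c.num_classes, hidden), hidden),
        "fc2_b": np.zeros(c.num_classes),
    }


class DenseHeadNet:
    """Ablation model: the capsule layers replaced by a plain MLP head.

    Same conv frontend and the same margin loss on per-class "lengths"
    ``p = sigmoid(logits)``, so it drops into the identical training and
    evaluation pipeline.
    """

    param_names = ("conv1_w", "conv1_b", "fc1_w", "fc1_b", "fc2_w", "fc2_b")

    def __init__(self, config: CapsNetConfig, params: dict[str, np.ndarray] | None = None,
                 rng: np.random.Generator | None = None, hidden: int = 64):
        self.config = config
        self.hidden = hidden
        if params is None:
            params = init_densehead_params(config, rng or np.random.default_rng(), hidden)
        self.params = params

    def forward(self, X: np.ndarray, want_cache: bool = False) -> dict:
        c = self.config
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1] != c.input_resolution:
            raise ConfigurationError(
                f"image resolution {X.shape[1:]} does not match config N={c.input_resolution}")
        x = X[:, None, :, :]
        p = self.params
        z1, cols1 = _conv_forward(x, p["conv1_w"], p["conv1_b"], c.frontend_stride)
        a1 = np.maximum(z1, 0.0)
        B = X.shape[0]
        flat = a1.reshape(B, -1)
        h1 = flat @ p["fc1_w"].T + p["fc1_b"]
        a2 = np.maximum(h1, 0.0)
        logits = a2 @ p["fc2_w"].T + p["fc2_b"]
        prob = 1.0 / (1.0 + np.exp(-logits))
        out = {"p": prob, "V": None, "u": flat, "c": None}
        if want_cache:
            out["cache"] = {"x": x, "cols1": cols1, "z1": z1, "flat": flat,
                            "h1": h1, "a2": a2, "prob": prob}
        return out

    def loss_and_grads(self, X, y):
        c = self.config
        out = self.forward(X, want_cache=True)
        cache = out["cache"]
        prob = out["p"]
        y = np.asarray(y, dtype=np.int64)
        loss = float(np.mean(margin_loss(prob, y, c.m_plus, c.m_minus, c.lambda_down)))
        dp = _margin_loss_grad(prob, y, c.m_plus, c.m_minus, c.lambda_down)
        dlogits = dp * prob * (1.0 - prob)
        p = self.params
        dfc2_w = dlogits.T @ cache["a2"]
        dfc2_b = dlogits.sum(axis=0)
        da2 = dlogits @ p["fc2_w"]
        dh1 = da2 * (cache["h1"] > 0)
        dfc1_w = dh1.T @ cache["flat"]
        dfc1_b = dh1.sum(axis=0)
        dflat = dh1 @ p["fc1_w"]
        da1 = dflat.reshape(cache["z1"].shape)
        dz1 = da1 * (cache["z1"] > 0)
        _, dw1, db1 = _conv_backward(dz1, cache["cols1"], p["conv1_w"],
                                     cache["x"].shape, c.frontend_stride)
        grads = {"conv1_w": dw1, "conv1_b": db1, "fc1_w": dfc1_w, "fc1_b": dfc1_b,
                 "fc2_w": dfc2_w, "fc2_b": dfc2_b}
        return loss, grads


class Adam:
    """Standard Adam on a named parameter dict."""

    def __init__(self, param_names, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: None for k in param_names}
        self.v = {k: None for k in param_names}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if self.m[k] is None:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
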