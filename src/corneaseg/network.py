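"""Six-layer fully convolutional network in NumPy.

Architecture (stride 1 everywhere, spatial size preserved):

    C1: 3 -> 128, 3x3, pad 1, BatchNorm + activation
    C2: 128 -> 64, 1x1,        BatchNorm
    C3: 64 -> 32,  3x3, pad 1, BatchNorm + activation
    C4: 32 -> 16,  1x1,        BatchNorm
    C5: 16 -> 8,   3x3, pad 1, BatchNorm + activation
    C6: 8 -> 4,    1x1,        BatchNorm
    softmax over the 4 output maps

The network is trained one image at a time, so batch normalization
normalizes each channel over the spatial positions of the single frame;
running statistics are tracked and travel with :class:`NetworkState` when a
state is copied to warm-start the next frame (the shared model).

Convolutions are computed as sums of shifted channel-matrix products, and
the backward pass is written out by hand (verified against finite
differences in the test suite).
"""
from __future__ import annotations

import copy as _copy
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import TrainConfig

__all__ = [
    "LAYER_SPECS",
    "N_CLASSES",
    "NetworkState",
    "IncompatibleStateError",
    "init_network",
    "forward",
    "backward",
    "SGDMomentum",
]

# (in_channels, out_channels, kernel_size, has_activation)
LAYER_SPECS: Tuple[Tuple[int, int, int, bool], ...] = (
    (3, 128, 3, True),
    (128, 64, 1, False),
    (64, 32, 3, True),
    (32, 16, 1, False),
    (16, 8, 3, True),
    (8, 4, 1, False),
)
N_CLASSES = LAYER_SPECS[-1][1]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


class IncompatibleStateError(ValueError):
    """Warm-start state does not match the network's layer specification."""


# ---------------------------------------------------------------------------
# activations

def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _act_forward(z: np.ndarray, name: str) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "leaky_relu":
        return np.where(z > 0, z, 0.01 * z)
    if name == "mish":
        return z * np.tanh(np.logaddexp(0.0, z))
    if name == "pish":  # smooth self-gated form
        return z * _sigmoid(z)
    raise ValueError(f"unknown activation {name!r}")


def _act_backward(z: np.ndarray, dy: np.ndarray, name: str) -> np.ndarray:
    if name == "relu":
        return dy * (z > 0)
    if name == "leaky_relu":
        return dy * np.where(z > 0, 1.0, 0.01)
    if name == "mish":
        t = np.tanh(np.logaddexp(0.0, z))
        return dy * (t + z * (1.0 - t * t) * _sigmoid(z))
    if name == "pish":
        s = _sigmoid(z)
        return dy * (s + z * s * (1.0 - s))
    raise ValueError(f"unknown activation {name!r}")


# ---------------------------------------------------------------------------
# state

class NetworkState:
    """Learnable parameters and normalization statistics of the FCN."""

    def __init__(self, layers: List[Dict[str, np.ndarray]], activation: str = "relu"):
        self.layers = layers
        self.activation = activation

    @property
    def dtype(self) -> np.dtype:
        return self.layers[0]["W"].dtype

    def copy(self) -> "NetworkState":
        """Deep copy; the shared model hands a copy to the next frame."""
        return NetworkState(
            layers=[{k: v.copy() for k, v in layer.items()} for layer in self.layers],
            activation=self.activation,
        )

    def spec(self) -> Tuple[Tuple[int, int, int], ...]:
        return tuple(
            (l["W"].shape[2], l["W"].shape[3], l["W"].shape[0]) for l in self.layers
        )

    def save(self, path) -> None:
        arrays = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.items():
                arrays[f"layer{i}_{k}"] = v
        np.savez(path, activation=np.array(self.activation), **arrays)

    @classmethod
    def load(cls, path) -> "NetworkState":
        data = np.load(path)
        n = max(int(k.split("_")[0][5:]) for k in data.files if k.startswith("layer")) + 1
        layers = []
        for i in range(n):
            prefix = f"layer{i}_"
            layers.append(
                {k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)}
            )
        return cls(layers=layers, activation=str(data["activation"]))


def init_network(
    cfg: TrainConfig,
    warm: Optional[NetworkState] = None,
    dtype=np.float32,
    seed: Optional[int] = None,
) -> NetworkState:
    """Fresh (He-initialized, seeded) or warm-started network state.

    With ``warm`` given, returns a deep copy of it after checking that its
    layer specification matches; otherwise draws new parameters
    deterministically from ``seed`` (default ``cfg.seed``).
    """
    if warm is not None:
        expected = tuple((ci, co, k) for ci, co, k, _ in LAYER_SPECS)
        if warm.spec() != expected:
            raise IncompatibleStateError(
                f"warm state spec {warm.spec()} != expected {expected}"
            )
        return warm.copy()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    layers = []
    for cin, cout, k, _ in LAYER_SPECS:
        fan_in = k * k * cin
        layers.append(
            {
                "W": rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, cin, cout)).astype(dtype),
                "b": np.zeros(cout, dtype=dtype),
                "gamma": np.ones(cout, dtype=dtype),
                "beta": np.zeros(cout, dtype=dtype),
                "running_mean": np.zeros(cout, dtype=dtype),
                "running_var": np.ones(cout, dtype=dtype),
            }
        )
    return NetworkState(layers=layers, activation=cfg.activation)


# ---------------------------------------------------------------------------
# layer math (channels-first internally: activations are (C, H*W))

def _im2col_cf(x: np.ndarray, h: int, w: int, k: int) -> np.ndarray:
    """Channels-first unfold: (Cin, H*W) -> (k*k*Cin, H*W).

    Row ``(di*k + dj)*Cin + c`` holds channel ``c`` of the input shifted by
    the kernel tap (di, dj); each copy runs in full image rows, so this is
    bandwidth-bound rather than strided-gather-bound.
    """
    cin = x.shape[0]
    pad = k // 2
    xp = np.pad(x.reshape(cin, h, w), ((0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((k * k * cin, h, w), dtype=x.dtype)
    for di in range(k):
        for dj in range(k):
            cols[(di * k + dj) * cin : (di * k + dj + 1) * cin] = xp[
                :, di : di + h, dj : dj + w
            ]
    return cols.reshape(k * k * cin, h * w)


def _w_flat(W: np.ndarray) -> np.ndarray:
    # (k, k, cin, cout) -> (cout, k*k*cin) matching _im2col_cf row order
    k, _, cin, cout = W.shape
    return np.ascontiguousarray(W.reshape(k * k * cin, cout).T)


def _conv_forward(x: np.ndarray, h: int, w: int, W: np.ndarray, b: np.ndarray):
    """x: (Cin, H*W) -> (out (Cout, H*W), cols for reuse in backward)."""
    k = W.shape[0]
    if k == 1:
        return W[0, 0].T @ x + b[:, None], None
    cols = _im2col_cf(x, h, w, k)
    return _w_flat(W) @ cols + b[:, None], cols


def _conv_backward(
    x: np.ndarray,
    h: int,
    w: int,
    W: np.ndarray,
    dout: np.ndarray,
    cols: Optional[np.ndarray],
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a channels-first convolution; dout is (Cout, H*W)."""
    k = W.shape[0]
    cin, cout = W.shape[2], W.shape[3]
    db = dout.sum(axis=1)
    if k == 1:
        dW = np.empty_like(W)
        dW[0, 0] = x @ dout.T
        dx = W[0, 0] @ dout
        return dx, dW, db
    if cols is None:
        cols = _im2col_cf(x, h, w, k)
    dW = np.ascontiguousarray((dout @ cols.T).T).reshape(W.shape)
    dcols = _w_flat(W).T @ dout  # (k*k*cin, H*W)
    pad = k // 2
    dxp = np.zeros((cin, h + 2 * pad, w + 2 * pad), dtype=x.dtype)
    dcols = dcols.reshape(k * k, cin, h, w)
    for di in range(k):
        for dj in range(k):
            dxp[:, di : di + h, dj : dj + w] += dcols[di * k + dj]
    dx = np.ascontiguousarray(dxp[:, pad : pad + h, pad : pad + w]).reshape(
        cin, h * w
    )
    return dx, dW, db


def _bn_forward(z: np.ndarray, layer: Dict[str, np.ndarray]) -> Tuple[np.ndarray, dict]:
    # z: (C, n_pixels); single-image training -> batch stats over pixels
    n = z.shape[1]
    mu = z.mean(axis=1)
    var = np.einsum("cn,cn->c", z, z) / n - mu * mu
    np.maximum(var, 0.0, out=var)
    istd = (1.0 / np.sqrt(var + _BN_EPS)).astype(z.dtype)
    xhat = (z - mu[:, None]) * istd[:, None]
    out = layer["gamma"][:, None] * xhat + layer["beta"][:, None]
    layer["running_mean"] = (
        (1.0 - _BN_MOMENTUM) * layer["running_mean"] + _BN_MOMENTUM * mu
    ).astype(layer["running_mean"].dtype)
    layer["running_var"] = (
        (1.0 - _BN_MOMENTUM) * layer["running_var"] + _BN_MOMENTUM * var
    ).astype(layer["running_var"].dtype)
    return out, {"xhat": xhat, "istd": istd}


def _bn_backward(
    dy: np.ndarray, cache: dict, layer: Dict[str, np.ndarray]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    xhat, istd = cache["xhat"], cache["istd"]
    n = dy.shape[1]
    dgamma = np.einsum("cn,cn->c", dy, xhat)
    dbeta = dy.sum(axis=1)
    dz = (layer["gamma"] * istd / n)[:, None] * (
        n * dy - dbeta[:, None] - xhat * dgamma[:, None]
    )
    return dz, dgamma, dbeta


def _softmax_cf(logits: np.ndarray) -> np.ndarray:
    # logits: (C, n)
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


# ---------------------------------------------------------------------------
# network forward / backward

def forward(
    state: NetworkState,
    frame: np.ndarray,
    train: bool = True,
    return_cache: bool = False,
):
    """Run the FCN on one (H, W, 3) frame; returns (H, W, 4) softmax maps.

    Fully convolutional: any spatial size is accepted and preserved.  In
    training mode batch statistics of this frame are used for normalization
    (and folded into the running statistics); in inference mode the running
    statistics are used.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != LAYER_SPECS[0][0]:
        raise ValueError(
            f"expected (H, W, {LAYER_SPECS[0][0]}) input, got shape {frame.shape}"
        )
    h, w, _ = frame.shape
    x = np.ascontiguousarray(
        frame.astype(state.dtype, copy=False).transpose(2, 0, 1)
    ).reshape(LAYER_SPECS[0][0], h * w)
    caches = []
    for li, (cin, cout, k, has_act) in enumerate(LAYER_SPECS):
        layer = state.layers[li]
        z, cols = _conv_forward(x, h, w, layer["W"], layer["b"])
        if train:
            zn, bn_cache = _bn_forward(z, layer)
        else:
            istd = 1.0 / np.sqrt(layer["running_var"] + _BN_EPS)
            zn = (
                layer["gamma"][:, None] * (z - layer["running_mean"][:, None])
                * istd[:, None]
                + layer["beta"][:, None]
            ).astype(z.dtype)
            bn_cache = None
        if has_act:
            y = _act_forward(zn, state.activation)
        else:
            y = zn
        if return_cache:
            caches.append({"x": x, "cols": cols, "bn": bn_cache, "zn": zn})
        x = y
    probs_cf = _softmax_cf(x)  # (4, H*W)
    probs = np.ascontiguousarray(probs_cf.T).reshape(h, w, N_CLASSES)
    if return_cache:
        return probs, (caches, (h, w))
    return probs


def backward(
    state: NetworkState, cache_bundle, dlogits: np.ndarray
) -> List[Dict[str, np.ndarray]]:
    """Backpropagate a gradient w.r.t. the C6 logits through all layers.

    ``dlogits`` is (H, W, 4); ``cache_bundle`` is the second return value of
    ``forward(..., return_cache=True)``.
    """
    caches, (h, w) = cache_bundle
    dy = np.ascontiguousarray(
        dlogits.reshape(h * w, N_CLASSES).astype(state.dtype).T
    )
    grads: List[Dict[str, np.ndarray]] = [None] * len(LAYER_SPECS)
    for li in range(len(LAYER_SPECS) - 1, -1, -1):
        cin, cout, k, has_act = LAYER_SPECS[li]
        layer = state.layers[li]
        cache = caches[li]
        if has_act:
            dy = _act_backward(cache["zn"], dy, state.activation)
        dz, dgamma, dbeta = _bn_backward(dy, cache["bn"], layer)
        dx, dW, db = _conv_backward(
            cache["x"], h, w, layer["W"], dz, cache["cols"]
        )
        grads[li] = {"W": dW, "b": db, "gamma": dgamma, "beta": dbeta}
        dy = dx
    return grads


class SGDMomentum:
    """Plain SGD with classical momentum over all learnable arrays."""

    def __init__(self, state: NetworkState, lr: float, momentum: float):
        self.lr = lr
        self.momentum = momentum
        self.velocity = [
            {k: np.zeros_like(layer[k]) for k in ("W", "b", "gamma", "beta")}
            for layer in state.layers
        ]

    def step(self, state: NetworkState, grads: List[Dict[str, np.ndarray]]) -> None:
        for layer, g, v in zip(state.layers, grads, self.velocity):
            for k in ("W", "b", "gamma", "beta"):
                v[k] = self.momentum * v[k] - self.lr * g[k]
                layer[k] += v[k]
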