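"""A compact numpy backend that executes :class:`ModelSpec` graphs.

The networks trained in this package are deliberately small (tens to a few
hundred thousand parameters at desk scale), so a plain numpy implementation
of the handful of required layer kinds — 'same'-padded convolution with
stride 1/2, batch-norm, dropout, 2x2 max-pool, x2 nearest upsampling with a
2x2 convolution, concatenation/addition skips — is sufficient and keeps the
training stack fully deterministic under a seed.

Tensors are NHWC float32 by default (float64 available for gradient checks).  The final convolution's sigmoid/softmax is *not*
applied in :meth:`Network.forward`: losses consume logits for numerical
stability and :meth:`Network.predict_proba` applies the head activation.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .architectures import LayerDef, ModelSpec

__all__ = ["Network", "Adam", "bce_with_logits", "softmax_ce_with_logits"]

_EPS = 1e-5  # batch-norm variance floor


def _same_pad(h: int, k: int, s: int) -> tuple[int, int, int]:
    out = -(-h // s)
    total = max((out - 1) * s + k - h, 0)
    return out, total // 2, total - total // 2


def _conv_forward(x, W, b, stride):
    k = W.shape[0]
    n, h, w, cin = x.shape
    oh, pt, pb = _same_pad(h, k, stride)
    ow, pl, pr = _same_pad(w, k, stride)
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    out = np.broadcast_to(b, (n, oh, ow, W.shape[3])).copy()
    for i in range(k):
        for j in range(k):
            patch = xp[:, i : i + stride * oh : stride, j : j + stride * ow : stride, :]
            out += patch @ W[i, j]
    return out, xp


def _conv_backward(g, xp, W, stride, in_shape):
    k = W.shape[0]
    n, h, w, cin = in_shape
    _, pt, _ = _same_pad(h, k, stride)
    _, pl, _ = _same_pad(w, k, stride)
    oh, ow = g.shape[1], g.shape[2]
    dxp = np.zeros_like(xp)
    dW = np.empty_like(W)
    for i in range(k):
        for j in range(k):
            patch = xp[:, i : i + stride * oh : stride, j : j + stride * ow : stride, :]
            dW[i, j] = np.tensordot(patch, g, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, i : i + stride * oh : stride, j : j + stride * ow : stride, :] += g @ W[i, j].T
    db = g.sum(axis=(0, 1, 2))
    dx = dxp[:, pt : pt + h, pl : pl + w, :]
    return dx, dW, db


def _resize_to(x, th, tw):
    """Center crop/pad (zero) the spatial dims of x to (th, tw)."""
    n, h, w, c = x.shape
    if h > th:
        top = (h - th) // 2
        x = x[:, top : top + th, :, :]
    elif h < th:
        top = (th - h) // 2
        x = np.pad(x, ((0, 0), (top, th - h - top), (0, 0), (0, 0)))
    n, h, w, c = x.shape
    if w > tw:
        left = (w - tw) // 2
        x = x[:, :, left : left + tw, :]
    elif w < tw:
        left = (tw - w) // 2
        x = np.pad(x, ((0, 0), (0, 0), (left, tw - w - left), (0, 0)))
    return x


def _resize_back(g, sh, sw):
    """Adjoint of :func:`_resize_to`: map gradients back to (sh, sw)."""
    return _resize_to(g, sh, sw)


def bce_with_logits(z, y):
    """Mean binary cross-entropy from logits; returns (loss, dloss/dz)."""
    p = expit(z)
    # stable log-sum-exp form: log(1+e^z) - y*z
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    grad = (p - y) / z.size
    return float(loss), grad


def softmax_ce_with_logits(z, y_onehot):
    """Mean 2-class cross-entropy from logits along the channel axis."""
    zmax = z.max(axis=-1, keepdims=True)
    ez = np.exp(z - zmax)
    p = ez / ez.sum(axis=-1, keepdims=True)
    npix = z.size // z.shape[-1]
    loss = -np.sum(y_onehot * (z - zmax - np.log(ez.sum(axis=-1, keepdims=True)))) / npix
    grad = (p - y_onehot) / npix
    return float(loss), grad


class Network:
    """Executable instantiation of a :class:`ModelSpec`.

    Parameters are He-initialized from the given rng; the object owns the
    forward/backward passes and exposes flat parameter/gradient dicts for
    the optimizer.
    """

    def __init__(self, spec: ModelSpec, rng: np.random.Generator,
                 dtype=np.float32):
        self.spec = spec
        self.dtype = np.dtype(dtype)
        self.shapes = spec.infer_shapes()
        self.params: dict[str, np.ndarray] = {}
        self.state: dict[str, np.ndarray] = {}  # batch-norm running stats
        for lay in spec.layers:
            cin = self.shapes[lay.inputs[0]][2] if lay.inputs else 0
            if lay.kind in ("conv", "upconv"):
                k = lay.kernel
                std = np.sqrt(2.0 / (k * k * cin))
                self.params[f"{lay.name}/W"] = rng.normal(
                    0.0, std, size=(k, k, cin, lay.filters)
                ).astype(self.dtype)
                self.params[f"{lay.name}/b"] = np.zeros(lay.filters, dtype=self.dtype)
            elif lay.kind == "bn":
                self.params[f"{lay.name}/gamma"] = np.ones(cin, dtype=self.dtype)
                self.params[f"{lay.name}/beta"] = np.zeros(cin, dtype=self.dtype)
                self.state[f"{lay.name}/mean"] = np.zeros(cin, dtype=self.dtype)
                self.state[f"{lay.name}/var"] = np.ones(cin, dtype=self.dtype)
        self.head = spec.layers[-1]
        self._cache: dict[str, dict] = {}

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- forward ---------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Run the graph; returns the head *logits* (N, side, side, C)."""
        if x.ndim == 3:
            x = x[..., None]
        x = x.astype(self.dtype)
        acts: dict[str, np.ndarray] = {}
        cache: dict[str, dict] = {}
        for lay in self.spec.layers:
            if lay.kind == "input":
                acts[lay.name] = x
                continue
            a = acts[lay.inputs[0]]
            c: dict = {"in_shape": a.shape}
            if lay.kind == "conv":
                W = self.params[f"{lay.name}/W"]
                out, xp = _conv_forward(a, W, self.params[f"{lay.name}/b"], lay.stride)
                c["xp"] = xp
                if lay.activation == "relu":
                    c["relu_mask"] = out > 0
                    out = np.where(c["relu_mask"], out, 0.0)
                # sigmoid/softmax heads stay as logits
            elif lay.kind == "upconv":
                up = a.repeat(2, axis=1).repeat(2, axis=2)
                c["up_shape"] = up.shape
                W = self.params[f"{lay.name}/W"]
                out, xp = _conv_forward(up, W, self.params[f"{lay.name}/b"], 1)
                c["xp"] = xp
                if lay.activation == "relu":
                    c["relu_mask"] = out > 0
                    out = np.where(c["relu_mask"], out, 0.0)
            elif lay.kind == "bn":
                out, c = self._bn_forward(lay, a, training)
                c["in_shape"] = a.shape
            elif lay.kind == "dropout":
                if training:
                    if rng is None:
                        rng = np.random.default_rng()
                    keep = 1.0 - lay.rate
                    mask = (rng.random(a.shape) < keep).astype(self.dtype) / keep
                    c["mask"] = mask
                    out = a * mask
                else:
                    out = a
            elif lay.kind == "maxpool":
                out, c = self._pool_forward(a)
                c["in_shape"] = a.shape
            elif lay.kind in ("concat", "add", "mul"):
                bten = acts[lay.inputs[1]]
                th, tw = bten.shape[1], bten.shape[2]
                ar = _resize_to(a, th, tw)
                c["a_shape"] = a.shape
                if lay.kind == "concat":
                    c["split"] = ar.shape[3]
                    out = np.concatenate([ar, bten], axis=3)
                elif lay.kind == "add":
                    out = ar + bten
                else:
                    c["ar"], c["b"] = ar, bten
                    out = ar * bten
            else:  # pragma: no cover
                raise ValueError(f"unsupported layer kind {lay.kind!r}")
            acts[lay.name] = out
            cache[lay.name] = c
        self._acts, self._cache = acts, cache
        return acts[self.spec.output_name]

    def _bn_forward(self, lay: LayerDef, a, training):
        g = self.params[f"{lay.name}/gamma"]
        beta = self.params[f"{lay.name}/beta"]
        if training:
            mu = a.mean(axis=(0, 1, 2))
            var = a.var(axis=(0, 1, 2))
            self.state[f"{lay.name}/mean"] = 0.9 * self.state[f"{lay.name}/mean"] + 0.1 * mu
            self.state[f"{lay.name}/var"] = 0.9 * self.state[f"{lay.name}/var"] + 0.1 * var
        else:
            mu = self.state[f"{lay.name}/mean"]
            var = self.state[f"{lay.name}/var"]
        inv = 1.0 / np.sqrt(var + _EPS)
        xhat = (a - mu) * inv
        out = g * xhat + beta
        return out, {"xhat": xhat, "inv": inv, "training": training}

    @staticmethod
    def _pool_forward(a):
        n, h, w, c = a.shape
        ph, pw = h % 2, w % 2
        ap = np.pad(a, ((0, 0), (0, ph), (0, pw), (0, 0)), constant_values=-np.inf)
        H2, W2 = ap.shape[1] // 2, ap.shape[2] // 2
        win = ap.reshape(n, H2, 2, W2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, H2, W2, 4, c)
        idx = win.argmax(axis=3)
        out = np.take_along_axis(win, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        return out, {"idx": idx, "padded_shape": ap.shape}

    # -- backward --------------------------------------------------------

    def backward(self, grad_out: np.ndarray) -> dict[str, np.ndarray]:
        """Backprop from head-logit gradients; returns parameter grads."""
        grads: dict[str, np.ndarray] = {k: np.zeros_like(v) for k, v in self.params.items()}
        act_grads: dict[str, np.ndarray] = {self.spec.output_name: grad_out.astype(self.dtype)}
        for lay in reversed(self.spec.layers):
            if lay.kind == "input" or lay.name not in act_grads:
                continue
            g = act_grads.pop(lay.name)
            c = self._cache[lay.name]

            def send(name: str, value: np.ndarray) -> None:
                if name in act_grads:
                    act_grads[name] = act_grads[name] + value
                else:
                    act_grads[name] = value

            if lay.kind in ("conv", "upconv"):
                if "relu_mask" in c:
                    g = np.where(c["relu_mask"], g, 0.0)
                W = self.params[f"{lay.name}/W"]
                src_shape = c["up_shape"] if lay.kind == "upconv" else c["in_shape"]
                stride = 1 if lay.kind == "upconv" else lay.stride
                dx, dW, db = _conv_backward(g, c["xp"], W, stride, src_shape)
                grads[f"{lay.name}/W"] += dW
                grads[f"{lay.name}/b"] += db
                if lay.kind == "upconv":
                    n, uh, uw, ch = dx.shape
                    dx = dx.reshape(n, uh // 2, 2, uw // 2, 2, ch).sum(axis=(2, 4))
                send(lay.inputs[0], dx)
            elif lay.kind == "bn":
                xhat, inv = c["xhat"], c["inv"]
                gam = self.params[f"{lay.name}/gamma"]
                grads[f"{lay.name}/beta"] += g.sum(axis=(0, 1, 2))
                grads[f"{lay.name}/gamma"] += (g * xhat).sum(axis=(0, 1, 2))
                if c["training"]:
                    m = g.shape[0] * g.shape[1] * g.shape[2]
                    gs = g.sum(axis=(0, 1, 2))
                    gxs = (g * xhat).sum(axis=(0, 1, 2))
                    dx = (gam * inv / m) * (m * g - gs - xhat * gxs)
                else:
                    dx = g * gam * inv
                send(lay.inputs[0], dx.astype(self.dtype))
            elif lay.kind == "dropout":
                send(lay.inputs[0], g * c["mask"] if "mask" in c else g)
            elif lay.kind == "maxpool":
                idx = c["idx"]
                n, H2, W2, ch = idx.shape
                dwin = np.zeros((n, H2, W2, 4, ch), dtype=self.dtype)
                np.put_along_axis(dwin, idx[:, :, :, None, :], g[:, :, :, None, :], axis=3)
                dpad = dwin.reshape(n, H2, W2, 2, 2, ch).transpose(0, 1, 3, 2, 4, 5).reshape(
                    n, 2 * H2, 2 * W2, ch
                )
                ih, iw = c["in_shape"][1], c["in_shape"][2]
                send(lay.inputs[0], dpad[:, :ih, :iw, :])
            elif lay.kind in ("concat", "add", "mul"):
                ash = c["a_shape"]
                if lay.kind == "concat":
                    ga, gb = g[..., : c["split"]], g[..., c["split"] :]
                elif lay.kind == "add":
                    ga, gb = g, g
                else:
                    ga, gb = g * c["b"], g * c["ar"]
                send(lay.inputs[0], _resize_back(ga, ash[1], ash[2]))
                send(lay.inputs[1], gb)
        return grads

    # -- inference -------------------------------------------------------

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Foreground probability map(s) in [0, 1], shape (N, side, side)."""
        z = self.forward(x, training=False)
        if self.head.activation == "softmax":
            zmax = z.max(axis=-1, keepdims=True)
            ez = np.exp(z - zmax)
            p = ez / ez.sum(axis=-1, keepdims=True)
            return p[..., 1]
        return expit(z[..., 0])


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in params.items():
            gk = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk * gk
            p -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
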