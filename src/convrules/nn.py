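"""Minimal NumPy convolutional network used as the built-in classifier.

Stride-1 'same' convolutions via im2col, 2x2 max pooling, ReLU, global average
pooling and a linear head, trained with Adam on the softmax cross-entropy.
Everything is plain float64 NumPy with explicit seeding, so training and
inference are bit-reproducible on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ArchConfig", "TinyCNN", "softmax", "cross_entropy"]


@dataclass(frozen=True)
class ArchConfig:
    """Architecture of the built-in CNN: three conv blocks, pooling after the
    first two, so the designated feature layer (post-ReLU output of the last
    conv) keeps a 16x16 spatial grid on 64x64 inputs."""

    channels: tuple[int, ...] = (8, 12, 16)
    kernel_sizes: tuple[int, ...] = (5, 3, 3)
    pool_after: tuple[bool, ...] = (True, True, False)
    n_classes: int = 2
    # global pooling of the head: "max" makes each kernel's contribution its
    # single strongest response, which pushes kernels toward selective,
    # spatially localized concepts; "avg" allows additive mixing
    pooling: str = "max"

    def __post_init__(self) -> None:
        if len(self.channels) < 2:
            raise ValueError("need at least two conv blocks")
        if not (len(self.channels) == len(self.kernel_sizes) == len(self.pool_after)):
            raise ValueError("per-block settings must have equal length")

    @property
    def n_kernels(self) -> int:
        return self.channels[-1]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N, H*W, C*k*k) patch matrix for a stride-1 same conv."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
    n, c, h, w = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)


def _col2im(dcols: np.ndarray, shape: tuple, k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patch gradients back."""
    n, c, h, w = shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    g = dcols.reshape(n, h, w, c, k, k)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + h, j : j + w] += g[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dxp[:, :, pad : pad + h, pad : pad + w]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> float:
    p = softmax(logits)
    return float(-np.mean(np.log(p[np.arange(len(targets)), targets] + 1e-12)))


class TinyCNN:
    """Three conv blocks + GAP + linear head; g(.) is everything up to and
    including the last conv's ReLU, h(.) is GAP + linear."""

    def __init__(self, arch: ArchConfig, seed: int = 0):
        self.arch = arch
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = 1
        for b, (c_out, k) in enumerate(zip(arch.channels, arch.kernel_sizes)):
            fan_in = c_in * k * k
            self.params[f"W{b}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, k, k))
            self.params[f"b{b}"] = np.zeros(c_out)
            c_in = c_out
        self.params["Wh"] = rng.normal(0.0, np.sqrt(2.0 / c_in), (arch.n_classes, c_in))
        self.params["bh"] = np.zeros(arch.n_classes)

    # ---- forward -----------------------------------------------------------

    def features(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        """g(x): (N,1,H,W) -> post-ReLU maps (N, k_l, h_l, w_l)."""
        a = x
        for b in range(len(self.arch.channels)):
            k = self.arch.kernel_sizes[b]
            pad = k // 2
            W, bias = self.params[f"W{b}"], self.params[f"b{b}"]
            cols = _im2col(a, k, pad)
            n, hw, _ = cols.shape
            h = w = int(np.sqrt(hw))
            z = (cols @ W.reshape(W.shape[0], -1).T + bias).transpose(0, 2, 1)
            z = z.reshape(n, W.shape[0], h, w)
            r = np.maximum(z, 0.0)
            if cache is not None:
                cache.append(("conv", a.shape, cols, z > 0))
            a = r
            if self.arch.pool_after[b]:
                n, c, h, w = a.shape
                win = a.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
                win = win.reshape(n, c, h // 2, w // 2, 4)
                idx = win.argmax(axis=-1)
                if cache is not None:
                    cache.append(("pool", (n, c, h, w), idx))
                a = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        return a

    def head(self, feats: np.ndarray, cache: list | None = None) -> np.ndarray:
        """h(feats): global pooling over space then linear -> (N, n_classes)."""
        if self.arch.pooling == "max":
            n, c = feats.shape[:2]
            flat = feats.reshape(n, c, -1)
            idx = flat.argmax(axis=2)
            g = np.take_along_axis(flat, idx[..., None], axis=2)[..., 0]
        else:
            idx = None
            g = feats.mean(axis=(2, 3))
        if cache is not None:
            cache.append(("head", feats.shape, g, idx))
        return g @ self.params["Wh"].T + self.params["bh"]

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.head(self.features(x))

    # ---- backward ----------------------------------------------------------

    def _backward(
        self,
        cache: list,
        dlogits: np.ndarray,
        drop_mask: np.ndarray | None = None,
        feat_penalty: np.ndarray | None = None,
    ) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        tag, feat_shape, g, idx = cache.pop()
        assert tag == "head"
        grads["Wh"] = dlogits.T @ g
        grads["bh"] = dlogits.sum(axis=0)
        dg = dlogits @ self.params["Wh"]
        n, c, h, w = feat_shape
        if idx is not None:  # max pooling: gradient flows to the argmax only
            dflat = np.zeros((n, c, h * w))
            np.put_along_axis(dflat, idx[..., None], dg[..., None], axis=2)
            da = dflat.reshape(feat_shape)
        else:
            da = np.broadcast_to(dg[:, :, None, None], feat_shape) / (h * w)
            da = np.ascontiguousarray(da)
        if feat_penalty is not None:
            da = da + feat_penalty
        if drop_mask is not None:
            da = da * drop_mask[:, :, None, None]
        for b in range(len(self.arch.channels) - 1, -1, -1):
            if self.arch.pool_after[b]:
                tag, (n, c, h, w), idx = cache.pop()
                assert tag == "pool"
                dwin = np.zeros((n, c, h // 2, w // 2, 4))
                np.put_along_axis(dwin, idx[..., None], da[..., None], axis=-1)
                da = (
                    dwin.reshape(n, c, h // 2, w // 2, 2, 2)
                    .transpose(0, 1, 2, 4, 3, 5)
                    .reshape(n, c, h, w)
                )
            tag, in_shape, cols, relu_mask = cache.pop()
            assert tag == "conv"
            k = self.arch.kernel_sizes[b]
            W = self.params[f"W{b}"]
            dz = da * relu_mask
            dz2 = dz.reshape(dz.shape[0], dz.shape[1], -1).transpose(0, 2, 1)  # N,HW,F
            grads[f"W{b}"] = (
                np.einsum("npf,npc->fc", dz2, cols).reshape(W.shape)
            )
            grads[f"b{b}"] = dz2.sum(axis=(0, 1))
            dcols = dz2 @ W.reshape(W.shape[0], -1)
            da = _col2im(dcols, in_shape, k, k // 2)
        return grads

    # ---- training ----------------------------------------------------------

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 30,
        batch_size: int = 32,
        lr: float = 3e-3,
        seed: int = 0,
        feature_dropout: float = 0.0,
        head_l2: float = 0.0,
        head_l1: float = 0.0,
        activation_l1: float = 0.0,
    ) -> list[float]:
        """Adam on softmax cross-entropy; returns the per-epoch mean loss.

        ``feature_dropout`` randomly zeroes whole feature-layer channels
        (unscaled, at a variable per-sample rate) during training, making the
        head robust to kernels being muted at inference time.  ``head_l2`` /
        ``head_l1`` shrink the *differential* head weight of each channel
        (its class-1 minus class-0 weight) — the only part that moves the
        decision — so channels carrying no class evidence end up with exactly
        zero influence and can be muted without changing any prediction.
        ``activation_l1`` penalizes the mean feature-layer activation,
        promoting sparse, spatially concentrated kernel responses: a kernel
        responding to several stimuli pays for all of them, so specialization
        is cheaper — the role class-wise activation-sparsity training plays
        in large networks.
        """
        rng = np.random.default_rng(seed)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v) for k, v in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        losses = []
        n = len(x)
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x[idx], y[idx]
                cache: list = []
                feats = self.features(xb, cache)
                drop_mask = None
                if feature_dropout > 0.0:
                    # unscaled channel zeroing at a per-sample rate drawn from
                    # [0, feature_dropout]: the head learns to classify from
                    # arbitrary kernel subsets, exactly the condition that
                    # muting experiments apply at inference time
                    rate = rng.uniform(0.0, feature_dropout, size=(len(idx), 1))
                    drop_mask = (rng.random((len(idx), feats.shape[1])) >= rate).astype(float)
                    feats = feats * drop_mask[:, :, None, None]
                logits = self.head(feats, cache)
                epoch_loss += cross_entropy(logits, yb) * len(idx)
                p = softmax(logits)
                p[np.arange(len(yb)), yb] -= 1.0
                feat_pen = None
                if activation_l1 > 0.0:
                    epoch_loss += activation_l1 * feats.mean() * len(idx)
                    feat_pen = np.full(feats.shape, activation_l1 / feats[0].size / len(idx))
                grads = self._backward(cache, p / len(idx), drop_mask=drop_mask, feat_penalty=feat_pen)
                t += 1
                for key, gval in grads.items():
                    m[key] = b1 * m[key] + (1 - b1) * gval
                    v[key] = b2 * v[key] + (1 - b2) * gval * gval
                    mh = m[key] / (1 - b1**t)
                    vh = v[key] / (1 - b2**t)
                    self.params[key] -= lr * mh / (np.sqrt(vh) + eps)
                if head_l2 or head_l1:
                    Wh = self.params["Wh"]
                    d = Wh[1] - Wh[0]
                    shrink = lr * (head_l2 * d + head_l1 * np.sign(d))
                    shrink = np.sign(d) * np.minimum(np.abs(shrink), np.abs(d))
                    Wh[1] -= 0.5 * shrink
                    Wh[0] += 0.5 * shrink
            losses.append(epoch_loss / n)
        return losses

    def refit_head(
        self,
        feats: np.ndarray,
        y: np.ndarray,
        epochs: int = 1200,
        lr: float = 5e-2,
        max_drop: float = 0.95,
        stability_bias: float = 0.9,
        diff_l1: float = 0.01,
        seed: int = 0,
    ) -> None:
        """Re-train only the linear head on pooled features under random
        channel muting (unscaled zeroing at per-sample rates up to
        ``max_drop``).

        Because the feature maps are non-negative, zeroing a channel of the
        pooled vector equals muting that kernel before pooling, so the head
        learns to classify from arbitrary kernel subsets — the condition the
        muting experiments probe.  ``stability_bias`` lowers the drop
        probability of consistently active channels, steering the decision
        weight onto the stable kernels (the ones frequent enough for concept
        assignment to label) rather than sporadically firing ones.  The
        convolutional features are untouched.
        """
        rng = np.random.default_rng(seed)
        if self.arch.pooling == "max":
            g = feats.reshape(feats.shape[0], feats.shape[1], -1).max(axis=2)
        else:
            g = feats.mean(axis=(2, 3))
        mean_act = g.mean(axis=0)
        stability = np.sqrt(mean_act / (mean_act.max() + 1e-12))
        keep_scale = 1.0 - stability_bias * stability
        Wh, bh = self.params["Wh"], self.params["bh"]
        m = {"W": np.zeros_like(Wh), "b": np.zeros_like(bh)}
        v = {"W": np.zeros_like(Wh), "b": np.zeros_like(bh)}
        b1, b2, eps = 0.9, 0.999, 1e-8
        n = len(g)
        for t in range(1, epochs + 1):
            rate = rng.uniform(0.0, max_drop, size=(n, 1))
            mask = (rng.random(g.shape) >= rate * keep_scale[None, :]).astype(float)
            gm = g * mask
            p = softmax(gm @ Wh.T + bh)
            p[np.arange(n), y] -= 1.0
            p /= n
            gw = {"W": p.T @ gm, "b": p.sum(axis=0)}
            for key, par in (("W", Wh), ("b", bh)):
                m[key] = b1 * m[key] + (1 - b1) * gw[key]
                v[key] = b2 * v[key] + (1 - b2) * gw[key] ** 2
                par -= lr * (m[key] / (1 - b1**t)) / (np.sqrt(v[key] / (1 - b2**t)) + eps)
            if diff_l1:
                # lasso on the differential weight: channels without class
                # evidence end up with exactly zero decision influence
                d = Wh[1] - Wh[0]
                shrink = np.sign(d) * np.minimum(lr * diff_l1, np.abs(d))
                Wh[1] -= 0.5 * shrink
                Wh[0] += 0.5 * shrink

    # ---- persistence -------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return dict(self.params)

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k])
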