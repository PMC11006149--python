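"""The g(.)/h(.) model decomposition: activation extraction and kernel masking.

A trained CNN classifier M is split at a designated feature-extraction layer l
into a feature part ``g`` (image -> one activation map per kernel) and a head
``h`` (maps -> class scores), so that ``h(g(x))`` is the model's own forward
pass.  Kernel masks intervene between the two: *muting* a set of kernels
replaces their maps with zeros before ``h``; *activating* a set means muting
its complement.  The designated layer is the post-nonlinearity output of the
last convolution (maps are therefore non-negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import ArchConfig, TinyCNN
from .phantom import PhantomDataset

__all__ = [
    "ActivationSet",
    "FeatureModel",
    "KernelMask",
    "TrainingError",
    "train_tiny_cnn",
    "extract_activations",
    "predict_masked",
    "save_checkpoint",
    "load_checkpoint",
]


class TrainingError(RuntimeError):
    """Raised when the built-in CNN fails to reach a usable accuracy."""


@dataclass
class ActivationSet:
    """Per-image, per-kernel activation maps A[i, k] from layer l."""

    activations: np.ndarray  # n x k_l x h_l x w_l
    image_ids: np.ndarray
    layer_id: str = "last_conv"

    def __post_init__(self) -> None:
        if self.activations.ndim != 4:
            raise ValueError("activations must be n x k x h x w")
        if not np.all(np.isfinite(self.activations)):
            raise ValueError("activations contain non-finite values")
        if len(self.image_ids) != len(self.activations):
            raise ValueError("image_ids misaligned with activations")

    @property
    def n_kernels(self) -> int:
        return self.activations.shape[1]


@dataclass(frozen=True)
class KernelMask:
    """Which kernels to silence.  ``mute`` zeroes the listed kernels;
    ``activate`` zeroes everything except the listed kernels."""

    mode: str  # "mute" | "activate"
    kernels: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.mode not in ("mute", "activate"):
            raise ValueError("mode must be 'mute' or 'activate'")

    def muted(self, n_kernels: int) -> np.ndarray:
        ids = np.asarray(sorted(self.kernels), dtype=np.int64)
        if ids.size and (ids.min() < 0 or ids.max() >= n_kernels):
            raise ValueError(f"kernel ids out of range 0..{n_kernels - 1}: {ids.tolist()}")
        keep = np.zeros(n_kernels, dtype=bool)
        keep[ids] = True
        return keep if self.mode == "mute" else ~keep

    @staticmethod
    def mute(kernels) -> "KernelMask":
        return KernelMask("mute", frozenset(int(k) for k in kernels))

    @staticmethod
    def activate_only(kernels) -> "KernelMask":
        return KernelMask("activate", frozenset(int(k) for k in kernels))


@dataclass
class FeatureModel:
    """A classifier exposing the g/h decomposition plus training metadata."""

    net: TinyCNN
    image_size: int
    train_accuracy: float = float("nan")
    val_accuracy: float = float("nan")

    @property
    def n_kernels(self) -> int:
        return self.net.arch.n_kernels

    def _as_input(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[-2:] != (self.image_size, self.image_size):
            raise ValueError(
                f"expected {self.image_size}x{self.image_size} images, got {x.shape[-2:]}"
            )
        return x[:, None, :, :]

    def g(self, images: np.ndarray) -> np.ndarray:
        """Feature maps at the designated layer, (n, k_l, h_l, w_l)."""
        return self.net.features(self._as_input(images))

    def h(self, feats: np.ndarray) -> np.ndarray:
        """Class logits from feature maps."""
        return self.net.head(feats)

    def predict_from_features(
        self, feats: np.ndarray, mask: KernelMask | None = None
    ) -> np.ndarray:
        """Predictions from precomputed g(x) maps; masking is applied here,
        so one feature extraction can serve many masks."""
        if mask is not None:
            keep = ~mask.muted(self.n_kernels)
            feats = feats * keep[None, :, None, None]
        return self.h(feats).argmax(axis=1)

    def predict(self, images: np.ndarray, mask: KernelMask | None = None) -> np.ndarray:
        return self.predict_from_features(self.g(images), mask)

    def accuracy(self, images: np.ndarray, labels: np.ndarray, mask: KernelMask | None = None) -> float:
        return float(np.mean(self.predict(images, mask) == np.asarray(labels)))


def train_tiny_cnn(
    dataset: PhantomDataset,
    arch: ArchConfig | None = None,
    seed: int = 0,
    epochs: int = 25,
    lr: float = 3e-3,
    batch_size: int = 32,
    val_fraction: float = 0.2,
    min_val_accuracy: float = 0.7,
    feature_dropout: float = 0.0,
    activation_l1: float = 0.05,
    head_refit_drop: float = 0.95,
) -> FeatureModel:
    """Train the built-in CNN on a balanced phantom dataset.

    A deterministic stratified tail of each class (``val_fraction``) is held
    out for validation.  After the convolutional training, the linear head is
    re-fit on the frozen features under random channel muting (rates up to
    ``head_refit_drop``), so that predictions degrade gracefully when kernels
    are muted — emulating the redundancy of much larger networks without
    disturbing what the kernels themselves learned.  Raises
    :class:`TrainingError` with diagnostics when validation accuracy ends
    below ``min_val_accuracy``.
    """
    arch = arch or ArchConfig()
    x = np.asarray(dataset.images, dtype=float)[:, None, :, :]
    y = np.asarray(dataset.labels, dtype=np.int64)
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    n_val0 = max(1, int(round(val_fraction * len(idx0))))
    n_val1 = max(1, int(round(val_fraction * len(idx1))))
    val_idx = np.concatenate([idx0[-n_val0:], idx1[-n_val1:]])
    train_idx = np.concatenate([idx0[:-n_val0], idx1[:-n_val1]])
    net = TinyCNN(arch, seed=seed)
    net.fit(
        x[train_idx],
        y[train_idx],
        epochs=epochs,
        batch_size=batch_size,
        lr=lr,
        seed=seed,
        feature_dropout=feature_dropout,
        activation_l1=activation_l1,
    )
    if head_refit_drop > 0.0:
        feats = net.features(x[train_idx])
        net.refit_head(feats, y[train_idx], max_drop=head_refit_drop, seed=seed)
    model = FeatureModel(net=net, image_size=dataset.config.image_size)
    model.train_accuracy = model.accuracy(dataset.images[train_idx], y[train_idx])
    model.val_accuracy = model.accuracy(dataset.images[val_idx], y[val_idx])
    if model.val_accuracy < min_val_accuracy:
        raise TrainingError(
            f"built-in CNN failed to converge: validation accuracy "
            f"{model.val_accuracy:.3f} < {min_val_accuracy} "
            f"(train accuracy {model.train_accuracy:.3f}, seed {seed}, "
            f"{epochs} epochs, lr {lr}); increase texture contrast or epochs"
        )
    return model


def extract_activations(
    model: FeatureModel, images: np.ndarray, batch_size: int = 64
) -> ActivationSet:
    """A[i, k] maps for every image; side-effect free on the model."""
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    maps = [model.g(images[s : s + batch_size]) for s in range(0, len(images), batch_size)]
    return ActivationSet(
        activations=np.concatenate(maps, axis=0), image_ids=np.arange(len(images))
    )


def predict_masked(model: FeatureModel, images: np.ndarray, mask: KernelMask) -> np.ndarray:
    """Class predictions with the mask applied between g and h."""
    return model.predict(images, mask)


def save_checkpoint(model: FeatureModel, path) -> None:
    arch = model.net.arch
    np.savez(
        path,
        image_size=model.image_size,
        train_accuracy=model.train_accuracy,
        val_accuracy=model.val_accuracy,
        channels=np.asarray(arch.channels),
        kernel_sizes=np.asarray(arch.kernel_sizes),
        pool_after=np.asarray(arch.pool_after),
        n_classes=arch.n_classes,
        **{f"param_{k}": v for k, v in model.net.state_dict().items()},
    )


def load_checkpoint(path) -> FeatureModel:
    z = np.load(path)
    arch = ArchConfig(
        channels=tuple(int(c) for c in z["channels"]),
        kernel_sizes=tuple(int(k) for k in z["kernel_sizes"]),
        pool_after=tuple(bool(p) for p in z["pool_after"]),
        n_classes=int(z["n_classes"]),
    )
    net = TinyCNN(arch)
    net.load_state_dict({k[len("param_") :]: z[k] for k in z.files if k.startswith("param_")})
    return FeatureModel(
        net=net,
        image_size=int(z["image_size"]),
        train_accuracy=float(z["train_accuracy"]),
        val_accuracy=float(z["val_accuracy"]),
    )
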