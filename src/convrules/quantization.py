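"""Quantization of kernel activations into logical literals.

For image i and kernel k at layer l, the kernel norm is the L1 norm of the
activation map, ``a[i, k] = sum |A[i, k]|``.  The per-kernel threshold is the
arithmetic mean of the norms over the *training* set,
``theta[k] = sum_i a[i, k] / n``.  Binarization maps a norm to +1 when it is
strictly above its threshold and to -1 otherwise; +1 is read as the positive
literal ``L_k``, -1 as the negated literal ``not L_k``.

Thresholds are always computed on the training split and frozen; validation
data is binarized against training thresholds (no leakage).
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adapter import ActivationSet

__all__ = [
    "KernelNormTable",
    "ThresholdVector",
    "LiteralTable",
    "kernel_codes",
    "kernel_norms",
    "compute_thresholds",
    "binarize",
]


def kernel_codes(n_kernels: int) -> list[str]:
    """Stable two-letter display codes ('AA', 'AB', ...) assigned by index."""
    letters = string.ascii_uppercase
    pairs = ("".join(p) for p in itertools.product(letters, repeat=2))
    return list(itertools.islice(pairs, n_kernels))


@dataclass
class KernelNormTable:
    """n x k_l matrix of kernel L1 norms, with optional labels for plotting."""

    norms: np.ndarray
    image_ids: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.norms = np.asarray(self.norms, dtype=float)
        if self.norms.ndim != 2:
            raise ValueError("norms must be an n x k matrix")
        if not np.all(np.isfinite(self.norms)):
            raise ValueError("norms contain non-finite values")
        if np.any(self.norms < 0):
            raise ValueError("L1 norms cannot be negative")

    @property
    def n_kernels(self) -> int:
        return self.norms.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.norms, columns=kernel_codes(self.n_kernels))
        df.insert(0, "image_id", self.image_ids)
        if self.labels is not None:
            df["label"] = self.labels
        return df

    def to_csv(self, path) -> None:
        """Kernel-norm-plot data: rows = images, columns = kernel codes."""
        self.to_frame().to_csv(path, index=False)


@dataclass
class ThresholdVector:
    """Per-kernel binarization thresholds, frozen from the training split."""

    theta: np.ndarray
    provenance: str = "mean over training set"

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 1:
            raise ValueError("theta must be a vector")


@dataclass
class LiteralTable:
    """n x k_l matrix of literals in {-1, +1}; +1 iff norm strictly above theta."""

    values: np.ndarray
    image_ids: np.ndarray
    thresholds: ThresholdVector
    labels: np.ndarray | None = None
    kernel_ids: np.ndarray | None = None  # original kernel index per column

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (-1, 1)).all():
            raise ValueError("literal values must be exactly +/-1")
        if self.kernel_ids is None:
            self.kernel_ids = np.arange(self.values.shape[1])
        self.kernel_ids = np.asarray(self.kernel_ids)
        if len(self.kernel_ids) != self.values.shape[1]:
            raise ValueError("kernel_ids misaligned with columns")

    @property
    def n_kernels(self) -> int:
        return self.values.shape[1]

    def codes(self) -> list[str]:
        all_codes = kernel_codes(int(self.kernel_ids.max()) + 1 if len(self.kernel_ids) else 0)
        return [all_codes[k] for k in self.kernel_ids]

    def column_of(self, kernel_id: int) -> int:
        hits = np.flatnonzero(self.kernel_ids == kernel_id)
        if not hits.size:
            raise KeyError(f"kernel {kernel_id} not present in literal table")
        return int(hits[0])

    def select_kernels(self, keep_ids) -> "LiteralTable":
        """Column subset (order preserved); used to restrict the vocabulary."""
        keep = set(int(k) for k in keep_ids)
        cols = [j for j, kid in enumerate(self.kernel_ids) if int(kid) in keep]
        return LiteralTable(
            values=self.values[:, cols],
            image_ids=self.image_ids,
            thresholds=ThresholdVector(
                self.thresholds.theta[cols], self.thresholds.provenance
            ),
            labels=self.labels,
            kernel_ids=self.kernel_ids[cols],
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.codes())
        df.insert(0, "image_id", self.image_ids)
        if self.labels is not None:
            df["label"] = self.labels
        df.to_csv(path, index=False)


def kernel_norms(activations: ActivationSet, labels: np.ndarray | None = None) -> KernelNormTable:
    """L1 norm (sum of absolute values) of every activation map."""
    a = activations.activations
    if not np.all(np.isfinite(a)):
        raise ValueError("activations contain NaN or inf")
    return KernelNormTable(
        norms=np.abs(a).sum(axis=(2, 3)),
        image_ids=np.asarray(activations.image_ids),
        labels=None if labels is None else np.asarray(labels),
    )


def compute_thresholds(train_norms: KernelNormTable) -> ThresholdVector:
    """Per-kernel arithmetic mean of the training norms."""
    if len(train_norms.norms) == 0:
        raise ValueError("cannot compute thresholds from an empty norm table")
    return ThresholdVector(theta=train_norms.norms.mean(axis=0))


def binarize(norms: KernelNormTable, thresholds: ThresholdVector) -> LiteralTable:
    """Map each norm to +1 iff strictly above its kernel's threshold, else -1.

    Ties (norm exactly equal to theta) binarize to -1.
    """
    if norms.n_kernels != len(thresholds.theta):
        raise ValueError(
            f"kernel count mismatch: norms have {norms.n_kernels}, "
            f"thresholds have {len(thresholds.theta)}"
        )
    values = np.where(norms.norms > thresholds.theta[None, :], 1, -1).astype(np.int8)
    return LiteralTable(
        values=values,
        image_ids=norms.image_ids,
        thresholds=thresholds,
        labels=norms.labels,
    )
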