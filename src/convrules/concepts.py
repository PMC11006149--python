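"""Assigning anatomical-region concepts to kernels via IOU hit rates.

A kernel's activation map is upsampled to image resolution, thresholded at a
percentile of its own values, and reduced to the tight bounding box of the
supra-threshold pixels.  Per image, a *hit* on a region is an
intersection-over-union above ``iou_min`` between that box and the region's
ground-truth box.  Hit rates aggregate over the whole dataset (images where
the kernel is silent count as misses).  A kernel is assigned the region with
the highest hit rate provided that rate exceeds ``hit_frac``; kernels with no
region above ``hit_frac``, or with more than ``max_regions`` regions above
it, are left uninterpretable.  The defaults — IOU > 0.5, hit rate > 70%, at
most two highly-hit regions — give concept labels that are specific to one
anatomical location.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize

from .adapter import ActivationSet
from .geometry import RegionBox, iou
from .quantization import LiteralTable, kernel_codes

__all__ = [
    "UNINTERPRETABLE",
    "ConceptMap",
    "activation_box",
    "iou",
    "RegionBox",
    "assign_concepts",
    "filter_interpretable",
]

UNINTERPRETABLE = "UNINTERPRETABLE"


def activation_box(
    activation_map: np.ndarray,
    image_size: int,
    percentile: float = 95.0,
    interpolation: str = "bilinear",
    smooth: int | None = None,
    level: float | None = None,
    min_size: int | None = None,
) -> RegionBox | None:
    """Tight bounding box of the strongest activated image region of one map.

    The map is upsampled to ``image_size`` (bilinear by default, "nearest"
    via ``interpolation``); with ``smooth`` it is then box-filtered at that
    width, spreading each unit's activation over (an estimate of) its
    receptive-field footprint.  The result is thresholded either at
    ``level`` times its peak (half-peak, ``level=0.5``, is the classic FWHM
    support) or, when ``level`` is ``None``, at the given percentile of its
    values.  Of the supra-threshold (>=) pixels, the connected component
    containing the maximum is taken as *the* activated region and its tight
    bounding box returned, so secondary activations elsewhere do not inflate
    the box.  ``min_size`` grows undersized boxes to that width, shifting
    inward at image borders, so a sharply peaked unit still claims its full
    receptive field.  A map with no positive activation yields ``None``.
    """
    m = np.asarray(activation_map, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("activation map contains non-finite values")
    if m.max() <= 0:
        return None
    order = {"bilinear": 1, "nearest": 0}[interpolation]
    up = resize(m, (image_size, image_size), order=order, anti_aliasing=False)
    if smooth:
        up = ndimage.uniform_filter(up, size=smooth)
    thr = level * up.max() if level is not None else np.percentile(up, percentile)
    mask = up >= thr
    labeled, _ = ndimage.label(mask)
    peak = np.unravel_index(np.argmax(up), up.shape)
    component = labeled == labeled[peak]
    ys, xs = np.nonzero(component)
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    if min_size:
        x0, x1 = _grow_span(x0, x1, min_size, image_size)
        y0, y1 = _grow_span(y0, y1, min_size, image_size)
    return RegionBox("activation", x0, y0, x1, y1)


def _grow_span(lo: int, hi: int, min_size: int, limit: int) -> tuple[int, int]:
    """Widen [lo, hi) to at least min_size, shifting inward at the borders."""
    if hi - lo >= min_size:
        return lo, hi
    center = (lo + hi) // 2
    lo = center - min_size // 2
    lo = max(0, min(lo, limit - min_size))
    return lo, lo + min_size


@dataclass
class ConceptMap:
    """Kernel -> region label (or uninterpretable) with per-region hit rates."""

    assignments: dict[int, str]
    hit_rates: pd.DataFrame  # index kernel id, columns region names
    highly_hit: dict[int, tuple[str, ...]]  # regions above hit_frac, per kernel
    iou_min: float = 0.5
    hit_frac: float = 0.70
    max_regions: int = 2
    percentile: float = 95.0

    def interpretable_kernels(self) -> list[int]:
        return [k for k, r in sorted(self.assignments.items()) if r != UNINTERPRETABLE]

    def kernels_for_region(self, region: str) -> list[int]:
        return [k for k, r in sorted(self.assignments.items()) if r == region]

    def groups(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for k, r in sorted(self.assignments.items()):
            if r != UNINTERPRETABLE:
                out.setdefault(r, []).append(k)
        return out

    def uninterpretable_kernels(self) -> list[int]:
        return [k for k, r in sorted(self.assignments.items()) if r == UNINTERPRETABLE]

    def to_csv(self, path) -> None:
        df = self.hit_rates.copy()
        codes = kernel_codes(int(df.index.max()) + 1)
        df.insert(0, "kernel_code", [codes[k] for k in df.index])
        df.insert(1, "assigned_region", [self.assignments[k] for k in df.index])
        df.to_csv(path, index_label="kernel")


def assign_concepts(
    activations: ActivationSet,
    boxes: list[dict[str, RegionBox]],
    image_size: int,
    iou_min: float = 0.5,
    hit_frac: float = 0.70,
    max_regions: int = 2,
    percentile: float = 95.0,
    interpolation: str = "bilinear",
    smooth: int | str | None = "auto",
    level: float | None = 0.5,
) -> ConceptMap:
    """Aggregate per-image IOU hits into a concept label per kernel.

    By default activation boxes use receptive-field smoothing (width
    ``image_size // 4``) and the half-peak support; pass ``smooth=None,
    level=None`` for raw percentile thresholding.
    """
    if smooth == "auto":
        smooth = image_size // 4
    n, k_l = activations.activations.shape[:2]
    if len(boxes) != n:
        missing = list(range(len(boxes), n))
        raise ValueError(f"missing region boxes for images {missing}")
    region_names = sorted({name for b in boxes for name in b})
    hits = np.zeros((k_l, len(region_names)))
    col = {r: j for j, r in enumerate(region_names)}
    for i in range(n):
        for k in range(k_l):
            abox = activation_box(
                activations.activations[i, k],
                image_size,
                percentile,
                interpolation,
                smooth=smooth,
                level=level,
                min_size=smooth,
            )
            if abox is None:
                continue  # silent kernel counts as a miss for every region
            for name, rbox in boxes[i].items():
                if iou(abox, rbox) > iou_min:
                    hits[k, col[name]] += 1
    rates = hits / n
    assignments: dict[int, str] = {}
    highly_hit: dict[int, tuple[str, ...]] = {}
    for k in range(k_l):
        above = [r for r in region_names if rates[k, col[r]] > hit_frac]
        highly_hit[k] = tuple(above)
        if not above or len(above) > max_regions:
            assignments[k] = UNINTERPRETABLE
        else:
            # highest hit rate wins; ties break by region-name order
            assignments[k] = max(above, key=lambda r: (rates[k, col[r]], _neg_name(r)))
    return ConceptMap(
        assignments=assignments,
        hit_rates=pd.DataFrame(rates, columns=region_names),
        highly_hit=highly_hit,
        iou_min=iou_min,
        hit_frac=hit_frac,
        max_regions=max_regions,
        percentile=percentile,
    )


class _neg_name(str):
    """Reverses string comparison so max() tie-breaks to the earlier name."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)


def filter_interpretable(literals: LiteralTable, concepts: ConceptMap) -> LiteralTable:
    """Restrict the literal vocabulary to interpretable kernels (order kept)."""
    keep = [k for k in concepts.interpretable_kernels() if k in set(literals.kernel_ids.tolist())]
    if not keep:
        raise ValueError("no interpretable kernels: cannot build a clinically relevant rule set")
    return literals.select_kernels(keep)
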