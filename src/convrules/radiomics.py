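"""Texture features for quantitative kernel-concept descriptions.

Kernel norms tell *that* a kernel separates the classes; radiomics features
on the kernel's assigned region tell *what* the kernel is measuring.  The
panel implemented here is the small set that characterizes homogenized
("obscured") versus structured texture:

* GLCM joint entropy — Shannon entropy (bits) of the normalized gray-level
  co-occurrence matrix; low values mean homogeneous texture.
* GLRLM gray-level and run-length non-uniformities — how unevenly runs
  distribute over gray levels / run lengths.
* First-order mean absolute deviation (MAD) and root mean square (RMS) of
  the raw intensities.

Crops are discretized per crop by min-max scaling into ``n_levels`` equal
bins (first-order features use raw intensities).  GLCM/GLRLM use distance 1
and the four undirected 2-D directions, averaging features over directions.
Pearson correlation links a kernel's per-image L1 norms to a region feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.feature import graycomatrix

from .geometry import RegionBox
from .quantization import KernelNormTable

__all__ = [
    "RegionCrop",
    "region_crop",
    "glcm_joint_entropy",
    "glrlm_nonuniformities",
    "first_order",
    "compute_feature_table",
    "correlate_norms",
    "CorrelationResult",
    "FEATURE_IDS",
]

FEATURE_IDS = (
    "GLCM_JointEntropy",
    "GLRLM_GrayLevelNonUniformity",
    "GLRLM_RunLengthNonUniformity",
    "FirstOrder_MAD",
    "FirstOrder_RMS",
)

#: Undirected neighbor offsets (row, col): 0, 45, 90 and 135 degrees.
_DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))


@dataclass
class RegionCrop:
    """One region's pixels: raw intensities plus per-crop discretization."""

    raw: np.ndarray  # float intensities
    levels: np.ndarray  # ints in 1..n_levels
    n_levels: int

    def __post_init__(self) -> None:
        if self.raw.size == 0:
            raise ValueError("empty region crop")
        if self.levels.min() < 1 or self.levels.max() > self.n_levels:
            raise ValueError("discretized levels out of range")


def discretize(values: np.ndarray, n_levels: int = 32) -> np.ndarray:
    """Min-max scale into 1..n_levels equal bins; constant input maps to 1."""
    v = np.asarray(values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.ones(v.shape, dtype=np.int64)
    lev = np.floor((v - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
    return np.clip(lev, 1, n_levels)


def region_crop(image: np.ndarray, box: RegionBox, n_levels: int = 32) -> RegionCrop:
    raw = np.asarray(image, dtype=float)[box.y0 : box.y1, box.x0 : box.x1]
    return RegionCrop(raw=raw, levels=discretize(raw, n_levels), n_levels=n_levels)


def glcm_joint_entropy(
    crop: RegionCrop,
    distance: int = 1,
    angles: tuple[float, ...] = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4),
) -> float:
    """Shannon entropy in bits of the symmetric co-occurrence matrix,
    averaged over the given angles (default: the four 2-D directions)."""
    if min(crop.levels.shape) < 2:
        raise ValueError("GLCM needs a crop of at least 2x2 pixels")
    img = (crop.levels - 1).astype(np.uint8)
    # skimage's angle convention yields the undirected offset set _DIRECTIONS
    mats = graycomatrix(
        img,
        distances=[distance],
        angles=list(angles),
        levels=crop.n_levels,
        symmetric=True,
        normed=True,
    )
    entropies = []
    for a in range(mats.shape[3]):
        p = mats[:, :, 0, a]
        p = p[p > 0]
        entropies.append(float(-(p * np.log2(p)).sum()))
    return float(np.mean(entropies))


def _lines(arr: np.ndarray, dr: int, dc: int):
    """All maximal lattice lines of ``arr`` along direction (dr, dc)."""
    h, w = arr.shape
    if (dr, dc) == (0, 1):
        yield from arr
    elif (dr, dc) == (1, 0):
        yield from arr.T
    elif (dr, dc) == (1, 1):
        for off in range(-(h - 1), w):
            yield np.diagonal(arr, offset=off)
    elif (dr, dc) == (1, -1):
        flipped = arr[:, ::-1]
        for off in range(-(h - 1), w):
            yield np.diagonal(flipped, offset=off)
    else:
        raise ValueError(f"unsupported direction {(dr, dc)}")


def _run_length_matrix(levels: np.ndarray, n_levels: int, direction: tuple[int, int]) -> np.ndarray:
    """P[i, j]: number of runs of gray level i+1 with length j+1."""
    max_len = max(levels.shape)
    P = np.zeros((n_levels, max_len))
    for line in _lines(levels, *direction):
        if len(line) == 0:
            continue
        boundaries = np.flatnonzero(np.diff(line)) + 1
        for seg in np.split(np.asarray(line), boundaries):
            P[seg[0] - 1, len(seg) - 1] += 1
    return P


def glrlm_nonuniformities(
    crop: RegionCrop, directions=_DIRECTIONS
) -> tuple[float, float]:
    """(gray-level non-uniformity, run-length non-uniformity), averaged over
    the given directions.

    With runs counted in P(i, j), GLN = sum_i (sum_j P)^2 / N_r and
    RLN = sum_j (sum_i P)^2 / N_r, where N_r is the total number of runs.
    """
    if crop.levels.size < 2:
        raise ValueError("GLRLM needs a crop with at least 2 pixels")
    gln_vals, rln_vals = [], []
    for d in directions:
        P = _run_length_matrix(crop.levels, crop.n_levels, tuple(d))
        n_runs = P.sum()
        gln_vals.append(float((P.sum(axis=1) ** 2).sum() / n_runs))
        rln_vals.append(float((P.sum(axis=0) ** 2).sum() / n_runs))
    return float(np.mean(gln_vals)), float(np.mean(rln_vals))


def first_order(crop: RegionCrop) -> tuple[float, float]:
    """(mean absolute deviation, root mean square) of the raw intensities."""
    x = crop.raw
    mad = float(np.mean(np.abs(x - x.mean())))
    rms = float(np.sqrt(np.mean(x**2)))
    return mad, rms


def compute_feature_table(
    images: np.ndarray,
    boxes: list[dict[str, RegionBox]],
    regions: list[str] | None = None,
    n_levels: int = 32,
) -> pd.DataFrame:
    """Tidy table of all panel features per (image, region)."""
    rows = []
    for i, img in enumerate(images):
        names = regions if regions is not None else sorted(boxes[i])
        for name in names:
            crop = region_crop(img, boxes[i][name], n_levels)
            je = glcm_joint_entropy(crop)
            gln, rln = glrlm_nonuniformities(crop)
            mad, rms = first_order(crop)
            for fid, val in zip(FEATURE_IDS, (je, gln, rln, mad, rms)):
                rows.append({"image_id": i, "region": name, "feature": fid, "value": val})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    kernel: int
    region: str
    feature: str
    r: float
    slope: float
    intercept: float
    n: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r)


def correlate_norms(
    norms: KernelNormTable,
    feature_table: pd.DataFrame,
    kernel: int,
    region: str,
    feature: str = "GLCM_JointEntropy",
) -> CorrelationResult:
    """Pearson correlation between one kernel's per-image L1 norms and a
    region feature, with the fitted trend line.

    Zero-variance inputs leave the correlation undefined (NaN).
    """
    sub = feature_table[(feature_table.region == region) & (feature_table.feature == feature)]
    sub = sub.sort_values("image_id")
    ids = sub.image_id.to_numpy()
    order = {int(i): j for j, i in enumerate(np.asarray(norms.image_ids))}
    rows = [order[int(i)] for i in ids]
    x = norms.norms[rows, kernel]
    y = sub.value.to_numpy()
    if len(x) < 3:
        raise ValueError("need at least 3 aligned images for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(kernel, region, feature, float("nan"), float("nan"), float("nan"), len(x))
    r = float(stats.pearsonr(x, y).statistic)
    slope, intercept = np.polyfit(x, y, 1)
    return CorrelationResult(kernel, region, feature, r, float(slope), float(intercept), len(x))
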