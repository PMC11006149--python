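"""Independent brute-force oracles used to check the library implementations.

Everything here is written as plain loops over elements, pairs or runs, kept
deliberately naive and separate from the package's vectorized code paths.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np


# ---- quantization ----------------------------------------------------------

def loop_kernel_norms(activations: np.ndarray) -> np.ndarray:
    n, k = activations.shape[:2]
    out = np.zeros((n, k))
    for i in range(n):
        for j in range(k):
            s = 0.0
            for v in activations[i, j].ravel():
                s += abs(v)
            out[i, j] = s
    return out


def loop_means(norms: np.ndarray) -> np.ndarray:
    n, k = norms.shape
    out = np.zeros(k)
    for j in range(k):
        s = 0.0
        for i in range(n):
            s += norms[i, j]
        out[j] = s / n
    return out


def loop_binarize(norms: np.ndarray, theta: np.ndarray) -> np.ndarray:
    n, k = norms.shape
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        for j in range(k):
            out[i, j] = 1 if norms[i, j] > theta[j] else -1
    return out


# ---- decision trees --------------------------------------------------------

def best_tree_errors(values: np.ndarray, targets: np.ndarray, depth: int) -> int:
    """Minimum training misclassifications achievable by any decision tree of
    the given depth over +/-1 literal columns (exhaustive search with
    memoization; no kernel repeats on a path)."""
    values = np.asarray(values)
    targets = np.asarray(targets)
    n, k = values.shape

    def solve(idx: tuple[int, ...], used: frozenset[int], d: int) -> int:
        sub = targets[list(idx)]
        majority_err = min(int(np.sum(sub == 0)), int(np.sum(sub == 1)))
        if d == 0 or majority_err == 0:
            return majority_err
        best = majority_err
        for col in range(k):
            if col in used:
                continue
            pos = tuple(i for i in idx if values[i, col] == 1)
            neg = tuple(i for i in idx if values[i, col] == -1)
            if not pos or not neg:
                continue
            err = solve(pos, used | {col}, d - 1) + solve(neg, used | {col}, d - 1)
            best = min(best, err)
        return best

    return solve(tuple(range(n)), frozenset(), depth)


# ---- geometry --------------------------------------------------------------

def pixel_iou(a, b, size: int = 80) -> float:
    """IOU by literally counting pixels on a grid."""
    ga = np.zeros((size, size), dtype=bool)
    gb = np.zeros((size, size), dtype=bool)
    ga[a.y0 : a.y1, a.x0 : a.x1] = True
    gb[b.y0 : b.y1, b.x0 : b.x1] = True
    inter = int(np.sum(ga & gb))
    union = int(np.sum(ga | gb))
    return inter / union


# ---- radiomics -------------------------------------------------------------

OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))


def glcm_entropy_brute(levels: np.ndarray, n_levels: int, offsets=OFFSETS) -> float:
    """Joint entropy (bits) of the symmetric normalized co-occurrence matrix,
    averaged over offsets, by explicit pair enumeration."""
    h, w = levels.shape
    entropies = []
    for dr, dc in offsets:
        counts: dict[tuple[int, int], int] = {}
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    for pair in ((levels[r, c], levels[r2, c2]), (levels[r2, c2], levels[r, c])):
                        counts[pair] = counts.get(pair, 0) + 1
        total = sum(counts.values())
        ent = 0.0
        for v in counts.values():
            p = v / total
            ent -= p * math.log2(p)
        entropies.append(ent)
    return float(np.mean(entropies))


def glrlm_brute(levels: np.ndarray, n_levels: int, offsets=OFFSETS) -> tuple[float, float]:
    """(GLN, RLN) averaged over directions by explicit run enumeration."""
    h, w = levels.shape
    glns, rlns = [], []
    for dr, dc in offsets:
        runs: list[tuple[int, int]] = []  # (gray level, run length)
        starts = []
        for r in range(h):
            for c in range(w):
                rp, cp = r - dr, c - dc
                if not (0 <= rp < h and 0 <= cp < w):
                    starts.append((r, c))
        for r0, c0 in starts:
            line = []
            r, c = r0, c0
            while 0 <= r < h and 0 <= c < w:
                line.append(levels[r, c])
                r, c = r + dr, c + dc
            i = 0
            while i < len(line):
                j = i
                while j < len(line) and line[j] == line[i]:
                    j += 1
                runs.append((int(line[i]), j - i))
                i = j
        n_runs = len(runs)
        by_level: dict[int, int] = {}
        by_length: dict[int, int] = {}
        for lev, length in runs:
            by_level[lev] = by_level.get(lev, 0) + 1
            by_length[length] = by_length.get(length, 0) + 1
        glns.append(sum(v * v for v in by_level.values()) / n_runs)
        rlns.append(sum(v * v for v in by_length.values()) / n_runs)
    return float(np.mean(glns)), float(np.mean(rlns))
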