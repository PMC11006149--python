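"""Relevance of kernel concept groups via muting / activation experiments.

Muting replaces a kernel's feature maps with zeros before the classifier
head; activating a set of kernels means muting its complement.  Four
experiments quantify how much the anatomically-assigned kernel groups carry:

* incremental activation of region groups versus size-matched random subsets
  of uninterpretable kernels (100 replicates by default);
* muting one region's kernels together with all uninterpretable kernels;
* exhaustive ranking of all size-``choose`` region-group combinations;
* a random-muting curve over increasing muted fractions.

All accuracies are against ground-truth labels on the supplied split, and all
randomness flows through an explicit seed, so every number is reproducible
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .adapter import FeatureModel, KernelMask
from .phantom import PhantomDataset

__all__ = [
    "KernelGroups",
    "AblationResult",
    "incremental_activation",
    "single_region_muting",
    "combination_ranking",
    "random_muting_curve",
]


@dataclass(frozen=True)
class KernelGroups:
    """Region name -> kernel id set, plus the uninterpretable pool."""

    groups: dict[str, tuple[int, ...]]
    uninterpretable: tuple[int, ...]
    n_kernels: int

    def __post_init__(self) -> None:
        seen: set[int] = set(self.uninterpretable)
        if len(seen) != len(self.uninterpretable):
            raise ValueError("duplicate uninterpretable kernel ids")
        for name, ids in self.groups.items():
            s = set(ids)
            if len(s) != len(ids):
                raise ValueError(f"duplicate kernel ids in group {name!r}")
            if s & seen:
                raise ValueError(f"group {name!r} overlaps another group")
            seen |= s
        if seen and (min(seen) < 0 or max(seen) >= self.n_kernels):
            raise ValueError("kernel ids out of range")

    @staticmethod
    def from_concept_map(concepts, n_kernels: int) -> "KernelGroups":
        return KernelGroups(
            groups={r: tuple(ids) for r, ids in concepts.groups().items()},
            uninterpretable=tuple(concepts.uninterpretable_kernels()),
            n_kernels=n_kernels,
        )

    def union(self, names) -> tuple[int, ...]:
        out: list[int] = []
        for name in names:
            out.extend(self.groups[name])
        return tuple(sorted(out))


@dataclass
class AblationResult:
    """Tidy per-condition records of one experiment."""

    experiment: str
    records: list[dict] = field(default_factory=list)
    seed: int | None = None

    def add(self, condition: str, accuracy: float, n_kernels: int, total: int, replicate: int | None = None) -> None:
        self.records.append(
            {
                "experiment": self.experiment,
                "condition": condition,
                "replicate": replicate,
                "accuracy": accuracy,
                "n_kernels": n_kernels,
                "pct_kernels": 100.0 * n_kernels / total,
            }
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def accuracy_of(self, condition: str) -> float:
        vals = [r["accuracy"] for r in self.records if r["condition"] == condition]
        if not vals:
            raise KeyError(condition)
        return vals[0]

    def baseline_stats(self, condition: str) -> tuple[float, float]:
        vals = [r["accuracy"] for r in self.records if r["condition"] == condition]
        return float(np.mean(vals)), float(np.std(vals))


class _MaskEvaluator:
    """Caches g(x) for a dataset so each mask costs only the head pass."""

    def __init__(self, model: FeatureModel, dataset: PhantomDataset):
        from .adapter import extract_activations

        self.model = model
        self.feats = extract_activations(model, dataset.images).activations
        self.labels = np.asarray(dataset.labels)

    def accuracy(self, mask: KernelMask | None) -> float:
        preds = self.model.predict_from_features(self.feats, mask)
        return float(np.mean(preds == self.labels))


def incremental_activation(
    model: FeatureModel,
    dataset: PhantomDataset,
    groups: KernelGroups,
    order: list[str] | None = None,
    n_reps: int = 100,
    seed: int = 0,
) -> AblationResult:
    """Accuracy as region groups are activated one by one, with size-matched
    random-uninterpretable baselines (sampled without replacement)."""
    order = list(order) if order is not None else sorted(groups.groups)
    unknown = [r for r in order if r not in groups.groups]
    if unknown:
        raise ValueError(f"unknown groups in order: {unknown}")
    rng = np.random.default_rng(seed)
    total = groups.n_kernels
    ev = _MaskEvaluator(model, dataset)
    result = AblationResult("incremental_activation", seed=seed)
    pool = np.asarray(groups.uninterpretable)
    for p in range(1, len(order) + 1):
        active = groups.union(order[:p])
        cond = "+".join(order[:p])
        result.add(cond, ev.accuracy(KernelMask.activate_only(active)), len(active), total)
        if len(active) > len(pool):
            raise ValueError(
                f"baseline needs {len(active)} uninterpretable kernels, only {len(pool)} available"
            )
        for rep in range(n_reps):
            sample = rng.choice(pool, size=len(active), replace=False)
            result.add(
                f"random_baseline_size_{len(active)}",
                ev.accuracy(KernelMask.activate_only(sample)),
                len(active),
                total,
                replicate=rep,
            )
    result.add("all_kernels", ev.accuracy(None), total, total)
    result.add(
        "all_uninterpretable_only",
        ev.accuracy(KernelMask.activate_only(pool)),
        len(pool),
        total,
    )
    return result


def single_region_muting(
    model: FeatureModel, dataset: PhantomDataset, groups: KernelGroups
) -> AblationResult:
    """Accuracy when one region's kernels are muted along with every
    uninterpretable kernel; the reference mutes uninterpretable only."""
    if not groups.groups:
        raise ValueError("no kernel groups to mute")
    total = groups.n_kernels
    ev = _MaskEvaluator(model, dataset)
    result = AblationResult("single_region_muting")
    uninterp = groups.uninterpretable
    result.add(
        "reference_uninterpretable_muted",
        ev.accuracy(KernelMask.mute(uninterp)),
        total - len(uninterp),
        total,
    )
    for region in sorted(groups.groups):
        muted = tuple(sorted(set(uninterp) | set(groups.groups[region])))
        result.add(
            f"mute_{region}",
            ev.accuracy(KernelMask.mute(muted)),
            total - len(muted),
            total,
        )
    return result


def combination_ranking(
    model: FeatureModel,
    dataset: PhantomDataset,
    groups: KernelGroups,
    choose: int = 4,
    top_k: int = 20,
    max_evaluations: int = 5000,
) -> AblationResult:
    """Exhaustively rank all size-``choose`` region combinations by the
    accuracy of activating only their kernels."""
    names = sorted(groups.groups)
    if choose > len(names):
        raise ValueError(f"cannot choose {choose} of {len(names)} groups")
    combos = list(combinations(names, choose))
    if len(combos) > max_evaluations:
        raise ValueError(
            f"{len(combos)} combinations exceed the cap of {max_evaluations}; "
            "restrict the groups or raise max_evaluations"
        )
    total = groups.n_kernels
    ev = _MaskEvaluator(model, dataset)
    scored = []
    for combo in combos:
        active = groups.union(combo)
        scored.append(("+".join(combo), ev.accuracy(KernelMask.activate_only(active)), len(active)))
    scored.sort(key=lambda t: (-t[1], t[0]))
    result = AblationResult("combination_ranking")
    for cond, acc, n_active in scored[:top_k]:
        result.add(cond, acc, n_active, total)
    result.add("all_kernels", ev.accuracy(None), total, total)
    return result


def random_muting_curve(
    model: FeatureModel,
    dataset: PhantomDataset,
    fractions=tuple(f / 10 for f in range(1, 10)),
    n_reps: int = 20,
    seed: int = 0,
) -> AblationResult:
    """Accuracy distribution while muting increasing random kernel fractions."""
    if any(not (0.0 < f < 1.0) for f in fractions):
        raise ValueError("fractions must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    total = model.n_kernels
    ev = _MaskEvaluator(model, dataset)
    result = AblationResult("random_muting_curve", seed=seed)
    result.add("fraction_0.0", ev.accuracy(None), total, total)
    for f in fractions:
        n_mute = int(round(f * total))
        for rep in range(n_reps):
            muted = rng.choice(total, size=n_mute, replace=False)
            result.add(
                f"fraction_{f:.1f}",
                ev.accuracy(KernelMask.mute(muted)),
                total - n_mute,
                total,
                replicate=rep,
            )
    return result
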