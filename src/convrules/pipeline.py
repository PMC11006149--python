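"""End-to-end orchestration: phantom -> CNN -> literals -> concepts -> rules
-> ablation -> radiomics, with every artifact written under one run directory.

The run directory holds one file per stage output (arrays as ``.npz``, tables
as CSV, rule sets as JSON/DOT) plus ``manifest.json`` carrying the config, its
hash and the seed, so any later stage — including the what-if intervention —
can verify it is operating on the bundle it was derived from.  Identical
config and seed reproduce every file byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ablation as ab
from .adapter import (
    ActivationSet,
    FeatureModel,
    extract_activations,
    load_checkpoint,
    save_checkpoint,
    train_tiny_cnn,
)
from .concepts import ConceptMap, assign_concepts, filter_interpretable
from .geometry import write_boxes_csv
from .nn import ArchConfig
from .phantom import PhantomConfig, PhantomDataset, generate_dataset, validation_config
from .quantization import (
    KernelNormTable,
    LiteralTable,
    ThresholdVector,
    binarize,
    compute_thresholds,
    kernel_codes,
    kernel_norms,
)
from .rules import (
    DecisionTree,
    EvaluationReport,
    InterventionResult,
    RuleSet,
    apply_rules,
    evaluate,
    induce_tree,
    intervene,
    prune_tree,
    tree_to_dot,
    tree_to_rules,
)

logger = logging.getLogger("convrules")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "what_if", "config_hash"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline in one validated, hashable place."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    arch: ArchConfig = field(default_factory=ArchConfig)
    val_n_per_class: int = 40
    epochs: int = 25
    lr: float = 3e-3
    min_val_accuracy: float = 0.7
    max_depth: int = 3
    min_leaf: int = 2
    prune_fraction: float = 0.2
    iou_min: float = 0.5
    hit_frac: float = 0.70
    max_regions: int = 2
    percentile: float = 95.0
    filter_uninterpretable: bool = True
    n_reps_incremental: int = 100
    n_reps_curve: int = 20
    combination_choose: int = 2
    top_k: int = 20
    n_levels: int = 32
    run_ablation: bool = True
    run_radiomics: bool = True
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self, seed=seed, phantom=dataclasses.replace(self.phantom, seed=seed)
        )


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything the pipeline computed, ready for inspection or export."""

    config: PipelineConfig
    dataset: PhantomDataset
    val_dataset: PhantomDataset
    model: FeatureModel
    norms: KernelNormTable
    thresholds: ThresholdVector
    literals: LiteralTable
    val_literals: LiteralTable
    cnn_train_predictions: np.ndarray
    cnn_val_predictions: np.ndarray
    concepts: ConceptMap
    baseline_tree: DecisionTree
    baseline_rules: RuleSet
    baseline_report: EvaluationReport
    baseline_val_report: EvaluationReport
    filtered_literals: LiteralTable | None = None
    tree: DecisionTree | None = None
    rules: RuleSet | None = None
    report: EvaluationReport | None = None
    val_report: EvaluationReport | None = None
    ablation_results: dict[str, ab.AblationResult] = field(default_factory=dict)
    feature_table: pd.DataFrame | None = None
    correlations: pd.DataFrame | None = None

    def summary(self) -> str:
        cfg = self.config
        codes = kernel_codes(self.model.n_kernels)
        lines = [
            f"convrules pipeline summary (seed {cfg.seed}, config {config_hash(cfg)})",
            "",
            f"phantom: {2 * cfg.phantom.n_per_class} train images "
            f"({cfg.phantom.image_size}px), signal regions {list(cfg.phantom.signal_regions)}",
            f"CNN: {self.model.n_kernels} kernels at the feature layer; "
            f"train acc {self.model.train_accuracy:.3f}, val acc {self.model.val_accuracy:.3f}",
            f"thresholds theta: min {self.thresholds.theta.min():.3f}, "
            f"median {np.median(self.thresholds.theta):.3f}, max {self.thresholds.theta.max():.3f}",
            f"concept thresholds: iou_min {cfg.iou_min}, hit_frac {cfg.hit_frac}, "
            f"max_regions {cfg.max_regions}, percentile {cfg.percentile}",
            "kernel concepts: "
            + ", ".join(
                f"{codes[k]}={r}" for k, r in sorted(self.concepts.assignments.items())
            ),
            "",
            "baseline rule set (all kernels):",
            _report_lines(self.baseline_report, self.baseline_val_report),
        ]
        if self.report is not None:
            lines += ["interpretable-kernel rule set:", _report_lines(self.report, self.val_report)]
        return "\n".join(lines) + "\n"


def _report_lines(train: EvaluationReport, val: EvaluationReport | None) -> str:
    out = (
        f"  train: accuracy {train.accuracy:.3f}, fidelity {train.fidelity:.3f}, "
        f"sensitivity {train.sensitivity:.3f}, specificity {train.specificity:.3f}"
    )
    if val is not None:
        out += (
            f"\n  validation: accuracy {val.accuracy:.3f}, fidelity {val.fidelity:.3f}, "
            f"sensitivity {val.sensitivity:.3f}, specificity {val.specificity:.3f}"
        )
    return out


def _grow_prune_split(n: int, labels: np.ndarray, fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic stratified split: the tail ``fraction`` of each class
    becomes the pruning fold."""
    grow, prune = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n_prune = int(round(fraction * len(idx)))
        prune.extend(idx[len(idx) - n_prune :])
        grow.extend(idx[: len(idx) - n_prune])
    return np.sort(np.asarray(grow, dtype=int)), np.sort(np.asarray(prune, dtype=int))


def _subset_literals(lit: LiteralTable, idx: np.ndarray) -> LiteralTable:
    return LiteralTable(
        values=lit.values[idx],
        image_ids=np.asarray(lit.image_ids)[idx],
        thresholds=lit.thresholds,
        labels=None if lit.labels is None else np.asarray(lit.labels)[idx],
        kernel_ids=lit.kernel_ids,
    )


def induce_pruned_rules(
    literals: LiteralTable,
    cnn_predictions: np.ndarray,
    labels: np.ndarray,
    max_depth: int = 3,
    min_leaf: int = 2,
    prune_fraction: float = 0.2,
) -> tuple[DecisionTree, RuleSet]:
    """Grow on (1 - prune_fraction) of the split, reduced-error prune on the rest."""
    grow_idx, prune_idx = _grow_prune_split(len(cnn_predictions), np.asarray(labels), prune_fraction)
    tree = induce_tree(
        _subset_literals(literals, grow_idx),
        cnn_predictions[grow_idx],
        max_depth=max_depth,
        min_leaf=min_leaf,
    )
    if len(prune_idx):
        tree = prune_tree(tree, _subset_literals(literals, prune_idx), cnn_predictions[prune_idx])
    else:
        warnings.warn("prune fraction left no images: skipping pruning", stacklevel=2)
    return tree, tree_to_rules(tree)


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Execute every stage; write the artifact bundle when ``outdir`` is given."""
    logger.info("generating phantom dataset (seed %d)", config.seed)
    dataset = generate_dataset(config.phantom)
    val_dataset = generate_dataset(validation_config(config.phantom, config.val_n_per_class))

    logger.info("training built-in CNN")
    model = train_tiny_cnn(
        dataset,
        arch=config.arch,
        seed=config.seed,
        epochs=config.epochs,
        lr=config.lr,
        min_val_accuracy=config.min_val_accuracy,
    )

    acts = extract_activations(model, dataset.images)
    val_acts = extract_activations(model, val_dataset.images)
    norms = kernel_norms(acts, labels=dataset.labels)
    thresholds = compute_thresholds(norms)
    logger.info(
        "thresholds theta: min %.3f max %.3f", thresholds.theta.min(), thresholds.theta.max()
    )
    literals = binarize(norms, thresholds)
    val_literals = binarize(kernel_norms(val_acts, labels=val_dataset.labels), thresholds)

    cnn_train = model.predict(dataset.images)
    cnn_val = model.predict(val_dataset.images)

    logger.info("assigning concepts (iou_min %.2f, hit_frac %.2f)", config.iou_min, config.hit_frac)
    concepts = assign_concepts(
        acts,
        dataset.boxes,
        image_size=config.phantom.image_size,
        iou_min=config.iou_min,
        hit_frac=config.hit_frac,
        max_regions=config.max_regions,
        percentile=config.percentile,
    )

    baseline_tree, baseline_rules = induce_pruned_rules(
        literals,
        cnn_train,
        dataset.labels,
        max_depth=config.max_depth,
        min_leaf=config.min_leaf,
        prune_fraction=config.prune_fraction,
    )
    baseline_report = evaluate(baseline_rules, literals, dataset.labels, cnn_train, split="train")
    baseline_val_report = evaluate(
        baseline_rules, val_literals, val_dataset.labels, cnn_val, split="validation"
    )

    result = PipelineResult(
        config=config,
        dataset=dataset,
        val_dataset=val_dataset,
        model=model,
        norms=norms,
        thresholds=thresholds,
        literals=literals,
        val_literals=val_literals,
        cnn_train_predictions=cnn_train,
        cnn_val_predictions=cnn_val,
        concepts=concepts,
        baseline_tree=baseline_tree,
        baseline_rules=baseline_rules,
        baseline_report=baseline_report,
        baseline_val_report=baseline_val_report,
    )

    if config.filter_uninterpretable and concepts.interpretable_kernels():
        filtered = filter_interpretable(literals, concepts)
        tree, rules = induce_pruned_rules(
            filtered,
            cnn_train,
            dataset.labels,
            max_depth=config.max_depth,
            min_leaf=config.min_leaf,
            prune_fraction=config.prune_fraction,
        )
        result.filtered_literals = filtered
        result.tree = tree
        result.rules = rules
        result.report = evaluate(rules, filtered, dataset.labels, cnn_train, split="train")
        result.val_report = evaluate(
            rules,
            filter_interpretable(val_literals, concepts),
            val_dataset.labels,
            cnn_val,
            split="validation",
        )
    elif config.filter_uninterpretable:
        warnings.warn("no interpretable kernels; skipping filtered rule set", stacklevel=2)

    if config.run_ablation:
        groups = ab.KernelGroups.from_concept_map(concepts, model.n_kernels)
        if groups.groups:
            order = sorted(groups.groups)
            try:
                result.ablation_results["incremental_activation"] = ab.incremental_activation(
                    model, dataset, groups, order=order, n_reps=config.n_reps_incremental, seed=config.seed
                )
            except ValueError as exc:
                logger.warning("incremental activation skipped: %s", exc)
            result.ablation_results["single_region_muting"] = ab.single_region_muting(
                model, dataset, groups
            )
            choose = min(config.combination_choose, len(groups.groups))
            result.ablation_results["combination_ranking"] = ab.combination_ranking(
                model, dataset, groups, choose=choose, top_k=config.top_k
            )
        result.ablation_results["random_muting_curve"] = ab.random_muting_curve(
            model, dataset, n_reps=config.n_reps_curve, seed=config.seed
        )

    if config.run_radiomics:
        regions = sorted({r for r in concepts.assignments.values() if r != "UNINTERPRETABLE"})
        if regions:
            from .radiomics import FEATURE_IDS, compute_feature_table, correlate_norms

            ft = compute_feature_table(dataset.images, dataset.boxes, regions=regions, n_levels=config.n_levels)
            corr_rows = []
            for k in concepts.interpretable_kernels():
                region = concepts.assignments[k]
                for fid in FEATURE_IDS:
                    c = correlate_norms(norms, ft, kernel=k, region=region, feature=fid)
                    corr_rows.append(
                        {"kernel": k, "region": region, "feature": fid, "r": c.r, "n": c.n}
                    )
            result.feature_table = ft
            result.correlations = pd.DataFrame(corr_rows)

    if outdir is not None:
        _write_bundle(result, Path(outdir))
    return result


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    manifest = {
        "config": dataclasses.asdict(cfg),
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str, sort_keys=True))
    save_checkpoint(result.model, outdir / "model.npz")
    write_boxes_csv(outdir / "boxes.csv", result.dataset.boxes)
    result.norms.to_csv(outdir / "kernel_norms.csv")
    result.literals.to_csv(outdir / "literals.csv")
    pd.DataFrame(
        {"kernel": np.arange(len(result.thresholds.theta)), "theta": result.thresholds.theta}
    ).to_csv(outdir / "thresholds.csv", index=False)
    pd.DataFrame(
        {
            "image_id": np.arange(len(result.cnn_train_predictions)),
            "cnn_prediction": result.cnn_train_predictions,
            "label": result.dataset.labels,
        }
    ).to_csv(outdir / "cnn_predictions.csv", index=False)
    result.concepts.to_csv(outdir / "concepts.csv")
    codes = dict(enumerate(kernel_codes(result.model.n_kernels)))
    (outdir / "rules_baseline.json").write_text(result.baseline_rules.to_json(codes))
    (outdir / "rules_baseline.dot").write_text(tree_to_dot(result.baseline_tree, codes))
    reports = [dataclasses.asdict(result.baseline_report), dataclasses.asdict(result.baseline_val_report)]
    if result.rules is not None:
        (outdir / "rules_filtered.json").write_text(result.rules.to_json(codes))
        (outdir / "rules_filtered.dot").write_text(tree_to_dot(result.tree, codes))
        reports += [dataclasses.asdict(result.report), dataclasses.asdict(result.val_report)]
    rep = pd.DataFrame(reports)
    rep.insert(0, "rule_set", ["baseline", "baseline", "filtered", "filtered"][: len(reports)])
    rep.to_csv(outdir / "evaluation.csv", index=False)
    for name, res in result.ablation_results.items():
        res.to_csv(outdir / f"ablation_{name}.csv")
    if result.feature_table is not None:
        result.feature_table.to_csv(outdir / "radiomics_features.csv", index=False)
        result.correlations.to_csv(outdir / "radiomics_correlations.csv", index=False)
    (outdir / "summary.txt").write_text(result.summary())


def what_if(
    run_dir,
    allow=None,
    deny=None,
    expected_hash: str | None = None,
) -> InterventionResult:
    """Re-induce the rule set from a saved bundle under allow/deny constraints.

    Raises when the bundle's config hash does not match ``expected_hash``
    (stale-bundle guard).  Writes before/after DOT files and a delta CSV back
    into the run directory.
    """
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    if expected_hash is not None and manifest["config_hash"] != expected_hash:
        raise ValueError(
            f"stale bundle: manifest hash {manifest['config_hash']} != expected {expected_hash}"
        )
    lit_df = pd.read_csv(run_dir / "literals.csv")
    thr = pd.read_csv(run_dir / "thresholds.csv")
    preds = pd.read_csv(run_dir / "cnn_predictions.csv")
    value_cols = [c for c in lit_df.columns if c not in ("image_id", "label")]
    literals = LiteralTable(
        values=lit_df[value_cols].to_numpy(),
        image_ids=lit_df.image_id.to_numpy(),
        thresholds=ThresholdVector(thr.theta.to_numpy()),
        labels=lit_df.label.to_numpy() if "label" in lit_df else None,
    )
    cfg = manifest["config"]
    res = intervene(
        literals,
        preds.cnn_prediction.to_numpy(),
        preds.label.to_numpy(),
        allow=allow,
        deny=deny,
        max_depth=int(cfg["max_depth"]),
        min_leaf=int(cfg["min_leaf"]),
    )
    codes = dict(enumerate(kernel_codes(literals.n_kernels)))
    before = induce_tree(literals, preds.cnn_prediction.to_numpy(), max_depth=int(cfg["max_depth"]), min_leaf=int(cfg["min_leaf"]))
    after = induce_tree(
        literals,
        preds.cnn_prediction.to_numpy(),
        max_depth=int(cfg["max_depth"]),
        allowed_kernels=allow,
        denied_kernels=deny,
        min_leaf=int(cfg["min_leaf"]),
    )
    (run_dir / "whatif_before.dot").write_text(tree_to_dot(before, codes))
    (run_dir / "whatif_after.dot").write_text(tree_to_dot(after, codes))
    pd.DataFrame(
        [
            {
                "fidelity_before": res.baseline_report.fidelity,
                "fidelity_after": res.report.fidelity,
                "fidelity_delta": res.fidelity_delta,
                "accuracy_before": res.baseline_report.accuracy,
                "accuracy_after": res.report.accuracy,
                "accuracy_delta": res.accuracy_delta,
            }
        ]
    ).to_csv(run_dir / "whatif_deltas.csv", index=False)
    return res
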