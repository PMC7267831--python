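"""End-to-end benchmark orchestration.

Given a network and a preprocessed geneset collection, build one labeled
task per geneset (Fisher-filtered negatives), split the genes under a
validation scheme, run the requested methods on cached feature matrices and
emit per-(geneset, method) evaluation records.

For k-fold cross-validation the per-geneset metric is the mean of the
fold-level metric values; the prior used for normalisation is the task-level
positive fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .evaluate import EvalRecord, auprc, auroc, log2_prior_ratio, p_at_topk
from .exceptions import ValidationError
from .features import FeatureMatrix
from .genesets import GenesetCollection, LabeledTask, build_task
from .network import GeneNetwork
from .predict import MethodConfig, _REPRESENTATION, apply_method, build_features
from .splits import (
    LabeledSplit,
    filter_tasks,
    restrict_task_to_network,
    stratified_kfold,
)

logger = logging.getLogger(__name__)

METRICS = ("auPRC", "P@TopK", "auROC")


@dataclass
class FeatureCache:
    """Compute each representation of one network at most once."""

    network: GeneNetwork
    config: MethodConfig = field(default_factory=MethodConfig)
    _cache: dict[str, FeatureMatrix] = field(default_factory=dict)

    def get(self, kind: str) -> FeatureMatrix:
        if kind not in self._cache:
            logger.info("computing %s features for %s", kind, self.network.name)
            self._cache[kind] = build_features(self.network, kind, self.config)
        return self._cache[kind]

    def for_method(self, method: str) -> FeatureMatrix:
        return self.get(_REPRESENTATION[method])


def build_tasks(
    collection: GenesetCollection,
    network: GeneNetwork,
    p_threshold: float = 0.05,
) -> list[LabeledTask]:
    """One task per geneset, restricted to genes present in the network."""
    tasks = []
    for sid in sorted(collection.sets):
        task = build_task(collection, sid, p_threshold=p_threshold)
        tasks.append(restrict_task_to_network(task, network.nodes))
    return tasks


def _labels_for(task: LabeledTask, genes) -> dict[str, int]:
    return {g: (1 if g in task.positives else 0) for g in genes}


def evaluate_split(
    methods: Sequence[str],
    cache: FeatureCache,
    task: LabeledTask,
    split: LabeledSplit,
    config: MethodConfig,
    use_negatives: bool = False,
) -> dict[str, dict[str, float]]:
    """Raw metric values per method on one split: {method: {metric: value}}."""
    out: dict[str, dict[str, float]] = {}
    for method in methods:
        result = apply_method(
            method, cache.for_method(method), task, split, config,
            use_negatives=use_negatives,
        )
        labels = _labels_for(task, result.scores)
        out[method] = {
            "auPRC": auprc(result.scores, labels),
            "P@TopK": p_at_topk(result.scores, labels),
            "auROC": auroc(result.scores, labels),
        }
    return out


def benchmark_cv(
    network: GeneNetwork,
    collection: GenesetCollection,
    methods: Sequence[str] = ("LP-A", "LP-I", "SL-A", "SL-I"),
    k: int = 5,
    seed: int = 0,
    config: MethodConfig | None = None,
    min_positives: int = 10,
    p_threshold: float = 0.05,
    use_negatives: bool = False,
) -> list[EvalRecord]:
    """Stratified k-fold benchmark over every qualifying geneset.

    Genesets need at least ``min_positives`` positives (and at least k
    positives and negatives) after restriction to network genes.  Records
    carry the fold-averaged raw metric, the task prior and the log2
    prior-ratio.
    """
    config = config or MethodConfig(seed=seed)
    cache = FeatureCache(network, config)
    records: list[EvalRecord] = []
    n_skipped = 0
    for task in build_tasks(collection, network, p_threshold=p_threshold):
        if (
            len(task.positives) < max(min_positives, k)
            or len(task.negatives) < k
        ):
            n_skipped += 1
            continue
        folds = stratified_kfold(task, k=k, seed=seed)
        per_method: dict[str, dict[str, list[float]]] = {
            m: {metric: [] for metric in METRICS} for m in methods
        }
        for split in folds:
            values = evaluate_split(methods, cache, task, split, config, use_negatives)
            for m in methods:
                for metric in METRICS:
                    per_method[m][metric].append(values[m][metric])
        prior = len(task.positives) / (len(task.positives) + len(task.negatives))
        for m in methods:
            for metric in METRICS:
                raw = float(np.mean(per_method[m][metric]))
                records.append(
                    EvalRecord(
                        geneset_id=task.geneset_id,
                        method=m,
                        metric=metric,
                        raw_value=raw,
                        prior=prior,
                        log2_ratio=(
                            log2_prior_ratio(raw, prior)
                            if metric in ("auPRC", "P@TopK")
                            else None
                        ),
                    )
                )
    if n_skipped:
        logger.info("benchmark_cv: skipped %d undersized geneset(s)", n_skipped)
    if not records:
        raise ValidationError("no genesets survived the task filter")
    return records


def benchmark_holdout(
    network: GeneNetwork,
    collection: GenesetCollection,
    split: LabeledSplit,
    methods: Sequence[str] = ("LP-A", "LP-I", "SL-A", "SL-I"),
    config: MethodConfig | None = None,
    min_positives: int = 10,
    p_threshold: float = 0.05,
    use_negatives: bool = False,
) -> list[EvalRecord]:
    """Temporal or study-bias holdout benchmark under a fixed split."""
    config = config or MethodConfig()
    cache = FeatureCache(network, config)
    tasks = build_tasks(collection, network, p_threshold=p_threshold)
    tasks = filter_tasks(tasks, split, min_positives=min_positives)
    if not tasks:
        raise ValidationError("no genesets survived the task filter")
    records: list[EvalRecord] = []
    for task in tasks:
        test_pos = task.positives & split.test_genes
        test_neg = task.negatives & split.test_genes
        if not test_pos or not test_neg:
            continue
        prior = len(test_pos) / (len(test_pos) + len(test_neg))
        values = evaluate_split(methods, cache, task, split, config, use_negatives)
        for m in methods:
            for metric in METRICS:
                raw = values[m][metric]
                records.append(
                    EvalRecord(
                        geneset_id=task.geneset_id, method=m, metric=metric,
                        raw_value=raw, prior=prior,
                        log2_ratio=(
                            log2_prior_ratio(raw, prior)
                            if metric in ("auPRC", "P@TopK")
                            else None
                        ),
                    )
                )
    return records


def records_to_auprc_table(records: Sequence[EvalRecord]) -> dict[str, list[float]]:
    """Per-method auPRC lists aligned by geneset id (sorted), the input the
    ranking and significance machinery expects."""
    by_method: dict[str, dict[str, float]] = {}
    for r in records:
        if r.metric != "auPRC":
            continue
        by_method.setdefault(r.method, {})[r.geneset_id] = r.raw_value
    if not by_method:
        raise ValidationError("no auPRC records")
    genesets = sorted(set.intersection(*(set(v) for v in by_method.values())))
    return {m: [by_method[m][g] for g in genesets] for m in by_method}


def write_records_tsv(
    records: Sequence[EvalRecord], path, collection: str = "", network: str = ""
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "collection\tnetwork\tgeneset\tmethod\tmetric\traw\tprior\tlog2_ratio\n"
        )
        for r in records:
            ratio = "" if r.log2_ratio is None else f"{r.log2_ratio:.6g}"
            fh.write(
                f"{collection}\t{network}\t{r.geneset_id}\t{r.method}\t{r.metric}\t"
                f"{r.raw_value:.6g}\t{r.prior:.6g}\t{ratio}\n"
            )
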