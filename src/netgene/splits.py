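"""Train/test gene partitions for the three validation schemes.

* temporal holdout — test genes are those whose every annotation in the
  collection is dated strictly after a cutoff (default January 1, 2017);
  any pre-cutoff annotation keeps a gene in training.
* study-bias holdout — genes ranked by publication count; the top
  ``train_fraction`` (default two-thirds) of the most-mentioned genes train,
  the least-mentioned remainder tests.
* stratified k-fold cross-validation — class proportions preserved per fold.

Both holdouts are deterministic functions of their inputs; only k-fold
shuffles, and that is seeded.
"""

from __future__ import annotations

import datetime
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .exceptions import ValidationError
from .genesets import GenesetCollection, LabeledTask

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = datetime.date(2017, 1, 1)


@dataclass(frozen=True)
class LabeledSplit:
    scheme: str  # temporal | study_bias | cv_fold
    train_genes: frozenset[str]
    test_genes: frozenset[str]
    fold_index: int | None = None

    def __post_init__(self) -> None:
        if self.train_genes & self.test_genes:
            raise ValidationError("train and test genes overlap")

    def to_json_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "fold_index": self.fold_index,
            "train": sorted(self.train_genes),
            "test": sorted(self.test_genes),
        }


def temporal_split(
    c: GenesetCollection, cutoff_date: datetime.date = DEFAULT_CUTOFF
) -> LabeledSplit:
    """Temporal holdout over a collection with dated annotations.

    Test genes only have annotations strictly after the cutoff; every other
    annotated gene trains.  Missing dates for any (gene, set) pair are an
    error listing the offenders.
    """
    if c.dates is None:
        raise ValidationError("temporal_split requires annotation dates")
    missing = [
        (g, sid)
        for sid, genes in c.sets.items()
        for g in genes
        if (g, sid) not in c.dates
    ]
    if missing:
        shown = ", ".join(f"{g}/{s}" for g, s in sorted(missing)[:10])
        raise ValidationError(
            f"missing annotation dates for {len(missing)} (gene, set) pair(s): {shown}"
        )
    earliest: dict[str, datetime.date] = {}
    for sid, genes in c.sets.items():
        for g in genes:
            d = c.dates[(g, sid)]
            if g not in earliest or d < earliest[g]:
                earliest[g] = d
    test = frozenset(g for g, d in earliest.items() if d > cutoff_date)
    train = frozenset(earliest) - test
    if not test:
        logger.warning("temporal_split: empty test set (no post-cutoff-only genes)")
    return LabeledSplit(scheme="temporal", train_genes=train, test_genes=test)


def study_bias_split(
    genes: Iterable[str],
    pubmed_counts: Mapping[str, int],
    train_fraction: float = 2 / 3,
) -> LabeledSplit:
    """Study-bias holdout: most-published genes train, least-published test.

    Genes are sorted by count descending with lexicographic tie-breaking; the
    first ``ceil(train_fraction * n)`` genes train.  A gene without a count is
    treated as count 0 (logged).
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError("train_fraction must be in (0, 1)")
    genes = sorted(set(genes))
    n_missing = sum(1 for g in genes if g not in pubmed_counts)
    if n_missing:
        logger.info("study_bias_split: %d gene(s) without counts treated as 0", n_missing)
    ranked = sorted(genes, key=lambda g: (-pubmed_counts.get(g, 0), g))
    n_train = math.ceil(train_fraction * len(ranked))
    return LabeledSplit(
        scheme="study_bias",
        train_genes=frozenset(ranked[:n_train]),
        test_genes=frozenset(ranked[n_train:]),
    )


def stratified_kfold(task: LabeledTask, k: int = 5, seed: int = 0) -> list[LabeledSplit]:
    """Stratified k-fold splits of a task's labeled genes.

    Per fold, positive and negative counts deviate from perfect
    proportionality by at most 1; shuffling is seeded, so identical seeds
    give identical folds.
    """
    if len(task.positives) < k or len(task.negatives) < k:
        raise ValidationError(
            f"task {task.geneset_id!r}: need >= {k} positives and negatives for {k}-fold CV"
        )
    genes = sorted(task.positives) + sorted(task.negatives)
    labels = np.r_[np.ones(len(task.positives), int), np.zeros(len(task.negatives), int)]
    genes_arr = np.array(genes)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(genes_arr, labels)):
        splits.append(
            LabeledSplit(
                scheme="cv_fold",
                train_genes=frozenset(genes_arr[train_idx]),
                test_genes=frozenset(genes_arr[test_idx]),
                fold_index=fold,
            )
        )
    return splits


def filter_tasks(
    tasks: Sequence[LabeledTask], split: LabeledSplit, min_positives: int = 10
) -> list[LabeledTask]:
    """Keep tasks with at least ``min_positives`` positive genes in both the
    training and the test side of the split (inclusive threshold)."""
    kept = []
    for task in tasks:
        n_train = len(task.positives & split.train_genes)
        n_test = len(task.positives & split.test_genes)
        if n_train >= min_positives and n_test >= min_positives:
            kept.append(task)
    return kept


def restrict_task_to_network(task: LabeledTask, network_nodes: Iterable[str]) -> LabeledTask:
    """Drop task genes absent from the network (logged); genes without a
    feature row can be neither trained on nor scored."""
    nodes = set(network_nodes)
    pos = task.positives & nodes
    neg = task.negatives & nodes
    dropped = (len(task.positives) - len(pos)) + (len(task.negatives) - len(neg))
    if dropped:
        logger.info("task %s: dropped %d gene(s) absent from network", task.geneset_id, dropped)
    return LabeledTask(geneset_id=task.geneset_id, positives=pos, negatives=neg)


def read_counts_tsv(path) -> dict[str, int]:
    """Read a ``<gene-id>\\t<count>`` publication-count table."""
    counts: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValidationError(f"{path}: line {lineno}: expected 2 columns")
            counts[parts[0]] = int(parts[1])
    return counts


def write_counts_tsv(counts: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(counts):
            fh.write(f"{gene}\t{counts[gene]}\n")
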