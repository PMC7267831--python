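"""The five gene-classification methods.

Two classes of methods over three network representations:

* label propagation — ``S = M x`` where x indicates training positives and M
  is the adjacency matrix (LP-A) or the RWR influence matrix (LP-I).  With
  the adjacency matrix a gene's score is the summed weight of its edges to
  positively labeled neighbours.  By default only positives enter x; an
  optional signed mode sets x = −1 on training negatives.
* supervised learning — L2-regularised logistic regression (C = 1.0) on each
  gene's feature row: adjacency row (SL-A), influence row (SL-I) or node2vec
  embedding (SL-E).  Scores are predicted probabilities in (0, 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from sklearn.linear_model import LogisticRegression

from .exceptions import ValidationError
from .features import DEFAULT_ALPHA, FeatureMatrix, Node2VecParams, embed_node2vec, rwr_influence
from .genesets import LabeledTask
from .network import GeneNetwork, adjacency
from .splits import LabeledSplit

logger = logging.getLogger(__name__)

METHODS = ("LP-A", "LP-I", "SL-A", "SL-I", "SL-E")
LP_METHODS = ("LP-A", "LP-I")
SL_METHODS = ("SL-A", "SL-I", "SL-E")

_REPRESENTATION = {  # method -> feature kind
    "LP-A": "adjacency",
    "LP-I": "influence",
    "SL-A": "adjacency",
    "SL-I": "influence",
    "SL-E": "embedding",
}


@dataclass(frozen=True)
class PredictionResult:
    geneset_id: str
    method: str
    scores: Mapping[str, float]  # test genes only
    missing: frozenset[str] = frozenset()  # test genes absent from the network


@dataclass(frozen=True)
class ModelWeights:
    """Fitted logistic-regression parameters: score = sigmoid(w·x + c)."""

    w: np.ndarray
    intercept: float


@dataclass(frozen=True)
class MethodConfig:
    """Hyperparameters shared by all methods; only C and alpha are fixed by
    the benchmarking protocol, the rest are conventional defaults."""

    alpha: float = DEFAULT_ALPHA
    C: float = 1.0
    tol: float = 1e-4
    max_iter: int = 1000
    node2vec: Node2VecParams = field(default_factory=Node2VecParams)
    seed: int = 0


def _filter_to_nodes(genes: Iterable[str], node_order: tuple[str, ...], what: str):
    present = [g for g in genes if g in set(node_order)]
    n_dropped = len(set(genes)) - len(present)
    if n_dropped:
        warnings.warn(f"{n_dropped} {what} gene(s) absent from network dropped", stacklevel=3)
    return present


def label_propagate(
    features: FeatureMatrix,
    train_positives: Iterable[str],
    test_genes: Iterable[str],
    use_negatives: bool = False,
    train_negatives: Iterable[str] | None = None,
    geneset_id: str = "",
    method: str = "LP",
) -> PredictionResult:
    """Propagate training labels through a feature matrix: ``S = M x``.

    x[i] = 1 for training positives, 0 otherwise; in signed mode (``use_negatives``)
    training negatives get −1.  Scores are reported for the requested test
    genes; test genes without a network row are reported as ``missing``.
    """
    if features.kind not in ("adjacency", "influence"):
        raise ValidationError("label_propagate needs an adjacency or influence matrix")
    node_set = set(features.node_order)
    pos = _filter_to_nodes(sorted(set(train_positives)), features.node_order, "positive")
    if not pos:
        raise ValidationError("no training positives present in the network")
    x = np.zeros(features.n_nodes)
    x[features.index_of(pos)] = 1.0
    if use_negatives and train_negatives:
        neg = [g for g in sorted(set(train_negatives)) if g in node_set]
        x[features.index_of(neg)] = -1.0
    s = features.values @ x
    test = sorted(set(test_genes))
    missing = frozenset(g for g in test if g not in node_set)
    scored = [g for g in test if g in node_set]
    scores = dict(zip(scored, s[features.index_of(scored)].tolist()))
    return PredictionResult(geneset_id=geneset_id, method=method, scores=scores, missing=missing)


def train_sl(
    features: FeatureMatrix,
    train_positives: Iterable[str],
    train_negatives: Iterable[str],
    C: float = 1.0,
    tol: float = 1e-4,
    max_iter: int = 1000,
) -> ModelWeights:
    """Fit L2-regularised logistic regression on the training genes' feature
    rows.  Features are not standardised: network rows carry meaningful scale.
    """
    pos = sorted(set(train_positives))
    neg = sorted(set(train_negatives))
    if set(pos) & set(neg):
        raise ValidationError("training positives and negatives overlap")
    if not pos or not neg:
        raise ValidationError("both classes must be nonempty for supervised learning")
    genes = pos + neg
    x = features.rows(genes)
    y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
    # L2 penalty is sklearn's default; C=1.0 per the benchmarking protocol.
    clf = LogisticRegression(C=C, solver="lbfgs", tol=tol, max_iter=max_iter)
    clf.fit(x, y)
    return ModelWeights(w=clf.coef_.ravel().copy(), intercept=float(clf.intercept_[0]))


def predict_sl(
    model: ModelWeights,
    features: FeatureMatrix,
    test_genes: Iterable[str],
    geneset_id: str = "",
    method: str = "SL",
) -> PredictionResult:
    """Score test genes with a fitted model: sigmoid(w·x + c) ∈ (0, 1)."""
    if model.w.shape[0] != features.n_features:
        raise ValidationError(
            f"model dimension {model.w.shape[0]} != feature dimension {features.n_features}"
        )
    node_set = set(features.node_order)
    test = sorted(set(test_genes))
    missing = frozenset(g for g in test if g not in node_set)
    scored = [g for g in test if g in node_set]
    z = features.rows(scored) @ model.w + model.intercept
    probs = 1.0 / (1.0 + np.exp(-z))
    return PredictionResult(
        geneset_id=geneset_id, method=method, scores=dict(zip(scored, probs.tolist())),
        missing=missing,
    )


def build_features(
    network: GeneNetwork, kind: str, config: MethodConfig | None = None
) -> FeatureMatrix:
    """Compute one representation of a network (adjacency / influence /
    embedding).  Callers benchmarking several methods should cache the result
    per network rather than recompute it per task."""
    config = config or MethodConfig()
    a = adjacency(network)
    if kind == "adjacency":
        return a
    if kind == "influence":
        return rwr_influence(a, alpha=config.alpha)
    if kind == "embedding":
        return embed_node2vec(network, params=config.node2vec, seed=config.seed)
    raise ValidationError(f"unknown representation {kind!r}")


def apply_method(
    method: str,
    features: FeatureMatrix,
    task: LabeledTask,
    split: LabeledSplit,
    config: MethodConfig | None = None,
    use_negatives: bool = False,
) -> PredictionResult:
    """Run one method on precomputed features for one task and split.

    Training genes are the task's positives/negatives inside the split's
    train side; the scored genes are the task's labeled genes inside the
    split's test side.
    """
    config = config or MethodConfig()
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}")
    if features.kind != _REPRESENTATION[method]:
        raise ValidationError(
            f"{method} needs {_REPRESENTATION[method]} features, got {features.kind}"
        )
    train_pos = task.positives & split.train_genes
    train_neg = task.negatives & split.train_genes
    test = (task.positives | task.negatives) & split.test_genes
    if method in LP_METHODS:
        return label_propagate(
            features, train_pos, test,
            use_negatives=use_negatives, train_negatives=train_neg,
            geneset_id=task.geneset_id, method=method,
        )
    node_set = set(features.node_order)
    model = train_sl(
        features,
        train_pos & node_set,
        train_neg & node_set,
        C=config.C, tol=config.tol, max_iter=config.max_iter,
    )
    return predict_sl(model, features, test, geneset_id=task.geneset_id, method=method)


def run_method(
    method: str,
    network: GeneNetwork,
    task: LabeledTask,
    split: LabeledSplit,
    config: MethodConfig | None = None,
    use_negatives: bool = False,
) -> PredictionResult:
    """Dispatch one method end-to-end: build the representation the method
    needs, then train/propagate and score the split's test genes."""
    config = config or MethodConfig()
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}")
    features = build_features(network, _REPRESENTATION[method], config)
    return apply_method(method, features, task, split, config, use_negatives=use_negatives)


def write_predictions_tsv(results: Iterable[PredictionResult], task_labels, path) -> None:
    """Write ``<geneset-id>\\t<method>\\t<gene-id>\\t<score>\\t<label>`` rows;
    ``task_labels`` maps geneset_id -> set of positive genes."""
    with open(path, "w") as fh:
        for res in results:
            positives = task_labels.get(res.geneset_id, frozenset())
            for gene in sorted(res.scores):
                label = 1 if gene in positives else 0
                fh.write(f"{res.geneset_id}\t{res.method}\t{gene}\t{res.scores[gene]:.8g}\t{label}\n")
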