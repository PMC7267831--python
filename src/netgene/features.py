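"""Per-gene feature representations of a network.

Three representations are supported, each a row-per-gene matrix tied to a
fixed node order:

* ``adjacency`` — the weighted adjacency matrix A itself (each gene's feature
  vector is its full connectivity profile);
* ``influence`` — the random-walk-with-restart (RWR) kernel
  ``F = α (I − (1−α) W_D)^{-1}`` with ``W_D = A D^{-1}`` column-normalised,
  capturing global network proximity;
* ``embedding`` — low-dimensional node2vec vectors trained on a corpus of
  second-order biased random walks with skip-gram negative sampling.

The influence matrix is column-stochastic whenever the network has no
zero-degree nodes: column j of F is the stationary visiting distribution of a
walk restarting at node j with probability α per step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .exceptions import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .network import GeneNetwork

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.85  # restart probability used for every network


@dataclass(frozen=True)
class FeatureMatrix:
    """A |V| x m real matrix whose row i describes ``node_order[i]``."""

    values: np.ndarray
    node_order: tuple[str, ...]
    kind: str  # adjacency | influence | embedding

    def __post_init__(self) -> None:
        if self.kind not in ("adjacency", "influence", "embedding"):
            raise ValidationError(f"unknown feature kind {self.kind!r}")
        if self.values.shape[0] != len(self.node_order):
            raise ValidationError(
                f"row count {self.values.shape[0]} != node count {len(self.node_order)}"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.node_order)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def index_of(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.node_order)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def rows(self, genes: Sequence[str]) -> np.ndarray:
        return self.values[self.index_of(genes)]

    # -- serialisation -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write values as .npy with a sidecar ``<path>.nodes.txt`` listing
        the node order, one gene per line."""
        path = Path(path)
        np.save(path, self.values)
        sidecar = path.with_suffix(path.suffix + ".nodes.txt")
        sidecar.write_text("\n".join(self.node_order) + "\n")

    @classmethod
    def load(cls, path: str | Path, kind: str) -> "FeatureMatrix":
        path = Path(path)
        values = np.load(path)
        sidecar = path.with_suffix(path.suffix + ".nodes.txt")
        nodes = tuple(sidecar.read_text().split())
        return cls(values=values, node_order=nodes, kind=kind)

    def to_word2vec_text(self, path: str | Path) -> None:
        """Export as word2vec text format: header then ``<gene> v1 ... vd``."""
        with open(path, "w") as fh:
            fh.write(f"{self.n_nodes} {self.n_features}\n")
            for gene, row in zip(self.node_order, self.values):
                fh.write(gene + " " + " ".join(f"{x:.6g}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# RWR influence matrix
# ---------------------------------------------------------------------------


def rwr_influence(adjacency: FeatureMatrix, alpha: float = DEFAULT_ALPHA) -> FeatureMatrix:
    """Random-walk-with-restart influence matrix F = α (I − (1−α) W_D)^{-1}.

    ``W_D = A D^{-1}`` is the column-normalised (column-stochastic) walk
    matrix, D the diagonal of weighted degrees.  α is the probability of
    restarting at the seed at each step; α = 1 gives the identity (no
    diffusion).  Columns of F sum to 1 and all entries are non-negative
    (Neumann series of a non-negative matrix).

    Zero-degree nodes make their W_D column all-zero, so their F column is
    α·e_i; they are kept with a warning.
    """
    if adjacency.kind != "adjacency":
        raise ValidationError("rwr_influence expects an adjacency feature matrix")
    if not (0.0 < alpha <= 1.0):
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    a = adjacency.values
    if np.any(a < 0):
        raise ValidationError("adjacency matrix must be non-negative")
    deg = a.sum(axis=0)
    zero = deg == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-degree node(s); their influence column is alpha*e_i",
            stacklevel=2,
        )
    inv_deg = np.where(zero, 0.0, 1.0 / np.where(zero, 1.0, deg))
    w_d = a * inv_deg[np.newaxis, :]  # A @ D^{-1}: scale columns
    n = a.shape[0]
    m = np.eye(n) - (1.0 - alpha) * w_d
    # Solve M F = alpha*I column-wise; dense is fine at benchmark scale.
    f = alpha * np.linalg.solve(m, np.eye(n))
    return FeatureMatrix(values=f, node_order=adjacency.node_order, kind="influence")


# ---------------------------------------------------------------------------
# node2vec embedding
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Node2VecParams:
    """Walk-corpus and skip-gram settings.

    p and q are the return / in-out parameters of the second-order walk
    (bias 1/p to step back to the previous node, 1 to a common neighbour,
    1/q to an outward node); both default to 0.1.  The remaining values are
    the conventional node2vec defaults and are all overridable.
    """

    p: float = 0.1
    q: float = 0.1
    dim: int = 128
    walk_length: int = 80
    num_walks: int = 10
    window: int = 10
    epochs: int = 1
    negatives: int = 5
    learning_rate: float = 0.025


def _neighbor_arrays(network: "GeneNetwork"):
    """Sorted neighbour-index and weight arrays per node."""
    n = network.n_nodes
    nbrs: list[list[int]] = [[] for _ in range(n)]
    wts: list[list[float]] = [[] for _ in range(n)]
    for (u, v), w in network.edges.items():
        i, j = network.node_index(u), network.node_index(v)
        nbrs[i].append(j)
        wts[i].append(w)
        nbrs[j].append(i)
        wts[j].append(w)
    out_n, out_w = [], []
    for i in range(n):
        order = np.argsort(nbrs[i])
        out_n.append(np.asarray(nbrs[i], dtype=np.int64)[order])
        out_w.append(np.asarray(wts[i], dtype=float)[order])
    return out_n, out_w


def _simulate_walks(
    nbr_idx, nbr_w, n: int, params: Node2VecParams, rng: np.random.Generator
) -> list[np.ndarray]:
    """Second-order biased random walks (weighted node2vec sampling)."""
    walks: list[np.ndarray] = []
    isolated_warned = False
    for _ in range(params.num_walks):
        for start in rng.permutation(n):
            if nbr_idx[start].size == 0:
                if not isolated_warned:
                    warnings.warn("isolated node(s): emitting length-1 walks", stacklevel=3)
                    isolated_warned = True
                walks.append(np.array([start], dtype=np.int64))
                continue
            walk = np.empty(params.walk_length, dtype=np.int64)
            walk[0] = start
            prev = -1
            cur = int(start)
            for step in range(1, params.walk_length):
                cand = nbr_idx[cur]
                w = nbr_w[cur].copy()
                if prev >= 0:
                    back = cand == prev
                    common = np.isin(cand, nbr_idx[prev], assume_unique=True)
                    bias = np.where(back, 1.0 / params.p, np.where(common, 1.0, 1.0 / params.q))
                    w *= bias
                cum = np.cumsum(w)
                nxt = int(cand[np.searchsorted(cum, rng.random() * cum[-1], side="right")])
                walk[step] = nxt
                prev, cur = cur, nxt
            walks.append(walk)
    return walks


def _skipgram_pairs(walks: list[np.ndarray], window: int) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for walk in walks:
        length = walk.size
        for offset in range(1, window + 1):
            if offset >= length:
                break
            centers.append(walk[:-offset])
            contexts.append(walk[offset:])
            centers.append(walk[offset:])
            contexts.append(walk[:-offset])
    if not centers:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(centers), np.concatenate(contexts)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _train_sgns(
    centers: np.ndarray,
    contexts: np.ndarray,
    n_nodes: int,
    params: Node2VecParams,
    rng: np.random.Generator,
    batch_size: int = 2048,
) -> np.ndarray:
    """Skip-gram with negative sampling by mini-batch SGD (numpy)."""
    dim = params.dim
    w_in = (rng.random((n_nodes, dim)) - 0.5) / dim
    w_out = np.zeros((n_nodes, dim))
    counts = np.bincount(centers, minlength=n_nodes).astype(float)
    noise = counts**0.75
    if noise.sum() == 0:
        noise = np.ones(n_nodes)
    noise_cum = np.cumsum(noise / noise.sum())
    n_pairs = centers.size
    total = max(1, params.epochs * n_pairs)
    seen = 0
    lr0 = params.learning_rate
    for _ in range(params.epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch_size):
            sel = order[lo : lo + batch_size]
            c = centers[sel]
            pos = contexts[sel]
            b = c.size
            neg = np.searchsorted(noise_cum, rng.random((b, params.negatives)))
            lr = max(lr0 * (1.0 - seen / total), lr0 * 1e-4)
            v = w_in[c]  # (b, d)
            # positive targets
            u_pos = w_out[pos]
            g_pos = _sigmoid(np.einsum("bd,bd->b", v, u_pos)) - 1.0  # (b,)
            grad_v = g_pos[:, None] * u_pos
            np.add.at(w_out, pos, -lr * g_pos[:, None] * v)
            # negative targets
            u_neg = w_out[neg]  # (b, k, d)
            g_neg = _sigmoid(np.einsum("bd,bkd->bk", v, u_neg))  # (b, k)
            grad_v += np.einsum("bk,bkd->bd", g_neg, u_neg)
            np.add.at(w_out, neg, -lr * g_neg[:, :, None] * v[:, None, :])
            np.add.at(w_in, c, -lr * grad_v)
            seen += b
    return w_in


def embed_node2vec(
    network: "GeneNetwork",
    p: float = 0.1,
    q: float = 0.1,
    dim: int = 128,
    walk_length: int = 80,
    num_walks: int = 10,
    window: int = 10,
    epochs: int = 1,
    seed: int = 0,
    params: Node2VecParams | None = None,
) -> FeatureMatrix:
    """node2vec node embeddings of a weighted network.

    Generates ``num_walks`` second-order biased random walks of
    ``walk_length`` per node (return parameter ``p``, in-out parameter ``q``,
    transition probabilities proportional to edge weight times the p/q bias)
    and fits skip-gram with negative sampling over the walk corpus.  Fully
    deterministic for a fixed seed (single-worker numpy SGD).

    Returns an ``embedding`` feature matrix with one ``dim``-vector per node
    in the network's lexicographic node order.
    """
    if params is None:
        params = Node2VecParams(
            p=p, q=q, dim=dim, walk_length=walk_length, num_walks=num_walks,
            window=window, epochs=epochs,
        )
    if network.n_nodes == 0:
        raise ValidationError("embed_node2vec: empty network")
    if params.dim >= network.n_nodes:
        raise ValidationError(
            f"embedding dim {params.dim} must be < number of nodes {network.n_nodes}"
        )
    if params.p <= 0 or params.q <= 0:
        raise ValidationError("p and q must be positive")
    rng = np.random.default_rng(seed)
    nbr_idx, nbr_w = _neighbor_arrays(network)
    walks = _simulate_walks(nbr_idx, nbr_w, network.n_nodes, params, rng)
    centers, contexts = _skipgram_pairs(walks, params.window)
    vectors = _train_sgns(centers, contexts, network.n_nodes, params, rng)
    return FeatureMatrix(values=vectors, node_order=network.nodes, kind="embedding")
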