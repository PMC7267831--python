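"""Weighted undirected gene networks.

A :class:`GeneNetwork` is the in-memory form of a molecular interaction
network: nodes are opaque gene identifiers (strings), edges are unordered
pairs with a strictly positive weight.  Node order is fixed lexicographically
so that every matrix derived from the network is bit-reproducible across runs.

Self-loops are removed at load time (a gene must not vote for itself during
label propagation or degree normalisation) and duplicate edges collapse by
keeping the maximum weight, which is deterministic and order-independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .exceptions import ParseError, ValidationError

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


def _canon(u: str, v: str) -> Edge:
    """Canonical unordered key for an edge."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class GeneNetwork:
    """Weighted undirected network over string gene IDs.

    Parameters
    ----------
    nodes
        All node IDs in lexicographic order (may include isolated nodes).
    edges
        Mapping from canonical ``(u, v)`` pairs (``u < v``) to positive weights.
    name
        Free-text label, used in logs and output manifests.
    """

    nodes: tuple[str, ...]
    edges: Mapping[Edge, float]
    name: str = "network"
    _index: dict[str, int] = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(self.nodes)})

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edge_weights: Iterable[tuple[str, str, float]],
        extra_nodes: Iterable[str] = (),
        name: str = "network",
    ) -> "GeneNetwork":
        """Build a network from ``(u, v, w)`` triples.

        Self-loops are dropped (logged), zero-weight edges are dropped,
        duplicates collapse by max weight, negative weights raise.
        """
        edges: dict[Edge, float] = {}
        n_self = 0
        n_zero = 0
        for u, v, w in edge_weights:
            w = float(w)
            if w < 0:
                raise ValidationError(f"negative edge weight {w} on ({u}, {v})")
            if u == v:
                n_self += 1
                continue
            if w == 0.0:
                n_zero += 1
                continue
            key = _canon(u, v)
            prev = edges.get(key)
            if prev is None or w > prev:
                edges[key] = w
        if n_self:
            logger.info("%s: dropped %d self-loop(s)", name, n_self)
        if n_zero:
            logger.info("%s: dropped %d zero-weight edge(s)", name, n_zero)
        node_set = {g for e in edges for g in e}
        node_set.update(extra_nodes)
        return cls(nodes=tuple(sorted(node_set)), edges=edges, name=name)

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self, gene: str) -> int:
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def weight(self, u: str, v: str) -> float:
        """Edge weight, 0.0 if the edge is absent."""
        return self.edges.get(_canon(u, v), 0.0)

    def neighbors(self, gene: str) -> dict[str, float]:
        """Neighbours of ``gene`` with edge weights (O(|E|); loaders and
        feature builders use vectorised paths instead)."""
        out: dict[str, float] = {}
        for (u, v), w in self.edges.items():
            if u == gene:
                out[v] = w
            elif v == gene:
                out[u] = w
        return out

    def degrees(self):
        """Weighted degree per node, in node order (numpy array)."""
        import numpy as np

        d = np.zeros(self.n_nodes)
        for (u, v), w in self.edges.items():
            d[self._index[u]] += w
            d[self._index[v]] += w
        return d


def load_edge_list(
    path: str | Path,
    weighted: bool = True,
    min_weight: float | None = None,
    name: str | None = None,
) -> GeneNetwork:
    """Load a network from an edge-list TSV.

    Each non-comment line is ``gene1<TAB>gene2[<TAB>weight]`` (any whitespace
    accepted as separator).  Two-column lines get weight 1.0; with
    ``weighted=False`` an explicit third column is ignored and every edge gets
    weight 1.0.  ``min_weight`` optionally drops edges below a score cutoff
    (no cutoff is applied by default).
    """
    path = Path(path)
    triples: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 2:
                u, v = parts
                w = 1.0
            elif len(parts) == 3:
                u, v = parts[:2]
                if weighted:
                    try:
                        w = float(parts[2])
                    except ValueError as exc:
                        raise ParseError(
                            f"{path}: line {lineno}: cannot parse weight {parts[2]!r}"
                        ) from exc
                    if w < 0:
                        raise ValidationError(
                            f"{path}: line {lineno}: negative weight {w}"
                        )
                else:
                    w = 1.0
            else:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            if min_weight is not None and w < min_weight:
                continue
            triples.append((u, v, w))
    return GeneNetwork.from_edges(triples, name=name or path.stem)


def write_edge_list(network: GeneNetwork, path: str | Path) -> None:
    """Write the network as a 3-column edge-list TSV (canonical edge order)."""
    with open(path, "w") as fh:
        for (u, v) in sorted(network.edges):
            # repr keeps the shortest exact decimal, so reloads are lossless
            fh.write(f"{u}\t{v}\t{network.edges[(u, v)]!r}\n")


def load_mapping_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read a ``source-id<TAB>target-id`` file; repeated sources accumulate
    into one-to-many mappings."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            mapping.setdefault(parts[0], set()).add(parts[1])
    return mapping


def apply_id_mapping(
    network: GeneNetwork, mapping: Mapping[str, set[str]]
) -> GeneNetwork:
    """Translate node IDs through a (possibly one-to-many) mapping.

    An edge ``(u, v, w)`` becomes ``(u', v', w)`` for every pair of mapped
    targets ``u' ∈ mapping[u]``, ``v' ∈ mapping[v]`` with ``u' != v'`` —
    ambiguous mappings add edges between all possible target pairs.  Nodes
    without a mapping entry are dropped (logged).  Duplicates collapse by
    max weight as usual.
    """
    if not mapping:
        raise ValidationError("apply_id_mapping: empty mapping")
    dropped = {g for g in network.nodes if g not in mapping}
    if dropped:
        logger.info("%s: %d unmapped node(s) dropped", network.name, len(dropped))
    triples: list[tuple[str, str, float]] = []
    for (u, v), w in network.edges.items():
        if u in dropped or v in dropped:
            continue
        for u2 in mapping[u]:
            for v2 in mapping[v]:
                if u2 != v2:
                    triples.append((u2, v2, w))
    return GeneNetwork.from_edges(triples, name=f"{network.name}@mapped")


def adjacency(network: GeneNetwork):
    """Weighted adjacency matrix A of the network as a feature matrix.

    ``A[i, j]`` is the weight of the edge between ``node_order[i]`` and
    ``node_order[j]``, 0 if absent; symmetric with zero diagonal.
    """
    import numpy as np

    from .features import FeatureMatrix

    if network.n_nodes == 0:
        raise ValidationError("adjacency: empty network")
    n = network.n_nodes
    a = np.zeros((n, n))
    for (u, v), w in network.edges.items():
        i, j = network.node_index(u), network.node_index(v)
        a[i, j] = w
        a[j, i] = w
    return FeatureMatrix(values=a, node_order=network.nodes, kind="adjacency")
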