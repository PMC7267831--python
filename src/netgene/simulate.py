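"""Synthetic planted-module benchmarks.

The generator produces everything the pipeline consumes — a weighted network,
a geneset collection, annotation dates and study-bias publication counts —
with the statistical structure the framework assumes:

* the network is a planted-partition (stochastic block) graph: each module's
  members connect i.i.d. with probability ``p_within``, every other pair with
  ``p_between``.  Modules double as ground-truth genesets, so edge density
  and segregation of the planted sets are controlled directly.
* annotation artifacts emulate real collections: near-duplicate genesets
  (Jaccard > 0.8), multi-attribute genes injected into many sets, per-gene
  annotation dates straddling a temporal cutoff, and heavy-tailed
  publication counts drawn from a discrete power law.

Everything is a pure function of the config: the same seed yields
byte-identical outputs.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .genesets import GenesetCollection, write_dates_tsv, write_gmt
from .network import GeneNetwork, write_edge_list
from .splits import write_counts_tsv

PRE_CUTOFF_DATE = datetime.date(2015, 3, 1)
POST_CUTOFF_DATE = datetime.date(2018, 6, 1)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    Defaults are the benchmark's standard study conditions: a 500-gene
    network with ten planted 30-gene modules, within-module edge probability
    0.3 against a 0.01 background, unit weights, and a power-law study-bias
    exponent of 1.5 to emulate the heavy tail of PubMed mention counts.
    """

    n_genes: int = 500
    n_modules: int = 10
    module_size_range: tuple[int, int] = (30, 30)
    p_within: float = 0.3
    p_between: float = 0.01
    weight_distribution: str | tuple = "unit"  # "unit" or ("uniform", lo, hi)
    n_redundant_pairs: int = 0
    multi_attribute_genes: int = 0
    date_cutoff_fraction: float = 0.3
    study_bias_shape: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_between < self.p_within <= 1.0):
            raise ValidationError("need 0 <= p_between < p_within <= 1")
        lo, hi = self.module_size_range
        if lo < 2 or hi < lo:
            raise ValidationError("bad module_size_range")
        if self.n_modules * hi > self.n_genes:
            raise ValidationError(
                f"{self.n_modules} modules of up to {hi} genes exceed n_genes={self.n_genes}"
            )


@dataclass(frozen=True)
class AnnotationArtifacts:
    """Collection with injected annotation structure plus its study-bias
    counts (counts are not a GenesetCollection field, hence the bundle)."""

    collection: GenesetCollection
    study_bias_counts: dict[str, int] = field(default_factory=dict)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"g{i:0{width}d}" for i in range(n)]


def generate_planted_network(cfg: SimConfig) -> tuple[GeneNetwork, GenesetCollection]:
    """Planted-partition network plus the module genesets.

    Module sizes are drawn uniformly from ``module_size_range``; module
    members occupy a prefix of the gene list, the rest is unassigned
    background.  All pair probabilities are evaluated vectorised over the
    upper triangle, so the output is reproducible bit-for-bit per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = np.array(_gene_ids(cfg.n_genes))
    lo, hi = cfg.module_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_modules)
    if sizes.sum() > cfg.n_genes:
        raise ValidationError("drawn module sizes exceed n_genes")
    membership = np.full(cfg.n_genes, -1, dtype=int)
    start = 0
    sets: dict[str, frozenset[str]] = {}
    for m, size in enumerate(sizes):
        idx = np.arange(start, start + size)
        membership[idx] = m
        sets[f"M{m:02d}"] = frozenset(genes[idx])
        start += size

    iu, ju = np.triu_indices(cfg.n_genes, k=1)
    same = (membership[iu] >= 0) & (membership[iu] == membership[ju])
    prob = np.where(same, cfg.p_within, cfg.p_between)
    present = rng.random(iu.size) < prob
    iu, ju = iu[present], ju[present]
    if cfg.weight_distribution == "unit":
        weights = np.ones(iu.size)
    elif (
        isinstance(cfg.weight_distribution, tuple)
        and cfg.weight_distribution[0] == "uniform"
    ):
        lo_w, hi_w = cfg.weight_distribution[1:]
        weights = rng.uniform(lo_w, hi_w, size=iu.size)
    else:
        raise ValidationError(f"unknown weight_distribution {cfg.weight_distribution!r}")
    triples = [
        (genes[i], genes[j], float(w)) for i, j, w in zip(iu, ju, weights)
    ]
    network = GeneNetwork.from_edges(
        triples, extra_nodes=genes.tolist(), name=f"planted-seed{cfg.seed}"
    )
    collection = GenesetCollection(sets=sets, name=f"modules-seed{cfg.seed}")
    return network, collection


def add_annotation_artifacts(c: GenesetCollection, cfg: SimConfig) -> AnnotationArtifacts:
    """Inject realistic annotation structure into a planted collection.

    Adds ``n_redundant_pairs`` near-duplicate sets (drop 1/10 of the members
    of an existing set, guaranteeing Jaccard >= 0.9 with the original),
    injects ``multi_attribute_genes`` genes into eleven sets each (or all
    sets if fewer exist), stamps each gene's annotations entirely pre- or
    post-cutoff with post probability ``date_cutoff_fraction``, and draws
    per-gene publication counts from a discrete Pareto tail with exponent
    ``study_bias_shape``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    sets: dict[str, set[str]] = {sid: set(g) for sid, g in c.sets.items()}

    base_ids = sorted(c.sets)
    for k in range(cfg.n_redundant_pairs):
        src = base_ids[k % len(base_ids)]
        members = sorted(c.sets[src])
        n_drop = max(1, len(members) // 10) if len(members) > 2 else 0
        dup = set(members[n_drop:]) if n_drop else set(members)
        sets[f"{src}__dup{k}"] = dup

    universe = sorted({g for genes in sets.values() for g in genes})
    if cfg.multi_attribute_genes:
        promiscuous = rng.choice(universe, size=cfg.multi_attribute_genes, replace=False)
        target_ids = sorted(sets)[: min(11, len(sets))]
        for g in promiscuous:
            for sid in target_ids:
                sets[sid].add(str(g))

    frozen = {sid: frozenset(genes) for sid, genes in sorted(sets.items())}
    all_genes = sorted({g for genes in frozen.values() for g in genes})
    post = rng.random(len(all_genes)) < cfg.date_cutoff_fraction
    gene_date = {
        g: (POST_CUTOFF_DATE if flag else PRE_CUTOFF_DATE)
        for g, flag in zip(all_genes, post)
    }
    dates = {
        (g, sid): gene_date[g] for sid, genes in frozen.items() for g in genes
    }
    counts = {
        g: int(np.floor((1.0 - u) ** (-1.0 / cfg.study_bias_shape)))
        for g, u in zip(all_genes, rng.random(len(all_genes)))
    }
    collection = replace(c, sets=frozen, dates=dates)
    return AnnotationArtifacts(collection=collection, study_bias_counts=counts)


def write_fixture(
    out_dir: str | Path,
    cfg: SimConfig,
) -> dict[str, Path]:
    """Generate a full benchmark fixture and write it in the standard text
    formats (edge-list TSV, GMT, date TSV, count TSV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    network, collection = generate_planted_network(cfg)
    artifacts = add_annotation_artifacts(collection, cfg)
    paths = {
        "network": out_dir / "network.tsv",
        "gmt": out_dir / "collection.gmt",
        "dates": out_dir / "dates.tsv",
        "counts": out_dir / "counts.tsv",
    }
    write_edge_list(network, paths["network"])
    write_gmt(artifacts.collection, paths["gmt"])
    write_dates_tsv(artifacts.collection.dates, paths["dates"])
    write_counts_tsv(artifacts.study_bias_counts, paths["counts"])
    return paths
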