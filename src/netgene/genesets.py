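"""Geneset collections and their preprocessing.

A collection is a family of named gene sets (functions, diseases, traits)
from one annotation source, optionally carrying an ontology (child→parent
DAG over set IDs) and per-(gene, set) annotation dates.  Preprocessing turns
a raw collection into specific, largely non-redundant prediction tasks:

1. propagate annotations up the ontology,
2. drop sets outside a size window,
3. drop sets highly overlapping an already-kept set (Jaccard, greedy
   keep-largest-first),
4. strip multi-attribute genes (genes in more than ``max_memberships`` of the
   surviving sets) from every set.

Negative examples for a target set are all annotated genes that are neither
in the target nor in any other set that significantly overlaps it (one-sided
Fisher's exact test over the annotated-gene universe, p < 0.05).
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

from scipy.stats import hypergeom

from .exceptions import ParseError, ValidationError

logger = logging.getLogger(__name__)

Date = datetime.date


@dataclass(frozen=True)
class GenesetCollection:
    """Named gene sets with optional ontology and annotation dates."""

    sets: Mapping[str, frozenset[str]]
    ontology: frozenset[tuple[str, str]] | None = None  # (child, parent)
    dates: Mapping[tuple[str, str], Date] | None = None  # (gene, set) -> date
    name: str = "collection"

    def __post_init__(self) -> None:
        for sid, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"geneset {sid!r} is empty")

    @property
    def universe(self) -> frozenset[str]:
        """Union of all annotated genes in the collection."""
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def membership_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for genes in self.sets.values():
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        return counts

    def with_sets(self, sets: Mapping[str, frozenset[str]]) -> "GenesetCollection":
        """Copy with new sets; dates restricted to surviving (gene, set) pairs."""
        dates = self.dates
        if dates is not None:
            dates = {
                (g, s): d
                for (g, s), d in dates.items()
                if s in sets and g in sets[s]
            }
        return replace(self, sets=dict(sets), dates=dates)


@dataclass(frozen=True)
class LabeledTask:
    """One binary prediction task: a geneset's positives and negatives."""

    geneset_id: str
    positives: frozenset[str]
    negatives: frozenset[str]

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValidationError(
                f"task {self.geneset_id!r}: positives and negatives overlap"
            )


# ---------------------------------------------------------------------------
# I/O: GMT, ontology TSV, date TSV
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path, name: str | None = None) -> GenesetCollection:
    """Read a GMT file: ``<set-id>\\t<description>\\t<gene>...`` per line."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT needs id, description, >=1 gene"
                )
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    return GenesetCollection(sets=sets, name=name or path.stem)


def write_gmt(c: GenesetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(c.sets):
            genes = "\t".join(sorted(c.sets[sid]))
            fh.write(f"{sid}\t{c.name}\t{genes}\n")


def read_ontology_tsv(path: str | Path) -> frozenset[tuple[str, str]]:
    """Read ``<child-id>\\t<parent-id>`` pairs."""
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            pairs.add((parts[0], parts[1]))
    return frozenset(pairs)


def read_dates_tsv(path: str | Path) -> dict[tuple[str, str], Date]:
    """Read ``<gene-id>\\t<set-id>\\t<YYYY-MM-DD>`` annotation dates."""
    dates: dict[tuple[str, str], Date] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 columns")
            try:
                d = datetime.date.fromisoformat(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad date {parts[2]!r}") from exc
            dates[(parts[0], parts[1])] = d
    return dates


def write_dates_tsv(dates: Mapping[tuple[str, str], Date], path: str | Path) -> None:
    with open(path, "w") as fh:
        for (gene, sid) in sorted(dates):
            fh.write(f"{gene}\t{sid}\t{dates[(gene, sid)].isoformat()}\n")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def _ancestors(ontology: frozenset[tuple[str, str]]) -> dict[str, set[str]]:
    """All ancestors per node; raises on a cycle, naming a member."""
    parents: dict[str, set[str]] = {}
    for child, parent in ontology:
        parents.setdefault(child, set()).add(parent)
    memo: dict[str, set[str]] = {}
    WHITE, GRAY, BLACK = 0, 1, 2
    color: dict[str, int] = {}

    def visit(node: str) -> set[str]:
        state = color.get(node, WHITE)
        if state == GRAY:
            raise ValidationError(f"ontology cycle detected involving {node!r}")
        if state == BLACK:
            return memo[node]
        color[node] = GRAY
        anc: set[str] = set()
        for p in parents.get(node, ()):  # noqa: B905
            anc.add(p)
            anc |= visit(p)
        color[node] = BLACK
        memo[node] = anc
        return anc

    for node in set(parents) | {p for ps in parents.values() for p in ps}:
        visit(node)
    return memo


def propagate_annotations(c: GenesetCollection) -> GenesetCollection:
    """Propagate annotations up the ontology: a gene annotated to a set is
    annotated to every ancestor of that set.  Idempotent.

    Dates, if present, propagate too: the ancestor annotation takes the
    earliest date among contributing descendants (and its own, if already
    annotated).
    """
    if c.ontology is None:
        raise ValidationError("propagate_annotations: collection has no ontology")
    anc = _ancestors(c.ontology)
    sets: dict[str, set[str]] = {sid: set(genes) for sid, genes in c.sets.items()}
    new_dates: dict[tuple[str, str], Date] | None = (
        dict(c.dates) if c.dates is not None else None
    )
    for sid, genes in c.sets.items():
        for parent in anc.get(sid, ()):  # ancestors may be sets unseen so far
            sets.setdefault(parent, set()).update(genes)
            if new_dates is not None:
                for g in genes:
                    child_date = c.dates.get((g, sid))
                    if child_date is None:
                        continue
                    prev = new_dates.get((g, parent))
                    if prev is None or child_date < prev:
                        new_dates[(g, parent)] = child_date
    frozen = {sid: frozenset(genes) for sid, genes in sets.items() if genes}
    return replace(c, sets=frozen, dates=new_dates)


def filter_by_size(
    c: GenesetCollection, min_size: int = 10, max_size: float = float("inf")
) -> GenesetCollection:
    """Keep only sets with ``min_size <= |set| <= max_size``."""
    if min_size < 1:
        raise ValidationError("min_size must be >= 1")
    if min_size > max_size:
        raise ValidationError("min_size > max_size")
    kept = {
        sid: genes for sid, genes in c.sets.items() if min_size <= len(genes) <= max_size
    }
    logger.info("%s: size filter kept %d/%d sets", c.name, len(kept), len(c.sets))
    return c.with_sets(kept)


def jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def remove_redundant(c: GenesetCollection, jaccard_threshold: float = 0.5) -> GenesetCollection:
    """Greedy redundancy filter.

    Sets are scanned in descending-size then lexicographic-id order; a set is
    dropped if its Jaccard index with any already-kept set exceeds the
    threshold.  Deterministic: equal-size duplicates keep the
    lexicographically first id.
    """
    if not (0.0 < jaccard_threshold <= 1.0):
        raise ValidationError("jaccard_threshold must be in (0, 1]")
    order = sorted(c.sets, key=lambda sid: (-len(c.sets[sid]), sid))
    kept: dict[str, frozenset[str]] = {}
    for sid in order:
        genes = c.sets[sid]
        if any(jaccard(genes, other) > jaccard_threshold for other in kept.values()):
            continue
        kept[sid] = genes
    logger.info("%s: redundancy filter kept %d/%d sets", c.name, len(kept), len(c.sets))
    return c.with_sets(kept)


def remove_multi_attribute_genes(
    c: GenesetCollection, max_memberships: int = 10
) -> GenesetCollection:
    """Remove genes that belong to more than ``max_memberships`` sets from all
    sets (strictly more: a gene in exactly ``max_memberships`` sets stays).
    Sets emptied by the removal are dropped."""
    counts = c.membership_counts()
    promiscuous = {g for g, n in counts.items() if n > max_memberships}
    if promiscuous:
        logger.info("%s: removing %d multi-attribute gene(s)", c.name, len(promiscuous))
    kept = {}
    for sid, genes in c.sets.items():
        remaining = genes - promiscuous
        if remaining:
            kept[sid] = remaining
    return c.with_sets(kept)


def preprocess(
    c: GenesetCollection,
    min_size: int = 10,
    max_size: float = 200,
    jaccard_threshold: float = 0.5,
    max_memberships: int = 10,
) -> GenesetCollection:
    """Full preprocessing pipeline in fixed order:
    propagate (if an ontology is present) → size filter → redundancy filter →
    multi-attribute gene removal."""
    if c.ontology is not None:
        c = propagate_annotations(c)
    c = filter_by_size(c, min_size=min_size, max_size=max_size)
    c = remove_redundant(c, jaccard_threshold=jaccard_threshold)
    return remove_multi_attribute_genes(c, max_memberships=max_memberships)


# ---------------------------------------------------------------------------
# Negative selection
# ---------------------------------------------------------------------------


def fisher_exact_one_sided(a: int, b: int, c2: int, d: int) -> float:
    """Upper-tail p-value of the 2x2 table [[a, b], [c2, d]].

    ``a`` is the overlap count; the p-value is P(X >= a) for
    X ~ Hypergeom(N = a+b+c2+d, K = a+b, n = a+c2), i.e. the one-sided
    Fisher's exact test for over-representation.
    """
    for x in (a, b, c2, d):
        if x < 0:
            raise ValidationError("Fisher table counts must be non-negative")
    n_total = a + b + c2 + d
    return float(hypergeom.sf(a - 1, n_total, a + b, a + c2))


def select_negatives(
    c: GenesetCollection, geneset_id: str, p_threshold: float = 0.05
) -> frozenset[str]:
    """Negative examples for one geneset.

    Starting from the union of all annotated genes, remove (i) the target's
    own genes and (ii) every gene of any other set whose overlap with the
    target is significant (one-sided Fisher p < ``p_threshold`` over that
    universe).
    """
    if geneset_id not in c.sets:
        raise ValidationError(f"unknown geneset {geneset_id!r}")
    universe = c.universe
    target = c.sets[geneset_id]
    n_univ = len(universe)
    excluded: set[str] = set(target)
    for sid, genes in c.sets.items():
        if sid == geneset_id:
            continue
        a = len(genes & target)
        p = fisher_exact_one_sided(
            a, len(target) - a, len(genes) - a, n_univ - len(target) - len(genes) + a
        )
        if p < p_threshold:
            excluded |= genes
    return frozenset(universe - excluded)


def build_task(
    c: GenesetCollection, geneset_id: str, p_threshold: float = 0.05
) -> LabeledTask:
    """Convenience: a LabeledTask with the set's genes as positives and
    Fisher-filtered non-members as negatives."""
    return LabeledTask(
        geneset_id=geneset_id,
        positives=c.sets[geneset_id],
        negatives=select_negatives(c, geneset_id, p_threshold=p_threshold),
    )
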