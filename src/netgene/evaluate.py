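"""Evaluation metrics, method ranking and significance testing.

Gene classification is heavily imbalanced, so the headline metrics are
precision-driven and prior-normalised: auPRC and P@TopK are reported as
log2(metric / prior), where the prior — test positives over all test genes —
is the expected precision of a random ranking.  A value of 0 means no better
than chance.  auROC is kept for completeness.

Method comparison follows a two-stage protocol: per-geneset competition
ranking ("1224"-style) averaged over a collection, then paired two-sided
Wilcoxon signed-rank tests between each supervised-learning method and each
label-propagation method, Benjamini–Hochberg corrected.  A method "beats the
other class" when it wins more genesets than both opposing methods and both
corrected p-values fall below alpha; if both methods of a class do so, the
whole class wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm, rankdata, spearmanr

from .exceptions import ValidationError
from .network import GeneNetwork

NEG_INF = float("-inf")


@dataclass(frozen=True)
class EvalRecord:
    geneset_id: str
    method: str
    metric: str  # auPRC | P@TopK | auROC
    raw_value: float
    prior: float
    log2_ratio: float | None = None


@dataclass(frozen=True)
class ComparisonVerdict:
    combination_id: str
    winner: str | None  # a method, a class ("SL"/"LP"), or None
    win_fraction: float
    adjusted_p_values: Mapping[str, float]
    win_counts: Mapping[str, tuple[int, int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Ranking metrics
# ---------------------------------------------------------------------------


def _ordered_labels(scores: Mapping[str, float], labels: Mapping[str, int]) -> np.ndarray:
    """Labels sorted by descending score, ties broken by gene id."""
    genes = sorted(scores, key=lambda g: (-scores[g], g))
    return np.array([labels[g] for g in genes], dtype=int)


def _check_two_classes(labels: Mapping[str, int]) -> tuple[int, int]:
    n_pos = sum(1 for v in labels.values() if v == 1)
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present in the test set")
    return n_pos, n_neg


def auprc(scores: Mapping[str, float], labels: Mapping[str, int]) -> float:
    """Area under the precision-recall curve as average precision: the mean,
    over positives, of the precision at each positive's rank.  Score ties are
    broken deterministically by gene id."""
    n_pos, _ = _check_two_classes(labels)
    y = _ordered_labels(scores, labels)
    cum_pos = np.cumsum(y)
    ranks = np.arange(1, len(y) + 1)
    precision_at_pos = (cum_pos / ranks)[y == 1]
    return float(precision_at_pos.sum() / n_pos)


def p_at_topk(
    scores: Mapping[str, float], labels: Mapping[str, int], k: int | None = None
) -> float:
    """Precision among the top-K scored genes; K defaults to the number of
    test positives."""
    n_pos, _ = _check_two_classes(labels)
    if k is None:
        k = n_pos
    if k < 1:
        raise ValidationError("K must be >= 1")
    if k > len(scores):
        raise ValidationError(f"K={k} exceeds number of test genes {len(scores)}")
    y = _ordered_labels(scores, labels)
    return float(y[:k].sum() / k)


def auroc(scores: Mapping[str, float], labels: Mapping[str, int]) -> float:
    """Probability a random positive outscores a random negative; tied scores
    earn half credit (Mann–Whitney with midranks)."""
    n_pos, n_neg = _check_two_classes(labels)
    genes = sorted(scores)
    s = np.array([scores[g] for g in genes])
    y = np.array([labels[g] for g in genes])
    r = rankdata(s)
    u = r[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def log2_prior_ratio(raw: float, prior: float) -> float:
    """Prior-normalised metric: log2(raw / prior); raw = 0 maps to −inf."""
    if not (0.0 < prior < 1.0):
        raise ValidationError(f"prior must be in (0, 1), got {prior}")
    if raw < 0:
        raise ValidationError("metric value must be non-negative")
    if raw == 0.0:
        return NEG_INF
    return math.log2(raw / prior)


# ---------------------------------------------------------------------------
# Ranking and significance
# ---------------------------------------------------------------------------


def competition_rank(values: Mapping[str, float]) -> dict[str, int]:
    """Standard competition ("1224") ranking: the best value gets rank 1,
    ties share the smallest rank, the next distinct value's rank counts all
    better entries."""
    if len(values) < 2:
        raise ValidationError("competition_rank needs >= 2 methods")
    return {
        m: 1 + sum(1 for v in values.values() if v > values[m]) for m in values
    }


def average_rank(per_geneset_ranks: Sequence[Mapping[str, int]]) -> dict[str, float]:
    """Arithmetic mean of each method's ranks over genesets."""
    if not per_geneset_ranks:
        raise ValidationError("empty rank list")
    methods = set(per_geneset_ranks[0])
    for ranks in per_geneset_ranks:
        if set(ranks) != methods:
            raise ValidationError("inconsistent method sets across genesets")
    return {
        m: float(np.mean([ranks[m] for ranks in per_geneset_ranks])) for m in methods
    }


@dataclass(frozen=True)
class WilcoxonResult:
    p_value: float
    n_a_wins: int
    n_b_wins: int
    all_tied: bool = False

    def __iter__(self):  # allows tuple-style unpacking
        return iter((self.p_value, self.n_a_wins, self.n_b_wins))


def _exact_signed_rank_p(ranks2: np.ndarray, w2: float) -> float:
    """Two-sided exact p for the signed-rank statistic.

    ``ranks2`` are the |difference| ranks doubled (midranks become integers),
    ``w2`` the doubled positive-rank sum.  The null distribution over all 2^n
    sign assignments is accumulated by dynamic programming on the doubled
    rank-sum, which is equivalent to full enumeration.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w2))
    p_low = counts[: w2 + 1].sum()
    p_high = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def wilcoxon_signed_rank(
    paired_a: Sequence[float], paired_b: Sequence[float], exact_max_n: int = 25
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are excluded per the classical procedure; win counts are
    raw comparisons before exclusion.  The p-value is exact (full sign-flip
    null distribution) for n <= ``exact_max_n`` nonzero differences,
    otherwise a normal approximation with continuity and tie correction.
    With all differences zero the p-value is undefined and reported as 1.0
    with the ``all_tied`` flag set.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired samples must have equal length")
    d = a - b
    n_a_wins = int((d > 0).sum())
    n_b_wins = int((d < 0).sum())
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(1.0, n_a_wins, n_b_wins, all_tied=True)
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    if n <= exact_max_n:
        p = _exact_signed_rank_p(np.round(2 * ranks), 2 * w_plus)
    else:
        mean = n * (n + 1) / 4
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / 48
        sd = math.sqrt(n * (n + 1) * (2 * n + 1) / 24 - tie_term)
        # continuity correction toward the mean
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / sd
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return WilcoxonResult(p, n_a_wins, n_b_wins)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values (monotone-enforced, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for i in range(m - 1, -1, -1):
        idx = order[i]
        running_min = min(running_min, p[idx] * m / (i + 1))
        adjusted[idx] = running_min
    return adjusted.tolist()


CROSS_CLASS_COMPARISONS = (
    ("SL-A", "LP-A"),
    ("SL-A", "LP-I"),
    ("SL-I", "LP-A"),
    ("SL-I", "LP-I"),
)


def class_significance(
    per_geneset_auprc: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    combination_id: str = "",
) -> ComparisonVerdict:
    """Four cross-class comparisons with BH correction and the class rule.

    A method wins against the other class when it out-performs both opposing
    methods on more genesets than it loses and both corrected p-values are
    below ``alpha``.  If both methods of one class win, the verdict names the
    class ("SL"/"LP"); if exactly one wins, that method; otherwise none.
    ``win_fraction`` is the share of the 4·n cross-class comparisons won by
    the SL side.
    """
    required = {"SL-A", "SL-I", "LP-A", "LP-I"}
    if not required.issubset(per_geneset_auprc):
        missing = required - set(per_geneset_auprc)
        raise ValidationError(f"missing methods: {sorted(missing)}")
    lengths = {m: len(per_geneset_auprc[m]) for m in required}
    if len(set(lengths.values())) != 1:
        raise ValidationError("methods must have equal-length auPRC lists")

    raw_p: dict[str, float] = {}
    wins: dict[str, tuple[int, int]] = {}
    sl_wins = 0
    n_comparisons = 0
    for sl_m, lp_m in CROSS_CLASS_COMPARISONS:
        res = wilcoxon_signed_rank(per_geneset_auprc[sl_m], per_geneset_auprc[lp_m])
        key = f"{sl_m} vs {lp_m}"
        raw_p[key] = res.p_value
        wins[key] = (res.n_a_wins, res.n_b_wins)
        sl_wins += res.n_a_wins
        n_comparisons += len(per_geneset_auprc[sl_m])
    keys = list(raw_p)
    adjusted = dict(zip(keys, bh_fdr([raw_p[k] for k in keys])))

    def method_beats_class(method: str, opponents: tuple[str, str], side: int) -> bool:
        for opp in opponents:
            key = (
                f"{method} vs {opp}" if side == 0 else f"{opp} vs {method}"
            )
            w = wins[key]
            my_wins, their_wins = (w[0], w[1]) if side == 0 else (w[1], w[0])
            if not (my_wins > their_wins and adjusted[key] < alpha):
                return False
        return True

    sl_a = method_beats_class("SL-A", ("LP-A", "LP-I"), side=0)
    sl_i = method_beats_class("SL-I", ("LP-A", "LP-I"), side=0)
    lp_a = method_beats_class("LP-A", ("SL-A", "SL-I"), side=1)
    lp_i = method_beats_class("LP-I", ("SL-A", "SL-I"), side=1)

    winner: str | None = None
    if sl_a and sl_i:
        winner = "SL"
    elif lp_a and lp_i:
        winner = "LP"
    elif sl_a:
        winner = "SL-A"
    elif sl_i:
        winner = "SL-I"
    elif lp_a:
        winner = "LP-A"
    elif lp_i:
        winner = "LP-I"

    return ComparisonVerdict(
        combination_id=combination_id,
        winner=winner,
        win_fraction=sl_wins / n_comparisons if n_comparisons else 0.0,
        adjusted_p_values=adjusted,
        win_counts=wins,
    )


# ---------------------------------------------------------------------------
# Geneset network properties
# ---------------------------------------------------------------------------


def edge_density(network: GeneNetwork, geneset) -> float:
    """Within-geneset edge weight per possible member pair: how tightly the
    geneset is connected within itself."""
    members = set(geneset) & set(network.nodes)
    n = len(members)
    if n < 2:
        raise ValidationError("edge_density needs >= 2 geneset members in the network")
    within = sum(w for (u, v), w in network.edges.items() if u in members and v in members)
    return within / (n * (n - 1) / 2)


def segregation(network: GeneNetwork, geneset) -> float:
    """Fraction of the geneset's incident edge weight that stays inside the
    geneset: how isolated the set is from the rest of the network (in [0, 1])."""
    members = set(geneset) & set(network.nodes)
    within = 0.0
    incident = 0.0
    for (u, v), w in network.edges.items():
        u_in, v_in = u in members, v in members
        if u_in and v_in:
            within += w
            incident += w
        elif u_in or v_in:
            incident += w
    if incident == 0:
        raise ValidationError("geneset has no incident edges")
    return within / incident


def property_performance_correlation(
    properties: Sequence[float],
    performances: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Spearman rank correlation between a geneset property (e.g. edge
    density) and per-geneset performance, with a seeded bootstrap 95% CI.

    Constant input makes the correlation undefined: returns (nan, (nan, nan))
    — callers should treat that as flagged, not as zero.
    """
    x = np.asarray(properties, dtype=float)
    y = np.asarray(performances, dtype=float)
    if x.size != y.size:
        raise ValidationError("property and performance lists must align")
    if x.size < 10:
        raise ValidationError("need >= 10 genesets for a correlation estimate")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return (float("nan"), (float("nan"), float("nan")))
    rho = float(spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, x.size, x.size)
        if np.all(x[idx] == x[idx][0]) or np.all(y[idx] == y[idx][0]):
            boot[i] = np.nan
            continue
        boot[i] = spearmanr(x[idx], y[idx]).statistic
    lo, hi = np.nanpercentile(boot, [2.5, 97.5])
    return rho, (float(lo), float(hi))


def make_eval_record(
    geneset_id: str,
    method: str,
    metric: str,
    raw_value: float,
    n_test_pos: int,
    n_test_neg: int,
) -> EvalRecord:
    """Bundle a metric value with its prior and log2 ratio (auROC is not
    prior-normalised)."""
    prior = n_test_pos / (n_test_pos + n_test_neg)
    ratio = log2_prior_ratio(raw_value, prior) if metric in ("auPRC", "P@TopK") else None
    return EvalRecord(
        geneset_id=geneset_id, method=method, metric=metric,
        raw_value=raw_value, prior=prior, log2_ratio=ratio,
    )
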