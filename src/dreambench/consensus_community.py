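"""Rank-sum consensus and community analytics over many prediction lists.

Consensus: every team's ranked list assigns each candidate edge a rank
(unsubmitted edges get the average of the missing rank positions); edges
are re-ranked by ascending rank sum.

Community analytics: the identifiability histogram bins gold edges by how
many teams place them within a top-``cutoff`` window (default 2P); its
random-community reference; a two-sample KS test (exact for small
samples); topology classification of negatives (shortcut / co-regulated);
and the systematic-false-positive contingency analysis with Fisher's
exact test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .formats import GoldNetwork, PredictionList, ValidationError

__all__ = [
    "IdentifiabilityHistogram",
    "TopologyClassification",
    "rank_sum_consensus",
    "identifiability",
    "random_community_reference",
    "ks_two_sample",
    "classify_topologies",
    "systematic_fp_analysis",
    "SystematicFPResult",
    "fisher_exact_two_sided",
    "contingency_ratios",
]

KS_EXACT_MAX = 12  # m + n up to which the KS p-value is enumerated exactly


def _universe_pairs(
    universe: GoldNetwork | int | None, preds: list[PredictionList]
) -> list[tuple[str, str]]:
    if isinstance(universe, GoldNetwork):
        return universe.all_pairs()
    nodes = sorted({n for p in preds for e in p.edges for n in e})
    if isinstance(universe, int):
        if len(nodes) > universe:
            raise ValidationError(
                f"{len(nodes)} distinct nodes exceed declared universe of {universe}"
            )
        if len(nodes) < universe:
            # pad with conventional ids so the universe has the declared size
            existing = set(nodes)
            i = 1
            while len(nodes) < universe:
                name = f"G{i}"
                if name not in existing:
                    nodes.append(name)
                i += 1
            nodes.sort()
    return [(a, b) for a in nodes for b in nodes if a != b]


def rank_sum_consensus(
    preds: list[PredictionList], universe: GoldNetwork | int | None = None
) -> PredictionList:
    """Re-rank the candidate universe by ascending summed team rank.

    Truncated lists contribute the expected rank (k_t + 1 + R) / 2 for
    every unsubmitted edge, keeping the consensus deterministic.  Ties
    break lexicographically on (source, target).
    """
    if len(preds) < 2:
        raise ValidationError("need at least 2 prediction lists for a consensus")
    pairs = _universe_pairs(universe, preds)
    R = len(pairs)
    pair_set = set(pairs)
    sums = {e: 0.0 for e in pairs}
    for pred in preds:
        if len(pred) > R:
            raise ValidationError("prediction list longer than candidate universe")
        ranks = pred.ranks()
        for e in ranks:
            if e not in pair_set:
                raise ValidationError(f"edge {e[0]}->{e[1]} outside candidate universe")
        missing_rank = (len(pred) + 1 + R) / 2
        for e in pairs:
            sums[e] += ranks.get(e, missing_rank)
    ordered = sorted(pairs, key=lambda e: (sums[e], e[0], e[1]))
    return PredictionList(edges=tuple(ordered))


def _completed_top_edges(
    pred: PredictionList,
    pairs: list[tuple[str, str]],
    cutoff: int,
    rng: np.random.Generator,
) -> set[tuple[str, str]]:
    """Top-``cutoff`` edge set after random completion of a truncated list."""
    head = list(pred.edges[:cutoff])
    if len(head) >= cutoff:
        return set(head)
    submitted = set(pred.edges)
    missing = [e for e in pairs if e not in submitted]
    order = rng.permutation(len(missing))
    head.extend(missing[i] for i in order[: cutoff - len(head)])
    return set(head)


@dataclass(frozen=True)
class IdentifiabilityHistogram:
    """Gold edges binned by the number of teams that predict them."""

    cutoff: int
    n_teams: int
    bins: dict[int, int]  # teams t -> number of gold edges with exactly t votes

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.bins.get(t, 0) for t in range(self.n_teams + 1)])

    def edge_votes(self) -> np.ndarray:
        """Expand to one vote count per gold edge (for KS comparisons)."""
        return np.repeat(np.arange(self.n_teams + 1), self.counts)


def identifiability(
    preds: list[PredictionList],
    gold: GoldNetwork,
    cutoff: int | None = None,
    seed: int = 0,
) -> IdentifiabilityHistogram:
    """Histogram over gold edges of team votes within the top-cutoff window.

    ``cutoff`` defaults to 2P.  Truncated lists are completed with a seeded
    random ordering of the missing candidate edges before thresholding.
    """
    if cutoff is None:
        cutoff = 2 * gold.n_edges
    if cutoff > gold.n_pairs:
        raise ValidationError(f"cutoff {cutoff} exceeds universe size {gold.n_pairs}")
    pairs = gold.all_pairs()
    rng = np.random.default_rng(seed)
    votes = {e: 0 for e in gold.edges}
    for pred in preds:
        top = _completed_top_edges(pred, pairs, cutoff, rng)
        for e in gold.edges:
            if e in top:
                votes[e] += 1
    bins: dict[int, int] = {}
    for v in votes.values():
        bins[v] = bins.get(v, 0) + 1
    return IdentifiabilityHistogram(cutoff=cutoff, n_teams=len(preds), bins=bins)


def random_community_reference(
    gold: GoldNetwork,
    n_teams: int,
    cutoff: int | None = None,
    n_reps: int = 100,
    seed: int = 0,
) -> list[IdentifiabilityHistogram]:
    """Identifiability histograms for communities of uniformly random lists."""
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if cutoff is None:
        cutoff = 2 * gold.n_edges
    pairs = gold.all_pairs()
    rng = np.random.default_rng(seed)
    out = []
    edge_list = sorted(gold.edges)
    idx = {e: i for i, e in enumerate(pairs)}
    gold_idx = np.array([idx[e] for e in edge_list])
    R = len(pairs)
    for _ in range(n_reps):
        votes = np.zeros(len(edge_list), dtype=int)
        for _ in range(n_teams):
            positions = np.empty(R, dtype=int)
            positions[rng.permutation(R)] = np.arange(R)
            votes += positions[gold_idx] < cutoff
        bins: dict[int, int] = {}
        for v in votes:
            bins[int(v)] = bins.get(int(v), 0) + 1
        out.append(
            IdentifiabilityHistogram(cutoff=cutoff, n_teams=n_teams, bins=bins)
        )
    return out


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the sup of the absolute ECDF difference.  For m + n <= 12 the
    p-value is exact by enumeration of all label assignments (conditional
    on the pooled values); otherwise the asymptotic distribution is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")

    def stat(x, y):
        grid = np.concatenate([x, y])
        cx = np.searchsorted(np.sort(x), grid, side="right") / x.size
        cy = np.searchsorted(np.sort(y), grid, side="right") / y.size
        return float(np.max(np.abs(cx - cy)))

    d = stat(a, b)
    m, n = a.size, b.size
    if m + n <= KS_EXACT_MAX:
        pooled = np.concatenate([a, b])
        total = 0
        hits = 0
        for combo in itertools.combinations(range(m + n), m):
            total += 1
            sel = np.zeros(m + n, dtype=bool)
            sel[list(combo)] = True
            if stat(pooled[sel], pooled[~sel]) >= d - 1e-12:
                hits += 1
        return d, hits / total
    res = stats.ks_2samp(a, b, method="asymp")
    return d, float(res.pvalue)


@dataclass(frozen=True)
class TopologyClassification:
    """Per-negative-pair flags: shortcut, co-regulated, special (= either)."""

    shortcut: dict[tuple[str, str], bool]
    co_regulated: dict[tuple[str, str], bool]

    def special(self, pair: tuple[str, str]) -> bool:
        return self.shortcut[pair] or self.co_regulated[pair]

    @property
    def n_special(self) -> int:
        return sum(1 for p in self.shortcut if self.special(p))


def classify_topologies(gold: GoldNetwork) -> TopologyClassification:
    """Classify every negative ordered pair (A, B):

    - shortcut: a directed path A -> ... -> B of length >= 2 exists;
    - co-regulated: some node C has edges C -> A and C -> B.
    """
    g = nx.DiGraph()
    g.add_nodes_from(gold.nodes)
    g.add_edges_from(gold.edges)
    desc = {n: nx.descendants(g, n) for n in gold.nodes}
    preds = {n: set(g.predecessors(n)) for n in gold.nodes}
    shortcut = {}
    co_reg = {}
    for a, b in gold.negatives():
        # (a, b) is a negative, so any a->...->b path has length >= 2
        shortcut[(a, b)] = b in desc[a]
        co_reg[(a, b)] = bool(preds[a] & preds[b])
    return TopologyClassification(shortcut=shortcut, co_regulated=co_reg)


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p by the point-probability method: the sum of
    hypergeometric probabilities of all tables (with the observed margins)
    no more likely than the observed one."""
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValidationError("contingency counts must be non-negative integers")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass(frozen=True)
class SystematicFPResult:
    """2x2 cross-classification of negatives with row ratios and Fisher p."""

    table: tuple[tuple[int, int], tuple[int, int]]  # rows: systematic, rare
    # columns: special, generic
    n_systematic: int
    boundary_ties_included: bool
    fisher_p: float

    @property
    def systematic_ratio(self) -> float:
        special, generic = self.table[0]
        return special / generic

    @property
    def rare_ratio(self) -> float:
        special, generic = self.table[1]
        return special / generic

    @property
    def total(self) -> int:
        return sum(v for row in self.table for v in row)


def contingency_ratios(
    table: tuple[tuple[int, int], tuple[int, int]],
) -> tuple[float, float]:
    """Per-row special-to-generic ratios of a 2x2 contingency table."""
    (a, b), (c, d) = table
    return a / b, c / d


def systematic_fp_analysis(
    preds: list[PredictionList],
    gold: GoldNetwork,
    cutoff: int | None = None,
    top_fraction: float = 0.01,
    seed: int = 0,
) -> SystematicFPResult:
    """Cross-classify negatives by community vote count and topology.

    Negatives are ranked by the number of teams predicting them within the
    top-``cutoff`` window (truncated lists randomly completed, seeded); the
    top ``top_fraction`` are the systematic false positives.  Vote ties
    straddling the boundary are all included, so the systematic row may
    slightly exceed the nominal fraction (flagged in the result).
    """
    if not preds:
        raise ValidationError("need at least one prediction list")
    if not (0 < top_fraction < 1):
        raise ValidationError(f"top_fraction must be in (0,1), got {top_fraction}")
    if cutoff is None:
        cutoff = 2 * gold.n_edges
    pairs = gold.all_pairs()
    negatives = gold.negatives()
    rng = np.random.default_rng(seed)
    votes = {e: 0 for e in negatives}
    for pred in preds:
        top = _completed_top_edges(pred, pairs, cutoff, rng)
        for e in negatives:
            if e in top:
                votes[e] += 1
    n_top = max(1, math.ceil(top_fraction * len(negatives)))
    ordered = sorted(negatives, key=lambda e: (-votes[e], e))
    threshold = votes[ordered[n_top - 1]]
    systematic = {e for e in negatives if votes[e] > threshold}
    ties = [e for e in negatives if votes[e] == threshold]
    ties_included = len(systematic) + len(ties) > n_top
    systematic.update(ties)

    topo = classify_topologies(gold)
    counts = [[0, 0], [0, 0]]
    for e in negatives:
        row = 0 if e in systematic else 1
        col = 0 if topo.special(e) else 1
        counts[row][col] += 1
    table = (tuple(counts[0]), tuple(counts[1]))
    p = fisher_exact_two_sided(table)
    return SystematicFPResult(
        table=table,
        n_systematic=len(systematic),
        boundary_ties_included=ties_included,
        fisher_p=p,
    )
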