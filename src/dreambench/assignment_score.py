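"""Exact scoring of measurement-to-species assignment tables.

An assignment table maps M measurements injectively onto S molecular
species, so there are S!/(S-M)! distinct tables.  A submission is scored by
the probability that a uniformly random table matches a fixed reference in
at least as many cells.  Counts by number of agreements are computed
exactly (inclusion-exclusion over forbidden cells, verified against brute
enumeration in the test suite); by symmetry they do not depend on the
reference table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .formats import AssignmentTable, ValidationError

__all__ = [
    "MatchDistribution",
    "match_distribution",
    "score_assignment",
    "cell_match_probability",
    "community_pvalue",
    "community_overlay",
]

_MAX_SPECIES = 12  # exact-enumeration guard; challenge scale is tiny


def _falling(n: int, k: int) -> int:
    """n * (n-1) * ... * (n-k+1); 1 for k = 0."""
    out = 1
    for i in range(k):
        out *= n - i
    return out


@dataclass(frozen=True)
class MatchDistribution:
    """Exact counts of assignment tables by number of correct cells."""

    n_species: int
    n_measurements: int
    count_by_matches: dict[int, int]

    @property
    def total_tables(self) -> int:
        return _falling(self.n_species, self.n_measurements)

    def tail_probability(self, n_correct: int) -> float:
        """P(matches >= n_correct) under a uniform random table."""
        if n_correct <= 0:
            return 1.0
        tail = sum(
            c for m, c in self.count_by_matches.items() if m >= n_correct
        )
        return tail / self.total_tables


def match_distribution(n_species: int, n_measurements: int) -> MatchDistribution:
    """Exact distribution of agreements between a uniform random injective
    assignment and a fixed reference.

    The count with exactly ``m`` agreements is
    ``C(M, m) * A(S - m, M - m)`` where ``A(s, k)`` counts injective maps of
    ``k`` items into ``s`` species avoiding one distinct forbidden species
    per item (a rectangular derangement number).
    """
    S, M = int(n_species), int(n_measurements)
    if not (1 <= M <= S):
        raise ValidationError(
            f"need 1 <= n_measurements <= n_species, got M={M}, S={S}"
        )
    if S > _MAX_SPECIES:
        raise ValidationError(
            f"exact enumeration supports at most {_MAX_SPECIES} species (got {S})"
        )

    def avoiding(s: int, k: int) -> int:
        # inclusion-exclusion over which forbidden cells are hit
        return sum(
            (-1) ** j * math.comb(k, j) * _falling(s - j, k - j)
            for j in range(k + 1)
        )

    counts = {m: math.comb(M, m) * avoiding(S - m, M - m) for m in range(M + 1)}
    dist = MatchDistribution(S, M, counts)
    assert sum(counts.values()) == dist.total_tables
    return dist


def count_correct(submitted: AssignmentTable, gold: AssignmentTable) -> int:
    if not submitted.same_catalogs(gold):
        raise ValidationError("submitted and gold tables have different catalogs")
    return sum(
        1 for m in gold.measurements if submitted.mapping[m] == gold.mapping[m]
    )


def score_assignment(
    submitted: AssignmentTable, gold: AssignmentTable
) -> tuple[int, float]:
    """Number of correct assignments and the exact probability that a random
    table does at least as well."""
    n_correct = count_correct(submitted, gold)
    dist = match_distribution(gold.n_species, gold.n_measurements)
    return n_correct, dist.tail_probability(n_correct)


def cell_match_probability(
    n_species: int, n_measurements: int, n_cells: int
) -> float:
    """Probability that a uniform random table agrees with ``n_cells``
    specified (measurement, species) cells."""
    S, M, s = int(n_species), int(n_measurements), int(n_cells)
    if not (1 <= M <= S):
        raise ValidationError(f"need 1 <= n_measurements <= n_species, got M={M}, S={S}")
    if not (0 <= s <= M):
        raise ValidationError(f"need 0 <= n_cells <= n_measurements, got {s}")
    return _falling(S - s, M - s) / _falling(S, M)


def community_pvalue(n_teams: int, n_hits: int, q: float) -> float:
    """Upper binomial tail P(X >= n_hits) with X ~ Binomial(n_teams, q)."""
    if not (0 <= n_hits <= n_teams):
        raise ValidationError(f"need 0 <= n_hits <= n_teams, got {n_hits}/{n_teams}")
    if not (0 < q < 1):
        raise ValidationError(f"need 0 < q < 1, got q={q}")
    if n_hits == 0:
        return 1.0
    return float(stats.binom.sf(n_hits - 1, n_teams, q))


def community_overlay(
    tables: list[AssignmentTable], gold: AssignmentTable
) -> tuple[dict[tuple[str, str], int], dict[tuple[str, str], float]]:
    """Vote counts and per-cell binomial p-values for a community of tables.

    Returns (votes, pvalues), both keyed by (measurement, species); only
    cells receiving at least one vote are present.  The per-cell null uses
    the single-cell match probability q(s=1).
    """
    if not tables:
        raise ValidationError("need at least one assignment table")
    for t in tables:
        if not t.same_catalogs(gold):
            raise ValidationError("table catalogs differ from gold")
    votes: dict[tuple[str, str], int] = {}
    for t in tables:
        for m in gold.measurements:
            key = (m, t.mapping[m])
            votes[key] = votes.get(key, 0) + 1
    q = cell_match_probability(gold.n_species, gold.n_measurements, 1)
    pvalues = {
        cell: community_pvalue(len(tables), n, q) for cell, n in votes.items()
    }
    return votes, pvalues
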