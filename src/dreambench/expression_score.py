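"""Spearman profile scoring of predicted rank matrices.

A submission is a genes x time-points matrix whose columns are
permutations of 1..G.  It is compared with the gold matrix along both
axes: per time point (columns, vectors over genes) and per gene (rows,
vectors over time points).  Each profile yields a Spearman rho and a
one-sided upper-tail p-value; per-axis p-values are condensed to a
summary p-value by their geometric mean, and the overall score is
``-log10(sqrt(p_time * p_gene))``.

The Spearman null is exact (full permutation enumeration) for n <= 9 and
a one-sided t approximation with n-2 degrees of freedom otherwise; the
boundary rho = +/-1 falls back to the exact tail 1/n! where the
approximation diverges.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .formats import RankMatrix, ValidationError

__all__ = [
    "ProfileScore",
    "spearman_rho",
    "spearman_pvalue",
    "profile_scores",
    "expression_overall_score",
    "gene_difficulty",
    "geometric_mean",
]

EXACT_N_MAX = 9


def geometric_mean(ps) -> float:
    ps = np.asarray(ps, dtype=float)
    return float(np.exp(np.mean(np.log(ps))))


def spearman_rho(a, b) -> float:
    """Spearman rank correlation; ties get average ranks."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("rank vectors must be 1-d and equal length")
    if a.size < 2:
        raise ValidationError("need at least 2 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("rho undefined for a constant vector")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


@lru_cache(maxsize=None)
def _exact_rho_distribution(n: int) -> np.ndarray:
    """Sorted Spearman rho values over all n! permutations vs the identity."""
    base = np.arange(1, n + 1)
    perms = np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)
    d2 = ((perms - base) ** 2).sum(axis=1)
    rho = 1 - 6 * d2 / (n * (n**2 - 1))
    return np.sort(rho)


def spearman_pvalue(rho: float, n: int) -> float:
    """One-sided upper-tail P(rho_null >= rho) for tie-free ranks of length n."""
    n = int(n)
    if n < 3:
        raise ValidationError("need n >= 3 for a Spearman p-value")
    rho = float(rho)
    if not -1 - 1e-9 <= rho <= 1 + 1e-9:
        raise ValidationError(f"rho={rho} outside [-1, 1]")
    if n <= EXACT_N_MAX:
        dist = _exact_rho_distribution(n)
        idx = np.searchsorted(dist, rho - 1e-12, side="left")
        return float((dist.size - idx) / dist.size)
    if rho >= 1 - 1e-12:
        return 1.0 / math.factorial(n)
    if rho <= -1 + 1e-12:
        return 1.0
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    return float(stats.t.sf(t, df=n - 2))


@dataclass(frozen=True)
class ProfileScore:
    """Per-profile rho/p along one axis plus the geometric-mean summary."""

    axis: str  # "time" or "gene"
    labels: tuple[str, ...]
    rho: tuple[float, ...]
    pvalues: tuple[float, ...]

    @property
    def summary_p(self) -> float:
        return geometric_mean(self.pvalues)


def _check_aligned(pred: RankMatrix, gold: RankMatrix) -> None:
    if list(pred.genes) != list(gold.genes) or list(pred.time_points) != list(
        gold.time_points
    ):
        raise ValidationError("prediction and gold labels do not match")


def profile_scores(pred: RankMatrix, gold: RankMatrix, axis: str) -> ProfileScore:
    """Score per time point (``axis='time'``) or per gene (``axis='gene'``)."""
    _check_aligned(pred, gold)
    if axis == "time":
        labels = tuple(map(str, gold.time_points))
        vec_pairs = [
            (pred.ranks[c].to_numpy(), gold.ranks[c].to_numpy())
            for c in gold.time_points
        ]
    elif axis == "gene":
        labels = tuple(map(str, gold.genes))
        vec_pairs = [
            (pred.ranks.loc[g].to_numpy(), gold.ranks.loc[g].to_numpy())
            for g in gold.genes
        ]
    else:
        raise ValidationError(f"axis must be 'time' or 'gene', got {axis!r}")
    rhos, ps = [], []
    for a, b in vec_pairs:
        r = spearman_rho(a, b)
        rhos.append(r)
        ps.append(spearman_pvalue(r, len(a)))
    return ProfileScore(axis=axis, labels=labels, rho=tuple(rhos), pvalues=tuple(ps))


def expression_overall_score(p_time: float, p_gene: float) -> float:
    """-log10 of the geometric mean of the two summary p-values."""
    for name, p in (("p_time", p_time), ("p_gene", p_gene)):
        if not (0 < p <= 1):
            raise ValidationError(f"{name}={p} outside (0, 1]")
    return float(-math.log10(math.sqrt(p_time * p_gene)))


def gene_difficulty(preds: list[RankMatrix], gold: RankMatrix) -> dict[str, float]:
    """Per-gene geometric mean, across teams, of gene-profile p-values.

    Small values mark easy (well-predicted) genes, values near 1 mark hard
    ones; sorting gives best-/worst-predicted lists.
    """
    if not preds:
        raise ValidationError("need at least one team prediction")
    per_team = []
    for pred in preds:
        score = profile_scores(pred, gold, axis="gene")
        per_team.append(np.array(score.pvalues))
    stacked = np.vstack(per_team)
    means = np.exp(np.mean(np.log(stacked), axis=0))
    return {g: float(v) for g, v in zip(gold.genes, means)}
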