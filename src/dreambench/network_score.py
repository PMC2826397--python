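"""ROC and precision-recall evaluation of ranked edge lists.

A prediction is a ranked list of candidate directed edges over the
universe of R = N(N-1) ordered non-self pairs.  Scanning the list depth
k = 1..R traces confusion counts TP(k), FP(k) and the derived
precision/recall and TPR/FPR curves.

Truncated lists (fewer than R submitted edges) are completed *in
expectation*: the unsubmitted edges are treated as appended in uniformly
random order and the expected counts are used, so scores are deterministic.
Beyond the truncation depth the per-step true-positive increment is the
constant P_r / (P_r + N_r), where P_r and N_r are the unsubmitted positives
and negatives; AUROC by trapezoidal integration of the completed curve and
AUPR by the expected average-precision formula are then exactly the
expectations over random tail orderings (validated against a brute-force
Monte-Carlo oracle in the test suite).

Significance is assessed against an empirical null of uniformly random
full-length orderings, with stretched-exponential tail extrapolation for
observations outside the sampled range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import GoldNetwork, PredictionList, ValidationError
from .null_models import StretchedExponentialFit, fit_stretched_exponential, tail_pvalue

__all__ = [
    "ConfusionCurves",
    "confusion_curves",
    "auroc",
    "aupr",
    "network_null",
    "metric_pvalue",
    "network_overall_score",
    "NetworkScoreSet",
    "random_metrics_from_positive_ranks",
]


@dataclass(frozen=True)
class ConfusionCurves:
    """TP/FP counts for every list depth k = 1..R (fractional past k_t)."""

    tp: np.ndarray  # shape (R,), TP(k); fractional for k > k_t
    k_t: int  # truncation depth (R for a full list)
    n_positives: int
    n_negatives: int

    @property
    def n_pairs(self) -> int:
        return self.n_positives + self.n_negatives

    @property
    def fp(self) -> np.ndarray:
        return np.arange(1, self.n_pairs + 1) - self.tp

    @property
    def recall(self) -> np.ndarray:
        return self.tp / self.n_positives

    tpr = recall

    @property
    def fpr(self) -> np.ndarray:
        return self.fp / self.n_negatives

    @property
    def precision(self) -> np.ndarray:
        return self.tp / np.arange(1, self.n_pairs + 1)


def curves_from_labels(hits, n_positives: int, n_negatives: int) -> ConfusionCurves:
    """Build curves from the submitted prefix's positive/negative labels.

    ``hits`` is the boolean label sequence of the submitted edges in rank
    order (length k_t <= P + N); the unsubmitted remainder is completed in
    expectation.
    """
    P, N = int(n_positives), int(n_negatives)
    if P <= 0 or N <= 0:
        raise ValidationError("need at least one positive and one negative")
    hits = np.asarray(hits, dtype=float)
    R = P + N
    k_t = hits.size
    if k_t > R:
        raise ValidationError("more labels than candidate pairs")
    if hits.sum() > P or (k_t - hits.sum()) > N:
        raise ValidationError("label sequence inconsistent with P and N")
    tp = np.empty(R, dtype=float)
    tp[:k_t] = np.cumsum(hits)
    if k_t < R:
        tp_head = tp[k_t - 1] if k_t > 0 else 0.0
        p_rem = P - tp_head
        n_rem = (R - k_t) - p_rem
        rate = p_rem / (p_rem + n_rem)
        tp[k_t:] = tp_head + rate * np.arange(1, R - k_t + 1)
    return ConfusionCurves(tp=tp, k_t=k_t, n_positives=P, n_negatives=N)


def confusion_curves(pred: PredictionList, gold: GoldNetwork) -> ConfusionCurves:
    """Exact counts up to the truncation depth, expected counts beyond it."""
    universe = set(gold.all_pairs())
    for s, t in pred.edges:
        if (s, t) not in universe:
            raise ValidationError(f"predicted edge {s}->{t} outside candidate universe")
    hits = np.array([e in gold.edges for e in pred.edges], dtype=float)
    return curves_from_labels(hits, gold.n_edges, gold.n_negatives)


def auroc(curves: ConfusionCurves) -> float:
    """Area under TPR vs FPR by trapezoidal integration from the origin.

    Equals the concordant-pair fraction for full lists and the exact
    expectation under random tail ordering for truncated lists.
    """
    fpr = np.concatenate([[0.0], curves.fpr])
    tpr = np.concatenate([[0.0], curves.tpr])
    return float(np.trapezoid(tpr, fpr))


def aupr(curves: ConfusionCurves) -> float:
    """Average precision: mean over positives of precision at retrieval.

    For depths beyond the truncation the contribution is the expectation
    conditional on a positive occupying that slot:
    weight P_r/(P_r+N_r) and E[TP(k) | positive at k] =
    TP(k_t) + 1 + (k - k_t - 1) (P_r - 1)/(P_r + N_r - 1).
    """
    P = curves.n_positives
    R = curves.n_pairs
    k_t = curves.k_t
    k = np.arange(1, R + 1, dtype=float)
    total = 0.0
    if k_t > 0:
        tp_head = curves.tp[:k_t]
        is_pos = np.diff(np.concatenate([[0.0], tp_head])) > 0.5
        total += float(np.sum(tp_head[is_pos] / k[:k_t][is_pos]))
    if k_t < R:
        tp_t = curves.tp[k_t - 1] if k_t > 0 else 0.0
        p_rem = P - tp_t
        n_rem = (R - k_t) - p_rem
        if p_rem > 0:
            w = p_rem / (p_rem + n_rem)
            kk = k[k_t:]
            steps = kk - k_t - 1
            if p_rem + n_rem > 1:
                exp_tp = tp_t + 1 + steps * (p_rem - 1) / (p_rem + n_rem - 1)
            else:
                exp_tp = tp_t + 1
            total += float(np.sum(w * exp_tp / kk))
    return total / P


def random_metrics_from_positive_ranks(ranks: np.ndarray, P: int, N: int) -> tuple[float, float]:
    """(AUROC, AUPR) of a full list given the sorted 1-based ranks of its
    positives; O(P) closed forms used by the null simulation."""
    ranks = np.asarray(ranks, dtype=float)
    i = np.arange(1, P + 1, dtype=float)
    a = 1.0 - (ranks.sum() - P * (P + 1) / 2) / (P * N)
    ap = float(np.mean(i / ranks))
    return float(a), ap


def network_null(
    gold: GoldNetwork, n_reps: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled (AUROC, AUPR) of uniformly random full-length orderings."""
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    P = gold.n_edges
    R = gold.n_pairs
    N = R - P
    rng = np.random.default_rng(seed)
    aurocs = np.empty(n_reps)
    auprs = np.empty(n_reps)
    i = np.arange(1, P + 1, dtype=float)
    for r in range(n_reps):
        ranks = np.sort(rng.choice(R, size=P, replace=False) + 1).astype(float)
        aurocs[r] = 1.0 - (ranks.sum() - P * (P + 1) / 2) / (P * N)
        auprs[r] = np.mean(i / ranks)
    return aurocs, auprs


def metric_pvalue(
    observed: float,
    null_sample,
    side: str = "upper",
    fit: StretchedExponentialFit | None = None,
    fit_tails: bool = True,
) -> float:
    """P-value of a metric against an empirical null sample.

    Inside the sampled range the add-one-smoothed tail fraction
    ``(r + 1)/(n + 1)`` is used; outside it the stretched-exponential fit
    is integrated (fitted on demand unless supplied), falling back to the
    smoothed fraction when tail fitting is disabled.
    """
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size < 1:
        raise ValidationError("empty null sample")
    observed = float(observed)
    if side == "upper":
        r = int(np.sum(null_sample >= observed))
        outside = observed > null_sample.max()
    elif side == "lower":
        r = int(np.sum(null_sample <= observed))
        outside = observed < null_sample.min()
    else:
        raise ValidationError(f"side must be 'upper' or 'lower', got {side!r}")
    if outside and fit_tails:
        if fit is None:
            fit = fit_stretched_exponential(null_sample)
        return tail_pvalue(fit, observed, side=side)
    return (r + 1) / (null_sample.size + 1)


@dataclass(frozen=True)
class NetworkScoreSet:
    """Per-network metrics/p-values and the condensed overall score."""

    network_names: tuple[str, ...]
    auroc: tuple[float, ...]
    aupr: tuple[float, ...]
    p_auroc: tuple[float, ...]
    p_aupr: tuple[float, ...]

    @property
    def summary_p_auroc(self) -> float:
        return float(np.exp(np.mean(np.log(self.p_auroc))))

    @property
    def summary_p_aupr(self) -> float:
        return float(np.exp(np.mean(np.log(self.p_aupr))))

    @property
    def overall_score(self) -> float:
        return float(
            -0.5 * (np.log10(self.summary_p_aupr) + np.log10(self.summary_p_auroc))
        )


def network_overall_score(
    per_network: list[tuple[float, float]],
    names: list[str] | None = None,
    metrics: list[tuple[float, float]] | None = None,
    require_count: int | None = 5,
) -> NetworkScoreSet:
    """Condense per-network (p_AUPR, p_AUROC) pairs into an overall score.

    By default exactly five networks are required (one subchallenge); pass
    ``require_count=None`` to accept any number.
    """
    if require_count is not None and len(per_network) != require_count:
        raise ValidationError(
            f"expected {require_count} networks, got {len(per_network)}"
        )
    if not per_network:
        raise ValidationError("no per-network p-values")
    for p_aupr, p_auroc in per_network:
        for p in (p_aupr, p_auroc):
            if not (0 < p <= 1):
                raise ValidationError(f"p-value {p} outside (0, 1]")
    if names is None:
        names = [f"network{i + 1}" for i in range(len(per_network))]
    if metrics is None:
        metrics = [(float("nan"), float("nan"))] * len(per_network)
    return NetworkScoreSet(
        network_names=tuple(names),
        auroc=tuple(m[0] for m in metrics),
        aupr=tuple(m[1] for m in metrics),
        p_aupr=tuple(p[0] for p in per_network),
        p_auroc=tuple(p[1] for p in per_network),
    )
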