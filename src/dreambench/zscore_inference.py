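"""Null-mutant z-score network inference.

For each ordered gene pair (A, B) the z-score is the expression of B in
the A-knockout strain, standardized by the mean and standard deviation of
B across the strain panel (wild type plus every knockout; knockdown
strains can be opted in).  Deletion of a direct regulator shifts its
target far from baseline, so ranking candidate edges by |z|, descending,
yields a network prediction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .formats import PredictionList, StrainExpressionMatrix, ValidationError

__all__ = ["zscore_matrix", "null_mutant_zscores"]


def zscore_matrix(
    data: StrainExpressionMatrix,
    include_knockdowns: bool = False,
    include_self: bool = False,
    ddof: int = 1,
) -> pd.DataFrame:
    """Signed z-score matrix, rows = putative regulator A, columns = target B.

    The diagonal is NaN (self-regulation is not a candidate).  A target
    whose expression is constant across the panel carries no signal: its
    column is scored 0 with a warning.

    By default the reading of gene B in its *own* knockout strain is left
    out of B's mean/sd: that cell is zero by construction (the gene is
    deleted), so including it drags every column's baseline toward zero by
    an amount proportional to the column's expression level, which destroys
    comparability of z-scores across targets.  ``include_self=True``
    restores the literal all-strains panel.
    """
    genes = list(data.genes)
    if len(genes) + 1 < 3:
        raise ValidationError("need at least 3 strains (WT plus 2 knockouts)")
    panel = data.steady_state(include_knockdowns=include_knockdowns)
    values = panel.to_numpy(dtype=float)  # strains x genes
    n_strains, n_genes = values.shape
    if include_self:
        mean = values.mean(axis=0)
        sd = values.std(axis=0, ddof=ddof)
    else:
        # drop, per column, the row of that gene's own knockout strain
        ko_row = {g: panel.index.get_loc(g) for g in genes}
        keep = np.ones((n_strains, n_genes), dtype=bool)
        for j, g in enumerate(genes):
            keep[ko_row[g], j] = False
        n_kept = keep.sum(axis=0)
        masked = np.where(keep, values, 0.0)
        mean = masked.sum(axis=0) / n_kept
        dev2 = np.where(keep, (values - mean) ** 2, 0.0)
        sd = np.sqrt(dev2.sum(axis=0) / (n_kept - ddof))
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"constant expression for {int(flat.sum())} gene(s); "
            "their incoming z-scores are set to 0",
            stacklevel=2,
        )
    ko = data.knockouts.loc[genes].to_numpy(dtype=float)  # deleted gene x genes
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (ko - mean) / sd
    z[:, flat] = 0.0
    np.fill_diagonal(z, np.nan)
    return pd.DataFrame(z, index=genes, columns=genes)


def null_mutant_zscores(
    data: StrainExpressionMatrix,
    include_knockdowns: bool = False,
    include_self: bool = False,
    ddof: int = 1,
) -> PredictionList:
    """Full-length edge ranking by |z| descending.

    Ties break lexicographically on (source, target) so the output is
    deterministic.  Confidences are |z| rescaled to (0, 1].
    """
    z = zscore_matrix(
        data,
        include_knockdowns=include_knockdowns,
        include_self=include_self,
        ddof=ddof,
    )
    genes = list(z.index)
    entries = []
    for a in genes:
        for b in genes:
            if a == b:
                continue
            entries.append((abs(float(z.at[a, b])), a, b))
    entries.sort(key=lambda e: (-e[0], e[1], e[2]))
    top = entries[0][0]
    if top == 0:
        confs = tuple(1.0 for _ in entries)
    else:
        confs = tuple(e[0] / top for e in entries)
    return PredictionList(
        edges=tuple((a, b) for _, a, b in entries), confidences=confs
    )
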