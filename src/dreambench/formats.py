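"""Domain types and TSV readers/writers.

Every file the toolkit touches goes through this module, and all structural
validation lives here.  The TSV dialect is deliberately rigid: tab-separated,
UTF-8, ``#`` comment lines ignored, no quoting.  Missing measurement cells may
be spelled ``NA``, ``NaN`` or left empty.

Node identifiers are opaque, case-sensitive strings.  Ranked edge lists keep
their file order as the authoritative ranking; an optional confidence column
is validated (non-increasing) but never used to re-sort.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "PredictionList",
    "GoldNetwork",
    "MeasurementTable",
    "RankMatrix",
    "AssignmentTable",
    "StrainExpressionMatrix",
    "ScoreReport",
    "read_prediction_list",
    "write_prediction_list",
    "read_gold_network",
    "write_gold_network",
    "read_measurement_table",
    "write_measurement_table",
    "read_rank_matrix",
    "write_rank_matrix",
    "read_assignment_table",
    "write_assignment_table",
    "read_challenge_bundle",
]

_NA_STRINGS = {"NA", "NaN", "nan", ""}


class FormatError(ValueError):
    """A file could not be parsed in the expected dialect."""


class ValidationError(FormatError):
    """A parsed value violates a structural invariant."""


def _data_lines(path: str | os.PathLike) -> list[tuple[int, list[str]]]:
    """Return (1-based line number, fields) for every non-comment line."""
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append((i, line.split("\t")))
    return out


# ---------------------------------------------------------------------------
# GoldNetwork
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GoldNetwork:
    """A directed gold-standard network over a fixed node universe.

    The candidate universe is every ordered non-self pair, so with ``N``
    nodes there are ``R = N(N-1)`` candidates, of which ``P`` are edges
    (positives) and ``R - P`` are negatives.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError("duplicate node ids in gold network")
        node_set = set(self.nodes)
        for s, t in self.edges:
            if s == t:
                raise ValidationError(f"self-edge {s}->{t} in gold network")
            if s not in node_set or t not in node_set:
                raise ValidationError(f"edge {s}->{t} references unknown node")
        if len(self.edges) < 1:
            raise ValidationError("gold network must have at least one edge")

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] | None = None,
    ) -> "GoldNetwork":
        edges = frozenset(tuple(e) for e in edges)
        if nodes is None:
            nodes = sorted({n for e in edges for n in e})
        return cls(nodes=tuple(nodes), edges=edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        """P, the number of positives."""
        return len(self.edges)

    @property
    def n_pairs(self) -> int:
        """R = N(N-1), the size of the candidate universe."""
        n = self.n_nodes
        return n * (n - 1)

    @property
    def n_negatives(self) -> int:
        return self.n_pairs - self.n_edges

    def all_pairs(self) -> list[tuple[str, str]]:
        """All ordered non-self pairs, lexicographically sorted."""
        ns = sorted(self.nodes)
        return [(a, b) for a in ns for b in ns if a != b]

    def negatives(self) -> list[tuple[str, str]]:
        return [p for p in self.all_pairs() if p not in self.edges]


def _universe_size(universe: "GoldNetwork | int") -> int:
    if isinstance(universe, GoldNetwork):
        return universe.n_pairs
    n = int(universe)
    if n < 2:
        raise ValidationError("universe must contain at least 2 nodes")
    return n * (n - 1)


# ---------------------------------------------------------------------------
# PredictionList
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictionList:
    """An ordered ranked list of predicted directed edges.

    List order is the ranking (rank 1 first).  Confidences, when present,
    are advisory and must be non-increasing; equal-confidence rows keep
    their original order.
    """

    edges: tuple[tuple[str, str], ...]
    confidences: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        seen = set()
        for s, t in self.edges:
            if s == t:
                raise ValidationError(f"self-edge {s}->{t} in prediction list")
            if (s, t) in seen:
                raise ValidationError(f"duplicate edge {s}->{t} in prediction list")
            seen.add((s, t))
        if self.confidences is not None:
            if len(self.confidences) != len(self.edges):
                raise ValidationError("confidence count does not match edge count")
            for i in range(1, len(self.confidences)):
                if self.confidences[i] > self.confidences[i - 1] + 1e-12:
                    raise ValidationError(
                        f"confidence increases at row {i + 1} "
                        f"({self.confidences[i - 1]} -> {self.confidences[i]})"
                    )

    def __len__(self) -> int:
        return len(self.edges)

    def ranks(self) -> dict[tuple[str, str], int]:
        """Map edge -> 1-based rank."""
        return {e: i + 1 for i, e in enumerate(self.edges)}


def read_prediction_list(
    path: str | os.PathLike, universe: GoldNetwork | int
) -> PredictionList:
    """Read a ranked edge list (``source\\ttarget[\\tconfidence]``).

    ``universe`` bounds the list length at ``N(N-1)``; a :class:`GoldNetwork`
    universe additionally restricts node ids to its node set.
    """
    rows = _data_lines(path)
    if not rows:
        raise FormatError(f"{path}: no edges")
    edges: list[tuple[str, str]] = []
    confs: list[float] = []
    has_conf = len(rows[0][1]) >= 3
    for lineno, fields in rows:
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected at least 2 columns")
        s, t = fields[0], fields[1]
        if s == t:
            raise ValidationError(f"{path}:{lineno}: self-edge {s}->{t}")
        if (s, t) in set(edges):
            raise ValidationError(f"{path}:{lineno}: duplicate edge {s}->{t}")
        if isinstance(universe, GoldNetwork):
            if s not in universe.nodes or t not in universe.nodes:
                raise ValidationError(
                    f"{path}:{lineno}: edge {s}->{t} outside node universe"
                )
        edges.append((s, t))
        if has_conf:
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: missing confidence column")
            try:
                c = float(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad confidence {fields[2]!r}") from exc
            if confs and c > confs[-1] + 1e-12:
                raise ValidationError(
                    f"{path}:{lineno}: confidence increases ({confs[-1]} -> {c})"
                )
            confs.append(c)
    if len(edges) > _universe_size(universe):
        raise ValidationError(
            f"{path}: {len(edges)} edges exceed universe size {_universe_size(universe)}"
        )
    return PredictionList(
        edges=tuple(edges), confidences=tuple(confs) if has_conf else None
    )


def write_prediction_list(pred: PredictionList, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, (s, t) in enumerate(pred.edges):
            if pred.confidences is not None:
                fh.write(f"{s}\t{t}\t{pred.confidences[i]:.17g}\n")
            else:
                fh.write(f"{s}\t{t}\n")


def read_gold_network(
    path: str | os.PathLike, nodes: Iterable[str] | None = None
) -> GoldNetwork:
    """Read a gold standard edge list (``source\\ttarget\\t1``).

    Pairs absent from the file are negatives.  Explicit ``0`` rows are
    accepted (and checked: a pair may not appear as both 0 and 1).
    """
    declared: list[str] | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            if raw.startswith("# nodes:"):
                declared = raw[len("# nodes:"):].split()
                break
    rows = _data_lines(path)
    if not rows:
        raise FormatError(f"{path}: no edges")
    pos: set[tuple[str, str]] = set()
    neg: set[tuple[str, str]] = set()
    seen_nodes: set[str] = set()
    for lineno, fields in rows:
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected at least 2 columns")
        s, t = fields[0], fields[1]
        seen_nodes.update((s, t))
        flag = 1
        if len(fields) >= 3:
            try:
                flag = int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad edge flag {fields[2]!r}") from exc
            if flag not in (0, 1):
                raise FormatError(f"{path}:{lineno}: edge flag must be 0 or 1")
        (pos if flag == 1 else neg).add((s, t))
    both = pos & neg
    if both:
        s, t = sorted(both)[0]
        raise ValidationError(f"{path}: pair {s}->{t} listed as both edge and non-edge")
    if nodes is None:
        nodes = declared if declared is not None else sorted(seen_nodes)
    return GoldNetwork.from_edges(pos, nodes=nodes)


def write_gold_network(
    gold: GoldNetwork, path: str | os.PathLike, explicit_negatives: bool = False
) -> None:
    """Write edges as ``source\\ttarget\\t1``.  The full node universe is
    recorded in a ``# nodes:`` comment directive so isolated nodes survive a
    round trip."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# nodes: " + " ".join(sorted(gold.nodes)) + "\n")
        for s, t in sorted(gold.edges):
            fh.write(f"{s}\t{t}\t1\n")
        if explicit_negatives:
            for s, t in gold.negatives():
                fh.write(f"{s}\t{t}\t0\n")


# ---------------------------------------------------------------------------
# MeasurementTable
# ---------------------------------------------------------------------------


@dataclass
class MeasurementTable:
    """A condition x analyte matrix of non-negative measurements.

    ``mask`` marks prediction-target cells.  In training files the masked
    cells carry no value (NaN); in truth tables they carry the withheld
    measurement.
    """

    values: pd.DataFrame  # rows: condition labels, columns: analytes
    mask: pd.DataFrame  # same shape, bool; True = withheld / target

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValidationError("values and mask shapes differ")
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate condition labels")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate analyte names")
        vals = self.values.to_numpy(dtype=float)
        observed = ~self.mask.to_numpy(dtype=bool)
        if np.isnan(vals[observed]).any():
            raise ValidationError("unmasked cell has no value")
        finite = vals[np.isfinite(vals)]
        if finite.size and finite.min() < 0:
            raise ValidationError("negative measurement value")

    @property
    def conditions(self) -> list[str]:
        return list(self.values.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)

    def masked_cells(self) -> list[tuple[str, str]]:
        rows, cols = np.nonzero(self.mask.to_numpy(dtype=bool))
        return [
            (self.values.index[r], self.values.columns[c])
            for r, c in zip(rows, cols)
        ]


def read_measurement_table(
    path: str | os.PathLike, index_cols: int = 1
) -> MeasurementTable:
    """Read a measurement TSV: header row of analytes after ``index_cols``
    condition-descriptor columns; cells numeric or NA."""
    rows = _data_lines(path)
    if not rows:
        raise FormatError(f"{path}: empty table")
    _, header = rows[0]
    if len(header) <= index_cols:
        raise FormatError(f"{path}: no analyte columns")
    analytes = header[index_cols:]
    width = len(header)
    labels: list[str] = []
    data: list[list[float]] = []
    mask: list[list[bool]] = []
    for lineno, fields in rows[1:]:
        if len(fields) != width:
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, expected {width})"
            )
        labels.append("|".join(fields[:index_cols]))
        vrow: list[float] = []
        mrow: list[bool] = []
        for cell in fields[index_cols:]:
            if cell.strip() in _NA_STRINGS:
                vrow.append(math.nan)
                mrow.append(True)
            else:
                try:
                    v = float(cell)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad cell {cell!r}") from exc
                if v < 0:
                    raise ValidationError(f"{path}:{lineno}: negative value {v}")
                vrow.append(v)
                mrow.append(False)
        data.append(vrow)
        mask.append(mrow)
    values = pd.DataFrame(data, index=labels, columns=analytes, dtype=float)
    maskdf = pd.DataFrame(mask, index=labels, columns=analytes, dtype=bool)
    return MeasurementTable(values=values, mask=maskdf)


def write_measurement_table(
    table: MeasurementTable, path: str | os.PathLike, condition_header: str = "condition"
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(condition_header + "\t" + "\t".join(table.analytes) + "\n")
        vals = table.values.to_numpy(dtype=float)
        msk = table.mask.to_numpy(dtype=bool)
        for r, label in enumerate(table.conditions):
            # masked cells are written as NA (training-file semantics);
            # truth values for masked cells live only in memory
            cells = [
                "NA" if msk[r, c] else f"{vals[r, c]:.17g}"
                for c in range(vals.shape[1])
            ]
            fh.write(label + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# RankMatrix
# ---------------------------------------------------------------------------


@dataclass
class RankMatrix:
    """Genes x time-points matrix whose columns are permutations of 1..G.

    Rank 1 is the most induced gene, rank G the most repressed.
    """

    ranks: pd.DataFrame  # rows: gene ids, columns: time points, int values

    def __post_init__(self) -> None:
        g = self.ranks.shape[0]
        if self.ranks.index.has_duplicates:
            raise ValidationError("duplicate gene ids")
        if self.ranks.columns.has_duplicates:
            raise ValidationError("duplicate time-point labels")
        expected = np.arange(1, g + 1)
        arr = self.ranks.to_numpy()
        for j, col in enumerate(self.ranks.columns):
            if not np.array_equal(np.sort(arr[:, j]), expected):
                raise ValidationError(
                    f"column {col!r} is not a permutation of 1..{g}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.ranks.index)

    @property
    def time_points(self) -> list[str]:
        return list(self.ranks.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.ranks.shape


def read_rank_matrix(path: str | os.PathLike) -> RankMatrix:
    rows = _data_lines(path)
    if len(rows) < 2:
        raise FormatError(f"{path}: empty rank matrix")
    _, header = rows[0]
    cols = header[1:]
    if not cols:
        raise FormatError(f"{path}: no time-point columns")
    genes = []
    data = []
    for lineno, fields in rows[1:]:
        if len(fields) != len(header):
            raise FormatError(f"{path}:{lineno}: ragged row")
        genes.append(fields[0])
        try:
            data.append([int(x) for x in fields[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer rank") from exc
    return RankMatrix(ranks=pd.DataFrame(data, index=genes, columns=cols, dtype=int))


def write_rank_matrix(
    matrix: RankMatrix, path: str | os.PathLike, gene_header: str = "gene"
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(gene_header + "\t" + "\t".join(map(str, matrix.time_points)) + "\n")
        arr = matrix.ranks.to_numpy()
        for i, gene in enumerate(matrix.genes):
            fh.write(str(gene) + "\t" + "\t".join(str(int(v)) for v in arr[i]) + "\n")


# ---------------------------------------------------------------------------
# AssignmentTable
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssignmentTable:
    """An injective map from measurements to molecular species."""

    mapping: Mapping[str, str]  # measurement -> species
    species: tuple[str, ...]
    measurements: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValidationError("duplicate species in catalog")
        if len(set(self.measurements)) != len(self.measurements):
            raise ValidationError("duplicate measurements in catalog")
        if len(self.measurements) > len(self.species):
            raise ValidationError("more measurements than species")
        assigned = set()
        for m in self.measurements:
            if m not in self.mapping:
                raise ValidationError(f"measurement {m!r} not assigned")
            sp = self.mapping[m]
            if sp not in self.species:
                raise ValidationError(f"unknown species {sp!r}")
            if sp in assigned:
                raise ValidationError(f"species {sp!r} assigned twice")
            assigned.add(sp)
        extra = set(self.mapping) - set(self.measurements)
        if extra:
            raise ValidationError(f"assignment for unknown measurement {sorted(extra)[0]!r}")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_measurements(self) -> int:
        return len(self.measurements)

    def same_catalogs(self, other: "AssignmentTable") -> bool:
        return set(self.species) == set(other.species) and set(
            self.measurements
        ) == set(other.measurements)


def read_assignment_table(
    path: str | os.PathLike,
    species: Sequence[str] | None = None,
    measurements: Sequence[str] | None = None,
) -> AssignmentTable:
    """Read ``measurement\\tspecies`` rows.

    Catalogs default to the observed ids; pass explicit catalogs to score
    against a gold table that shares them.
    """
    rows = _data_lines(path)
    if not rows:
        raise FormatError(f"{path}: empty assignment table")
    mapping: dict[str, str] = {}
    for lineno, fields in rows:
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns")
        m, sp = fields
        if m in mapping:
            raise ValidationError(f"{path}:{lineno}: measurement {m!r} assigned twice")
        mapping[m] = sp
    meas = tuple(measurements) if measurements is not None else tuple(mapping)
    spec = tuple(species) if species is not None else tuple(sorted(set(mapping.values())))
    return AssignmentTable(mapping=mapping, species=spec, measurements=meas)


def write_assignment_table(table: AssignmentTable, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in table.measurements:
            fh.write(f"{m}\t{table.mapping[m]}\n")


# ---------------------------------------------------------------------------
# StrainExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class StrainExpressionMatrix:
    """Steady-state expression for WT, knockdown and knockout strains,
    plus optional time-course trajectories.

    ``knockouts`` / ``knockdowns`` are indexed by the deleted gene and hold
    one full expression profile (all genes) per strain.
    """

    genes: tuple[str, ...]
    wildtype: pd.Series  # index: genes
    knockouts: pd.DataFrame  # index: deleted gene, columns: genes
    knockdowns: pd.DataFrame | None = None
    trajectories: list[pd.DataFrame] = field(default_factory=list)  # index: time

    def __post_init__(self) -> None:
        genes = list(self.genes)
        if list(self.wildtype.index) != genes:
            raise ValidationError("wildtype index does not match gene catalog")
        if list(self.knockouts.columns) != genes:
            raise ValidationError("knockout columns do not match gene catalog")
        missing = set(genes) - set(self.knockouts.index)
        if missing:
            raise ValidationError(
                f"missing knockout strain for gene {sorted(missing)[0]!r}"
            )
        if self.knockdowns is not None and list(self.knockdowns.columns) != genes:
            raise ValidationError("knockdown columns do not match gene catalog")
        for df in [self.wildtype.to_frame().T, self.knockouts] + (
            [self.knockdowns] if self.knockdowns is not None else []
        ):
            if not np.isfinite(df.to_numpy(dtype=float)).all():
                raise ValidationError("non-finite expression value")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def steady_state(self, include_knockdowns: bool = False) -> pd.DataFrame:
        """Strains x genes matrix: WT row plus one row per deletion strain."""
        parts = [self.wildtype.to_frame("WT").T, self.knockouts]
        if include_knockdowns:
            if self.knockdowns is None:
                raise ValidationError("no knockdown strains available")
            kd = self.knockdowns.copy()
            kd.index = [f"KD:{g}" for g in kd.index]
            parts.append(kd)
        out = pd.concat(parts)
        return out


def _read_profile_table(path: str | os.PathLike) -> pd.DataFrame:
    rows = _data_lines(path)
    if len(rows) < 2:
        raise FormatError(f"{path}: empty table")
    header = rows[0][1]
    labels, data = [], []
    for lineno, fields in rows[1:]:
        if len(fields) != len(header):
            raise FormatError(f"{path}:{lineno}: ragged row")
        labels.append(fields[0])
        try:
            data.append([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric cell") from exc
    return pd.DataFrame(data, index=labels, columns=header[1:], dtype=float)


def read_challenge_bundle(directory: str | os.PathLike) -> StrainExpressionMatrix:
    """Read a simulator bundle: wildtype.tsv, knockouts.tsv, knockdowns.tsv
    (optional), trajectories/*.tsv (optional)."""
    d = str(directory)
    wt_df = _read_profile_table(os.path.join(d, "wildtype.tsv"))
    if wt_df.shape[0] != 1:
        raise FormatError("wildtype.tsv must contain exactly one strain row")
    genes = tuple(wt_df.columns)
    wildtype = wt_df.iloc[0]
    wildtype.name = None
    knockouts = _read_profile_table(os.path.join(d, "knockouts.tsv"))
    knockdowns = None
    kd_path = os.path.join(d, "knockdowns.tsv")
    if os.path.exists(kd_path):
        knockdowns = _read_profile_table(kd_path)
    trajectories = []
    traj_dir = os.path.join(d, "trajectories")
    if os.path.isdir(traj_dir):
        for name in sorted(os.listdir(traj_dir)):
            if name.endswith(".tsv"):
                df = _read_profile_table(os.path.join(traj_dir, name))
                df.index = df.index.astype(float)
                trajectories.append(df)
    return StrainExpressionMatrix(
        genes=genes,
        wildtype=wildtype.astype(float),
        knockouts=knockouts,
        knockdowns=knockdowns,
        trajectories=trajectories,
    )


# ---------------------------------------------------------------------------
# ScoreReport
# ---------------------------------------------------------------------------


@dataclass
class ScoreReport:
    """Per-item metrics/p-values, summary p-values, and the overall score.

    The overall score is ``-log10`` of the geometric mean of the summary
    p-values, so one unit corresponds to an order of magnitude in p.
    """

    metrics: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)
    summary_pvalues: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, p in {**self.pvalues, **self.summary_pvalues}.items():
            if not (0 < p <= 1):
                raise ValidationError(f"p-value {name!r}={p} outside (0,1]")

    @property
    def overall_score(self) -> float:
        ps = list(self.summary_pvalues.values())
        if not ps:
            raise ValidationError("no summary p-values")
        return -float(np.mean(np.log10(ps)))

    def to_dict(self) -> dict:
        return {
            "metrics": dict(self.metrics),
            "pvalues": dict(self.pvalues),
            "summary_pvalues": dict(self.summary_pvalues),
            "overall_score": self.overall_score,
        }
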