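"""Synthetic gene-network fixtures: random acyclic networks and simulated
steady-state, knockdown, knockout and trajectory data.

The dynamics are deliberately simple: additive saturating regulation with
linear decay,

    dx_i/dt = basal_i + sum_j w_ij * s(x_j) - decay_i * x_i

with the Hill-type s(x) = x^h / (K^h + x^h) for activation and
1 - s(x) for repression.  Because the generated graphs are acyclic,
steady states are solved exactly in topological order.  Strain
conventions: a knockout clamps the deleted gene to zero and the system is
re-equilibrated; a knockdown clamps it to half (configurable) its
wild-type level.  Independent Gaussian noise of a configurable standard
deviation is added to every reported value.

The default half-saturation sits well below wild-type expression levels,
so regulation is near-saturated in the unperturbed system: deleting a
regulator produces a large shift in its direct targets (the regulatory
input collapses from ~w to 0) but only a tiny shift downstream (targets
of targets stay in the saturated regime).  This Boolean-like character --
strong direct, weak indirect effects -- is what makes the z-score
inference method effective on these fixtures.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .formats import GoldNetwork, StrainExpressionMatrix, ValidationError, write_gold_network

__all__ = [
    "SimulationConfig",
    "PRESETS",
    "generate_network",
    "simulate_dataset",
    "write_challenge_bundle",
    "preset_config",
    "steady_state_residual",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_nodes: int = 10
    n_edges: int = 11
    n_trajectories: int = 4
    time_grid: tuple[float, ...] = tuple(float(t) for t in range(0, 21, 2))
    noise_sd: float = 0.0
    knockdown_factor: float = 0.5
    seed: int = 0
    regulator_fraction: float = 0.5  # at most this fraction of nodes regulate
    max_in_degree: int | None = None
    activation_bias: float = 0.8  # fraction of edges that activate
    weight_range: tuple[float, float] = (1.0, 2.0)
    basal_range: tuple[float, float] = (1.0, 1.5)
    decay: float = 1.0
    half_saturation: float = 0.3  # K well below WT levels => saturated regulation
    hill: float = 2.0  # activation steepness

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValidationError("need at least 2 nodes")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not (0 < self.knockdown_factor < 1):
            raise ValidationError("knockdown_factor must be in (0, 1)")
        if self.decay <= 0 or self.half_saturation <= 0 or self.hill <= 0:
            raise ValidationError("decay, half_saturation and hill must be > 0")


# Node counts, edge counts and trajectory counts of the three bundled
# presets follow the small/medium/large shapes of the original contests.
PRESETS: dict[str, SimulationConfig] = {
    "size10": SimulationConfig(n_nodes=10, n_edges=11, n_trajectories=4),
    "size50": SimulationConfig(n_nodes=50, n_edges=62, n_trajectories=23),
    "size100": SimulationConfig(n_nodes=100, n_edges=125, n_trajectories=46),
}


def _gene_names(n: int) -> list[str]:
    return [f"G{i + 1}" for i in range(n)]


def generate_network(config: SimulationConfig) -> GoldNetwork:
    """Seeded random DAG with a minority of regulator (source) nodes.

    Nodes are laid out in a random topological order; edges run from a
    regulator to a strictly later node, so the construction cannot create
    cycles.  ``max_in_degree`` restricts target fan-in (e.g. 1 for
    single-regulator networks).
    """
    n, m = config.n_nodes, config.n_edges
    rng = np.random.default_rng(config.seed)
    names = _gene_names(n)
    order = rng.permutation(n)  # order[i] = topological position of node i
    n_regs = max(1, int(round(config.regulator_fraction * n)))
    # regulators are drawn among the topologically earliest nodes so that
    # they have room for out-edges
    by_pos = np.argsort(order)
    regulators = set(by_pos[: max(n_regs, 1)])

    candidates = [
        (int(a), int(b))
        for a in regulators
        for b in range(n)
        if order[a] < order[b]
    ]
    if config.max_in_degree is not None:
        cap = config.max_in_degree * (n - 1)
        feasible = min(len(candidates), cap)
    else:
        feasible = len(candidates)
    if m > feasible:
        raise ValidationError(
            f"{m} edges infeasible for an acyclic graph with these constraints "
            f"(at most {feasible})"
        )
    chosen: list[tuple[int, int]] = []
    in_deg = np.zeros(n, dtype=int)
    perm = rng.permutation(len(candidates))
    for i in perm:
        a, b = candidates[i]
        if config.max_in_degree is not None and in_deg[b] >= config.max_in_degree:
            continue
        chosen.append((a, b))
        in_deg[b] += 1
        if len(chosen) == m:
            break
    if len(chosen) < m:
        raise ValidationError(
            f"could not place {m} edges under max_in_degree={config.max_in_degree}"
        )
    edges = frozenset((names[a], names[b]) for a, b in chosen)
    return GoldNetwork(nodes=tuple(names), edges=edges)


@dataclass
class _Dynamics:
    """Materialized parameters for one (network, config) pair."""

    genes: list[str]
    weights: np.ndarray  # genes x genes; weights[j, i] = effect of j on i
    signs: np.ndarray  # +1 activation, -1 repression, 0 no edge
    basal: np.ndarray
    decay: float
    K: float
    hill: float
    topo_order: list[int] = field(default_factory=list)


def _build_dynamics(network: GoldNetwork, config: SimulationConfig) -> _Dynamics:
    rng = np.random.default_rng(config.seed + 1)
    genes = list(network.nodes)
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    weights = np.zeros((n, n))
    signs = np.zeros((n, n))
    for s, t in sorted(network.edges):
        w = rng.uniform(*config.weight_range)
        sign = 1.0 if rng.random() < config.activation_bias else -1.0
        weights[idx[s], idx[t]] = w
        signs[idx[s], idx[t]] = sign
    basal = rng.uniform(*config.basal_range, size=n)
    # topological order via repeated source removal
    remaining = set(range(n))
    incoming = {i: {j for j in range(n) if weights[j, i] != 0} for i in range(n)}
    topo: list[int] = []
    while remaining:
        ready = sorted(i for i in remaining if not (incoming[i] & remaining))
        if not ready:
            raise ValidationError("network contains a cycle")
        topo.extend(ready)
        remaining -= set(ready)
    return _Dynamics(
        genes=genes,
        weights=weights,
        signs=signs,
        basal=basal,
        decay=config.decay,
        K=config.half_saturation,
        hill=config.hill,
        topo_order=topo,
    )


def _saturation(dyn: _Dynamics, x: np.ndarray) -> np.ndarray:
    xh = np.maximum(x, 0.0) ** dyn.hill
    return xh / (dyn.K**dyn.hill + xh)


def _regulation(dyn: _Dynamics, x: np.ndarray) -> np.ndarray:
    """Summed regulatory input to each gene given expression vector x."""
    sat = _saturation(dyn, x)
    act = np.clip(dyn.signs, 0, 1) * dyn.weights
    rep = np.clip(-dyn.signs, 0, 1) * dyn.weights
    return act.T @ sat + rep.T @ (1.0 - sat)


def _steady_state(
    dyn: _Dynamics, clamped: dict[int, float] | None = None
) -> np.ndarray:
    """Exact equilibrium, solved gene by gene in topological order."""
    n = len(dyn.genes)
    x = np.zeros(n)
    clamped = clamped or {}
    for i in dyn.topo_order:
        if i in clamped:
            x[i] = clamped[i]
            continue
        sat = _saturation(dyn, x)
        inputs = 0.0
        for j in range(n):
            if dyn.weights[j, i] != 0:
                s = sat[j] if dyn.signs[j, i] > 0 else 1.0 - sat[j]
                inputs += dyn.weights[j, i] * s
        x[i] = (dyn.basal[i] + inputs) / dyn.decay
    return x


def _derivative(dyn: _Dynamics, x: np.ndarray, clamped: dict[int, float]) -> np.ndarray:
    dx = dyn.basal + _regulation(dyn, np.maximum(x, 0.0)) - dyn.decay * x
    for i in clamped:
        dx[i] = 0.0
    return dx


def steady_state_residual(network: GoldNetwork, config: SimulationConfig) -> float:
    """max |dx/dt| at the reported wild-type equilibrium (diagnostic)."""
    dyn = _build_dynamics(network, config)
    x = _steady_state(dyn)
    return float(np.max(np.abs(_derivative(dyn, x, {}))))


def simulate_dataset(
    network: GoldNetwork, config: SimulationConfig
) -> StrainExpressionMatrix:
    """Simulate the full strain panel plus trajectories for a network.

    Knockouts clamp the deleted gene to 0 and re-equilibrate; knockdowns
    clamp to ``knockdown_factor`` times the wild-type level.  Trajectories
    start from seeded random initial states and are integrated on the
    configured time grid.  Gaussian noise (sd ``noise_sd``) is added to
    every reported value.
    """
    from scipy.integrate import solve_ivp

    dyn = _build_dynamics(network, config)
    genes = dyn.genes
    n = len(genes)
    rng = np.random.default_rng(config.seed + 2)

    wt = _steady_state(dyn)
    ko = np.vstack([_steady_state(dyn, {i: 0.0}) for i in range(n)])
    kd = np.vstack(
        [
            _steady_state(dyn, {i: config.knockdown_factor * wt[i]})
            for i in range(n)
        ]
    )

    times = np.asarray(config.time_grid, dtype=float)
    trajectories = []
    hi = max(2.0 * float(wt.max()), 1.0)
    for _ in range(config.n_trajectories):
        x0 = rng.uniform(0.0, hi, size=n)
        sol = solve_ivp(
            lambda _, x: _derivative(dyn, x, {}),
            (times[0], times[-1]),
            x0,
            t_eval=times,
            method="LSODA",
            rtol=1e-8,
            atol=1e-10,
        )
        if not sol.success:
            raise ValidationError(f"trajectory integration failed: {sol.message}")
        trajectories.append(sol.y.T.copy())  # time x genes

    if config.noise_sd > 0:
        wt = wt + rng.normal(0, config.noise_sd, size=wt.shape)
        ko = ko + rng.normal(0, config.noise_sd, size=ko.shape)
        kd = kd + rng.normal(0, config.noise_sd, size=kd.shape)
        trajectories = [
            t + rng.normal(0, config.noise_sd, size=t.shape) for t in trajectories
        ]

    wildtype = pd.Series(wt, index=genes)
    knockouts = pd.DataFrame(ko, index=genes, columns=genes)
    knockdowns = pd.DataFrame(kd, index=genes, columns=genes)
    traj_frames = [
        pd.DataFrame(t, index=times, columns=genes) for t in trajectories
    ]
    return StrainExpressionMatrix(
        genes=tuple(genes),
        wildtype=wildtype,
        knockouts=knockouts,
        knockdowns=knockdowns,
        trajectories=traj_frames,
    )


def _write_profile_table(
    df: pd.DataFrame, path: str, index_header: str
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(index_header + "\t" + "\t".join(map(str, df.columns)) + "\n")
        for label, row in zip(df.index, df.to_numpy(dtype=float)):
            fh.write(str(label) + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def write_challenge_bundle(
    data: StrainExpressionMatrix, network: GoldNetwork, out_dir: str | os.PathLike
) -> list[str]:
    """Write wildtype.tsv, knockouts.tsv, knockdowns.tsv, trajectories/*.tsv
    and gold_standard.tsv; returns the paths written."""
    d = str(out_dir)
    os.makedirs(d, exist_ok=True)
    paths = []

    wt_df = data.wildtype.to_frame("WT").T
    p = os.path.join(d, "wildtype.tsv")
    _write_profile_table(wt_df, p, "strain")
    paths.append(p)

    p = os.path.join(d, "knockouts.tsv")
    _write_profile_table(data.knockouts, p, "strain")
    paths.append(p)

    if data.knockdowns is not None:
        p = os.path.join(d, "knockdowns.tsv")
        _write_profile_table(data.knockdowns, p, "strain")
        paths.append(p)

    if data.trajectories:
        tdir = os.path.join(d, "trajectories")
        os.makedirs(tdir, exist_ok=True)
        width = len(str(len(data.trajectories)))
        for i, traj in enumerate(data.trajectories, start=1):
            p = os.path.join(tdir, f"traj_{i:0{width}d}.tsv")
            _write_profile_table(traj, p, "time")
            paths.append(p)

    p = os.path.join(d, "gold_standard.tsv")
    write_gold_network(network, p)
    paths.append(p)
    return paths


def preset_config(name: str, seed: int = 0, noise_sd: float | None = None) -> SimulationConfig:
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    cfg = replace(PRESETS[name], seed=seed)
    if noise_sd is not None:
        cfg = replace(cfg, noise_sd=noise_sd)
    return cfg
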