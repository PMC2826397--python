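import numpy as np
import pandas as pd
import pytest

from dreambench.formats import (
    AssignmentTable,
    GoldNetwork,
    MeasurementTable,
    PredictionList,
    RankMatrix,
)
from dreambench.insilico_sim import SimulationConfig, generate_network, simulate_dataset


@pytest.fixture
def small_gold():
    """4-node network: chain A->B->C plus fan A->D (P=3, R=12)."""
    return GoldNetwork.from_edges(
        {("A", "B"), ("B", "C"), ("A", "D")}, nodes=["A", "B", "C", "D"]
    )


@pytest.fixture
def perfect_prediction(small_gold):
    positives = sorted(small_gold.edges)
    negatives = small_gold.negatives()
    return PredictionList(edges=tuple(positives + negatives))


def random_prediction(gold: GoldNetwork, rng: np.random.Generator) -> PredictionList:
    pairs = gold.all_pairs()
    order = rng.permutation(len(pairs))
    return PredictionList(edges=tuple(pairs[i] for i in order))


def random_rank_matrix(
    n_genes: int, n_times: int, rng: np.random.Generator
) -> RankMatrix:
    data = np.column_stack(
        [rng.permutation(n_genes) + 1 for _ in range(n_times)]
    )
    return RankMatrix(
        ranks=pd.DataFrame(
            data,
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"t{j}" for j in range(n_times)],
        )
    )


@pytest.fixture
def gold_ranks():
    rng = np.random.default_rng(7)
    return random_rank_matrix(50, 8, rng)


@pytest.fixture
def measurement_truth():
    """3x3 truth table with two masked (withheld) cells."""
    values = pd.DataFrame(
        [[1000.0, 50.0, 300.0], [800.0, 60.0, 200.0], [900.0, 40.0, 250.0]],
        index=["c1", "c2", "c3"],
        columns=["A", "B", "C"],
    )
    mask = pd.DataFrame(
        [[False, False, False], [True, False, False], [False, False, True]],
        index=values.index,
        columns=values.columns,
    )
    return MeasurementTable(values=values, mask=mask)


@pytest.fixture
def gold_assignment():
    return AssignmentTable(
        mapping={"x1": "kinase", "x2": "phosphatase", "x3": "protein", "x4": "phosphoprotein"},
        species=(
            "complex",
            "phospho-complex",
            "protein",
            "phosphoprotein",
            "kinase",
            "phosphatase",
            "activated-phosphatase",
        ),
        measurements=("x1", "x2", "x3", "x4"),
    )


@pytest.fixture(scope="session")
def sim_net_and_data():
    cfg = SimulationConfig(n_nodes=10, n_edges=11, seed=3, n_trajectories=2)
    net = generate_network(cfg)
    return net, simulate_dataset(net, cfg), cfg
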