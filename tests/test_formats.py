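import numpy as np
import pandas as pd
import pytest

from dreambench.formats import (
    AssignmentTable,
    FormatError,
    GoldNetwork,
    MeasurementTable,
    PredictionList,
    RankMatrix,
    ValidationError,
    read_assignment_table,
    read_gold_network,
    read_measurement_table,
    read_prediction_list,
    read_rank_matrix,
    write_assignment_table,
    write_gold_network,
    write_measurement_table,
    write_prediction_list,
    write_rank_matrix,
)

from conftest import random_rank_matrix


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


class TestPredictionList:
    def test_read_table_format(self, tmp_path):
        p = tmp_path / "pred.tsv"
        write_lines(
            p,
            ["G85\tG1\t1.00", "G85\tG10\t0.99", "G10\tG85\t0.73", "G99\tG52\t0.44"],
        )
        pred = read_prediction_list(p, universe=100)
        assert len(pred) == 4
        assert pred.edges[0] == ("G85", "G1")
        assert pred.confidences[0] == 1.0

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "pred.tsv"
        p.write_text("# just a comment\n")
        with pytest.raises(FormatError, match="no edges"):
            read_prediction_list(p, universe=10)

    def test_self_edge_errors(self, tmp_path):
        p = tmp_path / "pred.tsv"
        write_lines(p, ["G1\tG1\t0.5"])
        with pytest.raises(ValidationError, match="self-edge"):
            read_prediction_list(p, universe=10)

    def test_duplicate_pair_errors(self, tmp_path):
        p = tmp_path / "pred.tsv"
        write_lines(p, ["G1\tG2\t0.9", "G1\tG2\t0.8"])
        with pytest.raises(ValidationError, match="duplicate"):
            read_prediction_list(p, universe=10)

    def test_increasing_confidence_names_row(self, tmp_path):
        p = tmp_path / "pred.tsv"
        write_lines(p, ["G1\tG2\t0.5", "G2\tG1\t0.9"])
        with pytest.raises(ValidationError, match=":2"):
            read_prediction_list(p, universe=10)

    def test_order_is_rank_even_with_ties(self, tmp_path):
        p = tmp_path / "pred.tsv"
        write_lines(p, ["G2\tG1\t0.5", "G1\tG2\t0.5", "G3\tG1\t0.5"])
        pred = read_prediction_list(p, universe=5)
        assert pred.ranks()[("G2", "G1")] == 1
        assert pred.ranks()[("G3", "G1")] == 3

    def test_round_trip(self, tmp_path):
        pred = PredictionList(
            edges=(("a", "b"), ("b", "a"), ("a", "c")),
            confidences=(1.0, 0.25, 0.25),
        )
        p = tmp_path / "pred.tsv"
        write_prediction_list(pred, p)
        back = read_prediction_list(p, universe=3)
        assert back.edges == pred.edges
        assert back.confidences == pytest.approx(pred.confidences, abs=1e-12)

    def test_universe_membership(self, tmp_path, small_gold):
        p = tmp_path / "pred.tsv"
        write_lines(p, ["A\tZ"])
        with pytest.raises(ValidationError, match="universe"):
            read_prediction_list(p, universe=small_gold)

    def test_length_bound(self, tmp_path):
        p = tmp_path / "pred.tsv"
        write_lines(p, ["A\tB", "B\tA", "A\tC"])
        with pytest.raises(ValidationError, match="exceed"):
            read_prediction_list(p, universe=2)


class TestGoldNetwork:
    def test_counts(self, small_gold):
        assert small_gold.n_nodes == 4
        assert small_gold.n_edges == 3
        assert small_gold.n_pairs == 12
        assert small_gold.n_negatives == 9

    def test_round_trip(self, tmp_path, small_gold):
        p = tmp_path / "gold.tsv"
        write_gold_network(small_gold, p)
        back = read_gold_network(p)
        assert back.edges == small_gold.edges

    def test_explicit_negatives_round_trip(self, tmp_path, small_gold):
        p = tmp_path / "gold.tsv"
        write_gold_network(small_gold, p, explicit_negatives=True)
        back = read_gold_network(p)
        assert back.edges == small_gold.edges
        assert set(back.nodes) == set(small_gold.nodes)

    def test_conflicting_flags_error(self, tmp_path):
        p = tmp_path / "gold.tsv"
        write_lines(p, ["A\tB\t1", "A\tB\t0"])
        with pytest.raises(ValidationError, match="both"):
            read_gold_network(p)

    def test_self_edge_rejected(self):
        with pytest.raises(ValidationError, match="self-edge"):
            GoldNetwork.from_edges({("A", "A")})


class TestMeasurementTable:
    def test_na_cells_become_mask(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_lines(p, ["cond\tA\tB", "c1\t1.5\tNA", "c2\t2\t3"])
        t = read_measurement_table(p)
        assert t.mask.to_numpy().sum() == 1
        assert t.masked_cells() == [("c1", "B")]

    def test_all_numeric_empty_mask(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_lines(p, ["cond\tA\tB", "c1\t1\t2", "c2\t3\t4"])
        t = read_measurement_table(p)
        assert not t.mask.to_numpy().any()

    def test_negative_value_errors(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_lines(p, ["cond\tA", "c1\t-5"])
        with pytest.raises(ValidationError, match="negative"):
            read_measurement_table(p)

    def test_ragged_row_errors(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_lines(p, ["cond\tA\tB", "c1\t1"])
        with pytest.raises(FormatError, match="ragged"):
            read_measurement_table(p)

    @pytest.mark.parametrize("na", ["NA", "NaN", ""])
    def test_na_spellings(self, tmp_path, na):
        p = tmp_path / "m.tsv"
        write_lines(p, ["cond\tA\tB", f"c1\t1\t{na}"])
        t = read_measurement_table(p)
        assert t.mask.at["c1", "B"]

    def test_round_trip(self, tmp_path, measurement_truth):
        # masked cells are serialized as NA, so the mask round-trips and the
        # observed values round-trip exactly
        p = tmp_path / "m.tsv"
        write_measurement_table(measurement_truth, p)
        back = read_measurement_table(p)
        assert (back.mask.to_numpy() == measurement_truth.mask.to_numpy()).all()
        obs = ~measurement_truth.mask.to_numpy()
        assert np.allclose(
            back.values.to_numpy()[obs],
            measurement_truth.values.to_numpy()[obs],
            atol=1e-12,
        )
        assert np.isnan(back.values.to_numpy()[~obs]).all()


class TestRankMatrix:
    def test_valid_small(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_lines(p, ["gene\tt0\tt1", "g1\t1\t3", "g2\t2\t2", "g3\t3\t1"])
        m = read_rank_matrix(p)
        assert m.shape == (3, 2)

    def test_non_permutation_names_column(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_lines(p, ["gene\tt0", "g1\t1", "g2\t1", "g3\t3"])
        with pytest.raises(ValidationError, match="t0"):
            read_rank_matrix(p)

    def test_simulator_scale_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        m = random_rank_matrix(50, 8, rng)
        p = tmp_path / "r.tsv"
        write_rank_matrix(m, p)
        back = read_rank_matrix(p)
        assert back.shape == (50, 8)
        assert (back.ranks.to_numpy() == m.ranks.to_numpy()).all()
        assert back.genes == m.genes


class TestAssignmentTable:
    def test_round_trip(self, tmp_path, gold_assignment):
        p = tmp_path / "a.tsv"
        write_assignment_table(gold_assignment, p)
        back = read_assignment_table(
            p,
            species=gold_assignment.species,
            measurements=gold_assignment.measurements,
        )
        assert dict(back.mapping) == dict(gold_assignment.mapping)

    def test_injectivity_enforced(self):
        with pytest.raises(ValidationError, match="twice"):
            AssignmentTable(
                mapping={"x1": "kinase", "x2": "kinase"},
                species=("kinase", "phosphatase"),
                measurements=("x1", "x2"),
            )

    def test_every_measurement_assigned(self):
        with pytest.raises(ValidationError, match="not assigned"):
            AssignmentTable(
                mapping={"x1": "kinase"},
                species=("kinase", "phosphatase"),
                measurements=("x1", "x2"),
            )

    def test_more_measurements_than_species(self):
        with pytest.raises(ValidationError, match="more measurements"):
            AssignmentTable(
                mapping={"x1": "a", "x2": "b"},
                species=("a",),
                measurements=("x1", "x2"),
            )


def test_comment_lines_ignored(tmp_path):
    p = tmp_path / "pred.tsv"
    write_lines(p, ["# header comment", "A\tB", "# interior", "B\tA"])
    pred = read_prediction_list(p, universe=4)
    assert len(pred) == 2
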