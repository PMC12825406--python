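import numpy as np
import pandas as pd
import pytest

from buzznet.data_model import (
    FunctionalGroupMap,
    InteractionMatrix,
    SchemaError,
    ValidationError,
    VisitRecord,
    aggregate_counts,
    read_references,
    read_single_visits,
    read_tables,
    read_visits,
    write_references,
    write_single_visits,
    write_visits,
)


def test_visit_csv_round_trip(tmp_path):
    records = [
        VisitRecord("P1", "B1"),
        VisitRecord("P1", "B1", behaviour="no_buzzing", touched_reproductive=False),
        VisitRecord("P2", "B2", observation_block="blk1"),
    ]
    path = tmp_path / "visits.csv"
    write_visits(records, path)
    back = read_visits(path)
    assert len(back) == 3
    assert [(r.plant_species, r.bee_species) for r in back] == [
        ("P1", "B1"), ("P1", "B1"), ("P2", "B2"),
    ]
    assert back[1].behaviour == "no_buzzing"
    assert back[1].touched_reproductive is False


def test_negative_stigma_count_cites_row(tmp_path):
    path = tmp_path / "sv.csv"
    path.write_text(
        "plant_species,bee_species,anther_count_remaining,stigma_count\n"
        "P1,B1,10,5\nP1,B2,10,-1\n"
    )
    with pytest.raises(ValidationError, match="row 3"):
        read_single_visits(path)


def test_missing_mandatory_column_names_it(tmp_path):
    path = tmp_path / "visits.csv"
    path.write_text("plant_species,behavior\nP1,buzzing\n")
    with pytest.raises(SchemaError, match="bee_species"):
        read_tables(path, "visits")


def test_matrix_csv_round_trip_is_lossless(tmp_path):
    rng = np.random.default_rng(42)
    weights = rng.gamma(2.0, 5.0, (10, 33))
    weights[rng.random(weights.shape) < 0.5] = 0.0
    plants = [f"plant_{i}" for i in range(10)]
    bees = [f"bee_{j}" for j in range(33)]
    matrix = InteractionMatrix(weights, plants, bees, "FPN")
    path = tmp_path / "m.csv"
    matrix.to_csv(path)
    back = InteractionMatrix.read_csv(path, "FPN")
    assert back.row_labels == plants
    assert back.col_labels == bees
    # 12 significant printed digits
    np.testing.assert_allclose(back.weights, weights, rtol=1e-11)


def test_reference_round_trip_and_replicates(tmp_path):
    from buzznet.data_model import ReferenceFlower

    refs = [
        ReferenceFlower("P1", "unvisited_anther_reference", (10.0,) * 6),
        ReferenceFlower("P1", "unvisited_stigma_control", (3.0,)),
    ]
    path = tmp_path / "refs.csv"
    write_references(refs, path)
    back = read_references(path)
    assert back[0].replicate_counts == (10.0,) * 6
    assert back[1].replicate_counts == (3.0,)


@pytest.mark.parametrize(
    "records,expected",
    [
        (
            [("P1", "B1"), ("P1", "B1"), ("P2", "B2")],
            [[2, 0], [0, 1]],
        ),
    ],
)
def test_aggregate_counts_tally(records, expected):
    vn = aggregate_counts([VisitRecord(p, b) for p, b in records])
    assert vn.weights.tolist() == expected
    assert vn.currency == "VN"


def test_aggregate_keeps_zero_columns_for_mapped_species():
    vn = aggregate_counts(
        [VisitRecord("P1", "B1")], plant_labels=["P1"], bee_labels=["B1", "B2"]
    )
    assert vn.col_labels == ["B1", "B2"]
    assert vn.weights[0, 1] == 0


def test_aggregate_conserves_total(synth):
    assert synth["vn"].total == len(synth["tables"].visits)


def test_touch_filter_drops_non_contact_visits():
    records = [
        VisitRecord("P1", "B1", touched_reproductive=True),
        VisitRecord("P1", "B1", touched_reproductive=False),
    ]
    all_in = aggregate_counts(records)
    touched = aggregate_counts(records, ["P1"], ["B1"], require_touch=True)
    assert all_in.total == 2
    assert touched.total == 1


def test_matrix_invariants_rejected():
    with pytest.raises(ValidationError):
        InteractionMatrix(np.array([[-1.0]]), ["P"], ["B"], "VN")
    with pytest.raises(ValidationError):
        InteractionMatrix(np.ones((2, 2)), ["P", "P"], ["A", "B"], "VN")
    with pytest.raises(ValidationError):
        InteractionMatrix(np.ones((2, 2)), ["P", "Q"], ["A", "B"], "XX")


def test_group_map_rejects_unknown_group():
    with pytest.raises(ValidationError):
        FunctionalGroupMap.from_pairs([("B1", "weird_group")])


def test_drop_empty_reports_dropped_labels():
    m = InteractionMatrix(
        np.array([[1.0, 0.0], [0.0, 0.0]]), ["P1", "P2"], ["B1", "B2"], "VN"
    )
    sub, dropped = m.drop_empty()
    assert sub.shape == (1, 1)
    assert dropped == {"plants": ["P2"], "bees": ["B2"]}
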