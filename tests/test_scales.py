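import io

import numpy as np
import pandas as pd
import pytest

from symptomnet.scales import (
    CONSTRUCT_ORDER,
    InstrumentSchema,
    ItemSpec,
    LikertResponseTable,
    ResponseValidationError,
    SchemaError,
    flag_negative_perfectionism,
    load_responses,
    score_scales,
    study_schema,
)


def _csv_from(df: pd.DataFrame) -> io.StringIO:
    buf = io.StringIO()
    df.to_csv(buf, index_label="participant_id")
    buf.seek(0)
    return buf


@pytest.fixture(scope="module")
def schema():
    return study_schema()


@pytest.fixture()
def full_battery(schema):
    rng = np.random.default_rng(5)
    data = {}
    for it in schema.items:
        data[it.item_id] = rng.integers(it.minimum, it.maximum + 1, size=3)
    return pd.DataFrame(data, index=["p1", "p2", "p3"])


class TestSchema:
    def test_study_battery_has_98_items_across_five_subscales(self, schema):
        assert len(schema.items) == 98
        counts = {s: len(schema.items_of(s)) for s in schema.subscales}
        assert counts == {
            "Procrastination": 16,
            "CognitiveFlexibility": 20,
            "NegativePerfectionism": 20,
            "PositivePerfectionism": 20,
            "Rumination": 22,
        }

    def test_panps_subscale_bounds_are_20_to_100(self, schema):
        assert schema.score_bounds("NegativePerfectionism") == (20, 100)
        assert schema.score_bounds("PositivePerfectionism") == (20, 100)

    def test_schema_roundtrips_through_yaml(self, schema, tmp_path):
        path = tmp_path / "schema.yaml"
        schema.to_file(path)
        again = InstrumentSchema.from_file(path)
        assert again.item_ids == schema.item_ids
        assert [it.reverse for it in again.items] == [it.reverse for it in schema.items]


class TestLoadResponses:
    def test_shape_passthrough(self, schema, full_battery):
        table = load_responses(_csv_from(full_battery), schema)
        assert table.n_participants == 3
        assert table.n_items == 98

    def test_out_of_range_response_names_participant_and_item(self, schema, full_battery):
        full_battery.loc["p2", "PANPS_N03"] = 6  # 1-5 item
        with pytest.raises(ResponseValidationError, match="PANPS_N03.*p2"):
            load_responses(_csv_from(full_battery), schema)

    def test_empty_csv_is_rejected(self, schema, full_battery):
        with pytest.raises(ValueError, match="no participants"):
            load_responses(_csv_from(full_battery.iloc[:0]), schema)

    def test_unknown_item_is_a_schema_error(self, schema, full_battery):
        full_battery["BOGUS01"] = 1
        with pytest.raises(SchemaError, match="BOGUS01"):
            load_responses(_csv_from(full_battery), schema)

    def test_missing_values_are_flagged_not_dropped(self, schema, full_battery):
        full_battery.loc["p1", "RRS05"] = np.nan
        table = load_responses(_csv_from(full_battery), schema)
        assert table.n_participants == 3
        assert table.missing_mask.sum() == 1


class TestScoring:
    def test_bounds_of_sum_scores(self, schema):
        # all PANPS-negative at 1 -> 20; at 5 -> 100; RRS all 4 -> 88
        rows = {}
        for it in schema.items:
            rows[it.item_id] = [
                {"NegativePerfectionism": 1}.get(it.subscale, it.minimum),
                {"NegativePerfectionism": 5, "Rumination": 4}.get(it.subscale, it.minimum),
            ]
        table = load_responses(_csv_from(pd.DataFrame(rows, index=["lo", "hi"])), schema)
        scored = score_scales(table).scores
        assert scored.loc["lo", "NegativePerfectionism"] == 20
        assert scored.loc["hi", "NegativePerfectionism"] == 100
        assert scored.loc["hi", "Rumination"] == 88

    def test_construct_column_order_is_fixed(self, schema, full_battery):
        table = load_responses(_csv_from(full_battery), schema)
        assert tuple(score_scales(table).construct_names) == CONSTRUCT_ORDER

    def test_scoring_is_item_order_invariant(self, schema, full_battery):
        table = load_responses(_csv_from(full_battery), schema)
        shuffled = full_battery[list(np.random.default_rng(3).permutation(full_battery.columns))]
        table2 = load_responses(_csv_from(shuffled), schema)
        pd.testing.assert_frame_equal(score_scales(table).scores, score_scales(table2).scores)

    def test_listwise_equals_imputation_on_complete_data(self, schema, full_battery):
        table = load_responses(_csv_from(full_battery), schema)
        pd.testing.assert_frame_equal(
            score_scales(table, "listwise").scores, score_scales(table, "impute").scores
        )

    def test_listwise_marks_affected_construct_only(self, schema, full_battery):
        full_battery.loc["p1", "RRS05"] = np.nan
        table = load_responses(_csv_from(full_battery), schema)
        scored = score_scales(table, "listwise").scores
        assert np.isnan(scored.loc["p1", "Rumination"])
        assert scored.drop(columns="Rumination").notna().all().all()

    def test_person_mean_imputation_uses_answered_items(self):
        items = [ItemSpec(f"A{i}", "A", 1, 5) for i in range(1, 5)]
        schema = InstrumentSchema(items)
        table = LikertResponseTable(
            responses=np.array([[2.0, 4.0, np.nan, 3.0]]),
            item_ids=[it.item_id for it in items],
            item_scale_map={it.item_id: "A" for it in items},
            category_bounds={it.item_id: (1, 5) for it in items},
            participant_ids=["p1"],
        )
        scored = score_scales(table, "impute", construct_order=("A",)).scores
        assert scored.loc["p1", "A"] == pytest.approx(3.0 * 4)  # person mean 3 x 4 items

    def test_imputation_with_all_items_missing_errors(self):
        items = [ItemSpec(f"A{i}", "A", 1, 5) for i in range(1, 3)]
        schema = InstrumentSchema(items)
        table = LikertResponseTable(
            responses=np.array([[np.nan, np.nan]]),
            item_ids=[it.item_id for it in items],
            item_scale_map={it.item_id: "A" for it in items},
            category_bounds={it.item_id: (1, 5) for it in items},
            participant_ids=["p1"],
        )
        with pytest.raises(ValueError, match="all A items missing"):
            score_scales(table, "impute", construct_order=("A",))

    def test_reverse_keyed_items_flip_within_bounds(self):
        items = [ItemSpec("A1", "A", 1, 5, reverse=True), ItemSpec("A2", "A", 1, 5)]
        schema = InstrumentSchema(items)
        table = LikertResponseTable(
            responses=np.array([[5.0, 2.0]]),
            item_ids=["A1", "A2"],
            item_scale_map={"A1": "A", "A2": "A"},
            category_bounds={"A1": (1, 5), "A2": (1, 5)},
            participant_ids=["p1"],
        )
        scored = score_scales(table, schema=schema, construct_order=("A",)).scores
        assert scored.loc["p1", "A"] == 1 + 2  # 5 reversed to 1


class TestNegativePerfectionismFlag:
    @pytest.mark.parametrize(
        "score,expected", [(69, True), (68, False), (100, True), (20, False)]
    )
    def test_cutoff_at_69(self, score, expected):
        assert flag_negative_perfectionism(score) is expected

    def test_out_of_bounds_score_errors(self):
        with pytest.raises(ValueError):
            flag_negative_perfectionism(101)
        with pytest.raises(ValueError):
            flag_negative_perfectionism(19)
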