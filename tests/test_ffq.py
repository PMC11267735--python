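"""Questionnaire processing: frequency mapping, quality levels, portions."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ffqval as fv
from ffqval.errors import CoverageError, RecordValidationError


class TestFrequenciesToDaily:
    def test_level_endpoints(self, schema, mapping, make_record):
        never = fv.frequencies_to_daily(make_record(level_code=1), mapping, schema)
        top = fv.frequencies_to_daily(make_record(level_code=9), mapping, schema)
        assert (never == 0.0).all()
        assert (top == 4.0).all()

    def test_weekly_midpoint(self, schema, mapping, make_record):
        # "2-3 times a week" -> 2.5/7 intakes/day
        out = fv.frequencies_to_daily(make_record(level_code=5), mapping, schema)
        assert out.iloc[0] == pytest.approx(2.5 / 7)

    def test_missing_items_imputed_as_zero_and_flagged(self, schema, mapping, make_record):
        rec = make_record(level_code=6, missing_items=schema.item_ids[:3])
        out = fv.frequencies_to_daily(rec, mapping, schema)
        assert (out.iloc[:3] == 0.0).all()
        assert out.attrs["imputed_items"] == schema.item_ids[:3]

    def test_out_of_scale_level_names_item(self, schema, mapping, make_record):
        rec = make_record()
        bad = dict(rec.responses)
        bad[schema.item_ids[5]] = 10
        rec = fv.FFQRecord(rec.participant_id, bad, rec.portion_indications)
        with pytest.raises(RecordValidationError, match=schema.item_ids[5]):
            fv.frequencies_to_daily(rec, mapping, schema)

    def test_cohort_version_matches_record_version(self, schema, mapping, make_record):
        recs = [make_record(level_code=c, pid=f"P{c}") for c in (1, 4, 7, 9)]
        wide = pd.DataFrame(
            [{**r.responses, **{f"portion_{k}": v for k, v in r.portion_indications.items()}}
             for r in recs],
            index=[r.participant_id for r in recs],
        )
        cohort = fv.cohort_frequencies_to_daily(wide, mapping, schema)
        for r in recs:
            single = fv.frequencies_to_daily(r, mapping, schema)
            assert np.allclose(cohort.loc[r.participant_id].to_numpy(), single.to_numpy())

    @settings(max_examples=30, deadline=None)
    @given(a=st.lists(st.integers(1, 9), min_size=108, max_size=108),
           b=st.lists(st.integers(1, 9), min_size=108, max_size=108))
    def test_monotone_in_levels(self, schema, mapping, a, b):
        """A record dominating another level-wise yields a dominating vector."""
        hi = [max(x, y) for x, y in zip(a, b)]
        rec_a = fv.FFQRecord("A", dict(zip(schema.item_ids, a)))
        rec_hi = fv.FFQRecord("H", dict(zip(schema.item_ids, hi)))
        fa = fv.frequencies_to_daily(rec_a, mapping, schema)
        fh = fv.frequencies_to_daily(rec_hi, mapping, schema)
        assert (fh >= fa).all()


class TestExcludeLevel:
    def test_complete_record_is_level_0(self, schema, make_record):
        qa = fv.assign_exclude_level(make_record(), schema)
        assert (qa.exclude_level, qa.portion_complete) == (0, True)

    def test_ten_percent_missing_is_level_1(self, schema, make_record):
        # 11 of 108 = 10.19% >= 10%
        rec = make_record(missing_items=schema.item_ids[:11])
        assert fv.assign_exclude_level(rec, schema).exclude_level == 1
        # 10 of 108 = 9.26% < 10%
        rec = make_record(missing_items=schema.item_ids[:10])
        assert fv.assign_exclude_level(rec, schema).exclude_level == 0

    def test_missing_portion_indication_is_level_2(self, schema, make_record):
        rec = make_record(portion_missing=("protein",))
        qa = fv.assign_exclude_level(rec, schema)
        assert (qa.exclude_level, qa.missing_fraction) == (2, 0.0)

    def test_partition_and_order_invariance(self, schema, make_record):
        """Every record gets exactly one level, independent of item order."""
        rec = make_record(missing_items=schema.item_ids[::7])
        qa = fv.assign_exclude_level(rec, schema)
        shuffled = dict(reversed(list(rec.responses.items())))
        rec2 = fv.FFQRecord(rec.participant_id, shuffled, rec.portion_indications)
        assert fv.assign_exclude_level(rec2, schema).exclude_level == qa.exclude_level
        assert qa.exclude_level in (0, 1, 2)

    def test_cohort_levels_match_record_levels(self, schema, make_record):
        recs = [
            make_record(pid="A"),
            make_record(pid="B", missing_items=schema.item_ids[:20]),
            make_record(pid="C", portion_missing=("starch",)),
        ]
        wide = pd.DataFrame(
            [{**{k: (np.nan if v is None else v) for k, v in r.responses.items()},
              **{f"portion_{k}": (np.nan if v is None else v)
                 for k, v in r.portion_indications.items()}}
             for r in recs],
            index=[r.participant_id for r in recs],
        )
        out = fv.cohort_exclude_levels(wide, schema)
        assert list(out["exclude_level"]) == [0, 1, 2]


class TestPortionAssignment:
    def _profile(self, sex="female", age=47):
        return fv.ParticipantProfile(
            id="P1", sex=sex, age=age, height_cm=165, weight_kg=65
        )

    def test_photo_levels_give_increasing_grams(self, schema, portions, make_record):
        veg_item = next(it for it in schema.items if it.portion_class == "vegetable")
        grams = []
        for lvl in (1, 4):
            rec = make_record()
            rec = fv.FFQRecord(
                rec.participant_id, rec.responses,
                {"starch": 2, "protein": 2, "vegetable": lvl},
            )
            out = fv.assign_portion_sizes(rec, portions, self._profile(), schema)
            grams.append(out[veg_item.id])
        assert grams[1] > grams[0]

    def test_fixed_natural_ignores_photo_indication(self, schema, portions, make_record):
        egg = schema.item("egg_boiled_fried")
        for lvl in (1, 4):
            rec = make_record()
            rec = fv.FFQRecord(
                rec.participant_id, rec.responses,
                {"starch": lvl, "protein": lvl, "vegetable": lvl},
            )
            out = fv.assign_portion_sizes(rec, portions, self._profile(), schema)
            assert out[egg.id] == egg.natural_unit_g

    def test_none_class_uses_median_table(self, schema, portions, make_record):
        item = next(it for it in schema.items if it.portion_class == "none")
        out = fv.assign_portion_sizes(
            make_record(), portions, self._profile("female", 47), schema
        )
        assert out[item.id] == pytest.approx(
            portions.median_portion("female", 47, item)
        )

    def test_missing_indication_blocks_unless_imputing(self, schema, portions, make_record):
        rec = make_record(portion_missing=("starch",))
        with pytest.raises(CoverageError, match="starch"):
            fv.assign_portion_sizes(rec, portions, self._profile(), schema)
        out = fv.assign_portion_sizes(
            rec, portions, self._profile(), schema, default_impute=True
        )
        assert out.attrs["imputed_classes"] == ["starch"]
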