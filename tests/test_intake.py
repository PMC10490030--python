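"""The intake engine: arithmetic, α-TE conversion, oracle equivalence."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import vitecal as v
from vitecal.isoforms import COMPONENTS, ISOFORMS


def brute_force_intake(response, instrument, db):
    """Independent triple-loop re-summation over (item, member, isoform)."""
    totals = {c: 0.0 for c in COMPONENTS}
    for item in instrument.items:
        portions_per_day = response.servings_per_week.get(item.item_id, 0.0) / 7.0
        members = item.member_food_ids
        for c in COMPONENTS:
            mean_content = sum(getattr(db[fid].content_per_100g, c) for fid in members) / len(members)
            totals[c] += portions_per_day * mean_content * item.portion_g / 100.0
    return totals


class TestScalarSteps:
    @pytest.mark.parametrize("weekly, daily", [(7.0, 1.0), (3.5, 0.5), (0.0, 0.0)])
    def test_daily_portions(self, weekly, daily):
        assert v.daily_portions(weekly) == daily

    def test_daily_portions_rejects_negative(self):
        with pytest.raises(v.DomainError):
            v.daily_portions(-1.0)

    def test_item_daily_intake_scales_per_portion_content(self):
        per_portion = v.IsoformVector(alpha_t=7.5)
        assert v.item_daily_intake(0.5, per_portion).alpha_t == pytest.approx(3.75)
        assert v.item_daily_intake(0.0, per_portion) == v.IsoformVector.zero()
        assert v.item_daily_intake(2.0, per_portion).isclose(per_portion + per_portion)


class TestAlphaTE:
    def test_pure_alpha_tocopherol_is_identity(self):
        assert v.alpha_te(v.IsoformVector(alpha_t=1.0)) == pytest.approx(1.0)

    def test_one_mg_of_every_isoform_sums_the_coefficients(self):
        vec = v.IsoformVector(**{iso: 1.0 for iso in ISOFORMS})
        assert v.alpha_te(vec) == pytest.approx(1.87)  # 1 + 0.4 + 0.1 + 0.01 + 0.3 + 0.05 + 0.01

    def test_delta_tocotrienol_carries_no_weight_by_default(self):
        assert v.alpha_te(v.IsoformVector(delta_t3=5.0)) == 0.0

    def test_delta_tocotrienol_weight_is_configurable(self):
        w = v.ConversionWeights().with_overrides({"delta_t3": 0.01})
        assert v.alpha_te(v.IsoformVector(delta_t3=5.0), w) == pytest.approx(0.05)

    def test_added_vitamin_e_folds_as_alpha_by_default(self):
        vec = v.IsoformVector(added_vit_e=2.0)
        assert v.alpha_te(vec) == pytest.approx(2.0)
        no_fold = v.ConversionWeights(fold_added_as_alpha=False)
        assert v.alpha_te(vec, no_fold) == 0.0

    def test_negative_weight_rejected(self):
        with pytest.raises(v.ValidationError):
            v.ConversionWeights(w_gamma_t=-0.1)

    @given(st.builds(v.IsoformVector, **{c: st.floats(0, 100, allow_nan=False) for c in COMPONENTS}))
    def test_alpha_te_at_least_alpha_tocopherol(self, vec):
        assert v.alpha_te(vec) >= vec.alpha_t


class TestRespondentIntake:
    def test_all_zero_response_gives_zero_result(self, tiny_instrument, tiny_db):
        resp = v.FFQResponse("r0", "female",
                             {i: 0.0 for i in tiny_instrument.item_ids()})
        res = v.respondent_intake(resp, tiny_instrument, tiny_db)
        assert res.daily == v.IsoformVector.zero()
        assert res.alpha_te == 0.0

    def test_chained_arithmetic_single_food(self, tiny_db):
        # 7 servings/week of one 30 g portion of a 25 mg/100 g food -> 7.5 mg/day
        instrument = v.FFQInstrument(items=(
            v.FFQItem("almonds", "Almonds", v.FoodGroup.NUTS, 30.0, member_food_ids=("almonds",)),
        ))
        resp = v.FFQResponse("r0", "male", {"almonds": 7.0})
        res = v.respondent_intake(resp, instrument, tiny_db)
        assert res.daily.alpha_t == pytest.approx(7.5)
        assert res.sum_tocopherols == pytest.approx(7.5 + 0.3)  # gamma: mean 1.0 * 30/100

    def test_matches_brute_force_oracle(self, instrument, fixture_db, small_cohort):
        responses, ffq_table, _ = small_cohort
        for resp in responses[:10]:
            res = v.respondent_intake(resp, instrument, fixture_db)
            oracle = brute_force_intake(resp, instrument, fixture_db)
            for c in COMPONENTS:
                assert getattr(res.daily, c) == pytest.approx(oracle[c], rel=1e-12, abs=1e-15)

    def test_by_group_partitions_the_daily_total(self, instrument, fixture_db, small_cohort):
        responses, _, _ = small_cohort
        res = v.respondent_intake(responses[0], instrument, fixture_db)
        regrouped = v.IsoformVector.zero()
        for vec in res.by_group.values():
            regrouped = regrouped + vec
        assert regrouped.isclose(res.daily, rel=1e-9)

    def test_derived_sums_consistent(self, instrument, fixture_db, small_cohort):
        responses, _, _ = small_cohort
        res = v.respondent_intake(responses[1], instrument, fixture_db)
        assert res.sum_tocopherols == pytest.approx(res.daily.sum_tocopherols)
        assert res.sum_tocotrienols == pytest.approx(res.daily.sum_tocotrienols)
        assert res.total_isoforms == pytest.approx(res.sum_tocopherols + res.sum_tocotrienols)

    @given(st.floats(min_value=0.0, max_value=20.0, allow_nan=False))
    def test_pipeline_linear_in_servings(self, instrument, fixture_db, c):
        base = {iid: (i % 5) * 0.5 for i, iid in enumerate(instrument.item_ids())}
        scaled = {iid: c * s for iid, s in base.items()}
        r1 = v.respondent_intake(v.FFQResponse("a", "female", base), instrument, fixture_db)
        r2 = v.respondent_intake(v.FFQResponse("a", "female", scaled), instrument, fixture_db)
        assert r2.daily.isclose(c * r1.daily, rel=1e-9, abs_=1e-12)
        assert r2.alpha_te == pytest.approx(c * r1.alpha_te, rel=1e-9, abs=1e-12)

    def test_lookup_failure_carries_respondent_context(self, tiny_instrument):
        empty_db = v.CompositionDB()
        resp = v.FFQResponse("r9", "male", {i: 1.0 for i in tiny_instrument.item_ids()})
        with pytest.raises(v.FoodLookupError, match="r9"):
            v.respondent_intake(resp, tiny_instrument, empty_db)


class TestIntakeTableIO:
    def test_round_trip(self, tmp_path, small_cohort):
        _, ffq_table, _ = small_cohort
        path = v.write_intake_table(ffq_table, tmp_path / "intake.csv")
        reloaded = v.read_intake_table(path)
        assert list(reloaded.columns) == list(ffq_table.columns)
        for c in COMPONENTS:
            assert reloaded[c].tolist() == pytest.approx(ffq_table[c].tolist())

    def test_rounding_only_in_writer(self, tmp_path, small_cohort):
        _, ffq_table, _ = small_cohort
        path = v.write_intake_table(ffq_table, tmp_path / "intake.csv", decimals=1)
        reloaded = v.read_intake_table(path)
        assert all(
            math.isclose(x, round(x, 1), abs_tol=1e-12) for x in reloaded["alpha_t"]
        )
        # in-memory table keeps full precision
        assert not all(
            math.isclose(x, round(x, 1), abs_tol=1e-12) for x in ffq_table["alpha_t"]
        )

    def test_missing_column_rejected(self, tmp_path, small_cohort):
        _, ffq_table, _ = small_cohort
        bad = ffq_table.drop(columns=["alpha_te"])
        bad.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(v.SchemaError, match="alpha_te"):
            v.read_intake_table(tmp_path / "bad.csv")
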