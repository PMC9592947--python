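"""Portion conversion, recipe densities, and daily intake aggregation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dietval import (
    ConsumptionRecord,
    NSRDetail,
    Quantity,
    daily_intakes,
    food_group_energy_shares,
    item_nutrients,
    portion_to_grams,
    read_records_csv,
    resolve_recipe_density,
    write_records_csv,
)
from dietval.intake import IntakeError


def rec(rid, source, code, grams, arm="CAPI", item_type="food", **kw):
    return ConsumptionRecord(
        respondent_id=rid,
        arm=arm,
        source=source,
        item_type=item_type,
        code=code,
        quantity=Quantity(grams=grams),
        **kw,
    )


class TestPortionToGrams:
    def test_direct_identity(self, small_bundle):
        assert portion_to_grams(Quantity(grams=250.0), small_bundle.portion_factors) == 250.0

    def test_standard_unit_fraction(self, small_bundle):
        q = Quantity(
            psem_code="standard_unit", unit_code="bottle", size_label="small", n_units=0.5
        )
        assert portion_to_grams(q, small_bundle.portion_factors) == 150.0

    def test_photo_multiple_units(self, small_bundle):
        q = Quantity(psem_code="photo", unit_code="P12", size_label="shown", n_units=2)
        assert portion_to_grams(q, small_bundle.portion_factors) == 170.0

    def test_missing_factor_names_triple(self, small_bundle):
        q = Quantity(psem_code="photo", unit_code="P99", size_label="shown", n_units=1)
        with pytest.raises(IntakeError, match="P99"):
            portion_to_grams(q, small_bundle.portion_factors)

    def test_quantity_forms_are_exclusive(self):
        with pytest.raises(IntakeError):
            Quantity(grams=100.0, psem_code="photo", unit_code="P12",
                     size_label="shown", n_units=1)
        with pytest.raises(IntakeError):
            Quantity()


class TestRecipeDensity:
    def test_rice_oil_dish(self, small_bundle):
        # 200 g rice (360 kcal/100 g) + 100 g oil (884 kcal/100 g) in 600 g
        # of prepared dish: (720 + 884) / 6 = 267.33 kcal / 100 g
        density = resolve_recipe_density(small_bundle.recipes["RC01"], small_bundle.foods)
        assert density.energy_kcal == pytest.approx(1604.0 / 6.0)
        assert density["fat_g"] == pytest.approx(100.0 / 6.0)

    def test_single_ingredient_identity(self, small_bundle):
        nsr = NSRDetail(ingredients=(("RICE", 100.0),), total_prepared_g=100.0)
        density = resolve_recipe_density(nsr, small_bundle.foods)
        assert density == small_bundle.foods["RICE"].composition

    def test_inverse_proportional_to_prepared_weight(self, small_bundle):
        base = resolve_recipe_density(small_bundle.recipes["RC01"], small_bundle.foods)
        halved = NSRDetail(
            ingredients=small_bundle.recipes["RC01"].ingredients, total_prepared_g=300.0
        )
        density = resolve_recipe_density(halved, small_bundle.foods)
        np.testing.assert_allclose(density.values, 2.0 * base.values)

    def test_missing_propagates_with_zero_contribution(self, small_bundle, rng):
        from conftest import make_food

        small_bundle.foods["MYST"] = make_food("MYST", energy_kcal=100, vitc_mg=None)
        nsr = NSRDetail(
            ingredients=(("MYST", 50.0), ("LEAF", 50.0)), total_prepared_g=100.0
        )
        density = resolve_recipe_density(nsr, small_bundle.foods)
        assert density.is_missing("vitc_mg")
        assert density["vitc_mg"] == pytest.approx(12.5)  # LEAF only

    def test_nutrient_conservation_random_recipes(self, small_bundle, rng):
        # density x prepared/100 equals the plain sum over ingredients
        codes = list(small_bundle.foods)
        for _ in range(50):
            n_ing = rng.integers(1, 4)
            ingredients = tuple(
                (codes[rng.integers(len(codes))], float(rng.uniform(5, 500)))
                for _ in range(n_ing)
            )
            prepared = float(rng.uniform(50, 2000))
            nsr = NSRDetail(ingredients=ingredients, total_prepared_g=prepared)
            density = resolve_recipe_density(nsr, small_bundle.foods)
            expected = np.zeros(10)
            for code, grams in ingredients:
                expected += small_bundle.foods[code].composition.values * grams / 100.0
            np.testing.assert_allclose(
                density.values * prepared / 100.0, expected, rtol=1e-12
            )


class TestItemNutrients:
    def test_recipe_portion(self, small_bundle):
        record = rec("R1", "WFR", "RC01", 150.0, item_type="standard_recipe")
        grams, nut, group = item_nutrients(record, small_bundle)
        assert grams == 150.0
        assert nut.energy_kcal == pytest.approx(401.0)
        # oil contributes 884 kcal vs rice's 720, so the dish classes as fats/oils
        assert group == "FO"

    def test_100g_equals_composition(self, small_bundle):
        _, nut, _ = item_nutrients(rec("R1", "WFR", "LEAF", 100.0), small_bundle)
        assert nut == small_bundle.foods["LEAF"].composition

    def test_missing_value_contributes_zero_with_flag(self, small_bundle):
        from conftest import make_food

        small_bundle.foods["MYST"] = make_food("MYST", energy_kcal=100, vitc_mg=None)
        _, nut, _ = item_nutrients(rec("R1", "WFR", "MYST", 200.0), small_bundle)
        assert nut["vitc_mg"] == 0.0
        assert nut.is_missing("vitc_mg")

    def test_resolution_error_names_record(self, small_bundle):
        with pytest.raises(IntakeError, match="R1.*NOPE"):
            item_nutrients(rec("R1", "WFR", "NOPE", 100.0), small_bundle)


class TestDailyIntakes:
    def test_additivity(self, small_bundle):
        records = [
            rec("R1", "WFR", "LEAF", 1000.0),  # 300 kcal
            rec("R1", "WFR", "RICE", 27.7778),  # ~100 kcal
        ]
        table = daily_intakes(records, small_bundle)
        row = table.nutrients.loc[("R1", "WFR")]
        assert row["item_count"] == 2
        assert row["energy_kcal"] == pytest.approx(400.0, rel=1e-4)
        assert row["gram_total"] == pytest.approx(1027.7778)

    def test_no_records_no_row(self, small_bundle):
        table = daily_intakes([rec("R1", "WFR", "RICE", 100.0)], small_bundle)
        assert ("R2", "WFR") not in table.nutrients.index

    def test_brute_force_oracle(self, small_bundle, rng):
        codes = ["RICE", "OIL", "LEAF"]
        records = []
        for i, arm in enumerate(["CAPI", "PAPI", "CAPI"]):
            for source in ("WFR", "R24"):
                for _ in range(2):
                    records.append(
                        rec(
                            f"R{i}",
                            source,
                            codes[rng.integers(3)],
                            float(rng.uniform(10, 400)),
                            arm=arm,
                        )
                    )
        table = daily_intakes(records, small_bundle)
        assert len(table.nutrients) == 6
        # independent per-record summation with plain dict arithmetic
        expected: dict = {}
        for r in records:
            comp = small_bundle.foods[r.code].composition
            key = (r.respondent_id, r.source)
            slot = expected.setdefault(key, {"g": 0.0, "kcal": 0.0, "n": 0})
            slot["g"] += r.quantity.grams
            slot["kcal"] += comp.energy_kcal * r.quantity.grams / 100.0
            slot["n"] += 1
        for key, slot in expected.items():
            row = table.nutrients.loc[key]
            assert row["gram_total"] == pytest.approx(slot["g"])
            assert row["energy_kcal"] == pytest.approx(slot["kcal"])
            assert row["item_count"] == slot["n"]

    def test_both_arms_rejected(self, small_bundle):
        records = [
            rec("R1", "WFR", "RICE", 100.0, arm="CAPI"),
            rec("R1", "R24", "RICE", 100.0, arm="PAPI"),
        ]
        with pytest.raises(IntakeError, match="both arms"):
            daily_intakes(records, small_bundle)

    def test_group_energy_partitions_total(self, small_bundle):
        records = [
            rec("R1", "WFR", "RICE", 100.0),
            rec("R1", "WFR", "OIL", 10.0),
            rec("R1", "WFR", "LEAF", 200.0),
        ]
        table = daily_intakes(records, small_bundle)
        assert table.group_energy.loc[("R1", "WFR")].sum() == pytest.approx(
            table.nutrients.loc[("R1", "WFR"), "energy_kcal"]
        )

    @given(factor=st.floats(min_value=0.1, max_value=10.0))
    def test_scale_equivariance(self, factor):
        # doubling every gram doubles totals and leaves shares unchanged
        from conftest import make_food
        from dietval import ReferenceBundle

        bundle = ReferenceBundle()
        bundle.group_map = {"CE": "c", "VE": "v"}
        bundle.foods["A"] = make_food("A", "CE", energy_kcal=300.0)
        bundle.foods["B"] = make_food("B", "VE", energy_kcal=100.0)
        base = [rec("R1", "WFR", "A", 100.0), rec("R1", "WFR", "B", 100.0)]
        scaled = [
            rec("R1", "WFR", r.code, r.quantity.grams * factor) for r in base
        ]
        t1 = daily_intakes(base, bundle)
        t2 = daily_intakes(scaled, bundle)
        row1, row2 = t1.nutrients.iloc[0], t2.nutrients.iloc[0]
        assert row2["gram_total"] == pytest.approx(factor * row1["gram_total"])
        assert row2["energy_kcal"] == pytest.approx(factor * row1["energy_kcal"])
        s1 = food_group_energy_shares(t1.group_energy.iloc[0])
        s2 = food_group_energy_shares(t2.group_energy.iloc[0])
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy())


class TestGroupShares:
    def test_simple_split(self, small_bundle):
        records = [rec("R1", "WFR", "RICE", 83.3333), rec("R1", "WFR", "LEAF", 333.3333)]
        table = daily_intakes(records, small_bundle)
        shares = food_group_energy_shares(table.group_energy.loc[("R1", "WFR")])
        assert shares["CE"] == pytest.approx(75.0, rel=1e-4)
        assert shares["VE"] == pytest.approx(25.0, rel=1e-4)
        assert shares.sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_group_day(self, small_bundle):
        table = daily_intakes([rec("R1", "WFR", "RICE", 100.0)], small_bundle)
        shares = food_group_energy_shares(table.group_energy.loc[("R1", "WFR")])
        assert shares["CE"] == 100.0

    def test_zero_energy_day_raises(self, small_bundle):
        import pandas as pd

        with pytest.raises(IntakeError, match="zero-energy"):
            food_group_energy_shares(pd.Series({"CE": 0.0, "VE": 0.0}))


class TestRecordsCSV:
    def test_round_trip_with_nsr(self, small_bundle, tmp_path):
        records = [
            rec("R1", "WFR", "RICE", 120.0),
            ConsumptionRecord(
                "R1",
                "CAPI",
                "R24",
                "food",
                "OIL",
                Quantity(
                    psem_code="standard_unit",
                    unit_code="bottle",
                    size_label="small",
                    n_units=0.25,
                ),
            ),
            ConsumptionRecord(
                "R1",
                "CAPI",
                "R24",
                "nonstandard_recipe",
                "NSR1",
                Quantity(grams=150.0),
                nsr_detail=NSRDetail(
                    ingredients=(("RICE", 100.0), ("OIL", 20.0)),
                    total_prepared_g=200.0,
                ),
            ),
        ]
        path = tmp_path / "records.csv"
        write_records_csv(records, path)
        again = read_records_csv(path)
        assert again == records
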