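"""Convert consumption records into daily nutrient intakes and group shares.

One respondent's day: plain foods quantified by direct weight or by a
portion size estimation method (a standard unit), plus a mixed dish whose
nutrient density comes from its recipe's ingredients and prepared weight.
"""

from dietval import (
    ConsumptionRecord,
    Quantity,
    SimConfig,
    daily_intakes,
    food_group_energy_shares,
    generate_reference_bundle,
    resolve_recipe_density,
)

bundle = generate_reference_bundle(SimConfig(menu_size=20, seed=1))
recipe_code = next(iter(bundle.recipes))
recipe = bundle.recipes[recipe_code]
density = resolve_recipe_density(recipe, bundle.foods)
print(f"recipe {recipe_code}: {len(recipe.ingredients)} ingredients, "
      f"{recipe.total_prepared_g:.0f} g prepared, "
      f"{density.energy_kcal:.1f} kcal/100 g")

records = [
    ConsumptionRecord("R1", "CAPI", "WFR", "food", "F001", Quantity(grams=250.0)),
    ConsumptionRecord(
        "R1", "CAPI", "WFR", "food", "F002",
        # half a small bowl: 150 g/unit x 0.5
        Quantity(psem_code="standard_unit", unit_code="bowl",
                 size_label="small", n_units=0.5),
    ),
    ConsumptionRecord("R1", "CAPI", "WFR", "standard_recipe", recipe_code,
                      Quantity(grams=300.0)),
]
intakes = daily_intakes(records, bundle)
row = intakes.nutrients.loc[("R1", "WFR")]
print(f"\nday total: {row['gram_total']:.0f} g over {row['item_count']} items, "
      f"{row['energy_kcal']:.0f} kcal, protein {row['protein_g']:.1f} g, "
      f"iron {row['fe_mg']:.1f} mg")

shares = food_group_energy_shares(intakes.group_energy.loc[("R1", "WFR")])
print("\nenergy by GIFT food group (%):")
print(shares[shares > 0].round(1).to_string())
print("shares sum to", round(shares.sum(), 9))
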