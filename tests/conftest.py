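import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dietval import (
    FoodEntry,
    NutrientVector,
    PortionFactor,
    ReferenceBundle,
    StandardRecipe,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_food(code, group="CE", name=None, **amounts):
    """A FoodEntry with given per-100 g amounts; unlisted nutrients are 0."""
    base = {
        "energy_kcal": 0.0,
        "fat_g": 0.0,
        "protein_g": 0.0,
        "carb_g": 0.0,
        "fibre_g": 0.0,
        "vita_mcg_rae": 0.0,
        "vitc_mg": 0.0,
        "ca_mg": 0.0,
        "fe_mg": 0.0,
        "zn_mg": 0.0,
    }
    base.update(amounts)
    return FoodEntry(
        food_code=code,
        name=name or code,
        gift_group=group,
        composition=NutrientVector.from_mapping(base),
    )


@pytest.fixture
def small_bundle():
    """Three foods (rice, oil, leafy veg) and one rice+oil recipe."""
    bundle = ReferenceBundle()
    bundle.group_map = {
        "CE": "Cereals and their products",
        "FO": "Fats and oils",
        "VE": "Vegetables and their products",
    }
    bundle.foods["RICE"] = make_food(
        "RICE", "CE", energy_kcal=360.0, carb_g=80.0, protein_g=7.0, fe_mg=1.2
    )
    bundle.foods["OIL"] = make_food("OIL", "FO", energy_kcal=884.0, fat_g=100.0)
    bundle.foods["LEAF"] = make_food(
        "LEAF", "VE", energy_kcal=30.0, carb_g=4.0, vitc_mg=25.0, vita_mcg_rae=200.0
    )
    bundle.recipes["RC01"] = StandardRecipe(
        recipe_code="RC01",
        ingredients=(("RICE", 200.0), ("OIL", 100.0)),
        total_prepared_g=600.0,
    )
    for pf in (
        PortionFactor("standard_unit", "bottle", "small", 300.0),
        PortionFactor("photo", "P12", "shown", 85.0),
    ):
        bundle.portion_factors[pf.key] = pf
    return bundle


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
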