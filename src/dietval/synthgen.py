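"""Synthetic study generator: reference bundles, paired WFR/24HR days, cost ledgers.

No deposited respondent-level data exist for this kind of validation study,
so the package ships a generator that emulates its design: each respondent
contributes a weighed-food-record (WFR) day, taken as truth, and a 24-hour
recall (R24) day derived from it with the error structure recall validation
is built to detect —

* **omission**: a truly consumed item is not recalled (probability
  ``omission_prob`` per item);
* **intrusion**: an item not consumed is reported (expected
  ``intrusion_prob`` intrusions per true item);
* **portion-size error**: each recalled portion is multiplied by
  ``portion_bias`` x a mean-one lognormal factor with coefficient of
  variation ``portion_cv``;
* **recipe substitution**: a mixed dish is recalled as a similar but
  different standard recipe (probability ``recipe_swap_prob``);
* **implausible-energy days**: a small fraction of respondents'
  WFR days are rescaled to breach the 500/5000 kcal plausibility bounds,
  exercising the outlier flags downstream.

Respondents alternate deterministically between the two interview-modality
arms (CAPI = computer-assisted, PAPI = pen-and-paper), mirroring a
randomised two-arm design; the 24HR day is generated conditionally on the
WFR day because every downstream statistic is paired. Every perturbation is
written to a truth table so parameter-recovery tests can compare observed
error rates with the generating ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import log, sqrt

import numpy as np
import pandas as pd

from .intake import ConsumptionRecord, Quantity
from .nutrients import NUTRIENTS, NutrientVector
from .refdata import FoodEntry, PortionFactor, ReferenceBundle, StandardRecipe

__all__ = [
    "SimConfig",
    "generate_reference_bundle",
    "generate_paired_records",
    "generate_cost_ledger",
]

# (code, label, energy kcal/100 g range, typical portion g, cereal-heavy menu weight)
# portions are flour/raw-equivalent grams sized so a typical 8-item day lands
# near 2200 kcal with roughly three-quarters of energy from cereals
_GIFT_GROUPS = (
    ("CE", "Cereals and their products", (320.0, 380.0), 130.0, 8.0),
    ("FO", "Fats and oils", (700.0, 900.0), 15.0, 1.5),
    ("PU", "Pulses, seeds and nuts", (300.0, 580.0), 50.0, 1.0),
    ("VE", "Vegetables and their products", (20.0, 60.0), 80.0, 1.0),
    ("FI", "Fish, shellfish and their products", (100.0, 220.0), 50.0, 0.8),
    ("ME", "Meat and meat products", (150.0, 300.0), 50.0, 0.5),
    ("FR", "Fruits and their products", (40.0, 90.0), 100.0, 0.5),
    ("MI", "Milk and milk products", (50.0, 90.0), 120.0, 0.4),
    ("RT", "Roots, tubers and plantains", (80.0, 150.0), 120.0, 0.4),
    ("BE", "Beverages", (30.0, 60.0), 250.0, 0.4),
    ("SP", "Spices and condiments", (50.0, 300.0), 8.0, 0.4),
)

#: Micronutrients allowed to be missing from the synthetic composition table.
_FRAGILE_NUTRIENTS = ("fibre_g", "vita_mcg_rae", "vitc_mg")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic validation study.

    Defaults emulate the field study the analysis is designed for: 116/115
    respondents per arm, one respondent day each, ~8 items per day from a
    cereal-dominated rural West African menu, moderate recall error and a
    few percent implausible-energy days.
    """

    n_capi: int = 116
    n_papi: int = 115
    menu_size: int = 40
    n_recipes: int = 4
    mean_items_per_day: float = 8.0
    omission_prob: float = 0.10
    intrusion_prob: float = 0.05
    portion_bias: float = 1.0
    portion_cv: float = 0.25
    recipe_swap_prob: float = 0.05
    outlier_prob: float = 0.03
    recipe_item_prob: float = 0.15
    psem_fraction: float = 0.30
    missing_fct_prob: float = 0.05
    cereal_heavy: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "omission_prob",
            "intrusion_prob",
            "recipe_swap_prob",
            "outlier_prob",
            "recipe_item_prob",
            "psem_fraction",
            "missing_fct_prob",
        ):
            p = getattr(self, name)
            if not 0.0 <= p < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {p}")
        if self.portion_bias <= 0:
            raise ValueError("portion_bias must be > 0")
        if self.portion_cv < 0:
            raise ValueError("portion_cv must be >= 0")
        if self.menu_size < 5:
            raise ValueError("menu_size must be >= 5 (foods span >= 5 food groups)")
        if self.n_recipes < 1 or self.n_capi < 1 or self.n_papi < 1:
            raise ValueError("n_recipes and arm sizes must be >= 1")

    def zero_noise(self) -> "SimConfig":
        """The same study with every recall-error channel switched off."""
        return replace(
            self,
            omission_prob=0.0,
            intrusion_prob=0.0,
            portion_bias=1.0,
            portion_cv=0.0,
            recipe_swap_prob=0.0,
            outlier_prob=0.0,
        )


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# reference bundle


def generate_reference_bundle(config: SimConfig) -> ReferenceBundle:
    """A valid reference bundle: ``menu_size`` foods over >= 5 GIFT groups,
    ``n_recipes`` standard recipes, and two PSEM conversion-factor families."""
    rng = _streams(config.seed, 3)[0]
    bundle = ReferenceBundle()
    bundle.group_map = {code: label for code, label, *_ in _GIFT_GROUPS}

    for i in range(config.menu_size):
        code, label, (e_lo, e_hi), _portion, _w = _GIFT_GROUPS[i % len(_GIFT_GROUPS)]
        energy = rng.uniform(e_lo, e_hi)
        # macro split consistent with Atwater factors (4/9/4 kcal per g)
        fat_share = rng.uniform(0.05, 0.9 if code == "FO" else 0.35)
        protein_share = rng.uniform(0.05, 0.4) * (1 - fat_share)
        carb_share = max(0.0, 1 - fat_share - protein_share)
        amounts: dict[str, float | None] = {
            "energy_kcal": energy,
            "fat_g": energy * fat_share / 9.0,
            "protein_g": energy * protein_share / 4.0,
            "carb_g": energy * carb_share / 4.0,
            "fibre_g": rng.uniform(0.0, 12.0),
            "vita_mcg_rae": rng.uniform(0.0, 300.0),
            "vitc_mg": rng.uniform(0.0, 40.0),
            "ca_mg": rng.uniform(2.0, 300.0),
            "fe_mg": rng.uniform(0.1, 12.0),
            "zn_mg": rng.uniform(0.1, 8.0),
        }
        # incomplete composition table: some micronutrient cells are blank,
        # but never on a group's first (most common) food
        if i >= len(_GIFT_GROUPS):
            for nut in _FRAGILE_NUTRIENTS:
                if rng.random() < config.missing_fct_prob:
                    amounts[nut] = None
        food_code = f"F{i + 1:03d}"
        bundle.foods[food_code] = FoodEntry(
            food_code=food_code,
            name=f"{label.split(',')[0].lower()} {i + 1}",
            gift_group=code,
            composition=NutrientVector.from_mapping(amounts),
        )

    food_codes = list(bundle.foods)
    for j in range(config.n_recipes):
        n_ing = int(rng.integers(2, 5))
        chosen = rng.choice(len(food_codes), size=n_ing, replace=False)
        ingredients = tuple(
            (food_codes[int(k)], float(np.round(rng.uniform(20.0, 400.0), 1)))
            for k in chosen
        )
        raw_total = sum(g for _c, g in ingredients)
        bundle.recipes[f"RC{j + 1:02d}"] = StandardRecipe(
            recipe_code=f"RC{j + 1:02d}",
            ingredients=ingredients,
            total_prepared_g=float(np.round(raw_total * rng.uniform(0.9, 2.0), 1)),
        )

    for unit, sizes in {
        "bowl": {"small": 150.0, "medium": 250.0, "large": 400.0},
        "cup": {"standard": 200.0},
        "spoon": {"table": 10.0},
    }.items():
        for size, grams in sizes.items():
            pf = PortionFactor("standard_unit", unit, size, grams)
            bundle.portion_factors[pf.key] = pf
    for p in range(6):
        grams = float(np.round(rng.uniform(30.0, 350.0), 1))
        pf = PortionFactor("photo", f"P{p + 1:02d}", "shown", grams)
        bundle.portion_factors[pf.key] = pf
    return bundle


# ---------------------------------------------------------------------------
# paired records


def _item_energy_per_100g(code: str, item_type: str, bundle: ReferenceBundle) -> float:
    if item_type == "food":
        return bundle.food(code).composition.energy_kcal
    from .intake import resolve_recipe_density

    return resolve_recipe_density(bundle.recipe(code), bundle.foods).energy_kcal


def generate_paired_records(
    config: SimConfig, bundle: ReferenceBundle
) -> tuple[list[ConsumptionRecord], pd.DataFrame]:
    """Generate one WFR day and one derived R24 day per respondent.

    Returns the flat record list (both sources, both arms) and a truth table
    with one row per WFR item, intrusion, and day-level rescaling event.
    """
    rng = _streams(config.seed, 3)[1]
    sigma = sqrt(log(1.0 + config.portion_cv**2)) if config.portion_cv > 0 else 0.0

    food_codes = list(bundle.foods)
    weights = np.array(
        [
            next(w for c, _l, _e, _p, w in _GIFT_GROUPS if c == f.gift_group)
            if config.cereal_heavy
            else 1.0
            for f in bundle.foods.values()
        ]
    )
    weights = weights / weights.sum()
    portions = {
        code: next(
            p for c, _l, _e, p, _w in _GIFT_GROUPS if c == bundle.foods[code].gift_group
        )
        for code in food_codes
    }
    recipe_codes = list(bundle.recipes)
    factor_rows = list(bundle.portion_factors.values())

    records: list[ConsumptionRecord] = []
    truth_rows: list[dict] = []
    n_total = config.n_capi + config.n_papi
    quota = {"CAPI": config.n_capi, "PAPI": config.n_papi}
    next_arm = "CAPI"

    for i in range(n_total):
        arm = next_arm if quota[next_arm] > 0 else ("PAPI" if next_arm == "CAPI" else "CAPI")
        quota[arm] -= 1
        next_arm = "PAPI" if arm == "CAPI" else "CAPI"
        rid = f"R{i + 1:04d}"

        n_items = max(1, int(rng.poisson(config.mean_items_per_day)))
        day: list[tuple[str, str, float]] = []  # (item_type, code, grams)
        for _ in range(n_items):
            if recipe_codes and rng.random() < config.recipe_item_prob:
                code = recipe_codes[int(rng.integers(len(recipe_codes)))]
                grams = float(rng.uniform(120.0, 320.0))
                day.append(("standard_recipe", code, grams))
            else:
                code = food_codes[int(rng.choice(len(food_codes), p=weights))]
                grams = float(portions[code] * rng.lognormal(-0.08, 0.4))
                day.append(("food", code, grams))

        # implausible-energy day: rescale the whole WFR day past a bound
        outlier_scale = 1.0
        if rng.random() < config.outlier_prob:
            energy = sum(
                g * _item_energy_per_100g(c, t, bundle) / 100.0 for t, c, g in day
            )
            target = 300.0 if rng.random() < 0.5 else 6000.0
            outlier_scale = target / energy
            day = [(t, c, g * outlier_scale) for t, c, g in day]

        for item_idx, (item_type, code, grams) in enumerate(day):
            records.append(
                ConsumptionRecord(rid, arm, "WFR", item_type, code, Quantity(grams=grams))
            )
            omitted = rng.random() < config.omission_prob
            event, r24_code, ratio = "kept", code, np.nan
            if omitted:
                event = "omitted"
            else:
                ratio = config.portion_bias * (
                    float(np.exp(rng.normal(-0.5 * sigma**2, sigma))) if sigma > 0 else 1.0
                )
                if (
                    item_type == "standard_recipe"
                    and len(recipe_codes) > 1
                    and rng.random() < config.recipe_swap_prob
                ):
                    event = "swapped"
                    others = [c for c in recipe_codes if c != code]
                    r24_code = others[int(rng.integers(len(others)))]
                r24_grams = grams * ratio
                records.append(
                    _r24_record(rid, arm, item_type, r24_code, r24_grams, config, rng, factor_rows)
                )
            truth_rows.append(
                {
                    "respondent_id": rid,
                    "arm": arm,
                    "item_index": item_idx,
                    "item_type": item_type,
                    "code": code,
                    "event": event,
                    "r24_code": r24_code if not omitted else "",
                    "wfr_grams": grams,
                    "portion_ratio": ratio,
                    "outlier_scale": outlier_scale,
                }
            )

        n_intrusions = int(rng.binomial(n_items, config.intrusion_prob))
        for k in range(n_intrusions):
            code = food_codes[int(rng.choice(len(food_codes), p=weights))]
            grams = float(portions[code] * rng.lognormal(-0.08, 0.4))
            records.append(
                _r24_record(rid, arm, "food", code, grams, config, rng, factor_rows)
            )
            truth_rows.append(
                {
                    "respondent_id": rid,
                    "arm": arm,
                    "item_index": n_items + k,
                    "item_type": "food",
                    "code": code,
                    "event": "intruded",
                    "r24_code": code,
                    "wfr_grams": np.nan,
                    "portion_ratio": np.nan,
                    "outlier_scale": outlier_scale,
                }
            )

    truth = pd.DataFrame(truth_rows)
    return records, truth


def _r24_record(
    rid: str,
    arm: str,
    item_type: str,
    code: str,
    grams: float,
    config: SimConfig,
    rng: np.random.Generator,
    factor_rows: list[PortionFactor],
) -> ConsumptionRecord:
    """An R24 record, re-expressed through a PSEM factor for a fraction of items."""
    if factor_rows and rng.random() < config.psem_fraction:
        pf = factor_rows[int(rng.integers(len(factor_rows)))]
        quantity = Quantity(
            psem_code=pf.psem_code,
            unit_code=pf.unit_code,
            size_label=pf.size_label,
            n_units=grams / pf.grams_per_unit,
        )
    else:
        quantity = Quantity(grams=grams)
    return ConsumptionRecord(rid, arm, "R24", item_type, code, quantity)


# ---------------------------------------------------------------------------
# cost ledger

# (activity, CAPI person-days, PAPI person-days, CAPI non-time, PAPI non-time)
# PAPI is more human-capital intensive (manual data entry and cleaning);
# CAPI carries higher equipment costs (tablets, software).
_LEDGER_SHAPE = (
    ("reference_data_prep", 60.0, 55.0, 800.0, 500.0),
    ("survey_prep", 25.0, 25.0, 3500.0, 1200.0),
    ("training", 30.0, 35.0, 900.0, 900.0),
    ("survey_execution", 120.0, 140.0, 2500.0, 2000.0),
    ("data_entry", 5.0, 60.0, 200.0, 600.0),
    ("cleaning_processing", 20.0, 45.0, 100.0, 100.0),
)

DAILY_WAGE = 40.0  # currency units per person-day


def generate_cost_ledger(config: SimConfig) -> pd.DataFrame:
    """A toy activity- and ingredients-based cost ledger for both modalities.

    Columns follow ``costs.csv``: modality, activity, category (time |
    non_time), quantity (person-days for time items), unit, unit_value,
    whose_time. Quantities are jittered around a fixed shape in which
    pen-and-paper interviewing is more labour intensive and the
    computer-assisted modality has higher equipment costs.
    """
    rng = _streams(config.seed, 3)[2]
    rows = []
    for activity, capi_pd, papi_pd, capi_nt, papi_nt in _LEDGER_SHAPE:
        for modality, pdays, ntcost in (
            ("CAPI", capi_pd, capi_nt),
            ("PAPI", papi_pd, papi_nt),
        ):
            rows.append(
                {
                    "modality": modality,
                    "activity": activity,
                    "category": "time",
                    "quantity": float(np.round(pdays * rng.uniform(0.9, 1.1), 1)),
                    "unit": "person_day",
                    "unit_value": DAILY_WAGE,
                    "whose_time": "staff",
                }
            )
            rows.append(
                {
                    "modality": modality,
                    "activity": activity,
                    "category": "non_time",
                    "quantity": 1.0,
                    "unit": "lump_sum",
                    "unit_value": float(np.round(ntcost * rng.uniform(0.9, 1.1), 2)),
                    "whose_time": "",
                }
            )
    # respondent time during the interview, valued at the minimum wage
    for modality, pdays in (("CAPI", 15.0), ("PAPI", 18.0)):
        rows.append(
            {
                "modality": modality,
                "activity": "survey_execution",
                "category": "time",
                "quantity": float(np.round(pdays * rng.uniform(0.9, 1.1), 1)),
                "unit": "person_day",
                "unit_value": DAILY_WAGE * 0.5,
                "whose_time": "respondent",
            }
        )
    return pd.DataFrame(rows)
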