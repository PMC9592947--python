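"""Convert consumption records into gram amounts and nutrient intakes.

A consumption record is one item (single food, standard recipe, or
non-standard recipe) consumed by one respondent on the day covered by one
source: the weighed food record (WFR, the benchmark, where amounts are
weighed directly) or the 24-hour recall (R24, where amounts come from a
portion size estimation method, PSEM). Records are converted to grams, then
to nutrients via the per-100 g composition of the food or the nutrient
density of the prepared recipe, and aggregated per respondent x source into
an intake table carrying gram totals, item counts, the ten-nutrient daily
vector and per-food-group energy.

Recipe nutrient density assumes conservation: the nutrients of the prepared
dish equal the sum over raw ingredients (no cooking retention or yield
factors), so density per 100 g = 100 x sum(ingredient_g x composition/100)
/ total_prepared_g. A mixed dish's energy is credited entirely to the dish's
own GIFT group (or, when the dish has none assigned, the group of its
highest-energy ingredient) rather than disaggregated to ingredients.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .nutrients import NUTRIENTS, NutrientVector
from .refdata import PortionFactor, RefDataError, ReferenceBundle, StandardRecipe

__all__ = [
    "Quantity",
    "NSRDetail",
    "ConsumptionRecord",
    "IntakeTable",
    "IntakeError",
    "portion_to_grams",
    "resolve_recipe_density",
    "item_nutrients",
    "daily_intakes",
    "food_group_energy_shares",
    "records_to_frame",
    "write_records_csv",
    "read_records_csv",
    "write_intake_table",
    "read_intake_table",
]

ARMS = ("CAPI", "PAPI")
SOURCES = ("WFR", "R24")
ITEM_TYPES = ("food", "standard_recipe", "nonstandard_recipe")


class IntakeError(ValueError):
    """A consumption record failed to resolve against the reference bundle."""


@dataclass(frozen=True)
class Quantity:
    """Either direct grams, or a PSEM portion (factor key + number of units)."""

    grams: float | None = None
    psem_code: str | None = None
    unit_code: str | None = None
    size_label: str | None = None
    n_units: float | None = None

    def __post_init__(self) -> None:
        direct = self.grams is not None
        psem = self.psem_code is not None
        if direct == psem:
            raise IntakeError("exactly one of grams or a PSEM portion must be given")
        if direct and self.grams <= 0:  # type: ignore[operator]
            raise IntakeError("direct grams must be > 0")
        if psem:
            if self.unit_code is None or self.size_label is None or self.n_units is None:
                raise IntakeError("PSEM quantity needs unit_code, size_label, n_units")
            if self.n_units <= 0:
                raise IntakeError("n_units must be > 0")


@dataclass(frozen=True)
class NSRDetail:
    """Inline ingredient list for a non-standard recipe (dish with no code)."""

    ingredients: tuple[tuple[str, float], ...]
    total_prepared_g: float
    gift_group: str | None = None


@dataclass(frozen=True)
class ConsumptionRecord:
    respondent_id: str
    arm: str  # CAPI | PAPI
    source: str  # WFR | R24
    item_type: str  # food | standard_recipe | nonstandard_recipe
    code: str
    quantity: Quantity
    nsr_detail: NSRDetail | None = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise IntakeError(f"unknown arm {self.arm!r}")
        if self.source not in SOURCES:
            raise IntakeError(f"unknown source {self.source!r}")
        if self.item_type not in ITEM_TYPES:
            raise IntakeError(f"unknown item_type {self.item_type!r}")
        if (self.item_type == "nonstandard_recipe") != (self.nsr_detail is not None):
            raise IntakeError(
                "nsr_detail must be present iff item_type is nonstandard_recipe"
            )


@dataclass
class IntakeTable:
    """Per (respondent, source) daily totals.

    ``nutrients``: DataFrame indexed by (respondent_id, source) with columns
    arm, gram_total, item_count, the ten nutrients, and per-nutrient
    ``<nutrient>_missing`` flags (True when any contributing item had a
    missing composition value).

    ``group_energy``: DataFrame on the same index, one column per GIFT group
    code, holding kcal contributed by that group.
    """

    nutrients: pd.DataFrame
    group_energy: pd.DataFrame

    def pair_frame(self, column: str = "energy_kcal") -> pd.DataFrame:
        """Wide per-respondent frame with WFR and R24 columns for ``column``."""
        wide = self.nutrients[column].unstack("source")
        arm = self.nutrients["arm"].groupby("respondent_id").first()
        wide["arm"] = arm
        return wide.dropna(subset=["WFR", "R24"])


# ---------------------------------------------------------------------------
# conversions


def portion_to_grams(
    quantity: Quantity, factors: dict[tuple[str, str, str], PortionFactor]
) -> float:
    """Resolve a quantity specification to grams consumed."""
    if quantity.grams is not None:
        return float(quantity.grams)
    key = (quantity.psem_code, quantity.unit_code, quantity.size_label)
    factor = factors.get(key)  # type: ignore[arg-type]
    if factor is None:
        raise IntakeError(f"no portion conversion factor for {key!r}")
    return factor.grams_per_unit * float(quantity.n_units)  # type: ignore[arg-type]


def resolve_recipe_density(
    recipe: StandardRecipe | NSRDetail, foods: dict
) -> NutrientVector:
    """Nutrient density (per 100 g prepared) of a standard or non-standard recipe.

    A nutrient is flagged missing in the output iff it is missing for any
    contributing ingredient; missing contributions add 0.
    """
    if recipe.total_prepared_g <= 0:
        raise RefDataError("total_prepared_g must be > 0")
    total = NutrientVector.zeros()
    for code, grams in recipe.ingredients:
        if code not in foods:
            raise RefDataError(f"recipe ingredient {code!r} not in food list")
        if grams <= 0:
            raise RefDataError(f"ingredient {code!r}: grams must be > 0")
        total = total + foods[code].composition.scale(grams / 100.0)
    return total.scale(100.0 / recipe.total_prepared_g)


def _dominant_ingredient_group(
    recipe: StandardRecipe | NSRDetail, bundle: ReferenceBundle
) -> str:
    best_group, best_energy = None, -1.0
    for code, grams in recipe.ingredients:
        food = bundle.food(code)
        energy = food.composition.energy_kcal * grams / 100.0
        if energy > best_energy:
            best_group, best_energy = food.gift_group, energy
    assert best_group is not None
    return best_group


def item_nutrients(
    record: ConsumptionRecord, bundle: ReferenceBundle
) -> tuple[float, NutrientVector, str]:
    """Resolve one record to (grams, nutrient totals, GIFT group)."""
    try:
        grams = portion_to_grams(record.quantity, bundle.portion_factors)
        if record.item_type == "food":
            food = bundle.food(record.code)
            density, group = food.composition, food.gift_group
        elif record.item_type == "standard_recipe":
            recipe = bundle.recipe(record.code)
            density = resolve_recipe_density(recipe, bundle.foods)
            group = recipe.gift_group or _dominant_ingredient_group(recipe, bundle)
        else:
            assert record.nsr_detail is not None
            density = resolve_recipe_density(record.nsr_detail, bundle.foods)
            group = record.nsr_detail.gift_group or _dominant_ingredient_group(
                record.nsr_detail, bundle
            )
    except (RefDataError, IntakeError) as exc:
        raise IntakeError(
            f"record ({record.respondent_id}, {record.source}, {record.code}): {exc}"
        ) from exc
    return grams, density.scale(grams / 100.0), group


def daily_intakes(
    records: list[ConsumptionRecord], bundle: ReferenceBundle
) -> IntakeTable:
    """Aggregate records into per (respondent, source) daily intake totals.

    Respondents with no records simply have no row (days are not zero
    filled); a respondent appearing under both arms is an error.
    """
    arm_of: dict[str, str] = {}
    acc: dict[tuple[str, str], dict] = {}
    group_acc: dict[tuple[str, str], dict[str, float]] = {}

    for record in records:
        prev = arm_of.setdefault(record.respondent_id, record.arm)
        if prev != record.arm:
            raise IntakeError(
                f"respondent {record.respondent_id} has records in both arms"
            )
        grams, nutrients, group = item_nutrients(record, bundle)
        key = (record.respondent_id, record.source)
        slot = acc.get(key)
        if slot is None:
            slot = acc[key] = {
                "gram_total": 0.0,
                "item_count": 0,
                "values": np.zeros(len(NUTRIENTS)),
                "missing": np.zeros(len(NUTRIENTS), dtype=bool),
            }
            group_acc[key] = {}
        slot["gram_total"] += grams
        slot["item_count"] += 1
        slot["values"] += nutrients.values
        slot["missing"] |= nutrients.missing
        group_acc[key][group] = group_acc[key].get(group, 0.0) + nutrients.energy_kcal

    index = pd.MultiIndex.from_tuples(
        sorted(acc), names=["respondent_id", "source"]
    )
    rows, group_rows = [], []
    for key in index:
        slot = acc[key]
        row = {
            "arm": arm_of[key[0]],
            "gram_total": slot["gram_total"],
            "item_count": slot["item_count"],
        }
        row.update(dict(zip(NUTRIENTS, slot["values"])))
        row.update(
            {f"{n}_missing": bool(m) for n, m in zip(NUTRIENTS, slot["missing"])}
        )
        rows.append(row)
        group_rows.append(group_acc[key])

    nutrients_df = pd.DataFrame(rows, index=index)
    group_df = pd.DataFrame(group_rows, index=index).fillna(0.0)
    group_df = group_df.reindex(sorted(group_df.columns), axis=1)
    return IntakeTable(nutrients=nutrients_df, group_energy=group_df)


def food_group_energy_shares(group_energy_row: pd.Series) -> pd.Series:
    """Percentage of a day's energy from each GIFT group (sums to 100)."""
    total = float(group_energy_row.sum())
    if total <= 0:
        raise IntakeError("food-group shares are undefined for a zero-energy day")
    return 100.0 * group_energy_row / total


def write_intake_table(
    intakes: IntakeTable, nutrients_csv: str | os.PathLike, group_csv: str | os.PathLike
) -> None:
    intakes.nutrients.to_csv(nutrients_csv)
    intakes.group_energy.to_csv(group_csv)


def read_intake_table(
    nutrients_csv: str | os.PathLike, group_csv: str | os.PathLike
) -> IntakeTable:
    nutrients = pd.read_csv(nutrients_csv, index_col=["respondent_id", "source"])
    group = pd.read_csv(group_csv, index_col=["respondent_id", "source"])
    return IntakeTable(nutrients=nutrients, group_energy=group)


# ---------------------------------------------------------------------------
# CSV interchange

_RECORD_COLUMNS = [
    "record_id",
    "respondent_id",
    "arm",
    "source",
    "item_type",
    "code",
    "grams",
    "psem_code",
    "unit_code",
    "size_label",
    "n_units",
]


def records_to_frame(records: list[ConsumptionRecord]) -> pd.DataFrame:
    rows = []
    for i, r in enumerate(records):
        q = r.quantity
        rows.append(
            {
                "record_id": i,
                "respondent_id": r.respondent_id,
                "arm": r.arm,
                "source": r.source,
                "item_type": r.item_type,
                "code": r.code,
                "grams": "" if q.grams is None else repr(float(q.grams)),
                "psem_code": q.psem_code or "",
                "unit_code": q.unit_code or "",
                "size_label": q.size_label or "",
                "n_units": "" if q.n_units is None else repr(float(q.n_units)),
            }
        )
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


def write_records_csv(records: list[ConsumptionRecord], path: str | os.PathLike) -> None:
    """Write records to CSV; non-standard recipe details go to sidecar files."""
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    nsr_rows, nsr_meta = [], []
    for i, r in enumerate(records):
        if r.nsr_detail is not None:
            nsr_meta.append(
                {
                    "record_id": i,
                    "total_prepared_g": repr(float(r.nsr_detail.total_prepared_g)),
                    "gift_group": r.nsr_detail.gift_group or "",
                }
            )
            for code, grams in r.nsr_detail.ingredients:
                nsr_rows.append(
                    {"record_id": i, "food_code": code, "ingredient_g": repr(float(grams))}
                )
    if nsr_meta:
        base = path.with_suffix("")
        pd.DataFrame(nsr_rows).to_csv(f"{base}.nsr_ingredients.csv", index=False)
        pd.DataFrame(nsr_meta).to_csv(f"{base}.nsr_meta.csv", index=False)


def read_records_csv(path: str | os.PathLike) -> list[ConsumptionRecord]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    base = path.with_suffix("")
    nsr_by_record: dict[int, NSRDetail] = {}
    meta_path = Path(f"{base}.nsr_meta.csv")
    if meta_path.exists():
        meta = pd.read_csv(meta_path, dtype=str, keep_default_na=False)
        ing = pd.read_csv(
            f"{base}.nsr_ingredients.csv", dtype=str, keep_default_na=False
        )
        for row in meta.itertuples(index=False):
            rid = int(row.record_id)
            sub = ing[ing.record_id == row.record_id]
            nsr_by_record[rid] = NSRDetail(
                ingredients=tuple(
                    (r.food_code, float(r.ingredient_g))
                    for r in sub.itertuples(index=False)
                ),
                total_prepared_g=float(row.total_prepared_g),
                gift_group=row.gift_group or None,
            )

    records = []
    for row in df.itertuples(index=False):
        if row.grams != "" and row.psem_code != "":
            raise IntakeError(
                f"record {row.record_id}: both grams and PSEM quantity populated"
            )
        if row.grams != "":
            quantity = Quantity(grams=float(row.grams))
        else:
            quantity = Quantity(
                psem_code=row.psem_code,
                unit_code=row.unit_code,
                size_label=row.size_label,
                n_units=float(row.n_units),
            )
        records.append(
            ConsumptionRecord(
                respondent_id=row.respondent_id,
                arm=row.arm,
                source=row.source,
                item_type=row.item_type,
                code=row.code,
                quantity=quantity,
                nsr_detail=nsr_by_record.get(int(row.record_id)),
            )
        )
    return records
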