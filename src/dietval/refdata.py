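"""Dietary reference bundle: food list, composition table, recipes, portion factors.

Converting coded consumption records into nutrient intakes requires a bundle
of "dietary reference data": a food list with a food composition table (FCT,
per 100 g), standard recipes (ingredient lists with the total prepared
weight of the dish), portion-size conversion factors for each portion size
estimation method (PSEM), and a map of FAO/WHO GIFT food-group codes to
labels. This module loads, validates, queries and round-trips that bundle.

CSV schemas (header row mandatory, UTF-8, "." decimal):

* ``foods.csv``: food_code,name,gift_group,energy_kcal,fat_g,protein_g,
  carb_g,fibre_g,vita_mcg_rae,vitc_mg,ca_mg,fe_mg,zn_mg — blank nutrient
  cells become missing flags, never zeros.
* ``recipes.csv``: recipe_code,food_code,ingredient_g (one row per
  ingredient).
* ``recipe_meta.csv``: recipe_code,total_prepared_g[,gift_group] — the
  optional gift_group assigns the whole dish's energy to one food group.
* ``portion_factors.csv``: psem_code,unit_code,size_label,grams_per_unit.
* ``groups.csv``: gift_group,label.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nutrients import NUTRIENTS, NutrientVector

__all__ = [
    "FoodEntry",
    "StandardRecipe",
    "PortionFactor",
    "ReferenceBundle",
    "RefDataError",
    "Violation",
    "load_reference_bundle",
    "write_reference_bundle",
    "validate_refdata",
    "fct_completeness",
    "PSEM_CODES",
]

#: Recognised portion size estimation methods. ``direct_weight`` quantities
#: carry grams directly and need no conversion-factor row.
PSEM_CODES = frozenset(
    {
        "direct_weight",
        "photo",
        "proxy_playdough",
        "proxy_sorghum",
        "proxy_water",
        "standard_unit",
    }
)

#: Sentinel "unmatched food" codes used on paper questionnaires; they must be
#: resolved to real codes before the data reach this package.
SENTINEL_CODES = frozenset({"9999", "99999", "99 999"})


class RefDataError(ValueError):
    """Malformed or inconsistent reference data (file/line context in message)."""


@dataclass(frozen=True)
class FoodEntry:
    food_code: str
    name: str
    gift_group: str
    composition: NutrientVector  # per 100 g


@dataclass(frozen=True)
class StandardRecipe:
    recipe_code: str
    ingredients: tuple[tuple[str, float], ...]  # (food_code, grams as used)
    total_prepared_g: float
    gift_group: str | None = None  # dish-level group; None -> dominant ingredient

    def __post_init__(self) -> None:
        if not self.ingredients:
            raise RefDataError(f"recipe {self.recipe_code}: no ingredients")
        for code, grams in self.ingredients:
            if grams <= 0:
                raise RefDataError(
                    f"recipe {self.recipe_code}: non-positive grams for {code}"
                )
        if self.total_prepared_g <= 0:
            raise RefDataError(
                f"recipe {self.recipe_code}: total_prepared_g must be > 0"
            )


@dataclass(frozen=True)
class PortionFactor:
    psem_code: str
    unit_code: str
    size_label: str
    grams_per_unit: float

    def __post_init__(self) -> None:
        if self.psem_code not in PSEM_CODES:
            raise RefDataError(f"unknown psem_code {self.psem_code!r}")
        if self.grams_per_unit <= 0:
            raise RefDataError(
                f"portion factor ({self.psem_code},{self.unit_code},"
                f"{self.size_label}): grams_per_unit must be > 0"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.psem_code, self.unit_code, self.size_label)


@dataclass
class ReferenceBundle:
    """The dietary reference data against which consumption records resolve."""

    foods: dict[str, FoodEntry] = field(default_factory=dict)
    recipes: dict[str, StandardRecipe] = field(default_factory=dict)
    portion_factors: dict[tuple[str, str, str], PortionFactor] = field(
        default_factory=dict
    )
    group_map: dict[str, str] = field(default_factory=dict)

    def food(self, code: str) -> FoodEntry:
        try:
            return self.foods[code]
        except KeyError:
            raise RefDataError(f"unknown food code {code!r}") from None

    def recipe(self, code: str) -> StandardRecipe:
        try:
            return self.recipes[code]
        except KeyError:
            raise RefDataError(f"unknown recipe code {code!r}") from None


@dataclass(frozen=True)
class Violation:
    """One referential-integrity failure found by :func:`validate_refdata`."""

    kind: str  # dangling_ingredient | unknown_group | unknown_recipe_group
    key: str  # the unresolvable key
    referenced_by: str  # object containing the reference

    def __str__(self) -> str:
        return f"{self.kind}: {self.key!r} referenced by {self.referenced_by}"


# ---------------------------------------------------------------------------
# loading


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise RefDataError(f"{path}: file not found")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise RefDataError(f"{path}: missing column {col!r}")
    return df

def _parse_float(raw: str, path: Path, line: int, col: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise RefDataError(
            f"{path}, line {line}, column {col}: cannot parse {raw!r} as a number"
        ) from None


def load_reference_bundle(directory: str | os.PathLike) -> ReferenceBundle:
    """Load a reference bundle from a directory of the five schema CSVs.

    Blank nutrient cells become missing flags; duplicate keys and sentinel
    food codes are rejected with the offending key named.
    """
    d = Path(directory)
    bundle = ReferenceBundle()

    groups = _read_csv(d / "groups.csv", ["gift_group", "label"])
    for line, row in enumerate(groups.itertuples(index=False), start=2):
        if row.gift_group in bundle.group_map:
            raise RefDataError(
                f"{d / 'groups.csv'}: duplicate gift_group {row.gift_group!r}"
            )
        bundle.group_map[row.gift_group] = row.label

    foods_path = d / "foods.csv"
    foods = _read_csv(foods_path, ["food_code", "name", "gift_group", *NUTRIENTS])
    for line, row in enumerate(foods.itertuples(index=False), start=2):
        code = row.food_code
        if code in SENTINEL_CODES:
            raise RefDataError(
                f"{foods_path}, line {line}: sentinel food code {code!r} must be "
                "resolved to a real code before loading"
            )
        if code in bundle.foods:
            raise RefDataError(f"{foods_path}: duplicate food_code {code!r}")
        amounts: dict[str, float | None] = {}
        for nut in NUTRIENTS:
            raw = getattr(row, nut).strip()
            amounts[nut] = None if raw == "" else _parse_float(raw, foods_path, line, nut)
        bundle.foods[code] = FoodEntry(
            food_code=code,
            name=row.name,
            gift_group=row.gift_group,
            composition=NutrientVector.from_mapping(amounts),
        )

    meta_path = d / "recipe_meta.csv"
    meta = _read_csv(meta_path, ["recipe_code", "total_prepared_g"])
    has_group = "gift_group" in meta.columns
    totals: dict[str, float] = {}
    recipe_groups: dict[str, str | None] = {}
    for line, row in enumerate(meta.itertuples(index=False), start=2):
        if row.recipe_code in totals:
            raise RefDataError(f"{meta_path}: duplicate recipe_code {row.recipe_code!r}")
        totals[row.recipe_code] = _parse_float(
            row.total_prepared_g, meta_path, line, "total_prepared_g"
        )
        grp = getattr(row, "gift_group", "") if has_group else ""
        recipe_groups[row.recipe_code] = grp.strip() or None

    rec_path = d / "recipes.csv"
    recs = _read_csv(rec_path, ["recipe_code", "food_code", "ingredient_g"])
    ingredients: dict[str, list[tuple[str, float]]] = {}
    for line, row in enumerate(recs.itertuples(index=False), start=2):
        grams = _parse_float(row.ingredient_g, rec_path, line, "ingredient_g")
        ingredients.setdefault(row.recipe_code, []).append((row.food_code, grams))
    for code, ing in ingredients.items():
        if code not in totals:
            raise RefDataError(
                f"{rec_path}: recipe {code!r} has no total_prepared_g in recipe_meta.csv"
            )
        bundle.recipes[code] = StandardRecipe(
            recipe_code=code,
            ingredients=tuple(ing),
            total_prepared_g=totals[code],
            gift_group=recipe_groups[code],
        )
    orphan_meta = set(totals) - set(ingredients)
    if orphan_meta:
        raise RefDataError(
            f"{meta_path}: recipe(s) {sorted(orphan_meta)} have metadata but no ingredients"
        )

    pf_path = d / "portion_factors.csv"
    factors = _read_csv(
        pf_path, ["psem_code", "unit_code", "size_label", "grams_per_unit"]
    )
    for line, row in enumerate(factors.itertuples(index=False), start=2):
        pf = PortionFactor(
            psem_code=row.psem_code,
            unit_code=row.unit_code,
            size_label=row.size_label,
            grams_per_unit=_parse_float(
                row.grams_per_unit, pf_path, line, "grams_per_unit"
            ),
        )
        if pf.key in bundle.portion_factors:
            raise RefDataError(f"{pf_path}: duplicate portion factor {pf.key!r}")
        bundle.portion_factors[pf.key] = pf

    return bundle


def write_reference_bundle(bundle: ReferenceBundle, directory: str | os.PathLike) -> None:
    """Write a bundle back to the five schema CSVs (lossless round-trip)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    rows = []
    for f in bundle.foods.values():
        row: dict[str, object] = {
            "food_code": f.food_code,
            "name": f.name,
            "gift_group": f.gift_group,
        }
        for i, nut in enumerate(NUTRIENTS):
            row[nut] = "" if f.composition.missing[i] else repr(float(f.composition.values[i]))
        rows.append(row)
    pd.DataFrame(rows, columns=["food_code", "name", "gift_group", *NUTRIENTS]).to_csv(
        d / "foods.csv", index=False
    )

    rec_rows = [
        {"recipe_code": r.recipe_code, "food_code": c, "ingredient_g": repr(float(g))}
        for r in bundle.recipes.values()
        for c, g in r.ingredients
    ]
    pd.DataFrame(
        rec_rows, columns=["recipe_code", "food_code", "ingredient_g"]
    ).to_csv(d / "recipes.csv", index=False)

    meta_rows = [
        {
            "recipe_code": r.recipe_code,
            "total_prepared_g": repr(float(r.total_prepared_g)),
            "gift_group": r.gift_group or "",
        }
        for r in bundle.recipes.values()
    ]
    pd.DataFrame(
        meta_rows, columns=["recipe_code", "total_prepared_g", "gift_group"]
    ).to_csv(d / "recipe_meta.csv", index=False)

    pf_rows = [
        {
            "psem_code": p.psem_code,
            "unit_code": p.unit_code,
            "size_label": p.size_label,
            "grams_per_unit": repr(float(p.grams_per_unit)),
        }
        for p in bundle.portion_factors.values()
    ]
    pd.DataFrame(
        pf_rows, columns=["psem_code", "unit_code", "size_label", "grams_per_unit"]
    ).to_csv(d / "portion_factors.csv", index=False)

    pd.DataFrame(
        [{"gift_group": g, "label": l} for g, l in bundle.group_map.items()],
        columns=["gift_group", "label"],
    ).to_csv(d / "groups.csv", index=False)


# ---------------------------------------------------------------------------
# validation and completeness


def validate_refdata(bundle: ReferenceBundle) -> list[Violation]:
    """Return every referential-integrity violation (empty list = consistent).

    Checks: every recipe ingredient resolves in the food list; every food's
    and recipe's GIFT group code is in the group map.
    """
    violations: list[Violation] = []
    for food in bundle.foods.values():
        if food.gift_group not in bundle.group_map:
            violations.append(
                Violation("unknown_group", food.gift_group, f"food {food.food_code}")
            )
    for recipe in bundle.recipes.values():
        for code, _grams in recipe.ingredients:
            if code not in bundle.foods:
                violations.append(
                    Violation(
                        "dangling_ingredient", code, f"recipe {recipe.recipe_code}"
                    )
                )
        if recipe.gift_group is not None and recipe.gift_group not in bundle.group_map:
            violations.append(
                Violation(
                    "unknown_recipe_group",
                    recipe.gift_group,
                    f"recipe {recipe.recipe_code}",
                )
            )
    return violations


def fct_completeness(
    bundle: ReferenceBundle, consumed_codes: set[str] | list[str]
) -> pd.Series:
    """Percentage of consumed food codes with a non-missing FCT value per nutrient.

    ``consumed_codes`` is the set of distinct foods actually reported; the
    result is 100 x (codes with a value) / |codes| for each nutrient.
    """
    codes = sorted(set(consumed_codes))
    if not codes:
        raise RefDataError("consumed_codes must be nonempty")
    present = np.zeros(len(NUTRIENTS))
    for code in codes:
        food = bundle.food(code)
        present += ~food.composition.missing
    return pd.Series(100.0 * present / len(codes), index=list(NUTRIENTS))
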