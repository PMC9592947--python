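"""Nutrient vectors with explicit missingness.

A food composition table reports nutrient content per 100 g of food. Ten
nutrients are tracked throughout the package: energy (kcal; kJ is a derived
view at 4.184 kJ/kcal), fat, protein, carbohydrate and fibre (g), vitamin A
(mcg retinol activity equivalents), vitamin C (mg), calcium, iron and zinc
(mg). Composition tables in low-resource settings are incomplete, so a blank
cell is carried as an explicit missing flag rather than imputed or zeroed:
missing values contribute 0 to intake sums but propagate a flag so that
per-nutrient table completeness can be reported alongside results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical nutrient order used everywhere (column names in foods.csv).
NUTRIENTS: tuple[str, ...] = (
    "energy_kcal",
    "fat_g",
    "protein_g",
    "carb_g",
    "fibre_g",
    "vita_mcg_rae",
    "vitc_mg",
    "ca_mg",
    "fe_mg",
    "zn_mg",
)

N_NUTRIENTS = len(NUTRIENTS)

#: Thermochemical conversion used for the kJ view of energy.
KJ_PER_KCAL = 4.184

_INDEX = {name: i for i, name in enumerate(NUTRIENTS)}


@dataclass(frozen=True)
class NutrientVector:
    """Ten nutrient amounts plus per-nutrient missingness flags.

    ``missing`` marks entries whose true amount is unknown. For a single
    food a missing entry carries value 0.0; in a sum over items the value is
    the total of the *known* contributions and the flag records that the
    total is a lower bound. Missing is distinct from a true zero: a food
    genuinely devoid of vitamin C has value 0 and missing False.
    """

    values: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (N_NUTRIENTS,):
            raise ValueError(
                f"expected {N_NUTRIENTS} nutrient values, got shape {values.shape}"
            )
        missing = self.missing
        if missing is None:
            missing = np.zeros(N_NUTRIENTS, dtype=bool)
        else:
            missing = np.asarray(missing, dtype=bool)
            if missing.shape != (N_NUTRIENTS,):
                raise ValueError("missing mask must have one flag per nutrient")
        if np.any(values < 0):
            bad = NUTRIENTS[int(np.argmax(values < 0))]
            raise ValueError(f"negative nutrient value for {bad}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "missing", missing)

    # -- constructors ------------------------------------------------------
    @classmethod
    def zeros(cls) -> "NutrientVector":
        return cls(np.zeros(N_NUTRIENTS))

    @classmethod
    def from_mapping(cls, amounts: dict[str, float | None]) -> "NutrientVector":
        """Build from a name -> amount mapping; None/NaN marks missing."""
        values = np.zeros(N_NUTRIENTS)
        missing = np.zeros(N_NUTRIENTS, dtype=bool)
        for name, amount in amounts.items():
            if name not in _INDEX:
                raise KeyError(f"unknown nutrient {name!r}")
            i = _INDEX[name]
            if amount is None or (isinstance(amount, float) and np.isnan(amount)):
                missing[i] = True
            else:
                values[i] = float(amount)
        return cls(values, missing)

    # -- accessors ---------------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return float(self.values[_INDEX[name]])

    def is_missing(self, name: str) -> bool:
        return bool(self.missing[_INDEX[name]])

    @property
    def energy_kcal(self) -> float:
        return float(self.values[0])

    @property
    def energy_kj(self) -> float:
        return self.energy_kcal * KJ_PER_KCAL

    def as_dict(self) -> dict[str, float]:
        return {name: float(v) for name, v in zip(NUTRIENTS, self.values)}

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        return NutrientVector(self.values + other.values, self.missing | other.missing)

    def scale(self, factor: float) -> "NutrientVector":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return NutrientVector(self.values * factor, self.missing.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NutrientVector):
            return NotImplemented
        return bool(
            np.array_equal(self.values, other.values)
            and np.array_equal(self.missing, other.missing)
        )
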