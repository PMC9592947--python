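"""Activity- and ingredients-based costing and cost-effectiveness.

Each survey modality's cost is itemised by activity (reference-data
preparation, survey preparation, training, survey execution, data entry,
cleaning/processing) and split into time items (person-days valued at a
wage; respondent time at the minimum wage) and non-time monetary items.

Accuracy against the weighed-record benchmark is measured on group means:
the average percentage error is 100 x |1 - mean(R24)/mean(WFR)| (capped at
100 so accuracy stays in [0, 100]) and average percentage accuracy is 100
minus that error. Three primary measures are tracked — item-count accuracy,
gram-amount accuracy, and a composite nutrient accuracy (the arithmetic
mean of the ten per-nutrient accuracies). Cost-effectiveness is cost per
percentage point of accuracy: each cost aggregate (total, person-days, time
cost, non-time cost) divided by each accuracy measure.

Reference-data-borrowing scenarios model a shared repository of dietary
reference data: a fraction of the computer-assisted modality's
reference-data preparation is borrowed rather than rebuilt, scaling that
activity's quantities by (1 - fraction) while the pen-and-paper ledger and
all accuracy measures stay unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intake import IntakeTable
from .nutrients import NUTRIENTS

__all__ = [
    "ACTIVITIES",
    "AccuracyMeasures",
    "CostSummary",
    "CEResult",
    "total_costs",
    "group_accuracy",
    "composite_nutrient_accuracy",
    "accuracy_from_intakes",
    "cost_effectiveness",
    "apply_borrowing_scenario",
]

ACTIVITIES = (
    "reference_data_prep",
    "survey_prep",
    "training",
    "survey_execution",
    "data_entry",
    "cleaning_processing",
)

LEDGER_COLUMNS = [
    "modality",
    "activity",
    "category",
    "quantity",
    "unit",
    "unit_value",
    "whose_time",
]


@dataclass(frozen=True)
class AccuracyMeasures:
    item_count_accuracy: float
    gram_accuracy: float
    nutrient_accuracy: dict[str, float]  # one entry per tracked nutrient
    composite_nutrient_accuracy: float

    def primary(self) -> dict[str, float]:
        return {
            "item_count": self.item_count_accuracy,
            "gram_amount": self.gram_accuracy,
            "composite_nutrient": self.composite_nutrient_accuracy,
        }


@dataclass(frozen=True)
class CostSummary:
    modality: str
    total_cost: float
    time_cost: float
    non_time_cost: float
    person_days: float
    by_activity: pd.DataFrame  # activity x category cost table


@dataclass(frozen=True)
class CEResult:
    modality: str
    scenario: str
    costs: CostSummary
    accuracy: AccuracyMeasures
    cost_per_accuracy_point: dict[str, dict[str, float]]  # aggregate -> measure -> ratio


def _check_ledger(ledger: pd.DataFrame) -> None:
    missing = set(LEDGER_COLUMNS[:4]) - set(ledger.columns)
    if missing:
        raise ValueError(f"cost ledger missing column(s) {sorted(missing)}")
    if ledger.empty:
        raise ValueError("cost ledger is empty")
    if (ledger["quantity"].astype(float) < 0).any():
        raise ValueError("negative quantity in cost ledger")


def total_costs(ledger: pd.DataFrame, modality: str) -> CostSummary:
    """Sum a modality's ledger into total, time, non-time cost and person-days."""
    _check_ledger(ledger)
    sub = ledger[ledger["modality"] == modality].copy()
    if sub.empty:
        empty = pd.DataFrame(0.0, index=list(ACTIVITIES), columns=["time", "non_time"])
        return CostSummary(modality, 0.0, 0.0, 0.0, 0.0, empty)
    sub["cost"] = sub["quantity"].astype(float) * sub["unit_value"].astype(float)
    by = (
        sub.pivot_table(
            index="activity", columns="category", values="cost", aggfunc="sum"
        )
        .reindex(list(ACTIVITIES))
        .reindex(columns=["time", "non_time"])
        .fillna(0.0)
    )
    time_cost = float(by["time"].sum())
    non_time_cost = float(by["non_time"].sum())
    person_days = float(sub.loc[sub["category"] == "time", "quantity"].astype(float).sum())
    return CostSummary(
        modality=modality,
        total_cost=time_cost + non_time_cost,
        time_cost=time_cost,
        non_time_cost=non_time_cost,
        person_days=person_days,
        by_activity=by,
    )


def group_accuracy(mean_24hr: float, mean_wfr: float) -> tuple[float, float]:
    """(percentage error, percentage accuracy) of a group mean vs the benchmark.

    error = 100 x |1 - mean_24hr / mean_wfr|, capped at 100; accuracy is its
    complement. E.g. group means of 3500 (recall) vs 4000 (weighed record)
    give 12.5 % error and 87.5 % accuracy.
    """
    if mean_wfr <= 0:
        raise ValueError("benchmark mean must be > 0")
    error = min(100.0, 100.0 * abs(1.0 - mean_24hr / mean_wfr))
    return error, 100.0 - error


def composite_nutrient_accuracy(per_nutrient: dict[str, float]) -> float:
    """Arithmetic mean of the per-nutrient accuracies (all ten required)."""
    missing = [n for n in NUTRIENTS if n not in per_nutrient]
    if missing:
        raise ValueError(f"missing accuracy for nutrient(s) {missing}")
    return float(np.mean([per_nutrient[n] for n in NUTRIENTS]))


def accuracy_from_intakes(intakes: IntakeTable, arm: str) -> AccuracyMeasures:
    """The three accuracy measures for one arm's recall vs its weighed record."""
    nut = intakes.nutrients
    sub = nut[nut["arm"] == arm]
    if sub.empty:
        raise ValueError(f"no intake rows for arm {arm!r}")
    means = sub.groupby(level="source").mean(numeric_only=True)
    if not {"WFR", "R24"}.issubset(means.index):
        raise ValueError(f"arm {arm!r} lacks one of the two sources")

    _, item_acc = group_accuracy(
        float(means.loc["R24", "item_count"]), float(means.loc["WFR", "item_count"])
    )
    _, gram_acc = group_accuracy(
        float(means.loc["R24", "gram_total"]), float(means.loc["WFR", "gram_total"])
    )
    per_nutrient = {}
    for n in NUTRIENTS:
        _, acc = group_accuracy(float(means.loc["R24", n]), float(means.loc["WFR", n]))
        per_nutrient[n] = acc
    return AccuracyMeasures(
        item_count_accuracy=item_acc,
        gram_accuracy=gram_acc,
        nutrient_accuracy=per_nutrient,
        composite_nutrient_accuracy=composite_nutrient_accuracy(per_nutrient),
    )


def cost_effectiveness(
    costs: CostSummary, accuracy: AccuracyMeasures, scenario: str = "base"
) -> CEResult:
    """Cost per percentage point of accuracy, for every aggregate x measure."""
    aggregates = {
        "total_cost": costs.total_cost,
        "person_days": costs.person_days,
        "time_cost": costs.time_cost,
        "non_time_cost": costs.non_time_cost,
    }
    ratios: dict[str, dict[str, float]] = {}
    for agg_name, agg in aggregates.items():
        ratios[agg_name] = {}
        for meas_name, acc in accuracy.primary().items():
            if acc <= 0:
                raise ValueError(
                    f"accuracy measure {meas_name!r} is zero; ratio undefined"
                )
            ratios[agg_name][meas_name] = agg / acc
    return CEResult(
        modality=costs.modality,
        scenario=scenario,
        costs=costs,
        accuracy=accuracy,
        cost_per_accuracy_point=ratios,
    )


def apply_borrowing_scenario(ledger: pd.DataFrame, borrow_fraction: float) -> pd.DataFrame:
    """Scale CAPI reference-data preparation by (1 - borrow_fraction).

    Models borrowing that share of dietary reference data from an existing
    repository instead of preparing it; the PAPI ledger is untouched.
    """
    if not 0.0 <= borrow_fraction < 1.0:
        raise ValueError("borrow_fraction must be in [0, 1)")
    _check_ledger(ledger)
    mask = (ledger["modality"] == "CAPI") & (ledger["activity"] == "reference_data_prep")
    if not mask.any():
        raise ValueError("ledger has no CAPI reference_data_prep activity")
    out = ledger.copy()
    out.loc[mask, "quantity"] = out.loc[mask, "quantity"].astype(float) * (
        1.0 - borrow_fraction
    )
    return out
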