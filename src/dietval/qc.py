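"""Outlier flagging, exclusions, and skewness-correcting transforms.

Before any method comparison, daily energy intakes are screened against the
conventional plausibility bounds for a single day — below 500 kcal
(2092 kJ) or above 5000 kcal (20 920 kJ) — and each recall day is checked
against its weighed-record partner for a discrepancy exceeding 1000 kcal
(4184 kJ). All three comparisons are strict: a day at exactly 500 or
5000 kcal is not flagged. The default exclusion policy drops a respondent
entirely when their *weighed record* energy is implausible (the benchmark
itself is untrustworthy) while pair-discrepancy flags are logged for review
but the respondents retained.

Nutrient intake distributions are right-skewed, so group-level tests run on
transformed values: natural log when all values are positive, cube root
when zeros are present (log is undefined at 0). Both transforms are
strictly increasing, so ranks and band membership are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intake import IntakeTable

__all__ = [
    "QCFlag",
    "ExclusionPolicy",
    "TransformResult",
    "flag_records",
    "apply_exclusions",
    "select_transform",
    "ENERGY_LOW_KCAL",
    "ENERGY_HIGH_KCAL",
    "PAIR_DISCREPANCY_KCAL",
]

ENERGY_LOW_KCAL = 500.0
ENERGY_HIGH_KCAL = 5000.0
PAIR_DISCREPANCY_KCAL = 1000.0


@dataclass(frozen=True)
class QCFlag:
    respondent_id: str
    source: str
    flag_kind: str  # energy_low | energy_high | pair_discrepancy
    value: float  # the energy (kcal) or |pair difference| that tripped the flag


@dataclass(frozen=True)
class ExclusionPolicy:
    """Which flags exclude a respondent outright (the rest are logged only).

    The default reproduces the convention of excluding respondents whose
    benchmark (WFR) energy is implausible, while retaining pair-discrepancy
    respondents in the data set.
    """

    exclude_kinds: tuple[str, ...] = ("energy_low", "energy_high")
    exclude_sources: tuple[str, ...] = ("WFR",)


@dataclass(frozen=True)
class TransformResult:
    name: str  # "log" | "cube_root"
    transformed: np.ndarray


def flag_records(intakes: IntakeTable) -> list[QCFlag]:
    """Flag implausible energies and large WFR/R24 discrepancies.

    Every 24HR row must have a WFR partner (pairing is mandatory in this
    design); a missing partner raises.
    """
    flags: list[QCFlag] = []
    energy = intakes.nutrients["energy_kcal"]
    for (rid, source), kcal in energy.items():
        if kcal < ENERGY_LOW_KCAL:
            flags.append(QCFlag(rid, source, "energy_low", float(kcal)))
        elif kcal > ENERGY_HIGH_KCAL:
            flags.append(QCFlag(rid, source, "energy_high", float(kcal)))

    wide = energy.unstack("source")
    if "R24" in wide.columns:
        missing_partner = wide.index[wide["R24"].notna() & wide.get("WFR", pd.Series(dtype=float)).isna()]
        if len(missing_partner):
            raise ValueError(
                f"respondent(s) {list(missing_partner)} have a 24HR day but no WFR partner"
            )
        both = wide.dropna(subset=["WFR", "R24"])
        diff = (both["R24"] - both["WFR"]).abs()
        for rid, d in diff[diff > PAIR_DISCREPANCY_KCAL].items():
            flags.append(QCFlag(rid, "R24", "pair_discrepancy", float(d)))
    return flags


def apply_exclusions(
    intakes: IntakeTable,
    flags: list[QCFlag],
    policy: ExclusionPolicy = ExclusionPolicy(),
) -> tuple[IntakeTable, pd.DataFrame]:
    """Drop respondents per policy; log every flag with the action taken.

    Returns the filtered table and a log frame (respondent_id, source,
    flag_kind, value, action) where action is ``excluded`` or ``retained``.
    Retained + excluded respondents partition the input.
    """
    excluded: set[str] = set()
    log_rows = []
    for f in flags:
        exclude = (
            f.flag_kind in policy.exclude_kinds and f.source in policy.exclude_sources
        )
        if exclude:
            excluded.add(f.respondent_id)
        log_rows.append(
            {
                "respondent_id": f.respondent_id,
                "source": f.source,
                "flag_kind": f.flag_kind,
                "value": f.value,
                "action": "excluded" if exclude else "retained",
            }
        )
    log = pd.DataFrame(
        log_rows, columns=["respondent_id", "source", "flag_kind", "value", "action"]
    )
    keep = ~intakes.nutrients.index.get_level_values("respondent_id").isin(excluded)
    keep_g = ~intakes.group_energy.index.get_level_values("respondent_id").isin(excluded)
    filtered = IntakeTable(
        nutrients=intakes.nutrients[keep].copy(),
        group_energy=intakes.group_energy[keep_g].copy(),
    )
    return filtered, log


def select_transform(values: np.ndarray | pd.Series) -> TransformResult:
    """Choose and apply the skewness-correcting transform.

    Natural log if all values are strictly positive, cube root otherwise
    (zero intakes — e.g. a day with no vitamin C source — make the log
    undefined). Negative intakes are impossible and raise.
    """
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("intake values cannot be negative")
    if np.all(arr > 0):
        return TransformResult("log", np.log(arr))
    return TransformResult("cube_root", np.cbrt(arr))
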