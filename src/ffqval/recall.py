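"""Harmonisation of repeated 24-hour recall days to the questionnaire space.

Each recall day is a list of consumed items with gram amounts and eating
occasions, mapped (many-to-one) onto the questionnaire's category space.  The
reference-method quantities are

* per-category daily frequencies: total occasions across days divided by the
  number of completed days (:func:`recall_daily_frequencies`), and
* daily energy/nutrient intakes: amount-weighted composition totals divided by
  the number of days (:func:`recall_nutrients`).

The long cohort format is one row per (participant, day, food):
``participant_id, day, food_id, amount_g, occasions``.  Days with no items
still count as completed days when listed in the participants' completed-day
counts — a fasting day is information.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, RecordValidationError
from .schema import FFQSchema

RECALL_COLUMNS = ("participant_id", "day", "food_id", "amount_g", "occasions")


@dataclass(frozen=True)
class RecallItem:
    food_id: str
    amount_g: float
    occasions: float = 1.0

    def __post_init__(self) -> None:
        if self.amount_g < 0:
            raise RecordValidationError(f"food {self.food_id!r}: negative amount")
        if self.occasions < 0:
            raise RecordValidationError(f"food {self.food_id!r}: negative occasions")


@dataclass(frozen=True)
class RecallDay:
    participant_id: str
    day: int
    items: tuple[RecallItem, ...] = ()
    date_class: str = "weekday"  # {weekday, weekend}


def identity_map(schema: FFQSchema) -> dict[str, str]:
    """Food-to-category map for data whose food ids are already category ids."""
    return {i: i for i in schema.item_ids}


def _map_foods(food_ids: np.ndarray, food_map: Mapping[str, str], schema: FFQSchema) -> np.ndarray:
    cats = np.empty(food_ids.shape, dtype=object)
    valid = set(schema.item_ids)
    for i, fid in enumerate(food_ids):
        try:
            cat = food_map[fid]
        except KeyError:
            raise CoverageError(f"food {fid!r} has no category mapping") from None
        if cat not in valid:
            raise CoverageError(f"food {fid!r} maps to unknown category {cat!r}")
        cats[i] = cat
    return cats


def recall_daily_frequencies(
    days: Sequence[RecallDay],
    food_map: Mapping[str, str],
    schema: FFQSchema,
) -> pd.Series:
    """Per-category intakes/day for one participant's completed recall days.

    Total occasion count per category across all days, divided by the number
    of days.  Only totals and day counts matter — the partition of occasions
    across days is irrelevant.
    """
    if len(days) == 0:
        raise RecordValidationError("no completed recall days")
    pid = days[0].participant_id
    totals = pd.Series(0.0, index=schema.item_ids)
    for day in days:
        if day.participant_id != pid:
            raise RecordValidationError("recall days belong to different participants")
        for it in day.items:
            cat = _map_foods(np.array([it.food_id]), food_map, schema)[0]
            totals[cat] += it.occasions
    # rounding at 1e-12 keeps sum-over-days / days exact for repeated
    # identical days, so spurious floating-point rank ties cannot arise
    out = (totals / len(days)).round(12)
    out.name = pid
    out.attrs["source"] = "recall"
    out.attrs["n_days"] = len(days)
    return out


def cohort_recall_frequencies(
    recalls: pd.DataFrame,
    food_map: Mapping[str, str],
    schema: FFQSchema,
    n_days: pd.Series,
) -> pd.DataFrame:
    """Vectorised daily frequencies for a long-format recall frame.

    ``n_days`` gives completed-day counts per participant (the divisor); it
    also fixes the participant set of the result, so participants whose days
    contained no mapped foods still get all-zero rows.
    """
    for col in RECALL_COLUMNS[:3] + ("occasions",):
        if col not in recalls.columns:
            raise RecordValidationError(f"recall frame missing column {col!r}")
    if (n_days <= 0).any():
        bad = n_days.index[n_days <= 0][0]
        raise RecordValidationError(f"participant {bad}: no completed recall days")
    cats = _map_foods(recalls["food_id"].to_numpy(dtype=object), food_map, schema)
    df = recalls[["participant_id", "occasions"]].copy()
    df["category_id"] = cats
    totals = (
        df.pivot_table(
            index="participant_id",
            columns="category_id",
            values="occasions",
            aggfunc="sum",
            fill_value=0.0,
        )
        .reindex(index=n_days.index, columns=schema.item_ids, fill_value=0.0)
    )
    out = totals.div(n_days, axis=0).round(12)  # see recall_daily_frequencies
    out.attrs["source"] = "recall"
    return out


def recall_nutrients(
    days: Sequence[RecallDay],
    composition: "pd.DataFrame",
    food_map: Mapping[str, str] | None = None,
) -> pd.Series:
    """Daily energy/nutrient totals for one participant's recall days.

    ``composition`` is indexed by food/category id with contents per 100 g
    (see :class:`ffqval.nutrients.FoodCompositionTable`; pass its ``.table``).
    When ``food_map`` is given, foods are mapped to categories before the
    composition lookup; otherwise food ids index the table directly.
    """
    if len(days) == 0:
        raise RecordValidationError("no completed recall days")
    totals = pd.Series(0.0, index=composition.columns)
    for day in days:
        for it in day.items:
            key = food_map[it.food_id] if food_map is not None else it.food_id
            if key not in composition.index:
                raise CoverageError(f"food {it.food_id!r} has no composition entry")
            totals += composition.loc[key] * (it.amount_g / 100.0)
    out = totals / len(days)
    out.name = days[0].participant_id
    out.attrs["source"] = "recall"
    return out


def cohort_recall_nutrients(
    recalls: pd.DataFrame,
    composition: pd.DataFrame,
    n_days: pd.Series,
    food_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Vectorised nutrient totals: participants x (energy + nutrients)."""
    keys = recalls["food_id"].to_numpy(dtype=object)
    if food_map is not None:
        keys = np.array([food_map.get(k, k) for k in keys], dtype=object)
    unknown = [k for k in np.unique(keys.astype(str)) if k not in composition.index]
    if unknown:
        raise CoverageError(f"foods without composition entry: {unknown[:5]}")
    comp = composition.loc[keys].to_numpy(dtype=float)
    contrib = comp * (recalls["amount_g"].to_numpy(dtype=float)[:, None] / 100.0)
    df = pd.DataFrame(contrib, columns=composition.columns)
    df["participant_id"] = recalls["participant_id"].to_numpy()
    totals = (
        df.groupby("participant_id")
        .sum()
        .reindex(index=n_days.index, fill_value=0.0)
    )
    out = totals.div(n_days, axis=0)
    out.attrs["source"] = "recall"
    return out


@dataclass(frozen=True)
class AttritionReport:
    """Participant counts at each attrition step of the recall-day filter."""

    consented: int
    at_least_one_day: int
    at_least_min_days: int
    min_days: int

    def as_dict(self) -> dict[str, int]:
        return {
            "consented": self.consented,
            "at_least_one_day": self.at_least_one_day,
            f"at_least_{self.min_days}_days": self.at_least_min_days,
        }


def inclusion_filter(
    participants: pd.DataFrame,
    min_days: int = 4,
) -> tuple[pd.DataFrame, AttritionReport]:
    """Keep participants with at least ``min_days`` completed recall days.

    Returns the retained subset (row order preserved) and the attrition
    counts (consented, >=1 day, >=min_days).
    """
    if min_days < 1:
        raise RecordValidationError("min_days must be >= 1")
    days = participants["completed_recall_days"]
    report = AttritionReport(
        consented=len(participants),
        at_least_one_day=int((days >= 1).sum()),
        at_least_min_days=int((days >= min_days).sum()),
        min_days=min_days,
    )
    return participants[days >= min_days], report
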