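"""Processing of raw frequency-questionnaire records.

Three operations turn a raw record into analysable quantities:

* :func:`frequencies_to_daily` maps the nine ordinal frequency levels onto
  representative intakes/day (0 to 4) through a :class:`~ffqval.schema.FrequencyMapping`;
  missing answers are imputed as 0 intakes/day and flagged.
* :func:`assign_exclude_level` applies the three-tier data-quality score:
  level 2 when any portion-photo indication is unanswered, level 1 when the
  portions are complete but >=10% of the questions are missing, level 0
  otherwise (usable for analysis).
* :func:`assign_portion_sizes` resolves a per-category portion in grams from
  the portion-photo indication (starch/protein/vegetable plates), a natural
  unit size (an egg, a glass), or the sex x 10-year-age-band median table.

Cohort-level variants (``cohort_*``) operate on a wide DataFrame with one row
per participant and one column per schema item (level codes 1-9, NaN for
missing) plus ``portion_starch``/``portion_protein``/``portion_vegetable``
columns, and are what the pipeline uses.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import CoverageError, RecordValidationError
from .participants import ParticipantProfile
from .schema import PHOTO_CLASSES, PHOTO_LEVELS, FFQSchema, FrequencyMapping, PortionTable

PORTION_COLUMNS = tuple(f"portion_{c}" for c in PHOTO_CLASSES)

#: missing-answer fraction at or above which a record drops to exclude level 1
MISSING_FRACTION_THRESHOLD = 0.10


@dataclass(frozen=True)
class FFQRecord:
    """One participant's raw questionnaire responses.

    ``responses`` maps item id -> frequency level code (1..9) or ``None``;
    ``portion_indications`` maps plate class -> photo level (1..4) or ``None``.
    """

    participant_id: str
    responses: Mapping[str, int | None]
    portion_indications: Mapping[str, int | None] = field(
        default_factory=lambda: {c: None for c in PHOTO_CLASSES}
    )

    def validate(self, schema: FFQSchema) -> None:
        n_levels = len(schema.frequency_levels)
        for item_id, code in self.responses.items():
            if code is None:
                continue
            if not 1 <= int(code) <= n_levels:
                raise RecordValidationError(
                    f"participant {self.participant_id}: item {item_id!r} has "
                    f"response level {code} outside 1-{n_levels}"
                )
        for cls_, lvl in self.portion_indications.items():
            if lvl is not None and lvl not in PHOTO_LEVELS:
                raise RecordValidationError(
                    f"participant {self.participant_id}: portion indication "
                    f"{cls_!r}={lvl} outside 1-4"
                )


@dataclass(frozen=True)
class QualityAssessment:
    """Three-tier exclusion score for one record."""

    participant_id: str
    exclude_level: int
    missing_fraction: float
    portion_complete: bool


def frequencies_to_daily(
    record: FFQRecord,
    mapping: FrequencyMapping,
    schema: FFQSchema,
) -> pd.Series:
    """Daily intake frequencies (intakes/day) for one record.

    Returns a Series indexed by schema item id.  Missing answers are imputed
    as 0 intakes/day; the set of imputed items is available as
    ``result.attrs["imputed_items"]`` and the source is tagged in
    ``result.attrs["source"]``.
    """
    record.validate(schema)
    values = np.empty(len(schema), dtype=float)
    imputed = []
    arr = mapping.array
    for i, item_id in enumerate(schema.item_ids):
        code = record.responses.get(item_id)
        if code is None or (isinstance(code, float) and np.isnan(code)):
            values[i] = 0.0
            imputed.append(item_id)
        else:
            values[i] = arr[int(code) - 1]
    # daily frequencies are rounded at 1e-12 on both the questionnaire and
    # recall paths so identical-by-construction values are identical floats
    out = pd.Series(values.round(12), index=schema.item_ids, name=record.participant_id)
    out.attrs["source"] = "ffq"
    out.attrs["imputed_items"] = imputed
    return out


def cohort_frequencies_to_daily(
    records: pd.DataFrame,
    mapping: FrequencyMapping,
    schema: FFQSchema,
) -> pd.DataFrame:
    """Vectorised :func:`frequencies_to_daily` over a wide cohort frame.

    ``records`` must contain one column per schema item holding level codes
    1..9 (NaN = missing).  Returns a participants x categories frame of
    intakes/day with ``attrs["source"] = "ffq"`` and the boolean imputation
    mask in ``attrs["imputed"]``.
    """
    missing_cols = [c for c in schema.item_ids if c not in records.columns]
    if missing_cols:
        raise RecordValidationError(f"records missing item columns: {missing_cols[:5]}...")
    codes = records[schema.item_ids].to_numpy(dtype=float)
    bad = (codes < 1) | (codes > len(schema.frequency_levels))
    if np.any(bad & ~np.isnan(codes)):
        i, j = np.argwhere(bad & ~np.isnan(codes))[0]
        raise RecordValidationError(
            f"participant {records.index[i]}: item {schema.item_ids[j]!r} has "
            f"response level {codes[i, j]:g} outside the scale"
        )
    imputed = np.isnan(codes)
    idx = np.where(imputed, 1, codes).astype(int) - 1
    freqs = mapping.array[idx]
    freqs[imputed] = 0.0
    # same 1e-12 rounding as the recall path; see frequencies_to_daily
    out = pd.DataFrame(freqs.round(12), index=records.index, columns=schema.item_ids)
    out.attrs["source"] = "ffq"
    out.attrs["imputed"] = pd.DataFrame(imputed, index=records.index, columns=schema.item_ids)
    return out


def assign_exclude_level(record: FFQRecord, schema: FFQSchema) -> QualityAssessment:
    """Classify one record into exclude level 0, 1 or 2.

    Level 2: any portion indication unanswered.  Level 1: portions complete
    but the missing-answer fraction is >= 10% of the schema items.  Level 0:
    neither — the record is usable.
    """
    record.validate(schema)
    n_missing = sum(
        1
        for item_id in schema.item_ids
        if record.responses.get(item_id) is None
    )
    missing_fraction = n_missing / len(schema)
    portion_complete = all(
        record.portion_indications.get(c) is not None for c in PHOTO_CLASSES
    )
    if not portion_complete:
        level = 2
    elif missing_fraction >= MISSING_FRACTION_THRESHOLD:
        level = 1
    else:
        level = 0
    return QualityAssessment(
        participant_id=record.participant_id,
        exclude_level=level,
        missing_fraction=missing_fraction,
        portion_complete=portion_complete,
    )


def cohort_exclude_levels(records: pd.DataFrame, schema: FFQSchema) -> pd.DataFrame:
    """Exclude level, missing fraction and portion completeness per participant."""
    codes = records[schema.item_ids].to_numpy(dtype=float)
    missing_fraction = np.isnan(codes).mean(axis=1)
    pcols = records.reindex(columns=list(PORTION_COLUMNS)).to_numpy(dtype=float)
    portion_complete = ~np.isnan(pcols).any(axis=1)
    level = np.where(
        ~portion_complete, 2, np.where(missing_fraction >= MISSING_FRACTION_THRESHOLD, 1, 0)
    )
    return pd.DataFrame(
        {
            "exclude_level": level,
            "missing_fraction": missing_fraction,
            "portion_complete": portion_complete,
        },
        index=records.index,
    )


def assign_portion_sizes(
    record: FFQRecord,
    portions: PortionTable,
    participant: ParticipantProfile,
    schema: FFQSchema,
    *,
    default_impute: bool = False,
) -> pd.Series:
    """Per-category portion in grams for one participant.

    Photo classes use the indicated plate level; ``fixed_natural`` categories
    use their natural-unit grams; everything else is looked up in the
    sex x age-band median table.  A missing photo indication raises
    :class:`~ffqval.errors.CoverageError` (the record is exclude level 2)
    unless ``default_impute`` is set, in which case photo level 2 is assumed
    and recorded in ``result.attrs["imputed_classes"]``.
    """
    grams = np.empty(len(schema), dtype=float)
    imputed_classes = []
    for i, item in enumerate(schema.items):
        if item.portion_class in PHOTO_CLASSES:
            lvl = record.portion_indications.get(item.portion_class)
            if lvl is None:
                if not default_impute:
                    raise CoverageError(
                        f"participant {record.participant_id}: portion indication "
                        f"{item.portion_class!r} missing (exclude level 2 record); "
                        "nutrient estimation blocked unless default_impute=True"
                    )
                lvl = 2
                if item.portion_class not in imputed_classes:
                    imputed_classes.append(item.portion_class)
            grams[i] = portions.photo_grams(item.portion_class, int(lvl))
        elif item.portion_class == "fixed_natural":
            grams[i] = float(item.natural_unit_g)
        else:  # "none" -> median table
            grams[i] = portions.median_portion(participant.sex, participant.age, item)
    out = pd.Series(grams, index=schema.item_ids, name=record.participant_id)
    out.attrs["imputed_classes"] = imputed_classes
    return out


def cohort_portion_sizes(
    records: pd.DataFrame,
    portions: PortionTable,
    participants: pd.DataFrame,
    schema: FFQSchema,
    *,
    default_impute: bool = False,
) -> pd.DataFrame:
    """Vectorised portion assignment: participants x categories grams."""
    n = len(records)
    grams = np.empty((n, len(schema)), dtype=float)
    part = participants.loc[records.index]
    sexes = part["sex"].to_numpy()
    ages = part["age"].to_numpy(dtype=float)
    for j, item in enumerate(schema.items):
        if item.portion_class in PHOTO_CLASSES:
            col = f"portion_{item.portion_class}"
            lvls = records[col].to_numpy(dtype=float) if col in records else np.full(n, np.nan)
            if np.isnan(lvls).any() and not default_impute:
                who = records.index[np.isnan(lvls)][0]
                raise CoverageError(
                    f"participant {who}: portion indication {item.portion_class!r} "
                    "missing (exclude level 2 record)"
                )
            lvls = np.where(np.isnan(lvls), 2, lvls).astype(int)
            table = np.asarray(portions.photo_levels[item.portion_class], dtype=float)
            grams[:, j] = table[lvls - 1]
        elif item.portion_class == "fixed_natural":
            grams[:, j] = float(item.natural_unit_g)
        else:
            grams[:, j] = [
                portions.median_portion(s, a, item) for s, a in zip(sexes, ages)
            ]
    return pd.DataFrame(grams, index=records.index, columns=schema.item_ids)
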