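"""Questionnaire schema, frequency mapping and portion tables.

The questionnaire is a semi-quantitative food frequency instrument: a fixed,
ordered list of food categories (108 in the packaged default), each answered
on a nine-level ordinal frequency scale, plus three portion-photo indications
(levels 1-4) for starch, protein and vegetable plate sizes.  This module holds
the static description of that instrument and the deterministic lookup tables
used to turn responses into quantities:

* :class:`FFQSchema` — the ordered item list with portion classes and the
  nine frequency-level labels;
* :class:`FrequencyMapping` — ordinal level -> representative intakes/day;
* :class:`PortionTable` — photo-level gram values per plate class, natural
  unit sizes, and the sex x 10-year-age-band median portion table used for
  categories without a photo or natural unit.

Packaged defaults load from ``ffqval/resources`` via :func:`FFQSchema.default`
etc.; every table can be replaced by a user-supplied YAML/CSV with the same
layout.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as _ilr
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, CoverageError

PORTION_CLASSES = ("starch", "protein", "vegetable", "fixed_natural", "none")
PHOTO_CLASSES = ("starch", "protein", "vegetable")
PHOTO_LEVELS = (1, 2, 3, 4)

#: 10-year age bands used by the median-portion lookup
AGE_BANDS = ("18-29", "30-39", "40-49", "50-59", "60-69", "70+")


def age_band(age: float) -> str:
    """Return the 10-year age band label for an adult age in years."""
    if age < 18:
        raise ConfigurationError(f"age {age} below adult range")
    if age >= 70:
        return "70+"
    if age < 30:
        return "18-29"
    lo = int(age // 10) * 10
    return f"{lo}-{lo + 9}"


def _resource_text(name: str) -> str:
    return _ilr.files("ffqval.resources").joinpath(name).read_text()


@dataclass(frozen=True)
class FFQItem:
    """One question of the frequency questionnaire."""

    id: str
    label: str
    group: str
    portion_class: str
    natural_unit_g: float | None = None
    base_portion_g: float = 100.0
    # synthetic-cohort parameters (latent habitual-intake model)
    median_freq_per_day: float = 0.1
    freq_gsd: float = 2.0
    zero_prob: float = 0.1

    def __post_init__(self) -> None:
        if self.portion_class not in PORTION_CLASSES:
            raise ConfigurationError(
                f"item {self.id!r}: unknown portion class {self.portion_class!r}"
            )
        if self.portion_class == "fixed_natural" and not self.natural_unit_g:
            raise ConfigurationError(
                f"item {self.id!r}: fixed_natural class requires natural_unit_g"
            )


@dataclass(frozen=True)
class FFQSchema:
    """Ordered item list plus the ordinal frequency-level labels."""

    items: tuple[FFQItem, ...]
    frequency_levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.frequency_levels) != 9:
            raise ConfigurationError(
                f"expected nine frequency levels, got {len(self.frequency_levels)}"
            )
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate item ids in schema")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.id for it in self.items]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for it in self.items:
            seen.setdefault(it.group, None)
        return list(seen)

    def item(self, item_id: str) -> FFQItem:
        try:
            return next(it for it in self.items if it.id == item_id)
        except StopIteration:
            raise KeyError(f"unknown item id {item_id!r}") from None

    @classmethod
    def from_dict(cls, doc: Mapping) -> "FFQSchema":
        items = tuple(FFQItem(**row) for row in doc["items"])
        return cls(items=items, frequency_levels=tuple(doc["frequency_levels"]))

    @classmethod
    def from_yaml(cls, path) -> "FFQSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "FFQSchema":
        """The packaged 108-item, 30-group default schema."""
        return cls.from_dict(yaml.safe_load(_resource_text("ffq_schema.yaml")))


@dataclass(frozen=True)
class FrequencyMapping:
    """Representative daily intake frequency for each ordinal level.

    The mapping must be monotone non-decreasing, start at 0 ("never") and end
    at 4 intakes/day (the instrument's top category, "4 times a day or more").
    Interior values are a convention; the packaged default uses arithmetic
    midpoints of each level's stated range.
    """

    levels: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.values):
            raise ConfigurationError("levels and values length mismatch")
        v = np.asarray(self.values, dtype=float)
        if np.any(np.diff(v) < 0):
            raise ConfigurationError("frequency mapping must be monotone non-decreasing")
        if v[0] != 0.0:
            raise ConfigurationError('level "never" must map to 0 intakes/day')
        if v[-1] != 4.0:
            raise ConfigurationError("top level must map to 4 intakes/day")

    def __len__(self) -> int:
        return len(self.levels)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def value_for(self, level: str) -> float:
        try:
            return self.values[self.levels.index(level)]
        except ValueError:
            raise KeyError(f"unknown frequency level {level!r}") from None

    def nearest_level_index(self, freq) -> np.ndarray:
        """Index of the level whose representative value is nearest to ``freq``.

        Ties go to the lower category; frequencies above the scale truncate to
        the top level.  Vectorised over ``freq``.
        """
        f = np.atleast_1d(np.asarray(freq, dtype=float))
        d = np.abs(f[:, None] - self.array[None, :])
        # argmin returns the first (= lower) index on ties
        return np.argmin(d, axis=1)

    @classmethod
    def from_dict(cls, doc: Mapping[str, float]) -> "FrequencyMapping":
        return cls(levels=tuple(doc.keys()), values=tuple(float(x) for x in doc.values()))

    @classmethod
    def from_yaml(cls, path) -> "FrequencyMapping":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "FrequencyMapping":
        return cls.from_dict(yaml.safe_load(_resource_text("frequency_mapping.yaml")))


@dataclass(frozen=True)
class PortionTable:
    """Gram values behind the three portion-assignment routes.

    ``photo_levels`` maps each plate class (starch/protein/vegetable) to four
    increasing gram values, one per photo level.  Categories with a natural
    unit (an egg, an apple, a glass) carry their grams on the schema item.
    Every remaining category falls back on a sex x 10-year-age-band median
    table; the packaged default materialises that table from each item's base
    portion and multiplicative sex/age factors, and a fully explicit CSV
    (columns sex, age_band, category_id, portion_g) can be supplied instead.
    """

    photo_levels: Mapping[str, Sequence[float]]
    sex_factor: Mapping[str, float] = field(default_factory=lambda: {"male": 1.0, "female": 1.0})
    age_band_factor: Mapping[str, float] = field(default_factory=lambda: {b: 1.0 for b in AGE_BANDS})
    median_table: pd.DataFrame | None = None  # overrides factors when given

    def __post_init__(self) -> None:
        for cls_ in PHOTO_CLASSES:
            if cls_ not in self.photo_levels:
                raise CoverageError(f"portion table missing photo class {cls_!r}")
            vals = list(self.photo_levels[cls_])
            if len(vals) != 4:
                raise ConfigurationError(f"photo class {cls_!r} needs 4 levels")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ConfigurationError(
                    f"photo class {cls_!r} gram values must be strictly increasing"
                )

    def photo_grams(self, plate_class: str, level: int) -> float:
        if plate_class not in self.photo_levels:
            raise CoverageError(f"no photo table for class {plate_class!r}")
        if level not in PHOTO_LEVELS:
            raise CoverageError(f"photo level {level!r} outside 1-4 for class {plate_class!r}")
        return float(self.photo_levels[plate_class][level - 1])

    def median_portion(self, sex: str, age: float, item: FFQItem) -> float:
        band = age_band(age)
        if self.median_table is not None:
            sel = self.median_table[
                (self.median_table["sex"] == sex)
                & (self.median_table["age_band"] == band)
                & (self.median_table["category_id"] == item.id)
            ]
            if sel.empty:
                raise CoverageError(
                    f"median portion table missing ({sex}, {band}, {item.id})"
                )
            return float(sel["portion_g"].iloc[0])
        try:
            return float(item.base_portion_g * self.sex_factor[sex] * self.age_band_factor[band])
        except KeyError as exc:
            raise CoverageError(f"median portion factors missing {exc.args[0]!r}") from None

    def materialised_median_table(self, schema: FFQSchema) -> pd.DataFrame:
        """Explicit (sex, age_band, category_id, portion_g) table."""
        rows = []
        for sex in self.sex_factor:
            for band in AGE_BANDS:
                for it in schema.items:
                    age = 75.0 if band == "70+" else float(int(band.split("-")[0]) + 1)
                    rows.append((sex, band, it.id, self.median_portion(sex, age, it)))
        return pd.DataFrame(rows, columns=["sex", "age_band", "category_id", "portion_g"])

    @classmethod
    def from_dict(cls, doc: Mapping) -> "PortionTable":
        return cls(
            photo_levels={k: tuple(float(x) for x in v) for k, v in doc["photo_levels"].items()},
            sex_factor=dict(doc.get("sex_factor", {"male": 1.0, "female": 1.0})),
            age_band_factor=dict(doc.get("age_band_factor", {b: 1.0 for b in AGE_BANDS})),
        )

    @classmethod
    def from_yaml(cls, path) -> "PortionTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "PortionTable":
        return cls.from_dict(yaml.safe_load(_resource_text("portion_tables.yaml")))


def load_food_group_mapping(path=None) -> dict[str, list[str]]:
    """Food-group mapping: group id -> member category ids (30 groups default)."""
    if path is None:
        doc = yaml.safe_load(_resource_text("food_groups.yaml"))
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or not doc:
        raise ConfigurationError("food group mapping must be a non-empty mapping")
    seen: dict[str, str] = {}
    for g, members in doc.items():
        if not members:
            raise ConfigurationError(f"food group {g!r} is empty")
        for m in members:
            if m in seen:
                raise ConfigurationError(
                    f"category {m!r} appears in groups {seen[m]!r} and {g!r}"
                )
            seen[m] = g
    return {g: list(members) for g, members in doc.items()}
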