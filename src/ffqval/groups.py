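"""Food-group aggregation and a priori diet-index scoring.

The 108 questionnaire categories aggregate by exact summation into 30 food
groups (:func:`aggregate_food_groups`), the common unit of the validity
analyses.  Three a priori diet-quality indices are scored from ranked group
intakes (:func:`score_index`):

* rMED — relative Mediterranean diet score: 9 components, tertiles scored
  0-2, meat and dairy reverse-scored, alcohol as a moderate-range criterion;
* HNFI — healthy Nordic food index: 6 components, 1 point at/above the
  cohort median;
* PDI — plant-based diet index: 18 components, quintiles 1-5, animal groups
  reverse-scored.

The component lists, cut rules and point assignments are data (shipped YAML
under ``ffqval/resources/index_specs``), not code: any published
operationalisation can be dropped in.  Rank-class cutoffs are computed within
the scoring cohort — and so are method-specific when each method's intakes
are scored separately — with values equal to a cutoff assigned to the higher
rank class (the "at/above median" convention).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources as _ilr
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError

RANK_RULES = {"median": 1, "tertile": 2, "quintile": 4}  # rule -> number of cutoffs


def aggregate_food_groups(
    intakes: pd.DataFrame | pd.Series,
    mapping: Mapping[str, Sequence[str]],
) -> pd.DataFrame | pd.Series:
    """Sum per-category intakes into food groups (exact sums).

    ``intakes`` is a participants x categories frame (or a single Series);
    ``mapping`` maps group id -> member category ids.  Group order follows the
    mapping.  A group referencing an unknown category is a configuration
    error.
    """
    single = isinstance(intakes, pd.Series)
    frame = intakes.to_frame().T if single else intakes
    known = set(frame.columns)
    for g, members in mapping.items():
        unknown = [m for m in members if m not in known]
        if unknown:
            raise ConfigurationError(
                f"food group {g!r} references unknown categories {unknown}"
            )
    # summation runs over a C-contiguous copy so the floating-point result is
    # independent of the input frame's memory layout (identical inputs from
    # different sources must aggregate to identical floats)
    out = pd.DataFrame(
        {
            g: np.ascontiguousarray(
                frame[list(members)].to_numpy(dtype=float)
            ).sum(axis=1)
            for g, members in mapping.items()
        },
        index=frame.index,
    )
    out.attrs.update(frame.attrs)
    if single:
        s = out.iloc[0]
        s.name = intakes.name
        s.attrs.update(intakes.attrs)
        return s
    return out


@dataclass(frozen=True)
class IndexComponent:
    """One scored component of a diet index."""

    name: str
    groups: tuple[str, ...]
    rule: str  # {median, tertile, quintile, range}
    direction: str = "+"
    points: tuple[int, ...] = ()
    range: Mapping[str, Sequence[float]] | Sequence[float] | None = None
    points_in: int = 2
    points_out: int = 0

    def __post_init__(self) -> None:
        if self.rule == "range":
            if self.range is None:
                raise ConfigurationError(f"component {self.name!r}: range rule needs bounds")
            return
        if self.rule not in RANK_RULES:
            raise ConfigurationError(f"component {self.name!r}: unknown rule {self.rule!r}")
        n_classes = RANK_RULES[self.rule] + 1
        if len(self.points) != n_classes:
            raise ConfigurationError(
                f"component {self.name!r}: {self.rule} rule needs "
                f"{n_classes} point values, got {len(self.points)}"
            )
        if self.direction not in ("+", "-"):
            raise ConfigurationError(f"component {self.name!r}: direction must be + or -")


@dataclass(frozen=True)
class DietIndexSpec:
    """A complete diet-index definition (components are data, not code)."""

    id: str
    components: tuple[IndexComponent, ...]
    description: str = ""
    stratification: str = "none"  # {none, sex}

    def __post_init__(self) -> None:
        if self.stratification not in ("none", "sex"):
            raise ConfigurationError(
                f"index {self.id!r}: unknown stratification {self.stratification!r}"
            )

    @property
    def score_range(self) -> tuple[int, int]:
        lo = hi = 0
        for c in self.components:
            if c.rule == "range":
                lo += min(c.points_in, c.points_out)
                hi += max(c.points_in, c.points_out)
            else:
                lo += min(c.points)
                hi += max(c.points)
        return lo, hi

    @classmethod
    def from_dict(cls, doc: Mapping) -> "DietIndexSpec":
        comps = []
        for c in doc["components"]:
            c = dict(c)
            comps.append(
                IndexComponent(
                    name=c["name"],
                    groups=tuple(c["groups"]),
                    rule=c["rule"],
                    direction=c.get("direction", "+"),
                    points=tuple(c.get("points", ())),
                    range=c.get("range"),
                    points_in=c.get("points_in", 2),
                    points_out=c.get("points_out", 0),
                )
            )
        return cls(
            id=doc["id"],
            components=tuple(comps),
            description=doc.get("description", ""),
            stratification=doc.get("stratification", "none"),
        )

    @classmethod
    def from_yaml(cls, path) -> "DietIndexSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls, index_id: str) -> "DietIndexSpec":
        """Load a packaged default spec: ``rmed``, ``hnfi`` or ``pdi``."""
        name = index_id.lower()
        text = _ilr.files("ffqval.resources").joinpath(f"index_specs/{name}.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))


def default_index_specs() -> dict[str, DietIndexSpec]:
    return {k: DietIndexSpec.default(k) for k in ("rmed", "hnfi", "pdi")}


def _rank_classes(values: np.ndarray, n_cutoffs: int, component: str) -> np.ndarray:
    """Rank class per value: cutoffs at equally spaced quantiles, ties up.

    Cutoffs are linear-interpolation quantiles of the scoring cohort; a value
    equal to a cutoff goes to the higher class.  A constant component
    degenerates: everyone lands in the lowest class and a warning is issued.
    """
    if np.max(values) == np.min(values):
        warnings.warn(
            f"diet-index component {component!r} has no variation; "
            "all participants assigned the lowest rank class",
            stacklevel=3,
        )
        return np.zeros(len(values), dtype=int)
    qs = np.arange(1, n_cutoffs + 1) / (n_cutoffs + 1)
    cutoffs = np.quantile(values, qs)
    return (values[:, None] >= cutoffs[None, :]).sum(axis=1)


def score_index(
    group_intakes: pd.DataFrame,
    spec: DietIndexSpec,
    sex: pd.Series | None = None,
    cutoff_cohort: pd.DataFrame | None = None,
) -> pd.Series:
    """Score a diet index for every participant of a cohort.

    ``group_intakes`` is a participants x food-groups frame (intakes/day).
    Cutoffs are computed within the scoring cohort — or within each sex
    stratum when the index definition asks for it — because rank classes are
    cohort-relative.
    ``cutoff_cohort`` optionally supplies a different frame to compute the
    cutoffs from (e.g. to reuse one method's cutoffs across methods);
    ``sex`` is required for sex stratification and sex-specific range rules.
    """
    n = len(group_intakes)
    min_cohort = max(RANK_RULES.get(c.rule, 0) + 1 for c in spec.components)
    if n < min_cohort:
        raise ConfigurationError(
            f"index {spec.id!r}: cohort of {n} smaller than the number of rank "
            f"classes ({min_cohort})"
        )
    ref = group_intakes if cutoff_cohort is None else cutoff_cohort

    if spec.stratification == "sex":
        if sex is None:
            raise ConfigurationError(f"index {spec.id!r}: sex stratification needs sex data")
        parts = []
        for s in sex.loc[group_intakes.index].unique():
            mask = sex.loc[group_intakes.index] == s
            sub = score_index(
                group_intakes[mask],
                DietIndexSpec(
                    id=spec.id,
                    components=spec.components,
                    description=spec.description,
                    stratification="none",
                ),
                sex=sex[mask],
                cutoff_cohort=None if cutoff_cohort is None else cutoff_cohort[mask.reindex(cutoff_cohort.index, fill_value=False)],
            )
            parts.append(sub)
        out = pd.concat(parts).reindex(group_intakes.index)
        out.name = spec.id
        return out

    scores = np.zeros(n, dtype=int)
    for comp in spec.components:
        missing = [g for g in comp.groups if g not in group_intakes.columns]
        if missing:
            raise ConfigurationError(
                f"index {spec.id!r} component {comp.name!r}: unknown groups {missing}"
            )
        values = group_intakes[list(comp.groups)].sum(axis=1).to_numpy(dtype=float)
        if comp.rule == "range":
            bounds = comp.range
            if isinstance(bounds, Mapping):
                if sex is None:
                    raise ConfigurationError(
                        f"index {spec.id!r} component {comp.name!r}: "
                        "sex-specific range needs sex data"
                    )
                sx = sex.loc[group_intakes.index].to_numpy()
                lo = np.array([bounds[s][0] for s in sx], dtype=float)
                hi = np.array([bounds[s][1] for s in sx], dtype=float)
            else:
                lo = np.full(n, float(bounds[0]))
                hi = np.full(n, float(bounds[1]))
            inside = (values >= lo) & (values <= hi)
            scores += np.where(inside, comp.points_in, comp.points_out)
        else:
            ref_values = ref[list(comp.groups)].sum(axis=1).to_numpy(dtype=float)
            n_cut = RANK_RULES[comp.rule]
            qs = np.arange(1, n_cut + 1) / (n_cut + 1)
            if np.max(ref_values) == np.min(ref_values):
                classes = _rank_classes(values, n_cut, comp.name)
            else:
                cutoffs = np.quantile(ref_values, qs)
                classes = (values[:, None] >= cutoffs[None, :]).sum(axis=1)
            pts = np.asarray(comp.points, dtype=int)
            if comp.direction == "-":
                pts = pts[::-1]
            scores += pts[classes]
    out = pd.Series(scores, index=group_intakes.index, name=spec.id)
    out.attrs.update(group_intakes.attrs)
    return out


def score_all_indices(
    group_intakes: pd.DataFrame,
    specs: Mapping[str, DietIndexSpec] | None = None,
    sex: pd.Series | None = None,
) -> pd.DataFrame:
    """Score every index of ``specs`` (default rMED/HNFI/PDI) as one frame."""
    specs = specs or default_index_specs()
    out = pd.DataFrame(
        {spec.id: score_index(group_intakes, spec, sex=sex) for spec in specs.values()}
    )
    out.attrs.update(group_intakes.attrs)
    return out
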