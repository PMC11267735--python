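"""Energy/nutrient estimation, misreporting screening and energy adjustment.

Questionnaire-side nutrient intakes are frequency x portion x composition
sums (:func:`estimate_nutrients`).  Reported energy is screened against the
participant's predicted resting energy expenditure
(:func:`resting_energy_expenditure`, Henry weight-only equations by sex and
age band): the ratio of reported energy intake to REE — called PAL here —
flags severe under-reporting strictly below 0.7 and implausible
over-reporting at or above 3.0 (:func:`pal_flag`).

Because total energy intake drives much of the between-person variation in
absolute nutrient intakes, nutrients are also energy-adjusted
(:func:`energy_adjust`): the residual method regresses nutrient on energy by
ordinary least squares and adds the prediction at cohort-mean energy back to
the residual (keeping natural units), so adjusted values are uncorrelated
with energy by construction; the density method simply rescales to units per
1,000 kcal.
"""
from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources as _ilr
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, CoverageError, FFQValError
from .participants import ParticipantProfile

KCAL_PER_MJ = 239.006

#: reported-energy / REE thresholds for the misreporting screen
PAL_UNDER_CUTOFF = 0.7
PAL_OVER_CUTOFF = 3.0

#: qualitative flags, in increasing PAL order
PAL_FLAGS = ("severe_under", "plausible", "implausible_over")

#: kcal per gram used for the internal-consistency check of composition data
ENERGY_FACTORS = {"protein_g": 4.0, "fat_g": 9.0, "carb_g": 4.0, "alcohol_g": 7.0}


@dataclass(frozen=True)
class FoodCompositionTable:
    """Energy and nutrient contents per 100 g, indexed by category/food id."""

    table: pd.DataFrame  # index: category_id; columns: energy_kcal + nutrients

    def __post_init__(self) -> None:
        if "energy_kcal" not in self.table.columns:
            raise ConfigurationError("composition table needs an energy_kcal column")
        if (self.table < 0).any().any():
            bad = self.table.index[(self.table < 0).any(axis=1)][0]
            raise ConfigurationError(f"negative composition values for {bad!r}")

    @property
    def columns(self) -> list[str]:
        return list(self.table.columns)

    @property
    def nutrients(self) -> list[str]:
        return [c for c in self.table.columns if c != "energy_kcal"]

    def per_gram(self) -> pd.DataFrame:
        return self.table / 100.0

    def check_energy_consistency(self, tol: float = 0.25) -> None:
        """Verify energy against the 4/9/4/7 macronutrient rule.

        ``tol`` is the allowed relative deviation; fixture tables should be
        exactly consistent, real tables carry rounding and fibre conventions.
        """
        present = {k: v for k, v in ENERGY_FACTORS.items() if k in self.table.columns}
        macro = sum(self.table[c] * f for c, f in present.items())
        rel = (self.table["energy_kcal"] - macro).abs() / self.table["energy_kcal"].clip(lower=1.0)
        if (rel > tol).any():
            bad = rel.idxmax()
            raise ConfigurationError(
                f"energy inconsistent with macronutrients for {bad!r} "
                f"(relative deviation {rel.max():.2f} > {tol})"
            )

    @classmethod
    def from_csv(cls, path_or_buf) -> "FoodCompositionTable":
        df = pd.read_csv(path_or_buf).set_index("category_id")
        return cls(table=df.astype(float))

    @classmethod
    def default(cls) -> "FoodCompositionTable":
        """The packaged synthetic composition table (108 categories)."""
        text = _ilr.files("ffqval.resources").joinpath(
            "food_composition_synthetic.csv"
        ).read_text()
        return cls.from_csv(io.StringIO(text))


def estimate_nutrients(
    freqs: pd.DataFrame | pd.Series,
    portions_g: pd.DataFrame | pd.Series,
    composition: FoodCompositionTable,
) -> pd.DataFrame | pd.Series:
    """Daily energy/nutrient intakes from frequencies and portions.

    nutrient = sum over categories of frequency x portion_g x content/g.
    ``freqs`` and ``portions_g`` are participants x categories (or single
    Series); every category with non-zero frequency must be covered by both
    the portion and composition data.
    """
    single = isinstance(freqs, pd.Series)
    f = freqs.to_frame().T if single else freqs
    p = portions_g.to_frame().T if isinstance(portions_g, pd.Series) else portions_g
    p = p.reindex(index=f.index, columns=f.columns)
    active = f.columns[(f != 0).any(axis=0)]
    uncovered = [c for c in active if c not in composition.table.index]
    if uncovered:
        raise CoverageError(f"no composition entry for categories {uncovered[:5]}")
    missing_portion = [c for c in active if p[c].isna().any()]
    if missing_portion:
        raise CoverageError(f"no portion for categories {missing_portion[:5]}")
    grams = (f * p.fillna(0.0)).to_numpy(dtype=float)
    comp = composition.per_gram().reindex(f.columns).fillna(0.0).to_numpy(dtype=float)
    out = pd.DataFrame(grams @ comp, index=f.index, columns=composition.columns)
    out.attrs.update(freqs.attrs)
    if single:
        s = out.iloc[0]
        s.name = freqs.name
        s.attrs.update(freqs.attrs)
        return s
    return out


@dataclass(frozen=True)
class REEEquations:
    """Sex- and age-band linear REE equations (weight, optionally height).

    Bands are half-open ``[age_min, age_max)``: an age exactly on a boundary
    belongs to the band starting there.  Coefficients are stored in the
    published unit (MJ/day by default) and converted to kcal/day on
    evaluation.
    """

    rows: tuple[dict, ...]
    unit: str = "MJ_per_day"

    def __post_init__(self) -> None:
        if self.unit not in ("MJ_per_day", "kcal_per_day"):
            raise ConfigurationError(f"unknown REE unit {self.unit!r}")

    def _row(self, sex: str, age: float) -> dict:
        for r in self.rows:
            if r["sex"] == sex and r["age_min"] <= age < r["age_max"]:
                return r
        raise CoverageError(f"no REE equation for ({sex}, age {age})")

    def kcal_per_day(self, p: ParticipantProfile) -> float:
        r = self._row(p.sex, p.age)
        value = r["intercept"] + r["weight_coef"] * p.weight_kg
        value += r.get("height_coef", 0.0) * (p.height_cm / 100.0)
        if self.unit == "MJ_per_day":
            value *= KCAL_PER_MJ
        return float(value)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "REEEquations":
        return cls(rows=tuple(dict(r) for r in doc["equations"]), unit=doc.get("unit", "MJ_per_day"))

    @classmethod
    def from_yaml(cls, path) -> "REEEquations":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "REEEquations":
        text = _ilr.files("ffqval.resources").joinpath("ree_equations.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))


def resting_energy_expenditure(
    participant: ParticipantProfile,
    equations: REEEquations | None = None,
) -> float:
    """Predicted resting energy expenditure in kcal/day."""
    return (equations or REEEquations.default()).kcal_per_day(participant)


@dataclass(frozen=True)
class PALResult:
    participant_id: str
    ree_kcal: float
    pal: float
    flag: str


def pal_flag(
    energy_kcal: float,
    ree_kcal: float,
    participant_id: str = "",
    under_cutoff: float = PAL_UNDER_CUTOFF,
    over_cutoff: float = PAL_OVER_CUTOFF,
) -> PALResult:
    """Classify reported energy against predicted resting expenditure.

    flag = ``severe_under`` for PAL strictly below ``under_cutoff`` (0.7),
    ``implausible_over`` at or above ``over_cutoff`` (3.0), else
    ``plausible``.  A PAL of exactly 0.7 is plausible; exactly 3.0 is not.
    """
    if ree_kcal <= 0:
        raise FFQValError(f"participant {participant_id}: REE must be positive")
    pal = energy_kcal / ree_kcal
    if pal < under_cutoff:
        flag = "severe_under"
    elif pal >= over_cutoff:
        flag = "implausible_over"
    else:
        flag = "plausible"
    return PALResult(participant_id=participant_id, ree_kcal=ree_kcal, pal=pal, flag=flag)


def cohort_pal_flags(
    energy_kcal: pd.Series,
    participants: pd.DataFrame,
    equations: REEEquations | None = None,
    under_cutoff: float = PAL_UNDER_CUTOFF,
    over_cutoff: float = PAL_OVER_CUTOFF,
) -> pd.DataFrame:
    """PAL, REE and flag per participant (columns ree_kcal, pal, flag)."""
    from .participants import profiles_from_frame

    eq = equations or REEEquations.default()
    sub = participants.loc[energy_kcal.index]
    ree = pd.Series(
        [eq.kcal_per_day(p) for p in profiles_from_frame(sub)],
        index=energy_kcal.index,
        name="ree_kcal",
    )
    pal = energy_kcal / ree
    flag = pd.Series(
        np.where(pal < under_cutoff, "severe_under",
                 np.where(pal >= over_cutoff, "implausible_over", "plausible")),
        index=energy_kcal.index,
        name="flag",
    )
    return pd.DataFrame({"ree_kcal": ree, "pal": pal, "flag": flag})


def energy_adjust(
    intakes: pd.DataFrame,
    method: str = "residual",
    nutrients: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Energy-adjust nutrient intakes across a cohort.

    ``method="residual"``: per nutrient, ordinary-least-squares regression on
    energy; adjusted value = residual + prediction at cohort-mean energy
    (natural units preserved; zero sample correlation with energy by
    construction).  ``method="density"``: nutrient / energy x 1000 (units per
    1,000 kcal); participants with zero energy get NaN, flagged in
    ``attrs["undefined_participants"]`` and excluded from downstream
    correlations by pairwise deletion.
    """
    if "energy_kcal" not in intakes.columns:
        raise ConfigurationError("intakes need an energy_kcal column")
    cols = list(nutrients) if nutrients is not None else [
        c for c in intakes.columns if c != "energy_kcal"
    ]
    energy = intakes["energy_kcal"].to_numpy(dtype=float)
    if method == "residual":
        if len(intakes) < 3:
            raise ConfigurationError("residual method needs a cohort of at least 3")
        x = np.column_stack([np.ones_like(energy), energy])
        y = intakes[cols].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        at_mean = np.array([1.0, energy.mean()]) @ beta
        out = pd.DataFrame(resid + at_mean, index=intakes.index, columns=cols)
    elif method == "density":
        with np.errstate(divide="ignore", invalid="ignore"):
            dens = intakes[cols].to_numpy(dtype=float) / energy[:, None] * 1000.0
        dens[energy == 0] = np.nan
        out = pd.DataFrame(dens, index=intakes.index, columns=cols)
        out.attrs["undefined_participants"] = list(intakes.index[energy == 0])
    else:
        raise ConfigurationError(f"unknown energy-adjustment method {method!r}")
    out.attrs["method"] = method
    out.attrs.setdefault("source", intakes.attrs.get("source"))
    return out
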