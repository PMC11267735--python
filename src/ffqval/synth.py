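"""Synthetic validation-study generator with retained ground truth.

A validation study compares a frequency questionnaire (test instrument,
administered twice) against repeated 24-hour recalls (reference method) on
the same participants.  No participant-level data from such studies is
public, so this module generates whole studies with a known latent truth:

* habitual intake per category is log-normal across participants
  (configurable median and geometric SD per category) with a Bernoulli
  never-consumer mask for episodically consumed foods, truncated at the
  questionnaire's 4/day ceiling;
* the questionnaire observes truth times a multiplicative bias and
  log-normal noise, discretised to the nearest of the nine representative
  scale values (ties to the lower category); the repeat administration
  redraws the noise independently given truth;
* recall days observe truth through Poisson day-level occasion counts (the
  within-person day-to-day variation the reference method averages over) and
  log-normal amount noise around the true portion.

Every generated dataset retains its :class:`TrueDietProfile` so downstream
statistics can be checked against the truth (see :mod:`ffqval.theory` for the
matching analytic predictions).  Generation is fully vectorised and
bit-reproducible from (config, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .ffq import FFQRecord, PORTION_COLUMNS
from .nutrients import FoodCompositionTable, REEEquations, estimate_nutrients
from .participants import participants_frame, profiles_from_frame
from .schema import (
    PHOTO_CLASSES,
    FFQSchema,
    FrequencyMapping,
    PortionTable,
)

#: completed-day distribution over 0..6 scheduled recall days; the shape
#: mirrors a study flow in which ~8% of consenters record no day, ~76% reach
#: the four-day inclusion rule and 93% of those complete all six days
DEFAULT_COMPLETION_PROBS = (0.081, 0.052, 0.052, 0.052, 0.0265, 0.0265, 0.710)


@dataclass(frozen=True)
class ErrorModel:
    """Measurement-error structure of the simulated instruments.

    ``ffq_bias`` is a multiplicative per-category factor (scalar or mapping
    by category id); ``ffq_noise_sd`` the log-scale SD of questionnaire
    noise; ``recall_within_person_sd`` the log-scale SD of day-level amount
    noise; ``episodic_zero_prob`` overrides the per-category never-consumer
    probabilities (None keeps the schema defaults).  ``recall_poisson=False``
    switches day-level occasion counts from Poisson draws to the exact
    (possibly fractional) daily frequency — the deterministic reference used
    by the zero-error identity checks.  ``repeat_drift`` multiplies truth in
    the repeat administration (0 drift = factor 1).
    """

    ffq_bias: float | Mapping[str, float] = 1.0
    ffq_noise_sd: float = 0.35
    recall_within_person_sd: float = 0.25
    episodic_zero_prob: float | Mapping[str, float] | None = None
    repeat_drift: float = 0.0
    recall_poisson: bool = True

    def __post_init__(self) -> None:
        if self.ffq_noise_sd < 0:
            raise ConfigurationError("ffq_noise_sd must be >= 0")
        if self.recall_within_person_sd < 0:
            raise ConfigurationError("recall_within_person_sd must be >= 0")
        probs = self.episodic_zero_prob
        if probs is not None:
            vals = probs.values() if isinstance(probs, Mapping) else [probs]
            for v in vals:
                if not 0.0 <= v <= 1.0:
                    raise ConfigurationError("episodic_zero_prob must be in [0, 1]")
        biases = (
            self.ffq_bias.values() if isinstance(self.ffq_bias, Mapping) else [self.ffq_bias]
        )
        for b in biases:
            if b <= 0:
                raise ConfigurationError("ffq_bias must be positive")

    @property
    def is_exact(self) -> bool:
        """True when the model introduces no error at all."""
        biases = (
            list(self.ffq_bias.values())
            if isinstance(self.ffq_bias, Mapping)
            else [self.ffq_bias]
        )
        return (
            self.ffq_noise_sd == 0
            and self.recall_within_person_sd == 0
            and all(b == 1.0 for b in biases)
            and not self.recall_poisson
            and self.repeat_drift == 0.0
        )

    @classmethod
    def zero(cls) -> "ErrorModel":
        """The error-free configuration: both instruments read truth exactly."""
        return cls(
            ffq_bias=1.0,
            ffq_noise_sd=0.0,
            recall_within_person_sd=0.0,
            episodic_zero_prob=0.0,
            repeat_drift=0.0,
            recall_poisson=False,
        )

    def bias_array(self, schema: FFQSchema) -> np.ndarray:
        if isinstance(self.ffq_bias, Mapping):
            return np.array([self.ffq_bias.get(i, 1.0) for i in schema.item_ids])
        return np.full(len(schema), float(self.ffq_bias))

    def zero_prob_array(self, schema: FFQSchema) -> np.ndarray:
        if self.episodic_zero_prob is None:
            return np.array([it.zero_prob for it in schema.items])
        if isinstance(self.episodic_zero_prob, Mapping):
            return np.array(
                [self.episodic_zero_prob.get(it.id, it.zero_prob) for it in schema.items]
            )
        return np.full(len(schema), float(self.episodic_zero_prob))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design settings of the generator.

    Defaults emulate the validation-study design the package targets:
    adults 35-64, ~61% women, six scheduled recall days with the completion
    distribution above, and a twice-administered questionnaire.
    ``snap_truth_to_scale=None`` applies the automatic rule: truth is snapped
    onto the nine representative scale values (and true portions onto the
    assignable portion values) exactly when the error model is exact, making
    the zero-noise round trip an identity.
    """

    n_days_scheduled: int = 6
    completion_probs: tuple[float, ...] = DEFAULT_COMPLETION_PROBS
    age_range: tuple[int, int] = (35, 64)
    female_fraction: float = 0.611
    height_mean_cm: Mapping[str, float] = field(
        default_factory=lambda: {"male": 179.5, "female": 165.5}
    )
    height_sd_cm: Mapping[str, float] = field(
        default_factory=lambda: {"male": 7.0, "female": 6.5}
    )
    bmi_mean: float = 26.1
    bmi_sd: float = 4.3
    portion_gsd: float = 1.2
    missing_response_prob: float = 0.0
    snap_truth_to_scale: bool | None = None
    # latent dietary-pattern structure: fraction of each category's log-scale
    # variance shared across a few pattern factors (eating patterns are
    # correlated across foods in real cohorts; 0 = independent categories)
    pattern_fraction: float = 0.5
    n_pattern_factors: int = 2

    def __post_init__(self) -> None:
        if len(self.completion_probs) != self.n_days_scheduled + 1:
            raise ConfigurationError(
                "completion_probs must have n_days_scheduled + 1 entries"
            )
        if abs(sum(self.completion_probs) - 1.0) > 1e-9:
            raise ConfigurationError("completion_probs must sum to 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigurationError("female_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_response_prob <= 1.0:
            raise ConfigurationError("missing_response_prob must be in [0, 1]")
        if self.portion_gsd < 1.0:
            raise ConfigurationError("portion_gsd must be >= 1")
        if not 0.0 <= self.pattern_fraction < 1.0:
            raise ConfigurationError("pattern_fraction must be in [0, 1)")
        if self.n_pattern_factors < 0:
            raise ConfigurationError("n_pattern_factors must be >= 0")


@dataclass(frozen=True)
class TrueDietProfile:
    """Latent truth for one participant (what both instruments try to see)."""

    participant_id: str
    freq_per_day: pd.Series  # per category, intakes/day, in [0, 4]
    portion_g: pd.Series  # per category mean portion
    energy_kcal: float


@dataclass(frozen=True)
class StudyDataset:
    """One synthetic validation study, truth included."""

    participants: pd.DataFrame  # indexed by participant_id
    ffq_baseline: pd.DataFrame  # wide: item codes 1-9 (+ portion_* columns)
    ffq_repeat: pd.DataFrame
    recalls: pd.DataFrame  # long: participant_id, day, date_class, food_id, amount_g, occasions
    truth_freq: pd.DataFrame  # participants x categories, intakes/day
    truth_portion: pd.DataFrame
    truth_energy: pd.Series
    seed: int
    schema: FFQSchema
    mapping: FrequencyMapping
    error_model: ErrorModel
    config: GeneratorConfig

    def truth_profile(self, participant_id: str) -> TrueDietProfile:
        return TrueDietProfile(
            participant_id=participant_id,
            freq_per_day=self.truth_freq.loc[participant_id],
            portion_g=self.truth_portion.loc[participant_id],
            energy_kcal=float(self.truth_energy.loc[participant_id]),
        )

    def recall_day_counts(self) -> pd.Series:
        return self.participants["completed_recall_days"]

    def food_map(self) -> dict[str, str]:
        """Synthetic recall food ids are category ids; the map is identity."""
        return {i: i for i in self.schema.item_ids}

    def write_csvs(self, outdir) -> list[Path]:
        """Write the study CSVs plus a data dictionary; returns paths."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        tables = {
            "participants.csv": self.participants.reset_index(),
            "ffq_baseline.csv": self.ffq_baseline.reset_index(),
            "ffq_repeat.csv": self.ffq_repeat.reset_index(),
            "recalls.csv": self.recalls,
            "truth_frequencies.csv": self.truth_freq.reset_index(),
            "truth_portions.csv": self.truth_portion.reset_index(),
        }
        for name, df in tables.items():
            path = out / name
            df.to_csv(path, index=False, float_format="%.10g")
            written.append(path)
        dd = out / "data_dictionary.md"
        dd.write_text(_data_dictionary(self))
        written.append(dd)
        return written


def _data_dictionary(ds: StudyDataset) -> str:
    lines = [
        "# Synthetic validation-study data dictionary",
        "",
        f"Generated with seed {ds.seed}; {len(ds.participants)} participants; "
        f"{len(ds.schema)} questionnaire categories on a "
        f"{len(ds.schema.frequency_levels)}-level frequency scale.",
        "",
        "## participants.csv",
        "participant_id; sex (male/female); age (years); height_cm; weight_kg;",
        "completed_recall_days (0-{}).".format(ds.config.n_days_scheduled),
        "",
        "## ffq_baseline.csv / ffq_repeat.csv",
        "One row per participant. Item columns (schema order) hold frequency",
        "level codes 1-9; empty = unanswered. portion_starch / portion_protein /",
        "portion_vegetable hold portion-photo levels 1-4.",
        "Level codes: "
        + "; ".join(
            f"{i + 1}={lvl}" for i, lvl in enumerate(ds.schema.frequency_levels)
        ),
        "",
        "## recalls.csv",
        "Long format, one row per (participant, day, food): participant_id;",
        "day (1-based index of the completed day); date_class (weekday/weekend);",
        "food_id (category id — the food-to-category map is identity for",
        "synthetic data); amount_g (grams consumed that day); occasions",
        "(eating occasions that day; fractional under the deterministic",
        "zero-error model).",
        "",
        "## truth_frequencies.csv / truth_portions.csv",
        "Latent habitual truth per participant and category: intakes/day in",
        "[0, 4], and mean portion in grams. Retained for oracle checks only —",
        "no real study observes these.",
    ]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _discretise(noisy: np.ndarray, mapping: FrequencyMapping) -> np.ndarray:
    """Level codes (1..9) by nearest representative value, ties to lower."""
    values = mapping.array
    d = np.abs(noisy[..., None] - values)
    return np.argmin(d, axis=-1) + 1


def _derive_portion_indications(
    true_portion: np.ndarray, schema: FFQSchema, portions: PortionTable
) -> dict[str, np.ndarray]:
    """Photo level (1-4) per class: nearest plate to the participant's mean
    true portion over that class's categories, ties to the lower plate."""
    classes = np.array([it.portion_class for it in schema.items])
    out = {}
    for cls_ in PHOTO_CLASSES:
        members = classes == cls_
        mean_portion = true_portion[:, members].mean(axis=1)
        plates = np.asarray(portions.photo_levels[cls_], dtype=float)
        out[cls_] = np.argmin(np.abs(mean_portion[:, None] - plates), axis=1) + 1
    return out


def generate_cohort(
    n: int,
    error_model: ErrorModel | None = None,
    config: GeneratorConfig | None = None,
    seed: int = 0,
    schema: FFQSchema | None = None,
    mapping: FrequencyMapping | None = None,
    portions: PortionTable | None = None,
    composition: FoodCompositionTable | None = None,
) -> StudyDataset:
    """Generate a complete synthetic validation study.

    Returns a :class:`StudyDataset` with ``n`` participants, baseline and
    repeat questionnaire records, up to six recall days each, and the latent
    truth.  Identical arguments (including ``seed``) reproduce the dataset
    bit for bit.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    error_model = error_model or ErrorModel()
    config = config or GeneratorConfig()
    schema = schema or FFQSchema.default()
    mapping = mapping or FrequencyMapping.default()
    portions = portions or PortionTable.default()
    composition = composition or FoodCompositionTable.default()
    rng = np.random.default_rng(seed)
    p = len(schema)
    ids = [f"P{i + 1:04d}" for i in range(n)]

    # --- participants -----------------------------------------------------
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    h_mean = np.array([config.height_mean_cm[s] for s in sex])
    h_sd = np.array([config.height_sd_cm[s] for s in sex])
    height = rng.normal(h_mean, h_sd)
    bmi = np.clip(rng.normal(config.bmi_mean, config.bmi_sd, size=n), 16.0, 50.0)
    weight = bmi * (height / 100.0) ** 2
    days = rng.choice(
        np.arange(config.n_days_scheduled + 1), size=n, p=config.completion_probs
    )
    participants = pd.DataFrame(
        {
            "sex": sex,
            "age": age,
            "height_cm": np.round(height, 1),
            "weight_kg": np.round(weight, 1),
            "completed_recall_days": days,
        },
        index=pd.Index(ids, name="participant_id"),
    )

    # --- latent truth -----------------------------------------------------
    medians = np.array([it.median_freq_per_day for it in schema.items])
    sigmas = np.log(np.array([it.freq_gsd for it in schema.items]))
    zero_probs = error_model.zero_prob_array(schema)
    never = rng.random((n, p)) < zero_probs[None, :]
    rho = config.pattern_fraction if config.n_pattern_factors > 0 else 0.0
    if rho > 0:
        # shared dietary-pattern factors: split each category's log variance
        # into a common part (loadings on a few factors) and a unique part,
        # preserving the marginal log-normal law per category
        raw = rng.normal(size=(config.n_pattern_factors, p))
        lam = raw / np.linalg.norm(raw, axis=0, keepdims=True)
        lam = lam * (np.sqrt(rho) * sigmas[None, :])
        factors = rng.normal(size=(n, config.n_pattern_factors))
        log_dev = factors @ lam + rng.normal(
            0.0, 1.0, size=(n, p)
        ) * (np.sqrt(1.0 - rho) * sigmas[None, :])
    else:
        log_dev = rng.normal(0.0, 1.0, size=(n, p)) * sigmas[None, :]
    freq = medians[None, :] * np.exp(log_dev)
    freq = np.clip(freq, 0.0, 4.0)
    freq[never] = 0.0

    base_portion = np.array([it.base_portion_g for it in schema.items])
    sex_factor = np.array([portions.sex_factor.get(s, 1.0) for s in sex])
    sigma_p = np.log(config.portion_gsd)
    portion = (
        base_portion[None, :]
        * sex_factor[:, None]
        * np.exp(rng.normal(0.0, sigma_p, size=(n, p)))
    )

    snap = config.snap_truth_to_scale
    if snap is None:
        snap = error_model.is_exact
    indications = _derive_portion_indications(portion, schema, portions)
    if snap:
        freq = mapping.array[_discretise(freq, mapping) - 1]
        # snap portions onto exactly what the portion-assignment path returns
        from .ffq import cohort_portion_sizes

        rec = pd.DataFrame(index=participants.index)
        for cls_ in PHOTO_CLASSES:
            rec[f"portion_{cls_}"] = indications[cls_]
        portion = cohort_portion_sizes(rec, portions, participants, schema).to_numpy()

    truth_freq = pd.DataFrame(freq, index=participants.index, columns=schema.item_ids)
    truth_portion = pd.DataFrame(portion, index=participants.index, columns=schema.item_ids)
    truth_energy = estimate_nutrients(truth_freq, truth_portion, composition)["energy_kcal"]
    truth_energy.name = "energy_kcal"

    # --- questionnaire administrations ------------------------------------
    bias = error_model.bias_array(schema)

    def ffq_frame(drift_factor: float) -> pd.DataFrame:
        noisy = freq * bias[None, :] * drift_factor
        if error_model.ffq_noise_sd > 0:
            noisy = noisy * np.exp(
                rng.normal(0.0, error_model.ffq_noise_sd, size=(n, p))
            )
        codes = _discretise(noisy, mapping).astype(float)
        if config.missing_response_prob > 0:
            miss = rng.random((n, p)) < config.missing_response_prob
            codes[miss] = np.nan
        df = pd.DataFrame(codes, index=participants.index, columns=schema.item_ids)
        for cls_ in PHOTO_CLASSES:
            df[f"portion_{cls_}"] = indications[cls_]
        return df

    ffq_baseline = ffq_frame(1.0)
    ffq_repeat = ffq_frame(1.0 + error_model.repeat_drift)

    # --- recall days -------------------------------------------------------
    max_days = config.n_days_scheduled
    if error_model.recall_poisson:
        counts = rng.poisson(np.broadcast_to(freq[:, None, :], (n, max_days, p))).astype(float)
    else:
        counts = np.broadcast_to(freq[:, None, :], (n, max_days, p)).copy()
    day_alive = np.arange(1, max_days + 1)[None, :] <= days[:, None]
    counts *= day_alive[:, :, None]
    if error_model.recall_within_person_sd > 0:
        amount_noise = np.exp(
            rng.normal(0.0, error_model.recall_within_person_sd, size=(n, max_days, p))
        )
    else:
        amount_noise = 1.0
    grams = counts * portion[:, None, :] * amount_noise
    date_class_draw = rng.random((n, max_days)) < (2.0 / 7.0)

    ii, dd, jj = np.nonzero(counts > 0)
    recalls = pd.DataFrame(
        {
            "participant_id": np.asarray(ids, dtype=object)[ii],
            "day": dd + 1,
            "date_class": np.where(date_class_draw[ii, dd], "weekend", "weekday"),
            "food_id": np.asarray(schema.item_ids, dtype=object)[jj],
            "amount_g": grams[ii, dd, jj],
            "occasions": counts[ii, dd, jj],
        }
    )

    return StudyDataset(
        participants=participants,
        ffq_baseline=ffq_baseline,
        ffq_repeat=ffq_repeat,
        recalls=recalls,
        truth_freq=truth_freq,
        truth_portion=truth_portion,
        truth_energy=truth_energy,
        seed=seed,
        schema=schema,
        mapping=mapping,
        error_model=error_model,
        config=config,
    )


def simulate_ffq_responses(
    truth: TrueDietProfile,
    error_model: ErrorModel,
    mapping: FrequencyMapping,
    seed: int = 0,
    schema: FFQSchema | None = None,
    portions: PortionTable | None = None,
) -> FFQRecord:
    """Simulate one questionnaire administration for one participant.

    The noisy true frequency is discretised to the level whose representative
    daily value is nearest (ties to the lower category); frequencies above
    the scale truncate to the top level; a true frequency of 0 stays "never".
    Portion indications are the plates nearest the participant's true mean
    portion per plate class.
    """
    schema = schema or FFQSchema.default()
    portions = portions or PortionTable.default()
    rng = np.random.default_rng(seed)
    f = truth.freq_per_day.reindex(schema.item_ids).to_numpy(dtype=float)
    noisy = f * error_model.bias_array(schema)
    if error_model.ffq_noise_sd > 0:
        noisy = noisy * np.exp(rng.normal(0.0, error_model.ffq_noise_sd, size=len(f)))
    codes = _discretise(noisy, mapping)
    responses = {i: int(c) for i, c in zip(schema.item_ids, codes)}
    port = truth.portion_g.reindex(schema.item_ids).to_numpy(dtype=float)
    indications = _derive_portion_indications(port[None, :], schema, portions)
    return FFQRecord(
        participant_id=truth.participant_id,
        responses=responses,
        portion_indications={c: int(indications[c][0]) for c in PHOTO_CLASSES},
    )


# ---------------------------------------------------------------------------
# constructed cohorts for the misreporting screen
# ---------------------------------------------------------------------------

def pal_calibration_energy(
    participants: pd.DataFrame,
    frac_under: float = 0.05,
    frac_over: float = 0.01,
    seed: int = 0,
    equations: REEEquations | None = None,
    under_cutoff: float = 0.7,
    over_cutoff: float = 3.0,
) -> pd.Series:
    """Reported-energy vector with exact misreporting fractions.

    Construct energies so that exactly ``round(frac_under * n)`` participants
    have reported-energy/REE strictly below the under-reporting cutoff and
    ``round(frac_over * n)`` at or above the over-reporting cutoff, the rest
    comfortably inside.  Used to calibrate the screening filter against known
    prevalence.
    """
    eq = equations or REEEquations.default()
    rng = np.random.default_rng(seed)
    n = len(participants)
    n_under = int(round(frac_under * n))
    n_over = int(round(frac_over * n))
    if n_under + n_over > n:
        raise ConfigurationError("misreporting fractions exceed the cohort")
    pal = rng.uniform(under_cutoff + 0.3, over_cutoff - 0.8, size=n)
    idx = rng.permutation(n)
    pal[idx[:n_under]] = rng.uniform(0.4, under_cutoff - 0.05, size=n_under)
    pal[idx[n_under:n_under + n_over]] = rng.uniform(
        over_cutoff, over_cutoff + 0.5, size=n_over
    )
    ree = np.array([eq.kcal_per_day(p) for p in profiles_from_frame(participants)])
    return pd.Series(pal * ree, index=participants.index, name="energy_kcal")


def write_config_yaml(path, error_model: ErrorModel, config: GeneratorConfig, seed: int) -> None:
    """Record the generator settings next to a written dataset."""
    doc = {
        "seed": seed,
        "error_model": {
            "ffq_bias": error_model.ffq_bias
            if not isinstance(error_model.ffq_bias, Mapping)
            else dict(error_model.ffq_bias),
            "ffq_noise_sd": error_model.ffq_noise_sd,
            "recall_within_person_sd": error_model.recall_within_person_sd,
            "episodic_zero_prob": error_model.episodic_zero_prob
            if not isinstance(error_model.episodic_zero_prob, Mapping)
            else dict(error_model.episodic_zero_prob),
            "repeat_drift": error_model.repeat_drift,
            "recall_poisson": error_model.recall_poisson,
        },
        "config": {
            "n_days_scheduled": config.n_days_scheduled,
            "completion_probs": list(config.completion_probs),
            "age_range": list(config.age_range),
            "female_fraction": config.female_fraction,
            "bmi_mean": config.bmi_mean,
            "bmi_sd": config.bmi_sd,
            "portion_gsd": config.portion_gsd,
            "missing_response_prob": config.missing_response_prob,
            "snap_truth_to_scale": config.snap_truth_to_scale,
            "pattern_fraction": config.pattern_fraction,
            "n_pattern_factors": config.n_pattern_factors,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
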