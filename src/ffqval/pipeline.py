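"""Full-study orchestration: raw records to validation report.

:func:`run_validation` executes the whole analysis a validation study runs:
questionnaire quality filtering, recall-day inclusion, frequency
harmonisation, food-group aggregation, diet-index scoring, nutrient
estimation with the misreporting (PAL) screen, and the statistics battery —
for the full cohort, the PAL-excluded subset, and sex strata.  Everything is
deterministic given the inputs and configuration, every exclusion is
logged, and the report serialises to tidy CSVs plus a JSON summary.

Quantile convention: all medians, quartiles and rank-class cutoffs use
linear interpolation of order statistics (numpy's default), recorded in the
report header.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ffq as ffq_mod
from . import groups as groups_mod
from . import nutrients as nutr_mod
from . import recall as recall_mod
from . import stats as stats_mod
from .errors import ConfigurationError
from .nutrients import FoodCompositionTable, REEEquations
from .schema import FFQSchema, FrequencyMapping, PortionTable, load_food_group_mapping
from .synth import StudyDataset

EXCLUSION_POLICIES = ("report_all", "exclude_pal_outliers", "flag_only")


@dataclass(frozen=True)
class RunConfig:
    """Settings of one validation run."""

    min_recall_days: int = 4
    pal_under_cutoff: float = 0.7
    pal_over_cutoff: float = 3.0
    exclusion_policy: str = "report_all"
    strata: str = "sex"  # {none, sex}
    pca_components: int = 2
    pca_log_offset: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exclusion_policy not in EXCLUSION_POLICIES:
            raise ConfigurationError(f"unknown exclusion policy {self.exclusion_policy!r}")
        if not 0 < self.pal_under_cutoff < self.pal_over_cutoff:
            raise ConfigurationError("PAL thresholds must be positive and ordered")
        if self.strata not in ("none", "sex"):
            raise ConfigurationError(f"unknown strata {self.strata!r}")
        if self.min_recall_days < 1:
            raise ConfigurationError("min_recall_days must be >= 1")


@dataclass
class ValidationReport:
    """All statistics of one run, as tidy frames keyed by variable."""

    config: RunConfig
    attrition: dict
    exclusions: pd.DataFrame  # participant_id, reason
    descriptives: pd.DataFrame
    food_group_stats: pd.DataFrame
    index_stats: pd.DataFrame
    nutrient_stats: pd.DataFrame
    cross_class: pd.DataFrame
    bland_altman: pd.DataFrame
    reproducibility: pd.DataFrame
    pca: dict
    strata_stats: pd.DataFrame
    pal_flags: pd.DataFrame
    quantile_rule: str = "linear interpolation of order statistics"

    def summary(self) -> dict:
        def rng(df, col):
            vals = df[col].dropna()
            return [float(vals.min()), float(vals.max())] if len(vals) else [None, None]

        return {
            "quantile_rule": self.quantile_rule,
            "n_analysed": self.attrition["analysed"],
            "attrition": self.attrition,
            "food_group_spearman_range": rng(self.food_group_stats, "spearman"),
            "index_pearson_range": rng(self.index_stats, "pearson"),
            "nutrient_pearson_range": rng(
                self.nutrient_stats[self.nutrient_stats["adjustment"] == "absolute"],
                "pearson",
            ),
            "icc_range": rng(self.reproducibility, "icc"),
            "pca": {k: {kk: (list(np.round(vv, 6)) if isinstance(vv, np.ndarray) else vv)
                        for kk, vv in v.items()}
                    for k, v in self.pca.items()},
            "pal_flag_counts": self.pal_flags["flag"].value_counts().to_dict(),
        }

    def write(self, outdir) -> list[Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        frames = {
            "descriptives.csv": self.descriptives,
            "food_group_stats.csv": self.food_group_stats,
            "index_stats.csv": self.index_stats,
            "nutrient_stats.csv": self.nutrient_stats,
            "cross_classification.csv": self.cross_class,
            "bland_altman.csv": self.bland_altman,
            "reproducibility.csv": self.reproducibility,
            "strata_stats.csv": self.strata_stats,
            "pal_flags.csv": self.pal_flags.reset_index(),
            "exclusions.csv": self.exclusions,
        }
        for name, df in frames.items():
            path = out / name
            df.to_csv(path, index=False, float_format="%.10g")
            written.append(path)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
        written.append(out / "summary.json")
        return written


def descriptives(
    food_groups: Mapping[str, pd.DataFrame],
    indices: Mapping[str, pd.DataFrame],
    nutrients: Mapping[str, pd.DataFrame],
) -> pd.DataFrame:
    """Cohort descriptives: medians (25th/75th) for food groups, mean (sd)
    for index scores and nutrients, per method."""
    rows = []
    for method, df in food_groups.items():
        for col in df.columns:
            v = df[col].to_numpy(dtype=float)
            rows.append((col, "food_group", method, "median_iqr",
                         float(np.median(v)),
                         float(np.quantile(v, 0.25)), float(np.quantile(v, 0.75))))
    for block, kind in ((indices, "index"), (nutrients, "nutrient")):
        for method, df in block.items():
            for col in df.columns:
                v = df[col].to_numpy(dtype=float)
                rows.append((col, kind, method, "mean_sd",
                             float(np.mean(v)), float(np.std(v, ddof=1)), np.nan))
    return pd.DataFrame(
        rows,
        columns=["variable", "kind", "method", "summary", "central", "low", "high"],
    )


def _corr_row(variable, ref, test, methods=("spearman",)):
    row = {"variable": variable, "n": len(ref)}
    for m in methods:
        res = stats_mod.correlate(ref, test, method=m, variable=variable)
        row[m] = res.coefficient
        row[f"{m}_p"] = res.p_value
    return row


def run_validation(
    dataset: StudyDataset,
    config: RunConfig | None = None,
    group_mapping: Mapping[str, Sequence[str]] | None = None,
    index_specs: Mapping[str, groups_mod.DietIndexSpec] | None = None,
    composition: FoodCompositionTable | None = None,
    ree: REEEquations | None = None,
    portions: PortionTable | None = None,
) -> ValidationReport:
    """Run the complete validity + reproducibility analysis of a study."""
    config = config or RunConfig()
    schema: FFQSchema = dataset.schema
    mapping: FrequencyMapping = dataset.mapping
    group_mapping = group_mapping or load_food_group_mapping()
    index_specs = index_specs or groups_mod.default_index_specs()
    composition = composition or FoodCompositionTable.default()
    ree = ree or REEEquations.default()
    portions = portions or PortionTable.default()

    exclusions = []

    # --- questionnaire quality -------------------------------------------
    quality = ffq_mod.cohort_exclude_levels(dataset.ffq_baseline, schema)
    quality_ok = quality.index[quality["exclude_level"] == 0]
    for pid in quality.index[quality["exclude_level"] > 0]:
        exclusions.append((pid, f"exclude_level_{quality.loc[pid, 'exclude_level']}"))

    # --- recall-day inclusion --------------------------------------------
    participants = dataset.participants.loc[quality_ok]
    included, attrition_rec = recall_mod.inclusion_filter(
        participants, min_days=config.min_recall_days
    )
    for pid in participants.index.difference(included.index):
        exclusions.append((pid, f"fewer_than_{config.min_recall_days}_recall_days"))
    cohort = included.index

    attrition = {
        "consented": int(len(dataset.participants)),
        "quality_ok": int(len(quality_ok)),
        "at_least_one_day": attrition_rec.at_least_one_day,
        f"at_least_{config.min_recall_days}_days": attrition_rec.at_least_min_days,
        "analysed": int(len(cohort)),
    }

    # --- harmonised frequencies ------------------------------------------
    ffq_freq = ffq_mod.cohort_frequencies_to_daily(
        dataset.ffq_baseline.loc[cohort], mapping, schema
    )
    ffq2_freq = ffq_mod.cohort_frequencies_to_daily(
        dataset.ffq_repeat.loc[cohort], mapping, schema
    )
    n_days = dataset.participants.loc[cohort, "completed_recall_days"]
    recalls = dataset.recalls[dataset.recalls["participant_id"].isin(set(cohort))]
    rec_freq = recall_mod.cohort_recall_frequencies(
        recalls, dataset.food_map(), schema, n_days
    )

    # --- groups, indices, nutrients ---------------------------------------
    fg = {
        "ffq": groups_mod.aggregate_food_groups(ffq_freq, group_mapping),
        "recall": groups_mod.aggregate_food_groups(rec_freq, group_mapping),
        "ffq_repeat": groups_mod.aggregate_food_groups(ffq2_freq, group_mapping),
    }
    sex = dataset.participants.loc[cohort, "sex"]
    idx_scores = {
        m: groups_mod.score_all_indices(fg[m], index_specs, sex=sex) for m in fg
    }
    portion_g = ffq_mod.cohort_portion_sizes(
        dataset.ffq_baseline.loc[cohort], portions, dataset.participants, schema
    )
    nutr = {
        "ffq": nutr_mod.estimate_nutrients(ffq_freq, portion_g, composition),
        "recall": recall_mod.cohort_recall_nutrients(
            recalls, composition.table, n_days, dataset.food_map()
        ),
        "ffq_repeat": nutr_mod.estimate_nutrients(ffq2_freq, portion_g, composition),
    }

    # --- misreporting screen ----------------------------------------------
    pal_ffq = nutr_mod.cohort_pal_flags(
        nutr["ffq"]["energy_kcal"], dataset.participants, ree,
        config.pal_under_cutoff, config.pal_over_cutoff,
    )
    pal_rec = nutr_mod.cohort_pal_flags(
        nutr["recall"]["energy_kcal"], dataset.participants, ree,
        config.pal_under_cutoff, config.pal_over_cutoff,
    )
    pal_flags = pd.DataFrame(
        {
            "pal_ffq": pal_ffq["pal"],
            "flag_ffq": pal_ffq["flag"],
            "pal_recall": pal_rec["pal"],
            "flag_recall": pal_rec["flag"],
        }
    )
    pal_outlier = (pal_ffq["flag"] != "plausible") | (pal_rec["flag"] != "plausible")
    pal_flags["flag"] = np.where(pal_outlier, "outlier", "plausible")
    for pid in pal_flags.index[pal_outlier]:
        exclusions.append((pid, "pal_outlier_flagged"))
    if config.exclusion_policy == "exclude_pal_outliers":
        analysis_cohort = cohort[~pal_outlier.loc[cohort]]
    else:
        analysis_cohort = cohort
    attrition["pal_outliers"] = int(pal_outlier.loc[cohort].sum())

    def sub(df):
        return df.loc[analysis_cohort]

    # --- statistics battery ------------------------------------------------
    fg_rows, cc_rows, ba_rows = [], [], []
    excl_mask = pal_outlier.loc[analysis_cohort].to_numpy()
    for g in fg["ffq"].columns:
        ref, test = sub(fg["recall"])[g], sub(fg["ffq"])[g]
        fg_rows.append(_corr_row(g, ref, test, ("spearman",)))
        cc = stats_mod.tertile_cross_classify(ref, test, variable=g)
        cc_rows.append({**cc.as_dict(), "kind": "food_group"})
        ba = stats_mod.bland_altman(ref, test, variable=g, excluded_mask=excl_mask)
        ba_rows.append(_ba_row(ba, "food_group"))
    food_group_stats = pd.DataFrame(fg_rows)

    idx_rows = []
    for name in idx_scores["ffq"].columns:
        ref, test = sub(idx_scores["recall"])[name], sub(idx_scores["ffq"])[name]
        row = _corr_row(name, ref, test, ("pearson", "spearman"))
        idx_rows.append(row)
        cc = stats_mod.tertile_cross_classify(ref, test, variable=name)
        cc_rows.append({**cc.as_dict(), "kind": "index"})
        ba = stats_mod.bland_altman(ref, test, variable=name, excluded_mask=excl_mask)
        ba_rows.append(_ba_row(ba, "index"))
    index_stats = pd.DataFrame(idx_rows)

    nut_rows = []
    adjusted = {
        "absolute": (sub(nutr["recall"]), sub(nutr["ffq"])),
        "residual": (
            nutr_mod.energy_adjust(sub(nutr["recall"]), "residual"),
            nutr_mod.energy_adjust(sub(nutr["ffq"]), "residual"),
        ),
        "density": (
            nutr_mod.energy_adjust(sub(nutr["recall"]), "density"),
            nutr_mod.energy_adjust(sub(nutr["ffq"]), "density"),
        ),
    }
    for var in nutr["ffq"].columns:
        for adj, (ref_df, test_df) in adjusted.items():
            if var not in ref_df.columns:  # energy has no energy-adjusted form
                continue
            row = _corr_row(var, ref_df[var], test_df[var], ("pearson", "spearman"))
            row["adjustment"] = adj
            nut_rows.append(row)
        ref, test = sub(nutr["recall"])[var], sub(nutr["ffq"])[var]
        cc = stats_mod.tertile_cross_classify(ref, test, variable=var)
        cc_rows.append({**cc.as_dict(), "kind": "nutrient"})
        ba = stats_mod.bland_altman(ref, test, variable=var, excluded_mask=excl_mask)
        ba_rows.append(_ba_row(ba, "nutrient"))
    nutrient_stats = pd.DataFrame(nut_rows)

    # --- reproducibility (baseline vs repeat questionnaire) ---------------
    rep_rows = []
    blocks = [
        ("food_group", fg["ffq"], fg["ffq_repeat"]),
        ("index", idx_scores["ffq"], idx_scores["ffq_repeat"]),
        ("nutrient", nutr["ffq"], nutr["ffq_repeat"]),
    ]
    for kind, first, second in blocks:
        for var in first.columns:
            m = np.column_stack([sub(first)[var], sub(second)[var]])
            icc = stats_mod.icc_agreement_average(m, variable=var)
            rep_rows.append(
                {
                    "variable": var,
                    "kind": kind,
                    "icc": icc.icc,
                    "ci_low": icc.ci95[0],
                    "ci_high": icc.ci95[1],
                    "icc_single": icc.icc_single,
                    "band": icc.band,
                    "n": icc.n,
                }
            )
    reproducibility = pd.DataFrame(rep_rows)

    # --- data-driven patterns ----------------------------------------------
    pca = {}
    for m in ("ffq", "recall"):
        res = stats_mod.pca_patterns(
            sub(fg[m]), k=config.pca_components, log_offset=config.pca_log_offset
        )
        pca[m] = {
            "r2": res.r2,
            "q2": res.q2,
            "explained_variance": res.explained_variance,
            "n": int(len(analysis_cohort)),
        }

    # --- sex strata ---------------------------------------------------------
    strata_rows = []
    if config.strata == "sex":
        sexes = dataset.participants.loc[analysis_cohort, "sex"]
        for s in sorted(sexes.unique()):
            members = analysis_cohort[(sexes == s).to_numpy()]
            if len(members) < 3:
                continue
            for g in fg["ffq"].columns:
                res = stats_mod.correlate(
                    fg["recall"].loc[members, g], fg["ffq"].loc[members, g],
                    method="spearman", variable=g,
                )
                strata_rows.append(
                    {"stratum": s, "variable": g, "kind": "food_group",
                     "spearman": res.coefficient, "n": res.n}
                )
            for name in idx_scores["ffq"].columns:
                res = stats_mod.correlate(
                    idx_scores["recall"].loc[members, name],
                    idx_scores["ffq"].loc[members, name],
                    method="spearman", variable=name,
                )
                strata_rows.append(
                    {"stratum": s, "variable": name, "kind": "index",
                     "spearman": res.coefficient, "n": res.n}
                )
    strata_stats = pd.DataFrame(
        strata_rows, columns=["stratum", "variable", "kind", "spearman", "n"]
    )

    desc = descriptives(
        {m: sub(fg[m]) for m in ("ffq", "recall")},
        {m: sub(idx_scores[m]) for m in ("ffq", "recall")},
        {m: sub(nutr[m]) for m in ("ffq", "recall")},
    )

    return ValidationReport(
        config=config,
        attrition=attrition,
        exclusions=pd.DataFrame(sorted(set(exclusions)), columns=["participant_id", "reason"]),
        descriptives=desc,
        food_group_stats=food_group_stats,
        index_stats=index_stats,
        nutrient_stats=nutrient_stats,
        cross_class=pd.DataFrame(cc_rows),
        bland_altman=pd.DataFrame(ba_rows),
        reproducibility=reproducibility,
        pca=pca,
        strata_stats=strata_stats,
        pal_flags=pal_flags.loc[analysis_cohort],
    )


def _ba_row(ba: stats_mod.BlandAltmanResult, kind: str) -> dict:
    return {
        "variable": ba.variable,
        "kind": kind,
        "n": ba.n,
        "mean_diff": ba.mean_diff,
        "sd_diff": ba.sd_diff,
        "ci_low": ba.ci_mean[0],
        "ci_high": ba.ci_mean[1],
        "loa_low": ba.limits[0],
        "loa_high": ba.limits[1],
        "n_above": ba.n_above,
        "n_below": ba.n_below,
    }
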