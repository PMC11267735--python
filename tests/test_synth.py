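"""Synthetic-study generator: determinism, identities, calibration."""
import numpy as np
import pandas as pd
import pytest

import ffqval as fv
from ffqval import theory
from ffqval.errors import ConfigurationError
from ffqval.synth import GeneratorConfig


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = fv.generate_cohort(10, seed=1)
        b = fv.generate_cohort(10, seed=1)
        pd.testing.assert_frame_equal(a.participants, b.participants)
        pd.testing.assert_frame_equal(a.ffq_baseline, b.ffq_baseline)
        pd.testing.assert_frame_equal(a.ffq_repeat, b.ffq_repeat)
        pd.testing.assert_frame_equal(a.recalls, b.recalls)
        pd.testing.assert_frame_equal(a.truth_freq, b.truth_freq)

    def test_different_seeds_differ(self):
        a = fv.generate_cohort(10, seed=1)
        b = fv.generate_cohort(10, seed=2)
        assert not a.truth_freq.equals(b.truth_freq)

    def test_written_csvs_reproducible(self, tmp_path):
        for d in ("one", "two"):
            fv.generate_cohort(8, seed=3).write_csvs(tmp_path / d)
        for name in ("participants.csv", "ffq_baseline.csv", "recalls.csv"):
            assert (tmp_path / "one" / name).read_bytes() == (
                tmp_path / "two" / name
            ).read_bytes()

    def test_roundtrip_through_csv(self, tmp_path):
        ds = fv.generate_cohort(8, seed=4)
        ds.write_csvs(tmp_path)
        from ffqval.io import read_study_csvs

        back = read_study_csvs(tmp_path)
        assert np.allclose(back.truth_freq.to_numpy(), ds.truth_freq.to_numpy())
        assert len(back.recalls) == len(ds.recalls)


class TestZeroErrorIdentity:
    def test_ffq_and_recalls_reproduce_truth_exactly(self, zero_error_dataset):
        ds = zero_error_dataset
        ffq = fv.cohort_frequencies_to_daily(ds.ffq_baseline, ds.mapping, ds.schema)
        assert np.allclose(ffq.to_numpy(), ds.truth_freq.to_numpy())
        n_days = ds.recall_day_counts()
        done = n_days[n_days > 0]
        rec = fv.cohort_recall_frequencies(
            ds.recalls[ds.recalls["participant_id"].isin(done.index)],
            ds.food_map(), ds.schema, done,
        )
        assert np.allclose(rec.to_numpy(), ds.truth_freq.loc[done.index].to_numpy())

    def test_zero_noise_truth_lies_on_the_scale(self, zero_error_dataset, mapping):
        vals = np.unique(zero_error_dataset.truth_freq.to_numpy())
        assert set(np.round(vals, 12)) <= set(np.round(mapping.array, 12))

    def test_discretisation_error_bounded_without_snapping(self, mapping):
        """With noise off but continuous truth, the questionnaire reading is
        within half the gap between adjacent scale values."""
        em = fv.ErrorModel(ffq_noise_sd=0.0, recall_within_person_sd=0.0,
                           recall_poisson=False)
        cfg = GeneratorConfig(snap_truth_to_scale=False)
        ds = fv.generate_cohort(30, em, cfg, seed=5)
        ffq = fv.cohort_frequencies_to_daily(ds.ffq_baseline, ds.mapping, ds.schema)
        gaps = np.diff(mapping.array)
        truth = ds.truth_freq.to_numpy()
        err = np.abs(ffq.to_numpy() - truth)
        # bound: half the larger neighbouring gap of the truth's cell
        max_half_gap = gaps.max() / 2
        assert err.max() <= max_half_gap + 1e-12


class TestErrorModelValidation:
    def test_invalid_fields_named(self):
        with pytest.raises(ConfigurationError, match="ffq_noise_sd"):
            fv.ErrorModel(ffq_noise_sd=-0.1)
        with pytest.raises(ConfigurationError, match="episodic_zero_prob"):
            fv.ErrorModel(episodic_zero_prob=1.5)
        with pytest.raises(ConfigurationError, match="ffq_bias"):
            fv.ErrorModel(ffq_bias=0.0)
        with pytest.raises(ConfigurationError, match="completion_probs"):
            GeneratorConfig(completion_probs=(0.5, 0.5))
        with pytest.raises(ConfigurationError, match="pattern_fraction"):
            GeneratorConfig(pattern_fraction=1.0)

    def test_n_must_be_positive(self):
        with pytest.raises(ConfigurationError, match="n must be"):
            fv.generate_cohort(0, seed=1)


class TestEpisodicZeroInflation:
    def test_configured_fraction_of_never_consumers(self):
        em = fv.ErrorModel(episodic_zero_prob=0.3)
        ds = fv.generate_cohort(600, em, seed=6)
        zero_frac = (ds.truth_freq.to_numpy() == 0).mean(axis=0)
        # Bernoulli(0.3) per category: all categories within 4 binomial sds
        se = np.sqrt(0.3 * 0.7 / 600)
        assert np.all(np.abs(zero_frac - 0.3) < 4 * se + 1e-9)

    def test_zero_prob_zero_means_everyone_consumes(self):
        em = fv.ErrorModel(episodic_zero_prob=0.0)
        ds = fv.generate_cohort(100, em, seed=7)
        assert (ds.truth_freq.to_numpy() > 0).all()


class TestRecallMeanRecovery:
    def test_recall_frequencies_unbiased_for_truth(self):
        """Sample-mean oracle: across participants the recall-derived daily
        frequency of each category matches the truth mean within 3 MC SEs."""
        em = fv.ErrorModel(episodic_zero_prob=0.0)
        cfg = GeneratorConfig(completion_probs=(0, 0, 0, 0, 0, 0, 1.0))
        ds = fv.generate_cohort(500, em, cfg, seed=8)
        rec = fv.cohort_recall_frequencies(
            ds.recalls, ds.food_map(), ds.schema, ds.recall_day_counts()
        )
        k = 6
        truth = ds.truth_freq
        for cat in list(truth.columns)[::9]:
            t = truth[cat].to_numpy()
            # Var(recall mean) = Var(truth)/n + E[truth]/(k n) for Poisson days
            se = np.sqrt(t.var(ddof=1) / 500 + t.mean() / (k * 500))
            assert abs(rec[cat].mean() - t.mean()) < 3 * se + 1e-12


class TestSimulateFFQResponses:
    @staticmethod
    def _truth(schema, freq_value):
        freqs = pd.Series(0.0, index=schema.item_ids)
        freqs.iloc[0] = freq_value
        portions = pd.Series(100.0, index=schema.item_ids)
        return fv.TrueDietProfile("P1", freqs, portions, 2000.0)

    def test_zero_truth_maps_to_never(self, schema, mapping):
        em = fv.ErrorModel(ffq_noise_sd=0.0)
        rec = fv.simulate_ffq_responses(self._truth(schema, 0.0), em, mapping)
        assert all(code == 1 for code in rec.responses.values())

    def test_above_scale_truncates_to_top(self, schema, mapping):
        em = fv.ErrorModel(ffq_noise_sd=0.0)
        rec = fv.simulate_ffq_responses(self._truth(schema, 4.5), em, mapping)
        assert rec.responses[schema.item_ids[0]] == 9

    def test_half_per_day_maps_to_nearest_level(self, schema, mapping):
        # nearest-value search oracle over the nine mapped values
        em = fv.ErrorModel(ffq_noise_sd=0.0)
        rec = fv.simulate_ffq_responses(self._truth(schema, 0.5), em, mapping)
        expected = int(np.argmin(np.abs(mapping.array - 0.5))) + 1
        assert rec.responses[schema.item_ids[0]] == expected


class TestAttenuationLaw:
    def test_observed_correlation_matches_analytic_value(self):
        """Measurement-error attenuation: the questionnaire-vs-recall Pearson
        correlation equals the conditional-moment prediction, which itself
        reduces to r_truth,FFQ * sqrt(sb^2/(sb^2+sw^2/k))."""
        em = fv.ErrorModel(ffq_noise_sd=0.35, episodic_zero_prob=0.0)
        cfg = GeneratorConfig(completion_probs=(0, 0, 0, 0, 0, 0, 1.0))
        ds = fv.generate_cohort(500, em, cfg, seed=9)
        cat = theory.attenuation_category(ds.schema)
        f = ds.truth_freq[cat].to_numpy()
        ffq = fv.cohort_frequencies_to_daily(ds.ffq_baseline, ds.mapping, ds.schema)[cat]
        rec = fv.cohort_recall_frequencies(
            ds.recalls, ds.food_map(), ds.schema, ds.recall_day_counts()
        )[cat]
        r_obs = fv.correlate(ffq, rec, method="pearson").coefficient
        r_pred = theory.attenuation_prediction(f, em, ds.mapping, k=6)
        assert r_obs == pytest.approx(r_pred, abs=0.08)
        # the classic law with the discretisation-free FFQ correlation is an
        # upper-bound approximation of the same quantity
        m, _ = theory.ffq_conditional_moments(f, em.ffq_noise_sd, 1.0, ds.mapping)
        r_truth_ffq = np.corrcoef(m, f)[0, 1]
        classic = theory.classic_attenuation(
            r_truth_ffq, f.var(ddof=1), f.mean(), k=6
        )
        assert classic == pytest.approx(r_pred, abs=0.15)

    def test_conditional_moments_zero_noise_reduce_to_discretisation(self, mapping):
        f = np.array([0.0, 0.3, 1.2, 3.9])
        m, v = theory.ffq_conditional_moments(f, 0.0, 1.0, mapping)
        idx = mapping.nearest_level_index(f)
        assert np.allclose(m, mapping.array[idx] * (f > 0))
        assert np.allclose(v, 0.0)
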