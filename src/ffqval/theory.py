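"""Analytic predictions for statistics computed on generated cohorts.

The generator's error structure is simple enough that the population values
of the headline statistics follow in closed form, conditional on the latent
truth sample:

* the questionnaire observes ``D(f * b * exp(eps))`` with ``eps ~ N(0, s^2)``
  and ``D`` the nearest-value discretisation onto the nine scale values, so
  the conditional mean and variance of the questionnaire reading given a
  true frequency ``f`` are finite sums over the nine cells with normal-CDF
  cell probabilities (:func:`ffq_conditional_moments`);
* the k-day recall mean of Poisson day counts has conditional mean ``f`` and
  conditional variance ``f / k``.

Because the recall error is additive and independent of the questionnaire
error given truth, the expected test-vs-reference Pearson correlation and
the repeat-questionnaire ICC follow from these conditional moments by the
law of total (co)variance (:func:`attenuation_prediction`,
:func:`icc_repeat_prediction`).  Ignoring discretisation they reduce to the
classic attenuation law

    r_obs = r(truth, FFQ) * sqrt(sb^2 / (sb^2 + sw^2 / k))

with ``sb^2`` the between-person and ``sw^2`` the within-person variance
(:func:`classic_attenuation`); for the Poisson count channel
``sw^2 = E[f]``.  These predictions are what parameter-recovery checks
compare measured statistics against.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .schema import FrequencyMapping
from .synth import ErrorModel
from .schema import FFQSchema


def discretisation_boundaries(mapping: FrequencyMapping) -> np.ndarray:
    """Cell boundaries of nearest-value discretisation (midpoints)."""
    v = mapping.array
    return (v[:-1] + v[1:]) / 2.0


def ffq_conditional_moments(
    truth_freq: np.ndarray,
    sigma: float,
    bias: float | np.ndarray,
    mapping: FrequencyMapping,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional mean and variance of the discretised questionnaire reading.

    For each true frequency ``f`` the questionnaire reports the scale value
    of the cell into which ``f * bias * exp(eps)`` falls.  Cell probabilities
    are differences of the log-normal CDF at the cell boundaries; a true
    frequency of zero reports "never" with certainty.  Returns arrays of the
    conditional mean and conditional variance, shaped like ``truth_freq``.
    """
    f = np.asarray(truth_freq, dtype=float)
    values = mapping.array
    bounds = discretisation_boundaries(mapping)
    scaled = f * bias
    m = np.zeros_like(f)
    second = np.zeros_like(f)
    pos = scaled > 0
    if sigma == 0:
        idx = mapping.nearest_level_index(scaled[pos])
        m[pos] = values[idx]
        second[pos] = values[idx] ** 2
        return m, second - m ** 2
    z = (np.log(bounds)[None, :] - np.log(scaled[pos])[:, None]) / sigma
    cdf = np.concatenate(
        [np.zeros((z.shape[0], 1)), norm.cdf(z), np.ones((z.shape[0], 1))], axis=1
    )
    probs = np.diff(cdf, axis=1)
    m[pos] = probs @ values
    second[pos] = probs @ values ** 2
    return m, second - m ** 2


def _moments_for(
    truth_freq: np.ndarray,
    error_model: ErrorModel,
    mapping: FrequencyMapping,
    bias: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    return ffq_conditional_moments(truth_freq, error_model.ffq_noise_sd, bias, mapping)


def attenuation_prediction(
    truth_freq: np.ndarray,
    error_model: ErrorModel,
    mapping: FrequencyMapping,
    k: int,
    bias: float = 1.0,
) -> float:
    """Expected Pearson correlation between questionnaire and k-day recall mean.

    Conditional on the truth sample ``f_1..f_n``:

        Cov(FFQ, recall) = Cov(m(f), f)
        Var(FFQ)         = Var(m(f)) + mean(v(f))
        Var(recall)      = Var(f) + mean(f) / k      (Poisson day counts)

    with ``m``/``v`` the conditional questionnaire moments.  The recall error
    is additive, zero-mean and independent of the questionnaire error given
    truth, so the correlation is exactly the ratio of these — the
    discretisation-aware version of the classic attenuation law.
    """
    f = np.asarray(truth_freq, dtype=float)
    m, v = _moments_for(f, error_model, mapping, bias)
    cov = np.cov(m, f, ddof=1)[0, 1]
    var_ffq = np.var(m, ddof=1) + v.mean()
    var_recall = np.var(f, ddof=1) + f.mean() / k
    return float(cov / np.sqrt(var_ffq * var_recall))


def icc_repeat_prediction(
    truth_freq: np.ndarray,
    error_model: ErrorModel,
    mapping: FrequencyMapping,
    k: int = 2,
    bias: float = 1.0,
) -> float:
    """Population ICC(A,k) of k independent questionnaire administrations.

    With no systematic occasion effect (the repeat redraws noise given the
    same truth), the absolute-agreement average-measures ICC is

        Var(m(f)) / (Var(m(f)) + mean(v(f)) / k).
    """
    f = np.asarray(truth_freq, dtype=float)
    m, v = _moments_for(f, error_model, mapping, bias)
    var_b = np.var(m, ddof=1)
    return float(var_b / (var_b + v.mean() / k))


def classic_attenuation(
    r_truth_ffq: float, var_between: float, var_within_day: float, k: int
) -> float:
    """The classic attenuation law, ignoring discretisation.

    ``var_between`` is the between-person variance of true intake,
    ``var_within_day`` the within-person day-to-day variance of the
    reference instrument (``E[f]`` for Poisson occasion counts), and ``k``
    the number of averaged reference days.
    """
    return r_truth_ffq * np.sqrt(var_between / (var_between + var_within_day / k))


def lognormal_between_variance(median: float, gsd: float) -> tuple[float, float]:
    """(mean, variance) of a log-normal intake with given median and geometric SD."""
    mu = np.log(median)
    s2 = np.log(gsd) ** 2
    mean = np.exp(mu + s2 / 2.0)
    var = np.exp(2 * mu + s2) * (np.exp(s2) - 1.0)
    return float(mean), float(var)


def attenuation_category(schema: FFQSchema, min_median: float = 0.3) -> str:
    """Pick a continuously consumed category suitable for attenuation checks:
    non-episodic (zero probability ~0 under an override of 0) with a median
    frequency high enough that the discretised signal carries information."""
    for it in schema.items:
        if it.median_freq_per_day >= min_median and it.zero_prob <= 0.05:
            return it.id
    return schema.items[0].id
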