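"""The method-agreement statistics battery.

Everything a relative-validity/reproducibility study computes when comparing
a test instrument with a reference method:

* :func:`correlate` — Spearman (foods; intakes are right-skewed) or Pearson
  (indices, nutrients) with two-sided p-values and pairwise-complete
  handling of undefined values;
* :func:`tertile_cross_classify` — ranked-thirds classification by each
  method, the 3x3 table and the same/adjacent/gross-misclassification
  percentages used to judge ranking agreement;
* :func:`bland_altman` — paired differences against paired means, the mean
  difference with its 95% CI, and the conventional 1.96-sd limits of
  agreement with outside-point counts;
* :func:`icc_agreement_average` — ICC(A,k): two-way model, absolute
  agreement, average of k measurements, from ANOVA mean squares, with an
  F-based 95% CI and the 0.5/0.75/0.9 qualitative bands;
* :func:`pca_patterns` — principal components of log-transformed,
  unit-variance-scaled food-group intakes, with cumulative R2 and the
  cross-validated predictive fraction Q2 = 1 - PRESS/SS from seven
  interleaved ("venetian blinds") cell-deletion groups.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, FFQValError

#: qualitative ICC bands: [0, .5) poor, [.5, .75) moderate, [.75, .9) good,
#: [.9, 1] excellent
ICC_BAND_EDGES = (0.5, 0.75, 0.9)
ICC_BANDS = ("poor", "moderate", "good", "excellent")


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    variable: str
    method: str  # {spearman, pearson}
    coefficient: float  # NaN when undefined (zero variance)
    p_value: float
    n: int
    note: str = ""


def correlate(
    x,
    y,
    method: str = "spearman",
    variable: str = "",
) -> CorrelationResult:
    """Correlation between two cohort vectors, pairwise-complete.

    Spearman uses average ranks for ties.  Zero variance in either vector
    leaves the coefficient undefined (NaN) with a note, rather than raising.
    """
    if method not in ("spearman", "pearson"):
        raise ConfigurationError(f"unknown correlation method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise FFQValError("correlate: length mismatch")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise FFQValError(f"correlate: need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(variable, method, float("nan"), float("nan"), n,
                                 note="zero variance; coefficient undefined")
    if method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        r, p = sps.pearsonr(x, y)
    return CorrelationResult(variable, method, float(r), float(p), n)


# ---------------------------------------------------------------------------
# tertile cross-classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossClassTable:
    """3x3 reference-tertile x test-tertile counts and summary percentages."""

    variable: str
    counts: np.ndarray  # [ref_tertile, test_tertile], 0-indexed
    n: int
    pct_same: float
    pct_adjacent: float
    pct_gross: float  # opposite-extreme assignments
    pct_same_lowest: float  # of the reference lowest tertile, also test lowest
    pct_same_highest: float
    tied_boundaries: bool = False

    def as_dict(self) -> dict:
        return {
            "variable": self.variable,
            "n": self.n,
            "pct_same": self.pct_same,
            "pct_adjacent": self.pct_adjacent,
            "pct_gross": self.pct_gross,
            "pct_same_lowest": self.pct_same_lowest,
            "pct_same_highest": self.pct_same_highest,
        }


def tertile_assign(values, ids=None) -> np.ndarray:
    """Tertile (0, 1, 2) per observation by ranked thirds.

    Stable sort on value breaks ties by input order (participant-id order
    when the vector is id-ordered), so heavily tied — e.g. zero-inflated —
    variables classify deterministically.  Boundaries fall at ceil(n/3) and
    ceil(2n/3) of the sorted sequence.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    order = np.argsort(v, kind="stable")
    b1 = int(np.ceil(n / 3))
    b2 = int(np.ceil(2 * n / 3))
    tert = np.empty(n, dtype=int)
    tert[order[:b1]] = 0
    tert[order[b1:b2]] = 1
    tert[order[b2:]] = 2
    return tert


def tertile_cross_classify(ref, test, variable: str = "") -> CrossClassTable:
    """Cross-tabulate tertile classifications by two methods."""
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise FFQValError("tertile_cross_classify: length mismatch")
    n = len(ref)
    if n < 3:
        raise FFQValError("tertile_cross_classify: need n >= 3")
    b1, b2 = int(np.ceil(n / 3)), int(np.ceil(2 * n / 3))

    def _boundary_tie(v: np.ndarray) -> bool:
        s = np.sort(v)
        return bool(s[b1 - 1] == s[b1] or s[b2 - 1] == s[b2])

    tied = _boundary_tie(ref) or _boundary_tie(test)
    if tied:
        warnings.warn(
            f"tertile boundaries involve ties for {variable or 'variable'}; "
            "stable input-order tie rule applied",
            stacklevel=2,
        )
    tr = tertile_assign(ref)
    tt = tertile_assign(test)
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (tr, tt), 1)
    same = np.trace(counts)
    gross = counts[0, 2] + counts[2, 0]
    adjacent = n - same - gross
    ref_low = counts[0].sum()
    ref_high = counts[2].sum()
    return CrossClassTable(
        variable=variable,
        counts=counts,
        n=n,
        pct_same=100.0 * same / n,
        pct_adjacent=100.0 * adjacent / n,
        pct_gross=100.0 * gross / n,
        pct_same_lowest=100.0 * counts[0, 0] / ref_low if ref_low else float("nan"),
        pct_same_highest=100.0 * counts[2, 2] / ref_high if ref_high else float("nan"),
        tied_boundaries=tied,
    )


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement between paired measurements (difference = test - reference).

    Both the 95% CI of the mean difference (systematic-bias band) and the
    conventional 1.96-sd limits of agreement (individual-point band) are
    reported; outside-point counts refer to the limits of agreement.
    """

    variable: str
    n: int
    mean_diff: float
    sd_diff: float
    ci_mean: tuple[float, float]
    limits: tuple[float, float]
    n_above: int
    n_below: int
    points: pd.DataFrame = field(repr=False, default=None)  # mean, diff, excluded


def bland_altman(
    ref,
    test,
    variable: str = "",
    excluded_mask=None,
) -> BlandAltmanResult:
    """Bland-Altman agreement analysis of test against reference.

    ``excluded_mask`` optionally flags participants (e.g. PAL outliers) in
    the exported plotting data without removing them from the computation,
    mirroring how such points are highlighted rather than dropped.
    """
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.shape != test.shape:
        raise FFQValError("bland_altman: length mismatch")
    n = len(ref)
    if n < 2:
        raise FFQValError("bland_altman: need n >= 2")
    diff = test - ref
    pair_mean = (test + ref) / 2.0
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    tcrit = float(sps.t.ppf(0.975, n - 1))
    half = tcrit * sd / np.sqrt(n)
    lo, hi = md - 1.96 * sd, md + 1.96 * sd
    points = pd.DataFrame({
        "pair_mean": pair_mean,
        "difference": diff,
        "excluded": np.asarray(excluded_mask, dtype=bool)
        if excluded_mask is not None else np.zeros(n, dtype=bool),
    })
    return BlandAltmanResult(
        variable=variable,
        n=n,
        mean_diff=md,
        sd_diff=sd,
        ci_mean=(md - half, md + half),
        limits=(lo, hi),
        n_above=int((diff > hi).sum()),
        n_below=int((diff < lo).sum()),
        points=points,
    )


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

def icc_band(icc: float) -> str:
    """Qualitative reproducibility band for an ICC value."""
    if icc < ICC_BAND_EDGES[0]:
        return "poor"
    if icc < ICC_BAND_EDGES[1]:
        return "moderate"
    if icc < ICC_BAND_EDGES[2]:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class ICCResult:
    variable: str
    icc: float  # ICC(A,k): absolute agreement, average measures
    ci95: tuple[float, float]
    icc_single: float  # ICC(A,1), for completeness
    msr: float  # rows (participants) mean square
    msc: float  # columns (occasions) mean square
    mse: float  # error mean square
    n: int
    k: int
    band: str


def icc_agreement_average(measurements, variable: str = "") -> ICCResult:
    """ICC for absolute agreement, average measures, two-way model.

    ``measurements`` is a complete n x k matrix (participants x occasions,
    e.g. baseline and repeat questionnaire administrations).  From the
    two-way ANOVA mean squares,

        ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

    with MSR/MSC/MSE the row/column/error mean squares.  The 95% CI follows
    the F-based construction for the absolute-agreement coefficients
    (single-measure bounds stepped up to k measurements).  Degenerate
    between-participant variance yields ICC <= 0, reported as computed with
    band "poor".
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2:
        raise FFQValError("icc: measurements must be an n x k matrix")
    n, k = m.shape
    if n < 3 or k < 2:
        raise FFQValError(f"icc: need n >= 3 and k >= 2, got {n} x {k}")
    if np.isnan(m).any():
        raise FFQValError("icc: matrix must be complete (no missing cells)")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((m - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    denom_k = msr + (msc - mse) / n
    icc_k = (msr - mse) / denom_k if denom_k != 0 else float("nan")
    denom_1 = msr + (k - 1) * mse + k * (msc - mse) / n
    icc_1 = (msr - mse) / denom_1 if denom_1 != 0 else float("nan")

    ci = _icc_agreement_ci(icc_1, msr, msc, mse, n, k)
    return ICCResult(
        variable=variable,
        icc=float(icc_k),
        ci95=ci,
        icc_single=float(icc_1),
        msr=float(msr),
        msc=float(msc),
        mse=float(mse),
        n=n,
        k=k,
        band=icc_band(float(icc_k)),
    )


def _icc_agreement_ci(icc_1: float, msr: float, msc: float, mse: float,
                      n: int, k: int, alpha: float = 0.05) -> tuple[float, float]:
    """95% CI for ICC(A,k) via the single-measure F construction.

    Single-measure bounds use the Satterthwaite-type degrees of freedom of
    the weighted mean-square denominator; average-measure bounds follow by
    the k-measurement step-up r -> k r / (1 + (k-1) r).
    """
    if not np.isfinite(icc_1) or mse == 0:
        # degenerate: perfect agreement or no error variance
        if mse == 0 and msr > 0:
            return (1.0, 1.0)
        return (float("nan"), float("nan"))
    a = (k * icc_1) / (n * (1.0 - icc_1)) if icc_1 != 1.0 else np.inf
    b = 1.0 + (k * icc_1 * (n - 1.0)) / (n * (1.0 - icc_1)) if icc_1 != 1.0 else np.inf
    if not np.isfinite(a):
        return (1.0, 1.0)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower1 = n * (msr - f1 * mse) / (
        f1 * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper1 = n * (f2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2 * msr
    )

    def step_up(r: float) -> float:
        return k * r / (1.0 + (k - 1.0) * r)

    return (float(step_up(lower1)), float(step_up(upper1)))


# ---------------------------------------------------------------------------
# PCA with cross-validated Q2
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAResult:
    """Principal components of preprocessed food-group intakes.

    ``r2`` and ``q2`` are cumulative over components: r2[a] is the variance
    fraction explained by components 1..a+1; q2[a] the cross-validated
    predictive fraction 1 - PRESS/SS of the (a+1)-component model.
    """

    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # observations x components
    explained_variance: np.ndarray
    r2: np.ndarray
    q2: np.ndarray
    dropped_columns: tuple[str, ...]
    log_offset: float
    n_cv_groups: int


def _preprocess(matrix: pd.DataFrame, log_offset: float) -> tuple[pd.DataFrame, tuple[str, ...]]:
    x = np.log10(matrix.to_numpy(dtype=float) + log_offset)
    x = pd.DataFrame(x, index=matrix.index, columns=matrix.columns)
    sd = x.std(ddof=1)
    dropped = tuple(x.columns[sd == 0])
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {list(dropped)}", stacklevel=3)
        x = x.drop(columns=list(dropped))
        sd = sd.drop(labels=list(dropped))
    return (x - x.mean()) / sd, dropped


def _pca_impute(x: np.ndarray, k: int, tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Rank-``k`` model predictions for a matrix with missing cells (NaN).

    Expectation-maximisation on the truncated SVD: missing cells start at 0
    (the column mean after centring), the rank-``k`` approximation of the
    completed matrix refills them, iterate to convergence.  This fits the
    principal-component model to the observed cells only and is the stable
    way to predict held-out cells in cross-validation.  Returns the full
    rank-``k`` approximation.
    """
    miss = np.isnan(x)
    xf = np.where(miss, 0.0, x)
    approx = np.zeros_like(xf)
    for _ in range(max_iter):
        u, s, vt = np.linalg.svd(xf, full_matrices=False)
        new_approx = (u[:, :k] * s[:k]) @ vt[:k]
        delta = np.abs(new_approx[miss] - approx[miss]).max() if miss.any() else 0.0
        approx = new_approx
        xf = np.where(miss, approx, x)
        if delta <= tol:
            break
    return approx


def pca_patterns(
    matrix: pd.DataFrame,
    k: int = 2,
    log_offset: float = 1.0,
    n_cv_groups: int = 7,
    cv_pattern: str = "cells",
) -> PCAResult:
    """PCA of food-group intakes with cross-validated predictive power.

    Preprocessing is log10(x + offset) followed by centring and scaling each
    column to unit variance, so groups on different intake scales weigh
    equally and zeros are admitted.  Components come from the singular value
    decomposition of the preprocessed matrix.  For Q2, every
    ``n_cv_groups``-th element — of the row-major cell sequence
    (``cv_pattern="cells"``, the venetian-blinds convention) or of the rows
    (``cv_pattern="rows"``) — is deleted in turn, a ``k``-component model is
    refit without the held-out entries (NIPALS with missing cells), the
    held-out entries are predicted, and Q2 = 1 - PRESS/SS.
    """
    if cv_pattern not in ("cells", "rows"):
        raise ConfigurationError(f"unknown cv_pattern {cv_pattern!r}")
    x, dropped = _preprocess(matrix, log_offset)
    n, p = x.shape
    if k >= min(n, p):
        raise ConfigurationError(f"k={k} must be below the matrix rank bound {min(n, p)}")
    xv = x.to_numpy(dtype=float)

    u, s, vt = np.linalg.svd(xv, full_matrices=False)
    # deterministic sign: largest-magnitude loading of each component positive
    for a in range(len(s)):
        j = np.argmax(np.abs(vt[a]))
        if vt[a, j] < 0:
            vt[a] *= -1.0
            u[:, a] *= -1.0
    ev = s ** 2 / (n - 1)
    total = (xv ** 2).sum()
    r2 = np.cumsum(s ** 2)[:k] / total

    press = np.zeros(k)
    cells = np.arange(n * p)
    for g in range(n_cv_groups):
        if cv_pattern == "cells":
            held = cells[g::n_cv_groups]
            rows, colsj = np.unravel_index(held, (n, p))
            xm = xv.copy()
            xm[rows, colsj] = np.nan
            for a in range(k):
                pred = _pca_impute(xm, a + 1)
                press[a] += ((xv[rows, colsj] - pred[rows, colsj]) ** 2).sum()
        else:
            # row-wise deletion: fit loadings on the kept rows, predict each
            # held-out row from its projection onto those loadings
            rows_held = np.arange(n)[g::n_cv_groups]
            keep = np.setdiff1d(np.arange(n), rows_held)
            _, _, vt_g = np.linalg.svd(xv[keep], full_matrices=False)
            for a in range(k):
                ld = vt_g[: a + 1].T
                pred = (xv[rows_held] @ ld) @ ld.T
                press[a] += ((xv[rows_held] - pred) ** 2).sum()
    q2 = 1.0 - press / total

    comp_names = [f"PC{a + 1}" for a in range(k)]
    return PCAResult(
        loadings=pd.DataFrame(vt[:k].T, index=x.columns, columns=comp_names),
        scores=pd.DataFrame(u[:, :k] * s[:k], index=x.index, columns=comp_names),
        explained_variance=ev[:k],
        r2=r2,
        q2=q2,
        dropped_columns=dropped,
        log_offset=log_offset,
        n_cv_groups=n_cv_groups,
    )
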