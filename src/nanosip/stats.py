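"""Normality-gated group comparisons, the subsample-median bootstrap
polynomial fit, and heterogeneity profiling.

The trend-fitting procedure is a subsample bootstrap: at every incubation
time point, 70% of the per-cell values are drawn (without replacement by
default — a 70% subset, not a classical with-replacement bootstrap), the
subsample medians form one (time, median) series, and a second-order
polynomial is least-squares fitted to it.  Repeating this many times gives
an empirical distribution per coefficient; the reported coefficient is the
center of the most populated histogram bin ("highest frequency of
occurrence").  The residual sum of squares (RSS) of the modal polynomial
is evaluated against the full-data per-time-point medians.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from .datatypes import TimeSeriesDataset

logger = logging.getLogger(__name__)

ALPHA = 0.05


# --------------------------------------------------------------------------
# Normality gate and pairwise tests


@dataclass(frozen=True)
class NormalityResult:
    p_value: float
    is_normal: bool


def test_normality(values, alpha: float = ALPHA) -> NormalityResult:
    """Shapiro-Wilk normality test; a sample is treated as normal if p > alpha.

    A constant sample is reported as non-normal with p = 0 (the statistic is
    undefined there) and a warning; fewer than 3 values is an error.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if np.ptp(values) == 0:
        logger.warning("normality test on a constant sample; reporting p=0 (non-normal)")
        return NormalityResult(p_value=0.0, is_normal=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns for n > 5000; p stays usable
        p = float(sp_stats.shapiro(values).pvalue)
    return NormalityResult(p_value=p, is_normal=p > alpha)


@dataclass(frozen=True)
class PairwiseTestResult:
    label_a: str
    label_b: str
    test: str  # "student_t" | "mann_whitney_u"
    statistic: float
    p_value: float
    significant: bool
    p_holm: float | None = None  # family-wise adjusted p, opt-in


def compare_groups(a, b, alpha: float = ALPHA, label_a: str = "a", label_b: str = "b") -> PairwiseTestResult:
    """Two-sample comparison with a Shapiro-Wilk gate.

    If both groups pass the normality test, an unpaired two-sided Student
    t-test with pooled variance is used; otherwise a two-sided
    Mann-Whitney U test.  Significance is declared at ``p < alpha``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("both groups need at least 3 observations")
    if test_normality(a, alpha).is_normal and test_normality(b, alpha).is_normal:
        res = sp_stats.ttest_ind(a, b, equal_var=True)
        test = "student_t"
    else:
        res = sp_stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mann_whitney_u"
    p = float(res.pvalue)
    return PairwiseTestResult(
        label_a=label_a,
        label_b=label_b,
        test=test,
        statistic=float(res.statistic),
        p_value=p,
        significant=p < alpha,
    )


def pairwise_matrix(
    data: TimeSeriesDataset, alpha: float = ALPHA, holm_adjust: bool = False
) -> list[PairwiseTestResult]:
    """All pairwise time-point comparisons (upper triangle).

    Time points with fewer than 3 cells are skipped with a warning (the
    gate itself needs n >= 3).  Raw p-values decide ``significant`` (no
    multiplicity correction by default); ``holm_adjust=True`` additionally
    fills the ``p_holm`` column with Holm-adjusted p-values.
    """
    out = []
    for i in range(data.n_timepoints):
        for j in range(i + 1, data.n_timepoints):
            a, b = data.groups[i], data.groups[j]
            if a.size < 3 or b.size < 3:
                logger.warning("skipping pair (%g h, %g h): a group has n < 3",
                               data.times_h[i], data.times_h[j])
                continue
            out.append(compare_groups(a, b, alpha,
                                      label_a=f"{data.times_h[i]:g}h",
                                      label_b=f"{data.times_h[j]:g}h"))
    if holm_adjust and out:
        from statsmodels.stats.multitest import multipletests

        adjusted = multipletests([r.p_value for r in out], method="holm")[1]
        out = [dataclasses.replace(r, p_holm=float(p)) for r, p in zip(out, adjusted)]
    return out


# --------------------------------------------------------------------------
# Subsample-median bootstrap polynomial fit


@dataclass
class BootstrapFitConfig:
    """Settings of the subsample-median polynomial fit."""

    subsample_fraction: float = 0.7
    n_reps: int = 10_000
    poly_order: int = 2
    seed: int = 0
    with_replacement: bool = False
    joint_mode: bool = False  # mode of the joint 3-D coefficient histogram

    def __post_init__(self) -> None:
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")


@dataclass
class BootstrapFitResult:
    """Modal polynomial coefficients and their empirical distributions.

    ``coefficients`` are ordered highest degree first (numpy polynomial
    convention); ``histograms`` maps a degree index (0 = highest) to
    ``(bin_edges, counts)`` with counts summing to ``n_reps``; ``rss`` is
    the residual sum of squares of the modal polynomial against the
    full-data per-time-point medians.
    """

    coefficients: tuple[float, ...]
    histograms: list[tuple[np.ndarray, np.ndarray]]
    rss: float
    times_h: list[float]
    full_medians: np.ndarray
    rep_coefficients: np.ndarray | None = None

    def predict(self, t) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(t, dtype=float))


def _coef_histogram(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Freedman-Diaconis histogram of one coefficient's rep values.

    Degenerate samples (all reps identical, or an IQR of zero) collapse to
    a single bin centered on the common/median value.
    """
    if np.ptp(values) == 0 or values.size < 2:
        v = float(values[0]) if np.ptp(values) == 0 else float(np.median(values))
        half = max(abs(v) * 1e-12, 1e-300)
        edges = np.array([v - half, v + half])
        return edges, np.array([values.size])
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    if iqr == 0:
        # FD bin width degenerates; a single bin spanning the data keeps the
        # mode at the bulk of the mass.
        edges = np.array([values.min(), values.max()])
        return edges, np.array([values.size])
    counts, edges = np.histogram(values, bins="fd")
    return edges, counts


def _modal_center(edges: np.ndarray, counts: np.ndarray) -> float:
    i = int(np.argmax(counts))  # ties: lowest bin wins
    return float((edges[i] + edges[i + 1]) / 2.0)


def bootstrap_polyfit(data: TimeSeriesDataset, config: BootstrapFitConfig | None = None) -> BootstrapFitResult:
    """Repeated 70%-subsample median polynomial fit with modal coefficients.

    Per repetition, each time point contributes the median of
    ``ceil(fraction * n)`` values drawn without replacement (or with, if
    configured); an order-``poly_order`` polynomial is least-squares fitted
    to the (time, median) pairs.  After all repetitions, each coefficient's
    reported value is the center of the most frequent bin of its
    Freedman-Diaconis histogram.  Deterministic given ``config.seed``.
    """
    config = config or BootstrapFitConfig()
    n_coef = config.poly_order + 1
    if data.n_timepoints < n_coef:
        raise ValueError(
            f"need at least {n_coef} time points for a degree-{config.poly_order} fit, "
            f"got {data.n_timepoints}"
        )
    times = np.asarray(data.times_h, dtype=float)
    rng = np.random.default_rng(config.seed)
    reps = config.n_reps

    medians = np.empty((reps, data.n_timepoints))
    for g, values in enumerate(data.groups):
        n = values.size
        m = math.ceil(config.subsample_fraction * n)
        if config.with_replacement:
            idx = rng.integers(0, n, size=(reps, m))
        else:
            # Rank the first m of a random permutation per rep, vectorized:
            # argpartition of iid uniforms yields a uniform m-subset.
            u = rng.random((reps, n))
            idx = np.argpartition(u, m - 1, axis=1)[:, :m]
        medians[:, g] = np.median(values[idx], axis=1)

    # One least-squares solve for all reps: coeffs = medians @ pinv(V).T,
    # columns of V are t^order ... t^0 (numpy polyval order).
    vand = np.vander(times, n_coef)
    coefs = medians @ np.linalg.pinv(vand).T  # (reps, n_coef)

    histograms = [_coef_histogram(coefs[:, j]) for j in range(n_coef)]
    if config.joint_mode:
        edges_list = [h[0] for h in histograms]
        joint, _ = np.histogramdd(coefs, bins=edges_list)
        flat = np.unravel_index(int(np.argmax(joint)), joint.shape)
        modal = tuple(float((e[i] + e[i + 1]) / 2.0) for e, i in zip(edges_list, flat))
    else:
        modal = tuple(_modal_center(*h) for h in histograms)

    full_medians = np.array([np.median(g) for g in data.groups])
    residuals = np.polyval(modal, times) - full_medians
    rss = float(residuals @ residuals)
    return BootstrapFitResult(
        coefficients=modal,
        histograms=histograms,
        rss=rss,
        times_h=list(data.times_h),
        full_medians=full_medians,
        rep_coefficients=coefs,
    )


# --------------------------------------------------------------------------
# Heterogeneity profiling


@dataclass
class HeterogeneityProfile:
    """Per-time-point dispersion and its trend over incubation time.

    ``robust_cv`` is the IQR divided by the absolute median (NaN where the
    median is zero).  ``trend_spearman`` is the Spearman rank correlation
    of IQR against time; when it is undefined (constant IQR) it is reported
    as 0 with ``trend_defined = False``.
    """

    times_h: list[float]
    iqr: list[float]
    robust_cv: list[float]
    n: list[int]
    undersized: list[bool]
    trend_spearman: float
    trend_defined: bool


def heterogeneity_profile(data: TimeSeriesDataset, min_n: int = 3) -> HeterogeneityProfile:
    """Profile how cell-to-cell spread evolves with incubation time."""
    iqrs, rcvs, ns, flags = [], [], [], []
    for t, values in zip(data.times_h, data.groups):
        n = values.size
        undersized = n < min_n
        if undersized:
            logger.warning("time point %g h has only n=%d cells; dispersion is unreliable", t, n)
        q75, q25 = np.percentile(values, [75, 25])
        iqr = float(q75 - q25)
        med = float(np.median(values))
        iqrs.append(iqr)
        rcvs.append(iqr / abs(med) if med != 0 else float("nan"))
        ns.append(int(n))
        flags.append(bool(undersized))
    if np.ptp(iqrs) == 0 or len(iqrs) < 2:
        trend, defined = 0.0, False
        logger.warning("IQR trend undefined (constant dispersion); reporting 0")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = sp_stats.spearmanr(data.times_h, iqrs).statistic
        if np.isnan(rho):
            trend, defined = 0.0, False
        else:
            trend, defined = float(rho), True
    return HeterogeneityProfile(
        times_h=list(data.times_h),
        iqr=iqrs,
        robust_cv=rcvs,
        n=ns,
        undersized=flags,
        trend_spearman=trend,
        trend_defined=defined,
    )
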