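"""Reliability and group-comparison statistics for EPTG measurements.

Covers the full analysis battery: Mann-Whitney U group comparisons,
Fisher's exact test for the sex ratio, Bonferroni-Holm adjustment,
two-way single-score intraclass correlation coefficients — ICC(A,1),
absolute agreement under a two-way random-effects model, and ICC(C,1),
consistency, insensitive to constant rater bias — with McGraw–Wong
F-based 95% confidence intervals and the conventional literature
classification (< 0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good, > 0.9
excellent; boundaries go to the higher class), a Monte Carlo permutation
test comparing the with-aid ICC against ICCs of tables whose rows are
randomly reassigned between the two aid conditions, and the a priori
Mann-Whitney sample-size computation via the noncentral-t power iteration
inflated by the asymptotic relative efficiency 0.955 under normal
parents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

from .errors import NumericalError, ValidationError

__all__ = [
    "ICCResult",
    "PermutationResult",
    "mann_whitney",
    "fisher_exact",
    "holm_adjust",
    "icc",
    "classify_icc",
    "permutation_icc_test",
    "mw_sample_size",
    "MANN_WHITNEY_ARE",
]

#: Asymptotic relative efficiency of the Mann-Whitney test vs the t-test
#: under normal parent distributions.
MANN_WHITNEY_ARE = 0.955


# ---------------------------------------------------------------------------
# classical tests
# ---------------------------------------------------------------------------

def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of group_a, p).

    Uses the exact null distribution for small samples without ties and
    the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    res = _sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2×2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError("fisher_exact needs a 2×2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValidationError("table must hold non-negative integers")
        t = t.astype(int)
    return float(_sps.fisher_exact(t, alternative="two-sided")[1])


def holm_adjust(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("p_values must be a non-empty 1D sequence")
    if np.any(p < 0) or np.any(p > 1) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    """A single-score ICC with its 95% CI and literature classification."""

    estimate: float
    ci_lo: float
    ci_hi: float
    form: str  # "A1" or "C1"
    n_subjects: int
    n_raters: int
    classification: str

    def __str__(self) -> str:
        return (f"ICC({self.form[0]},1) = {self.estimate:.2f} "
                f"[{self.ci_lo:.2f}-{self.ci_hi:.2f}] ({self.classification})")


def classify_icc(value: float) -> str:
    """Literature reliability classification of an ICC value.

    < 0.5 poor, [0.5, 0.75) moderate, [0.75, 0.9) good, >= 0.9 excellent
    (the published intervals overlap at their endpoints; boundaries are
    assigned to the higher class).
    """
    if value > 1:
        raise ValidationError("ICC cannot exceed 1")
    if value >= 0.9:
        return "excellent"
    if value >= 0.75:
        return "good"
    if value >= 0.5:
        return "moderate"
    return "poor"


def _mean_squares(y: np.ndarray):
    """Two-way ANOVA mean squares (rows = subjects, columns = raters).

    Works on a stack: y may be (n, k) or (B, n, k); returns MSR, MSC, MSE
    with matching leading shape.
    """
    n, k = y.shape[-2], y.shape[-1]
    grand = y.mean(axis=(-1, -2), keepdims=True)
    row_m = y.mean(axis=-1, keepdims=True)
    col_m = y.mean(axis=-2, keepdims=True)
    ssr = k * ((row_m - grand) ** 2).sum(axis=(-1, -2))
    ssc = n * ((col_m - grand) ** 2).sum(axis=(-1, -2))
    sst = ((y - grand) ** 2).sum(axis=(-1, -2))
    sse = sst - ssr - ssc
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def _icc_point(y: np.ndarray, form: str) -> np.ndarray:
    msr, msc, mse = _mean_squares(y)
    n, k = y.shape[-2], y.shape[-1]
    if form == "A1":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    elif form == "C1":
        denom = msr + (k - 1) * mse
    else:
        raise ValidationError(f"unknown ICC form: {form!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom == 0, 0.0, (msr - mse) / denom)
    return out


def icc(matrix, form: str = "A1", alpha: float = 0.05) -> ICCResult:
    """Single-score ICC of a complete subjects × raters matrix.

    form "A1": two-way random effects, absolute agreement,
    (MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE)).
    form "C1": two-way, consistency, (MSR − MSE) / (MSR + (k−1)MSE).
    Confidence intervals follow the McGraw–Wong F-based formulas
    (Satterthwaite degrees of freedom for A1).
    """
    y = np.asarray(matrix, float)
    if hasattr(matrix, "values"):
        y = np.asarray(matrix.values, float)
    if y.ndim != 2:
        raise ValidationError("matrix must be 2D (subjects × raters)")
    if np.isnan(y).any():
        raise ValidationError("missing cells are not supported (complete design)")
    n, k = y.shape
    if n < 3 or k < 2:
        raise ValidationError("need >= 3 subjects and >= 2 raters")
    msr, msc, mse = _mean_squares(y)
    est = float(min(_icc_point(y, form), 1.0))  # guard FP overshoot at 1
    df_e = (n - 1) * (k - 1)
    if form == "C1":
        if mse == 0:  # perfect consistency: degenerate interval
            lo, hi = est, 1.0
        else:
            f_obs = msr / mse
            f_l = f_obs / _sps.f.ppf(1 - alpha / 2, n - 1, df_e)
            f_u = f_obs * _sps.f.ppf(1 - alpha / 2, df_e, n - 1)
            lo = (f_l - 1) / (f_l + k - 1)
            hi = (f_u - 1) / (f_u + k - 1)
    else:  # A1, Satterthwaite
        if est >= 1.0 or mse == 0:
            lo, hi = est, 1.0
        else:
            a = k * est / (n * (1 - est))
            b = 1 + k * est * (n - 1) / (n * (1 - est))
            num = (a * msc + b * mse) ** 2
            den = ((a * msc) ** 2 / (k - 1)
                   + (b * mse) ** 2 / ((n - 1) * (k - 1)))
            v = num / den
            f_l = _sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = _sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = (n * (msr - f_l * mse)
                  / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
            hi = (n * (f_u * msr - mse)
                  / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
    lo = float(min(max(lo, -1.0), est))
    hi = float(max(min(hi, 1.0), est))
    return ICCResult(estimate=est, ci_lo=lo, ci_hi=hi, form=form,
                     n_subjects=n, n_raters=k,
                     classification=classify_icc(est))


# ---------------------------------------------------------------------------
# Monte Carlo permutation comparison of ICCs
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Outcome of the Monte Carlo permutation ICC comparison."""

    p_value: float
    n_permutations: int
    seed: int
    observed_icc: float
    null_mean: float
    null_q05: float
    null_q95: float
    statistic: str = "icc"


def permutation_icc_test(with_aid, without_aid, n_permutations: int = 100_000,
                         seed: int = 0, statistic: str = "icc",
                         batch: int = 2_000) -> PermutationResult:
    """Monte Carlo permutation test of ICC(A,1) improvement with aid.

    The observed statistic is the ICC(A,1) of the with-aid table (or, with
    ``statistic="difference"``, with-aid minus without-aid ICC, provided
    for sensitivity analysis).  For each replicate every subject's full
    rater row is drawn from the with-aid or without-aid table with
    probability ½; p = (#{replicate stat >= observed} + 1) /
    (n_permutations + 1) — the add-one correction keeps p > 0 where a raw
    proportion of "better" replicates would report an invalid zero.
    """
    w = np.asarray(with_aid, float)
    wo = np.asarray(without_aid, float)
    if hasattr(with_aid, "values"):
        w = np.asarray(with_aid.values, float)
    if hasattr(without_aid, "values"):
        wo = np.asarray(without_aid.values, float)
    if w.shape != wo.shape or w.ndim != 2:
        raise ValidationError("matrices must be 2D and share shape")
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    n = w.shape[0]
    if statistic == "icc":
        observed = float(_icc_point(w, "A1"))
    elif statistic == "difference":
        observed = float(_icc_point(w, "A1") - _icc_point(wo, "A1"))
    else:
        raise ValidationError("statistic must be 'icc' or 'difference'")
    rng = np.random.default_rng(seed)
    count = 0
    total = 0.0
    stats_all = []
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        pick = rng.random((b, n, 1)) < 0.5
        y = np.where(pick, w[None], wo[None])
        if statistic == "icc":
            s = _icc_point(y, "A1")
        else:
            y2 = np.where(pick, wo[None], w[None])
            s = _icc_point(y, "A1") - _icc_point(y2, "A1")
        count += int(np.sum(s >= observed - 1e-12))
        total += float(np.sum(s))
        stats_all.append(s)
        done += b
    null = np.concatenate(stats_all)
    p = (count + 1) / (n_permutations + 1)
    return PermutationResult(
        p_value=float(p), n_permutations=n_permutations, seed=seed,
        observed_icc=observed, null_mean=float(null.mean()),
        null_q05=float(np.quantile(null, 0.05)),
        null_q95=float(np.quantile(null, 0.95)), statistic=statistic,
    )


# ---------------------------------------------------------------------------
# a priori power analysis
# ---------------------------------------------------------------------------

def _t_test_power(n: int, d: float, alpha: float) -> float:
    df = 2 * n - 2
    ncp = d * np.sqrt(n / 2.0)
    crit = _sps.t.ppf(1 - alpha / 2, df)
    return float(1 - _sps.nct.cdf(crit, df, ncp) + _sps.nct.cdf(-crit, df, ncp))


def mw_sample_size(mean1: float, sd1: float, mean2: float, sd2: float,
                   alpha: float = 0.05, power: float = 0.8,
                   method: str = "are", floor: int = 3,
                   max_n: int = 10_000) -> int:
    """Per-group sample size for a two-sided Mann-Whitney comparison.

    Cohen's d is computed from the pooled SD; the smallest integer n
    giving the requested two-sample t-test power is found by iterating
    the noncentral-t power equation, then (``method="are"``, default)
    inflated by the Mann-Whitney asymptotic relative efficiency 0.955
    under normal parents and rounded up.  ``method="t-test"`` returns the
    plain t-test n.  The result is floored at ``floor`` per group.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("standard deviations must be positive")
    if mean1 == mean2:
        raise NumericalError("equal means: required sample size diverges")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValidationError("alpha and power must lie in (0, 1)")
    pooled = np.sqrt((sd1**2 + sd2**2) / 2.0)
    d = abs(mean1 - mean2) / pooled
    n_t = None
    for n in range(2, max_n + 1):
        if _t_test_power(n, d, alpha) >= power:
            n_t = n
            break
    if n_t is None:
        raise NumericalError(f"required n exceeds {max_n} per group")
    if method == "t-test":
        return max(n_t, floor)
    if method != "are":
        raise ValidationError("method must be 'are' or 't-test'")
    return max(int(np.ceil(n_t / MANN_WHITNEY_ARE)), floor)
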