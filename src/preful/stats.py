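"""Comparison statistics: paired Wilcoxon, correlations, ICC(A,1).

Pearson and Spearman correlations and the large-sample Wilcoxon test are
delegated to scipy; the exact Wilcoxon null distribution (needed at small
n, where the normal approximation is poor, and with tied or zero
differences) is computed by dynamic programming over the signed-rank sum;
the single-measure absolute-agreement intraclass correlation ICC(A,1) and
its F-based 95% confidence interval follow the standard two-way ANOVA
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as ss

EXACT_WILCOXON_MAX_N = 25


@dataclass
class PairedSample:
    a: np.ndarray
    b: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("paired sample needs two equal-length 1D vectors")
        if self.a.size < 3:
            raise ValueError("need at least 3 pairs")
        if not (np.isfinite(self.a).all() and np.isfinite(self.b).all()):
            raise ValueError("paired sample must be finite")


@dataclass
class ICCResult:
    icc: float
    ci_lo: float
    ci_hi: float
    n: int
    k: int


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the signed-rank sum via DP enumeration.

    Ranks may contain midranks (ties); doubling makes them integers and the
    distribution of ``W+`` over all 2^n sign assignments is built by
    convolution.  The two-sided p doubles the smaller tail (capped at 1),
    matching the symmetric-null convention.
    """
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(w_plus * 2))
    cdf = counts[: w2 + 1].sum()
    sf = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(sample: PairedSample) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped; the exact null is used up to n = 25
    non-zero differences, the tie-corrected normal approximation beyond.
    """
    d = sample.a - sample.b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    ranks = ss.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if d.size <= EXACT_WILCOXON_MAX_N:
        return _exact_signed_rank_p(ranks, w_plus)
    res = ss.wilcoxon(d, zero_method="wilcox", correction=True, method="approx")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def pearson(sample: PairedSample) -> tuple[float, float]:
    if sample.a.std() == 0 or sample.b.std() == 0:
        raise ValueError("zero variance: Pearson correlation undefined")
    r = ss.pearsonr(sample.a, sample.b)
    return float(r.statistic), float(r.pvalue)


def spearman(sample: PairedSample) -> tuple[float, float]:
    if sample.a.std() == 0 or sample.b.std() == 0:
        raise ValueError("zero variance: Spearman correlation undefined")
    rho = ss.spearmanr(sample.a, sample.b)
    return float(rho.statistic), float(rho.pvalue)


# ---------------------------------------------------------------------------
# ICC(A,1)
# ---------------------------------------------------------------------------


def _two_way_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """Row (subject), column (rater) and residual mean squares."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    return (ss_rows / (n - 1), ss_cols / (k - 1),
            ss_err / ((n - 1) * (k - 1)))


def icc_a1(data: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """Single-measure absolute-agreement ICC from an n x k matrix.

    Two-way model:
    ``ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))``,
    with the F-based (Satterthwaite df) confidence interval of McGraw &
    Wong for absolute agreement.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("data must be an n x k matrix")
    n, k = data.shape
    if n < 5 or k < 2:
        raise ValueError("need at least 5 subjects and 2 raters/scans")
    if not np.isfinite(data).all():
        raise ValueError("matrix must be complete and finite")
    if np.allclose(data, data.mean()):
        raise ValueError("zero total variance: ICC undefined")
    msr, msc, mse = _two_way_mean_squares(data)
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    df_e = (n - 1) * (k - 1)
    if mse > 0:
        fj = msc / mse
        vn = df_e * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
        vd = (n - 1) * k ** 2 * icc ** 2 * fj ** 2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
        v = vn / vd
    else:
        # perfect additivity: the Satterthwaite df reach their limit
        v = float(k - 1) if msc > 0 else float(df_e)
    f_u = ss.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = ss.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    lo, hi = float(min(lo, icc)), float(max(hi, icc))
    return ICCResult(icc=float(icc), ci_lo=lo, ci_hi=hi, n=n, k=k)
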