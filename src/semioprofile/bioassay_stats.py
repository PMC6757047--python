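"""Exact paired test and inter-observer reliability for bioassay data.

The exact Wilcoxon signed-rank test enumerates the full sign-flip null of
paired investigation durations (feasible because bioassays involve few
males); zero differences are dropped and tied absolute differences receive
midranks.  Inter-observer reliability uses the two-way single-measure
intraclass correlation with an F-based 95% confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import rankdata

__all__ = ["WilcoxonResult", "IccResult", "exact_wilcoxon_signed_rank", "icc_two_way_single"]

MAX_ENUMERATION_N = 20


@dataclass
class WilcoxonResult:
    V: float  # sum of ranks of positive differences
    p: float
    alternative: str
    n_effective: int


def signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the positive-rank sum for given |d| ranks.

    Returns (support, counts) where counts[i] is the number of the 2^n sign
    assignments with rank sum support[i].  Midranks are handled by doubling
    to integers and convolving subset sums.
    """
    r2 = np.rint(2.0 * np.asarray(ranks, float)).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r].copy()
    support = np.arange(total + 1) / 2.0
    return support, counts


def exact_wilcoxon_signed_rank(
    a: Sequence[float],
    b: Sequence[float] | None = None,
    alternative: str = "two-sided",
) -> WilcoxonResult:
    """Exact Wilcoxon signed-rank test by full sign-flip enumeration.

    ``a`` and ``b`` are paired measurements (or ``a`` the differences when
    ``b`` is omitted).  V is the sum of the ranks of positive differences;
    the p-value sums the exact null over the requested tail (two-sided:
    2 * min(tails), capped at 1).  All-zero differences give V = 0, p = 1
    with a warning.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, float)
    d = a - np.asarray(b, float) if b is not None else a
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all differences are zero; test is degenerate", stacklevel=2)
        return WilcoxonResult(V=0.0, p=1.0, alternative=alternative, n_effective=0)
    if n > MAX_ENUMERATION_N:
        raise ValueError(f"exact enumeration limited to n <= {MAX_ENUMERATION_N}")
    ranks = rankdata(np.abs(d))  # midranks for ties
    V = float(ranks[d > 0].sum())
    support, counts = signed_rank_distribution(ranks)
    total = counts.sum()  # 2^n
    p_greater = counts[support >= V - 1e-9].sum() / total
    p_less = counts[support <= V + 1e-9].sum() / total
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return WilcoxonResult(V=V, p=float(p), alternative=alternative, n_effective=n)


@dataclass
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    variant: str
    n_subjects: int
    n_raters: int


def icc_two_way_single(
    ratings: np.ndarray | Sequence[Sequence[float]],
    variant: str = "agreement",
    alpha: float = 0.05,
) -> IccResult:
    """Two-way single-measure intraclass correlation (raters x subjects).

    ``agreement`` is ICC(A,1) (absolute agreement; rater effects count as
    disagreement), ``consistency`` is ICC(C,1) (invariant to additive rater
    shifts).  Confidence bounds follow the standard F-based constructions
    (Satterthwaite degrees of freedom for the agreement variant).  Zero
    between-subject variance yields an ICC <= 0, not an error.
    """
    if variant not in ("agreement", "consistency"):
        raise ValueError(f"unknown variant {variant!r}")
    R = np.asarray(ratings, float)
    if R.ndim != 2 or R.shape[0] < 2 or R.shape[1] < 2:
        raise ValueError("ratings must be a raters x subjects matrix, both >= 2")
    if not np.isfinite(R).all():
        raise ValueError("ratings must be complete (no missing values)")
    k, n = R.shape  # raters, subjects

    grand = R.mean()
    subj_means = R.mean(axis=0)
    rater_means = R.mean(axis=1)
    ss_subj = k * float(((subj_means - grand) ** 2).sum())
    ss_rater = n * float(((rater_means - grand) ** 2).sum())
    ss_total = float(((R - grand) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_rater
    msr = ss_subj / (n - 1)  # between subjects
    msc = ss_rater / (k - 1)  # between raters
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    if variant == "consistency":
        denom = msr + (k - 1) * mse
        icc = (msr - mse) / denom if denom > 0 else 0.0
        if mse == 0:
            lo, hi = (1.0, 1.0) if icc == 1.0 else (icc, icc)
        else:
            fobs = msr / mse
            df1, df2 = n - 1, (n - 1) * (k - 1)
            fl = fobs / f_dist.ppf(1 - alpha / 2, df1, df2)
            fu = fobs * f_dist.ppf(1 - alpha / 2, df2, df1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
    else:
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        icc = (msr - mse) / denom if denom > 0 else 0.0
        if mse == 0 and msc == mse:
            lo = hi = icc
        else:
            a_ = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
            b_ = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
            if np.isinf(a_) or np.isinf(b_):
                lo = hi = 1.0
            else:
                num = (a_ * msc + b_ * mse) ** 2
                den = (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1))
                v = num / den if den > 0 else 1.0
                f_l = f_dist.ppf(1 - alpha / 2, n - 1, v)
                f_u = f_dist.ppf(1 - alpha / 2, v, n - 1)
                lo = n * (msr - f_l * mse) / (
                    f_l * (k * msc + (k * n - k - n) * mse) + n * msr
                )
                hi = n * (f_u * msr - mse) / (
                    k * msc + (k * n - k - n) * mse + n * f_u * msr
                )
    lo, hi = float(min(lo, hi)), float(max(lo, hi))
    return IccResult(
        icc=float(icc), ci_low=lo, ci_high=hi, variant=variant, n_subjects=n, n_raters=k
    )
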