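"""Effect-size algebra shared by the behavioural and disconnection analyses.

The quantities here are the standard companions of F, t, Wilcoxon and
Spearman statistics:

* partial eta squared,  eta_p^2 = F*df1 / (F*df1 + df2)
* Cohen's d_z for paired designs,  d_z = t / sqrt(n)
* the t-reference statistic of a Spearman correlation,
  t = rho * sqrt((n-2) / (1-rho^2)),  df = n-2
* the matched-pairs rank-biserial correlation from signed-rank sums,
  r_rb = (W+ - W-) / (W+ + W-)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

__all__ = [
    "EffectSizeReport",
    "partial_eta_sq",
    "cohens_dz_from_t",
    "spearman_t",
    "spearman_p",
    "bonferroni",
    "signed_rank_sums",
    "eta_p_sq_ci",
]


@dataclass
class EffectSizeReport:
    """Container for test statistics and their effect sizes.

    Only the fields relevant to the producing analysis are populated; the
    rest stay ``None``. ``flags`` collects degeneracy notes (constant data,
    undefined statistics) instead of raising.
    """

    F: Optional[float] = None
    df1: Optional[float] = None
    df2: Optional[float] = None
    partial_eta_sq: Optional[float] = None
    t: Optional[float] = None
    p: Optional[float] = None
    cohens_dz: Optional[float] = None
    rho: Optional[float] = None
    W_pos: Optional[float] = None
    W_neg: Optional[float] = None
    r_rb: Optional[float] = None
    n: Optional[int] = None
    ci: Optional[tuple[float, float]] = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = self.partial_eta_sq
        if v is not None and not math.isnan(v) and not (-1e-12 <= v <= 1 + 1e-12):
            raise ValueError("partial_eta_sq outside [0, 1]")
        for name in ("r_rb", "rho"):
            v = getattr(self, name)
            if v is not None and not math.isnan(v) and not (-1 - 1e-12 <= v <= 1 + 1e-12):
                raise ValueError(f"{name} outside [-1, 1]")


def partial_eta_sq(F: float, df1: float, df2: float) -> float:
    """Partial eta squared recovered from an F ratio and its degrees of freedom."""
    if F < 0:
        raise ValueError("F must be non-negative")
    return F * df1 / (F * df1 + df2)


def cohens_dz_from_t(t: float, n: int) -> float:
    """Cohen's d_z for a paired t statistic with n pairs."""
    if n < 2:
        raise ValueError("need at least 2 pairs")
    return t / math.sqrt(n)


def spearman_t(rho: float, n: int) -> float:
    """t-reference companion of a Spearman rho; undefined at |rho| = 1."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(rho) >= 1.0:
        raise ZeroDivisionError("|rho| = 1: companion t undefined")
    return rho * math.sqrt((n - 2) / (1.0 - rho * rho))


def spearman_p(rho: float, n: int) -> float:
    """Two-sided p of a Spearman rho via the t approximation with df = n-2."""
    t = spearman_t(rho, n)
    return 2.0 * float(sps.t.sf(abs(t), n - 2))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment over m comparisons, clipped at 1."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def signed_rank_sums(pre: np.ndarray, post: np.ndarray) -> tuple[float, float, int]:
    """Wilcoxon rank sums (W+, W-, n_used): zero differences dropped, mid-ranks for ties.

    W+ sums the ranks of positive differences (post - pre).
    """
    d = np.asarray(post, dtype=float) - np.asarray(pre, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences zero: signed-rank sums undefined")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    w_neg = float(ranks[d < 0].sum())
    return w_pos, w_neg, int(d.size)


def eta_p_sq_ci(F: float, df1: float, df2: float, level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for partial eta squared via the noncentral-F pivot.

    Inverts the noncentral-F CDF in the noncentrality parameter by bisection;
    the lower bound is clamped at 0 when the observed F is already below the
    relevant central quantile.
    """
    alpha = 1.0 - level

    def _invert(target: float) -> float:
        # largest lambda with P(F' <= F | lambda) >= target (monotone decreasing)
        lo, hi = 0.0, 10.0 * max(1.0, F * df1) + 100.0
        if sps.ncf.cdf(F, df1, df2, lo) < target:
            return 0.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if sps.ncf.cdf(F, df1, df2, mid) >= target:
                lo = mid
            else:
                hi = mid
        return lo

    lam_lo = _invert(1.0 - alpha / 2.0)
    lam_hi = _invert(alpha / 2.0)
    to_eta = lambda lam: lam / (lam + df1 + df2 + 1.0)
    return to_eta(lam_lo), to_eta(lam_hi)
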