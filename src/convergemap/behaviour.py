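"""Scoring and group statistics for the Bells cancellation test.

The Bells test asks the patient to cancel 35 bell targets hidden among 280
distractors. Two scores summarise performance:

* **total score** — the number of omitted targets, a global measure of
  visuospatial exploratory/selective attention;
* **asymmetry score** — left-minus-right omissions, the operational index of
  visuospatial neglect (positive = left-sided omissions dominate).

Postoperative change is expressed as delta = post - pre, so positive deltas
mean worsening. Group-level change is analysed with a two-way mixed
(split-plot) ANOVA — lesioned hemisphere as the between factor, timepoint as
the within factor — plus paired t / Wilcoxon follow-ups and Spearman
correlations, each reported with its effect size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import (
    EffectSizeReport,
    cohens_dz_from_t,
    partial_eta_sq,
    signed_rank_sums,
    spearman_t,
)

__all__ = [
    "BellsRecord",
    "score_bells",
    "build_behaviour_table",
    "classify_pathological",
    "mixed_rm_anova",
    "paired_effects",
    "spearman_report",
]

#: Items per test sheet (the canonical paper-and-pencil layout).
N_TARGETS_TOTAL = 35
N_DISTRACTORS = 280


@dataclass(frozen=True)
class BellsRecord:
    """One administration of the Bells test, reduced to per-hemifield omissions."""

    subject_id: str
    timepoint: str  # "pre" | "post"
    omissions_left: int
    omissions_right: int
    n_targets_total: int = N_TARGETS_TOTAL
    n_distractors: int = N_DISTRACTORS

    def __post_init__(self) -> None:
        if self.timepoint not in ("pre", "post"):
            raise ValueError(f"timepoint must be 'pre' or 'post', got {self.timepoint!r}")
        if self.omissions_left < 0 or self.omissions_right < 0:
            raise ValueError("omission counts must be non-negative")
        if self.omissions_left + self.omissions_right > self.n_targets_total:
            raise ValueError(
                f"omissions ({self.omissions_left}+{self.omissions_right}) exceed "
                f"the {self.n_targets_total} targets on the sheet"
            )


def score_bells(record: BellsRecord) -> tuple[int, int]:
    """Return (total score, asymmetry score) for one Bells administration.

    total = left + right omissions; asymmetry = left - right omissions.
    Pure and deterministic; validation happens in :class:`BellsRecord`.
    """
    total = record.omissions_left + record.omissions_right
    asymmetry = record.omissions_left - record.omissions_right
    return total, asymmetry


def build_behaviour_table(records: Sequence[BellsRecord], hemisphere: Mapping[str, str],
                          covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble pre/post records into one row per subject with delta scores.

    Parameters
    ----------
    records : paired pre and post :class:`BellsRecord` per subject.
    hemisphere : subject_id -> {"left", "right"} (side of the lesion).
    covariates : optional frame indexed by subject_id (age, education, ...).
    """
    rows: dict[str, dict] = {}
    for rec in records:
        total, asym = score_bells(rec)
        row = rows.setdefault(rec.subject_id, {"subject_id": rec.subject_id})
        row[f"{rec.timepoint}_total"] = total
        row[f"{rec.timepoint}_asymmetry"] = asym
        row[f"{rec.timepoint}_left"] = rec.omissions_left
        row[f"{rec.timepoint}_right"] = rec.omissions_right
    table = pd.DataFrame(list(rows.values())).set_index("subject_id")
    missing = [c for c in ("pre_total", "post_total") if c not in table or table[c].isna().any()]
    if missing:
        raise ValueError("every subject needs both a pre and a post record")
    table["hemisphere"] = pd.Series(dict(hemisphere))
    if table["hemisphere"].isna().any():
        raise ValueError("hemisphere missing for some subjects")
    # worsening-positive convention: positive delta = more omissions after surgery
    table["delta_total"] = table["post_total"] - table["pre_total"]
    table["delta_asymmetry"] = table["post_asymmetry"] - table["pre_asymmetry"]
    if covariates is not None:
        table = table.join(covariates, how="left")
    return table


def classify_pathological(table: pd.DataFrame, cutoffs: Mapping[str, float]) -> pd.DataFrame:
    """Flag scores exceeding configured normative cutoffs (strictly greater-than).

    ``cutoffs`` maps score column names (e.g. ``"post_total"``) to the
    normative cutoff above which the score is pathological. Published
    normative tables are not bundled, so the cutoffs are a required input.
    """
    if not cutoffs:
        raise ValueError("no cutoffs supplied; normative cutoffs are a required configuration")
    flags = pd.DataFrame(index=table.index)
    for column, cutoff in cutoffs.items():
        if column not in table.columns:
            raise KeyError(f"cutoff refers to unknown score column {column!r}")
        flags[f"{column}_pathological"] = table[column] > cutoff
    return flags


def _split_plot_ss(wide: pd.DataFrame, group: pd.Series) -> dict[str, float]:
    """Sums of squares for a balanced-cells split-plot design (weighted means).

    ``wide``: one row per subject, one column per within level.
    """
    y = wide.to_numpy(dtype=float)
    n, T = y.shape
    groups = group.to_numpy()
    levels = np.unique(groups)
    grand = y.mean()
    subj_means = y.mean(axis=1)
    ss_total = ((y - grand) ** 2).sum()
    ss_time = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_group = 0.0
    ss_cells = 0.0
    ss_subj_within = 0.0
    for g in levels:
        sel = groups == g
        ng = sel.sum()
        gmean = y[sel].mean()
        ss_group += T * ng * (gmean - grand) ** 2
        ss_cells += ng * ((y[sel].mean(axis=0) - grand) ** 2).sum()
        ss_subj_within += T * ((subj_means[sel] - gmean) ** 2).sum()
    ss_inter = ss_cells - ss_time - ss_group
    ss_err_within = ss_total - ss_cells - ss_subj_within
    return {
        "ss_time": ss_time, "ss_group": ss_group, "ss_inter": max(ss_inter, 0.0),
        "ss_subj_within": ss_subj_within, "ss_err_within": max(ss_err_within, 0.0),
        "n": n, "T": T, "g": len(levels),
    }


def mixed_rm_anova(values: pd.DataFrame, group: pd.Series) -> dict[str, EffectSizeReport]:
    """Two-way mixed (split-plot) ANOVA: within = timepoint, between = group.

    Parameters
    ----------
    values : DataFrame, one row per subject, one column per timepoint
        (e.g. columns ``["pre", "post"]``).
    group : Series aligned with ``values`` giving the between-factor level.

    Returns
    -------
    dict with keys ``"time"``, ``"group"``, ``"interaction"``; each an
    :class:`EffectSizeReport` with F, dfs and partial eta squared
    (eta_p^2 = F*df1/(F*df1 + df2), identical to SS_effect/(SS_effect+SS_error)).
    """
    values = values.dropna()
    group = group.loc[values.index]
    counts = group.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    if values.shape[1] != 2:
        raise ValueError("exactly two timepoints expected")
    ss = _split_plot_ss(values, group)
    n, T, g = ss["n"], ss["T"], ss["g"]
    df_time, df_inter = T - 1, (g - 1) * (T - 1)
    df_err_w = (n - g) * (T - 1)
    df_group, df_err_b = g - 1, n - g

    def _report(ss_eff: float, df1: int, ss_err: float, df2: int) -> EffectSizeReport:
        flags: tuple[str, ...] = ()
        if ss_err <= 1e-300:
            return EffectSizeReport(F=math.nan, df1=df1, df2=df2, partial_eta_sq=None,
                                    n=n, flags=("constant_data_F_undefined",))
        F = (ss_eff / df1) / (ss_err / df2)
        p = float(sps.f.sf(F, df1, df2))
        return EffectSizeReport(F=F, df1=df1, df2=df2, p=p,
                                partial_eta_sq=partial_eta_sq(F, df1, df2), n=n, flags=flags)

    return {
        "time": _report(ss["ss_time"], df_time, ss["ss_err_within"], df_err_w),
        "interaction": _report(ss["ss_inter"], df_inter, ss["ss_err_within"], df_err_w),
        "group": _report(ss["ss_group"], df_group, ss["ss_subj_within"], df_err_b),
    }


def paired_effects(pre: np.ndarray, post: np.ndarray, n_boot: int = 0,
                   seed: int | None = None) -> EffectSizeReport:
    """Paired t with Cohen's d_z, plus the Wilcoxon signed-rank companion.

    d_z = t / sqrt(n). Wilcoxon drops zero differences, uses mid-ranks for
    ties, the normal approximation with continuity correction for n > 25,
    and reports r_rb = (W+ - W-)/(W+ + W-). When every difference is zero
    the rank statistics are flagged undefined rather than raised.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or pre.size < 2:
        raise ValueError("pre and post must be matching 1-D vectors with n >= 2")
    n = pre.size
    d = post - pre
    flags: list[str] = []
    if np.std(d, ddof=1) == 0:
        t = math.nan
        dz = math.nan
        p = math.nan
        flags.append("constant_differences_t_undefined")
    else:
        t, p = sps.ttest_rel(post, pre)
        t, p = float(t), float(p)
        dz = cohens_dz_from_t(t, n)
    if np.all(d == 0):
        w_pos = w_neg = math.nan
        r_rb = math.nan
        flags.append("all_zero_differences_wilcoxon_undefined")
    else:
        w_pos, w_neg, n_used = signed_rank_sums(pre, post)
        r_rb = (w_pos - w_neg) / (w_pos + w_neg)
    ci = None
    if n_boot > 0 and not np.all(d == 0):
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            db = d[idx]
            if np.all(db == 0):
                continue
            wp, wn, _ = signed_rank_sums(np.zeros_like(db), db)
            reps.append((wp - wn) / (wp + wn))
        if reps:
            ci = tuple(np.percentile(reps, [2.5, 97.5]))
    return EffectSizeReport(t=t, p=p, cohens_dz=dz, W_pos=w_pos, W_neg=w_neg,
                            r_rb=r_rb, n=n, ci=ci, flags=tuple(flags))


def spearman_report(x: np.ndarray, y: np.ndarray, n_boot: int = 0,
                    seed: int | None = None) -> EffectSizeReport:
    """Spearman rho on mid-ranks with its t-reference companion statistic.

    t = rho*sqrt((n-2)/(1-rho^2)) with df = n-2; two-sided p from the t
    distribution. |rho| = 1 leaves t undefined (flagged), matching the
    degenerate monotone limit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be matching 1-D vectors with n >= 3")
    n = x.size
    if np.std(x) == 0 or np.std(y) == 0:
        return EffectSizeReport(rho=math.nan, n=n, flags=("zero_variance_rho_undefined",))
    rho = float(sps.spearmanr(x, y).statistic)
    if abs(rho) > 1.0 - 1e-12:
        rho = math.copysign(1.0, rho)  # collapse numerical fuzz at the monotone limit
    flags: list[str] = []
    if abs(rho) >= 1.0:
        t = math.nan
        p = math.nan
        flags.append("perfect_monotone_t_undefined")
    else:
        t = spearman_t(rho, n)
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            if np.std(x[idx]) == 0 or np.std(y[idx]) == 0:
                continue
            reps.append(float(sps.spearmanr(x[idx], y[idx]).statistic))
        if reps:
            ci = tuple(np.percentile(reps, [2.5, 97.5]))
    return EffectSizeReport(rho=rho, t=t, p=p, n=n, ci=ci, flags=tuple(flags))
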