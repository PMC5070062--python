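"""Statistical layer: normality gating, (rank) ANCOVA, FDR, correlations.

The group comparison follows the two-arm design of the study: a one-way ANCOVA
``dv ~ group + covariate`` (the covariate is the nonverbal developmental
score), Type III F test for the group term.  With a single two-level factor and
one covariate the Type III group sum of squares equals the extra sum of squares
of the group term given the covariate, which is what is computed here with
plain least squares; the implementation is cross-checked against
``pingouin.ancova`` in the test suite.

Variables failing a Shapiro–Wilk normality gate (p < 0.05) are analysed on
midranks: both the dependent variable and the covariate are rank-transformed
(pooled across groups, Conover–Iman style) and the same linear model is fitted.

Multiple comparisons are handled with the Benjamini–Hochberg step-up procedure
at q = 0.05, applied within a family of tests (per task by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError

ALPHA_NORMALITY = 0.05


@dataclass
class GroupComparison:
    variable: str
    group_stats: Mapping[str, tuple[float, float, int]]  # group -> (mean, sd, n)
    F: float
    p: float
    eta2_partial: float
    ranked: bool
    levene_p: float
    fdr_significant: bool | None = None

    def __post_init__(self) -> None:
        if self.F < 0 or not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise AnalysisError(f"invalid F/p for {self.variable}")


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    method: str  # "pearson" | "spearman"
    r: float
    p: float
    n: int


def shapiro_gate(values: Sequence[float], alpha: float = ALPHA_NORMALITY) -> bool:
    """True when a Shapiro–Wilk test does not reject normality (p >= alpha)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 finite values")
    if np.ptp(arr) == 0:
        return False  # degenerate: all identical, treat as non-normal
    return bool(sps.shapiro(arr).pvalue >= alpha)


def _clean(dv, group, covariate):
    dv = np.asarray(dv, dtype=float)
    group = np.asarray(group)
    cov = np.asarray(covariate, dtype=float)
    if not (len(dv) == len(group) == len(cov)):
        raise AnalysisError("dv, group and covariate must have equal length")
    keep = np.isfinite(dv) & np.isfinite(cov)
    return dv[keep], group[keep], cov[keep]


def ancova(dv, group, covariate, variable: str = "dv",
           ranked: bool = False) -> GroupComparison:
    """One-way ANCOVA ``dv ~ group + covariate`` with a Type III group F test.

    ``group`` must contain exactly two levels with at least two observations
    each after missing-value removal; otherwise an :class:`AnalysisError` names
    the variable.  Partial eta squared is ``SS_group / (SS_group + SS_resid)``.
    """
    dv, group, cov = _clean(dv, group, covariate)
    levels = sorted(set(group.tolist()))
    if len(levels) != 2:
        raise AnalysisError(f"{variable}: need exactly 2 groups, got {levels}")
    g = (group == levels[1]).astype(float)
    counts = [int(np.sum(group == lv)) for lv in levels]
    if min(counts) < 2:
        raise AnalysisError(
            f"{variable}: a group has <2 observations after missing-value removal"
        )
    n = len(dv)
    if n < 4:
        raise AnalysisError(f"{variable}: too few observations (n={n})")

    X_full = np.column_stack([np.ones(n), g, cov])
    X_red = np.column_stack([np.ones(n), cov])
    ss_full = _rss(X_full, dv)
    ss_red = _rss(X_red, dv)
    ss_group = max(ss_red - ss_full, 0.0)
    df_resid = n - 3
    eps = 1e-12 * max(1.0, float(np.sum(dv**2)))
    if ss_full <= eps:
        if ss_group <= eps:
            F, p, eta2 = 0.0, 1.0, 0.0
        else:
            F, p, eta2 = float("inf"), 0.0, 1.0
    else:
        F = ss_group / (ss_full / df_resid)
        p = float(sps.f.sf(F, 1, df_resid))
        eta2 = ss_group / (ss_group + ss_full)

    samples = [dv[group == lv] for lv in levels]
    if all(len(s) >= 2 for s in samples) and any(np.ptp(s) > 0 for s in samples):
        with np.errstate(divide="ignore", invalid="ignore"):
            levene_p = float(sps.levene(*samples, center="mean").pvalue)
    else:
        levene_p = float("nan")
    gstats = {
        lv: (float(np.mean(s)), float(np.std(s, ddof=1)) if len(s) > 1 else 0.0,
             len(s))
        for lv, s in zip(levels, samples)
    }
    return GroupComparison(
        variable=variable, group_stats=gstats, F=float(F), p=float(p),
        eta2_partial=float(eta2), ranked=ranked, levene_p=levene_p,
    )


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def rank_ancova(dv, group, covariate, variable: str = "dv") -> GroupComparison:
    """ANCOVA on midranks of both the dependent variable and the covariate
    (ranks pooled across groups).  Reported group means/SDs stay on the raw
    scale.  A dv with zero rank variance yields F = 0 by convention."""
    dv_c, group_c, cov_c = _clean(dv, group, covariate)
    r_dv = sps.rankdata(dv_c)
    r_cov = sps.rankdata(cov_c)
    res = ancova(r_dv, group_c, r_cov, variable=variable, ranked=True)
    levels = sorted(set(group_c.tolist()))
    raw_stats = {
        lv: (
            float(np.mean(dv_c[group_c == lv])),
            float(np.std(dv_c[group_c == lv], ddof=1))
            if np.sum(group_c == lv) > 1 else 0.0,
            int(np.sum(group_c == lv)),
        )
        for lv in levels
    }
    return replace(res, group_stats=raw_stats)


def bh_fdr(pvalues: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejections at FDR level ``q``.

    Sort p-values ascending, find the largest k with ``p_(k) <= k*q/m`` and
    reject hypotheses 1..k (boundary inclusive).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if passed.any():
        k = int(np.max(np.nonzero(passed)[0]))
        reject[order[: k + 1]] = True
    return reject


def auto_correlation(x, y, names: tuple[str, str] = ("x", "y")) -> CorrelationResult:
    """Pearson correlation when both variables pass the normality gate,
    Spearman otherwise; pairs with missing values are dropped first."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(names, "pearson", float("nan"), float("nan"),
                                 len(x))
    use_pearson = shapiro_gate(x) and shapiro_gate(y)
    if use_pearson:
        r, p = sps.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = sps.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(names, method, float(r), float(p), len(x))


def usable_trials_anova(counts: pd.DataFrame) -> dict[str, float]:
    """Mixed repeated-measures ANOVA on usable-trial counts.

    ``counts`` needs columns ``participant_id``, ``group``, ``task``, ``count``
    with all three tasks present for every participant (balanced within
    factor).  Returns F and p for the task main effect and the group × task
    interaction.  If every count is identical both F values are 0 by
    convention.
    """
    required = {"participant_id", "group", "task", "count"}
    if not required.issubset(counts.columns):
        raise AnalysisError(f"counts frame needs columns {sorted(required)}")
    per_subject = counts.groupby("participant_id")["task"].nunique()
    if (per_subject != 3).any():
        raise AnalysisError("every participant needs counts for all 3 tasks")
    if counts["participant_id"].nunique() < 2:
        raise AnalysisError("need at least 2 participants")
    vals = counts["count"].to_numpy(float)
    if np.ptp(vals) == 0:
        return {"F_task": 0.0, "p_task": 1.0,
                "F_interaction": 0.0, "p_interaction": 1.0}
    import pingouin as pg

    aov = pg.mixed_anova(
        data=counts, dv="count", within="task", between="group",
        subject="participant_id",
    )
    task_row = aov[aov["Source"] == "task"].iloc[0]
    inter_row = aov[aov["Source"] == "Interaction"].iloc[0]
    return {
        "F_task": float(task_row["F"]),
        "p_task": float(task_row["p_unc"]),
        "F_interaction": float(inter_row["F"]),
        "p_interaction": float(inter_row["p_unc"]),
    }


def compare_groups(
    values_by_participant: pd.DataFrame,
    variable: str,
    alpha: float = ALPHA_NORMALITY,
) -> GroupComparison:
    """Gate on normality (Shapiro–Wilk within each group) and run the
    parametric or rank ANCOVA accordingly.

    ``values_by_participant`` needs columns ``group``, ``covariate`` and the
    variable.
    """
    df = values_by_participant
    dv = df[variable].to_numpy(float)
    group = df["group"].to_numpy()
    cov = df["covariate"].to_numpy(float)
    keep = np.isfinite(dv) & np.isfinite(cov)
    normal = True
    for lv in sorted(set(group[keep].tolist())):
        vals = dv[keep][group[keep] == lv]
        if len(vals) < 3:
            normal = False
            break
        try:
            normal = normal and shapiro_gate(vals, alpha)
        except ValueError:
            normal = False
        if not normal:
            break
    fn = ancova if normal else rank_ancova
    return fn(dv, group, cov, variable=variable)
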