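"""Cohort statistics: normality gating, Wilcoxon signed-rank with effect
size, median split, repeated-measures mixed ANOVA with Bonferroni
post-hocs, and Friedman with Dunn-Bonferroni post-hocs.

Conventions follow the SPSS-style reporting common in applied EEG work:
the Wilcoxon statistic T is the smaller signed-rank sum, its z comes from
the tie-corrected normal approximation, and the effect size is
r = |z| / sqrt(N) with N counting observations (twice the pair count).
The mixed ANOVA reports uncorrected degrees of freedom — for N subjects,
g groups and k within levels the within/interaction error has
(N − g)(k − 1) df — and partial eta squared SS_effect/(SS_effect + SS_error).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestReport",
    "shapiro_gate",
    "log_transform",
    "signed_rank_z",
    "wilcoxon_signed_rank",
    "median_split",
    "mixed_anova",
    "bonferroni_posthoc",
    "friedman_test",
    "dunn_bonferroni",
]

ALPHA = 0.05  # fixed 5% significance threshold throughout


@dataclass
class TestReport:
    """A named test statistic with df, p, effect size and optional post-hocs."""

    name: str
    statistic: float
    df: tuple | None = None
    p: float | None = None
    effect_size: float | None = None
    effect_size_name: str | None = None
    extras: dict = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "statistic": self.statistic,
            "df": list(self.df) if self.df is not None else None,
            "p": self.p,
            "effect_size": self.effect_size,
            "effect_size_name": self.effect_size_name,
            "extras": self.extras,
        }
        if self.posthoc is not None:
            d["posthoc"] = self.posthoc.to_dict(orient="records")
        return d


# ---------------------------------------------------------------------------
# gating and transforms
# ---------------------------------------------------------------------------

def shapiro_gate(values, alpha: float = ALPHA) -> tuple[str, TestReport]:
    """Shapiro-Wilk normality decision used to select the downstream test.

    Returns ``("normal" | "non-normal", report)``; the decision is never
    taken silently — callers log the report.
    """
    x = np.asarray(list(values), dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) sample")
    w, p = sps.shapiro(x)
    decision = "normal" if p > alpha else "non-normal"
    return decision, TestReport(name="shapiro-wilk", statistic=float(w), p=float(p))


def log_transform(values) -> np.ndarray:
    """Natural log, elementwise; used to normalize planning times."""
    x = np.asarray(list(values), dtype=float)
    if np.any(x <= 0):
        raise ValueError("log transform requires strictly positive values")
    return np.log(x)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def signed_rank_z(T: float, n: int, tie_term: float = 0.0) -> float:
    """Normal-approximation z for a signed-rank sum T over n non-zero pairs.

    z = (T − n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 − tie_term), where tie_term is
    Σ(t³ − t)/48 over tied groups of absolute differences.
    """
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        raise ValueError("zero variance in signed-rank approximation")
    return (T - mu) / np.sqrt(var)


def wilcoxon_signed_rank(a, b) -> TestReport:
    """Paired two-sided Wilcoxon signed-rank test with effect size r.

    Zero differences are dropped before ranking; ties are mid-ranked with
    the variance correction. T is the smaller of the positive/negative rank
    sums, p comes from the normal approximation, and r = |z|/sqrt(N) where
    N = 2 × (number of pairs supplied, including zero differences).
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n_pairs = a.size
    d = b - a
    d = d[d != 0]
    n = d.size
    if n < 5:
        raise ValueError("need >= 5 non-zero differences")
    ranks = sps.rankdata(np.abs(d))
    r_plus = float(ranks[d > 0].sum())
    r_minus = float(ranks[d < 0].sum())
    T = min(r_plus, r_minus)
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts) / 48.0).sum())
    z = signed_rank_z(T, n, tie_term)
    p = 2.0 * sps.norm.sf(abs(z))
    r = abs(z) / np.sqrt(2 * n_pairs)
    return TestReport(
        name="wilcoxon-signed-rank",
        statistic=T,
        p=float(p),
        effect_size=float(r),
        effect_size_name="r",
        extras={"z": float(z), "n_pairs": n_pairs, "n_nonzero": n,
                "r_plus": r_plus, "r_minus": r_minus},
    )


# ---------------------------------------------------------------------------
# median split
# ---------------------------------------------------------------------------

def median_split(scores) -> tuple[np.ndarray, float]:
    """Dichotomize at the sample median: strictly below → ``"lower"``,
    at-or-above (ties included) → ``"higher"``. Returns (labels, median)."""
    x = np.asarray(list(scores), dtype=float)
    if x.size < 2:
        raise ValueError("median split needs at least 2 scores")
    med = float(np.median(x))
    labels = np.where(x < med, "lower", "higher")
    if not (labels == "lower").any():
        warnings.warn("median split produced an empty lower group", stacklevel=2)
    return labels, med


# ---------------------------------------------------------------------------
# repeated-measures mixed ANOVA
# ---------------------------------------------------------------------------

def mixed_anova(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "condition",
    between: str = "group",
    subject: str = "subject",
) -> TestReport:
    """Two-way mixed ANOVA (one within-subject, one between-subject factor).

    Requires a complete crossing (every subject measured at every within
    level). Sums of squares follow the classical decomposition
    SS_total = [SS_group + SS_subj(group)] + [SS_within + SS_interaction +
    SS_error_within]; no sphericity correction is applied, so the error df
    are (N − g) between and (N − g)(k − 1) within/interaction. The headline
    ``statistic``/``p``/``df`` of the report is the interaction effect;
    all three effects are in ``extras["effects"]``.
    """
    df = table[[subject, between, within, dv]].dropna()
    subjects = df[subject].unique()
    levels = sorted(df[within].unique())
    groups = sorted(df[between].unique())
    k, g, N = len(levels), len(groups), len(subjects)
    if g < 2 or k < 2:
        raise ValueError("need >= 2 groups and >= 2 within levels")
    pivot = df.pivot_table(index=[subject, between], columns=within, values=dv,
                           aggfunc="mean")
    if pivot.isna().any().any() or len(pivot) != N:
        raise ValueError("incomplete design: every subject needs every within level")
    for grp, cnt in pivot.index.get_level_values(1).value_counts().items():
        if cnt < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 subjects")

    y = pivot.to_numpy()  # subjects × levels
    grp_of = pivot.index.get_level_values(1).to_numpy()
    grand = y.mean()
    subj_means = y.mean(axis=1)
    lvl_means = y.mean(axis=0)

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(k * ((subj_means - grand) ** 2).sum())
    grp_sizes = {gr: int((grp_of == gr).sum()) for gr in groups}
    grp_means = {gr: y[grp_of == gr].mean() for gr in groups}
    ss_group = float(k * sum(grp_sizes[gr] * (grp_means[gr] - grand) ** 2 for gr in groups))
    ss_err_between = ss_between_subj - ss_group

    ss_within_total = ss_total - ss_between_subj
    ss_cond = float(N * ((lvl_means - grand) ** 2).sum())
    ss_inter = 0.0
    for gi, gr in enumerate(groups):
        cell = y[grp_of == gr].mean(axis=0)  # per-level means in group
        ss_inter += grp_sizes[gr] * float(
            ((cell - grp_means[gr] - lvl_means + grand) ** 2).sum()
        )
    ss_err_within = ss_within_total - ss_cond - ss_inter

    df_group, df_eb = g - 1, N - g
    df_cond = k - 1
    df_inter = (g - 1) * (k - 1)
    df_ew = (N - g) * (k - 1)

    def effect(name, ss, df1, ss_err, df2):
        ms, ms_e = ss / df1, ss_err / df2
        F = ms / ms_e
        p = float(sps.f.sf(F, df1, df2))
        eta = ss / (ss + ss_err)
        return {"effect": name, "SS": ss, "df": (df1, df2), "F": float(F),
                "p": p, "partial_eta_sq": float(eta), "SS_error": ss_err}

    effects = {
        "between": effect(between, ss_group, df_group, ss_err_between, df_eb),
        "within": effect(within, ss_cond, df_cond, ss_err_within, df_ew),
        "interaction": effect(f"{within}*{between}", ss_inter, df_inter, ss_err_within, df_ew),
    }
    inter = effects["interaction"]
    return TestReport(
        name="mixed-anova",
        statistic=inter["F"],
        df=inter["df"],
        p=inter["p"],
        effect_size=inter["partial_eta_sq"],
        effect_size_name="partial_eta_sq",
        extras={
            "effects": effects,
            "ss": {
                "total": ss_total,
                "between_subjects": ss_between_subj,
                "group": ss_group,
                "error_between": ss_err_between,
                "within_total": ss_within_total,
                "condition": ss_cond,
                "interaction": ss_inter,
                "error_within": ss_err_within,
            },
            "n_subjects": N, "n_groups": g, "n_levels": k,
            "group_sizes": grp_sizes,
        },
    )


def bonferroni_posthoc(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "condition",
    subject: str = "subject",
    between: str | None = None,
) -> pd.DataFrame:
    """Bonferroni-corrected pairwise paired t-tests between within levels.

    With ``between`` given, the comparisons are simple effects run separately
    inside each group. Adjusted p = min(1, raw p × m) with m the number of
    comparisons in the family. Reported regardless of the omnibus outcome.
    """
    def _pairs(sub: pd.DataFrame, label) -> list[dict]:
        pivot = sub.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
        levels = sorted(pivot.columns)
        if len(levels) < 2:
            raise ValueError("need at least 2 within levels")
        comps = list(combinations(levels, 2))
        rows = []
        for a, b in comps:
            t, p = sps.ttest_rel(pivot[a], pivot[b])
            rows.append({"group": label, "level_a": a, "level_b": b,
                         "t": float(t), "df": len(pivot) - 1, "p_raw": float(p),
                         "p_adj": float(min(1.0, p * len(comps)))})
        return rows

    if between is None:
        rows = _pairs(table, "all")
    else:
        rows = []
        for grp, sub in table.groupby(between):
            rows.extend(_pairs(sub, grp))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Friedman and Dunn-Bonferroni
# ---------------------------------------------------------------------------

def friedman_test(matrix) -> TestReport:
    """Friedman χ² over a subjects × levels matrix (tie-corrected), df = k − 1.

    χ² = [12/(nk(k+1)) Σ R_j² − 3n(k+1)] / C with the tie correction
    C = 1 − Σ(t³ − t)/(nk(k² − 1)); completely tied rows everywhere give
    χ² = 0 (no evidence of level differences), not a division by zero.
    """
    y = np.asarray(matrix, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 subjects and >= 2 levels")
    if np.isnan(y).any():
        raise ValueError("missing entries in Friedman matrix")
    n, k = y.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, y)
    col_sums = ranks.sum(axis=0)
    raw = 12.0 / (n * k * (k + 1)) * (col_sums**2).sum() - 3.0 * n * (k + 1)
    tie_sum = 0.0
    for row in y:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts**3 - counts).sum())
    C = 1.0 - tie_sum / (n * k * (k**2 - 1))
    chi2 = raw / C if C > 0 else 0.0
    p = float(sps.chi2.sf(chi2, k - 1)) if C > 0 else 1.0
    # Kendall's W as the companion effect size
    w = chi2 / (n * (k - 1))
    return TestReport(
        name="friedman",
        statistic=float(chi2),
        df=(k - 1,),
        p=p,
        effect_size=float(w),
        effect_size_name="kendall_w",
        extras={"n": n, "k": k},
    )


def dunn_bonferroni(matrix) -> pd.DataFrame:
    """Dunn's pairwise rank-mean z tests after Friedman, Bonferroni-adjusted.

    z_ij = (R̄_i − R̄_j) / sqrt(k(k+1)/(6n)); adjusted p = min(1, raw p × m)
    with m = k(k−1)/2 (so a 2-level design has adjustment factor 1).
    """
    y = np.asarray(matrix, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 subjects and >= 2 levels")
    if np.isnan(y).any():
        raise ValueError("missing entries")
    n, k = y.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, y)
    rbar = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    comps = list(combinations(range(k), 2))
    m = len(comps)
    rows = []
    for i, j in comps:
        z = (rbar[i] - rbar[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"level_a": i, "level_b": j, "mean_rank_a": float(rbar[i]),
                     "mean_rank_b": float(rbar[j]), "z": float(z),
                     "p_raw": float(p), "p_adj": float(min(1.0, p * m))})
    return pd.DataFrame(rows)
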