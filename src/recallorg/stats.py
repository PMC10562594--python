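"""Condition-contrast statistics for per-subject recall measures.

Provides the parametric tests the aggregation stage relies on — a
one-tailed one-sample t test against chance, a mixed-design ANOVA
(one within-subject factor crossed with a between-subject grouping,
with optional Greenhouse-Geisser correction for factors with more than
two levels), Welch's unequal-variance t test with Satterthwaite degrees
of freedom and Bonferroni adjustment, and a Pearson correlation with a
Fisher-z confidence interval — plus a sign-flipping paired permutation
test as an assumption-light companion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import ValidationError

__all__ = [
    "ContrastResult",
    "one_sample_vs_chance",
    "mixed_anova",
    "mixed_anova_2x2",
    "gg_epsilon",
    "paired_permutation",
    "welch_t",
    "recall_organization_correlation",
    "analyze_measures",
]


@dataclass(frozen=True)
class ContrastResult:
    """One statistical contrast (t, F, r or permutation)."""

    measure: str
    statistic: float
    df: tuple[float, ...]
    p: float
    effect_size: float
    effect_kind: str  # "cohen_d" | "partial_eta_sq" | "pearson_r"
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    ci: Optional[tuple[float, float]] = None
    adjustment: str = "none"
    n_perm: Optional[int] = None

    def __post_init__(self) -> None:
        if not (math.isnan(self.p) or 0 <= self.p <= 1):
            raise ValidationError(f"p-value {self.p} outside [0, 1]")


def _clean(x: Sequence[float]) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    return arr[~np.isnan(arr)]


def one_sample_vs_chance(
    scores: Sequence[float],
    mu0: float = 0.5,
    tail: str = "greater",
    measure: str = "score",
) -> ContrastResult:
    """One-sample t test of a factor score against chance.

    One-tailed by default; reports Cohen's d = (mean - mu0) / sd and the
    one-sided 95% confidence bound.
    """
    x = _clean(scores)
    n = x.size
    if n < 2:
        raise ValidationError(f"{measure}: fewer than 2 defined scores")
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValidationError(f"{measure}: zero variance")
    mean = float(x.mean())
    se = sd / math.sqrt(n)
    t = (mean - mu0) / se
    df = n - 1
    if tail == "greater":
        p = float(sps.t.sf(t, df))
        ci = (mean - sps.t.ppf(0.95, df) * se, math.inf)
    elif tail == "less":
        p = float(sps.t.cdf(t, df))
        ci = (-math.inf, mean + sps.t.ppf(0.95, df) * se)
    elif tail == "two-sided":
        p = float(2 * sps.t.sf(abs(t), df))
        h = sps.t.ppf(0.975, df) * se
        ci = (mean - h, mean + h)
    else:
        raise ValidationError(f"unknown tail {tail!r}")
    return ContrastResult(
        measure=measure,
        statistic=t,
        df=(float(df),),
        p=p,
        effect_size=(mean - mu0) / sd,
        effect_kind="cohen_d",
        means={"sample": mean},
        sds={"sample": sd},
        ci=ci,
    )


def gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon for an n x k measure matrix."""
    data = np.asarray(data, dtype=float)
    k = data.shape[1]
    if k < 3:
        return 1.0
    S = np.cov(data, rowvar=False)
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (
        (S**2).sum() - 2 * k * (row_means**2).sum() + k**2 * mean_all**2
    )
    if den == 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))


def _pivot(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: str,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Listwise-complete subject x within-level matrix plus group labels."""
    wide = data.pivot_table(
        index=subject, columns=within, values=dv, aggfunc="mean"
    )
    groups = data.groupby(subject)[between].agg(
        lambda s: s.iloc[0] if s.nunique() == 1 else np.nan
    )
    wide = wide.dropna()
    levels = list(wide.columns)
    g = groups.reindex(wide.index)
    keep = g.notna()
    wide, g = wide[keep.to_numpy()], g[keep]
    return wide.to_numpy(dtype=float), g.to_numpy(), levels


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: str,
    correction: bool = False,
) -> pd.DataFrame:
    """Mixed-design ANOVA: one within factor x one between-subject factor.

    Classical univariate sums-of-squares decomposition on the
    listwise-complete subject-by-level matrix (subjects missing any
    level, or with an ambiguous group label, are dropped). Returns one
    row per effect (between, within, interaction) with F, dfs, p and
    partial eta squared. ``correction=True`` applies the
    Greenhouse-Geisser epsilon to the within and interaction degrees of
    freedom (inert for two-level factors).
    """
    y, g, levels = _pivot(data, dv, within, subject, between)
    n, k = y.shape
    group_labels = sorted(pd.unique(g))
    if len(group_labels) < 2:
        raise ValidationError("between factor needs at least 2 groups")
    counts = {lab: int((g == lab).sum()) for lab in group_labels}
    if min(counts.values()) < 2:
        raise ValidationError(
            f"fewer than 2 subjects in a group: {counts}"
        )
    G = len(group_labels)
    grand = y.mean()
    subj_means = y.mean(axis=1)
    col_means = y.mean(axis=0)

    ss_total = float(((y - grand) ** 2).sum())
    ss_subjects = float(k * ((subj_means - grand) ** 2).sum())
    ss_between = float(
        sum(
            k * counts[lab] * (subj_means[g == lab].mean() - grand) ** 2
            for lab in group_labels
        )
    )
    ss_error_b = ss_subjects - ss_between
    ss_within_factor = float(n * ((col_means - grand) ** 2).sum())
    ss_inter = 0.0
    for lab in group_labels:
        rows = y[g == lab]
        cell = rows.mean(axis=0)
        gm = rows.mean()
        ss_inter += counts[lab] * float(
            ((cell - col_means - gm + grand) ** 2).sum()
        )
    ss_error_w = ss_total - ss_subjects - ss_within_factor - ss_inter

    df_b, df_err_b = G - 1, n - G
    df_w, df_i = k - 1, (k - 1) * (G - 1)
    df_err_w = (n - G) * (k - 1)
    eps = gg_epsilon(y) if correction else 1.0

    def row(name, ss, df1, ss_err, df2, scale=1.0):
        ms, ms_err = ss / df1, ss_err / df2
        f = ms / ms_err if ms_err > 0 else math.nan
        d1, d2 = df1 * scale, df2 * scale
        p = float(sps.f.sf(f, d1, d2)) if not math.isnan(f) else math.nan
        return {
            "effect": name,
            "SS": ss,
            "df1": d1,
            "df2": d2,
            "F": f,
            "p": p,
            "np2": ss / (ss + ss_err) if ss + ss_err > 0 else math.nan,
            "eps": scale,
        }

    out = pd.DataFrame(
        [
            row("between", ss_between, df_b, ss_error_b, df_err_b),
            row("within", ss_within_factor, df_w, ss_error_w, df_err_w, eps),
            row("interaction", ss_inter, df_i, ss_error_w, df_err_w, eps),
        ]
    )
    out.attrs["n"] = n
    out.attrs["levels"] = levels
    out.attrs["groups"] = counts
    return out


def mixed_anova_2x2(
    data: pd.DataFrame,
    dv: str,
    within: str = "condition",
    subject: str = "subject_id",
    between: str = "condition_order",
) -> dict[str, ContrastResult]:
    """2(within) x 2(between) mixed ANOVA returning one contrast per effect."""
    table = mixed_anova(data, dv, within, subject, between)
    y, g, levels = _pivot(data, dv, within, subject, between)
    means = {str(lev): float(y[:, i].mean()) for i, lev in enumerate(levels)}
    sds = {str(lev): float(y[:, i].std(ddof=1)) for i, lev in enumerate(levels)}
    results = {}
    for label, key in (
        ("condition", "within"),
        ("order", "between"),
        ("interaction", "interaction"),
    ):
        r = table.loc[table["effect"] == key].iloc[0]
        results[label] = ContrastResult(
            measure=f"{dv}:{label}",
            statistic=float(r["F"]),
            df=(float(r["df1"]), float(r["df2"])),
            p=float(r["p"]),
            effect_size=float(r["np2"]),
            effect_kind="partial_eta_sq",
            means=means,
            sds=sds,
        )
    return results


def paired_permutation(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    measure: str = "paired",
) -> ContrastResult:
    """Sign-flipping permutation test on within-subject differences.

    Two-sided p = (1 + #{|permuted mean| >= |observed mean|}) / (n_perm + 1).
    Pairs with a missing value are dropped listwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired samples differ in length")
    keep = ~(np.isnan(a) | np.isnan(b))
    d = (a - b)[keep]
    n = d.size
    if n < 6:
        raise ValidationError(f"{measure}: fewer than 6 complete pairs")
    obs = float(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    perm_means = (signs * d).mean(axis=1)
    p = float((1 + np.sum(np.abs(perm_means) >= abs(obs))) / (n_perm + 1))
    sd = float(d.std(ddof=1))
    return ContrastResult(
        measure=measure,
        statistic=obs,
        df=(float(n - 1),),
        p=p,
        effect_size=obs / sd if sd > 0 else math.nan,
        effect_kind="cohen_d",
        means={"A": float(a[keep].mean()), "B": float(b[keep].mean())},
        sds={"A": float(a[keep].std(ddof=1)), "B": float(b[keep].std(ddof=1))},
        n_perm=n_perm,
    )


def welch_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    bonferroni_m: int = 1,
    measure: str = "welch",
) -> ContrastResult:
    """Welch's t test with Satterthwaite degrees of freedom.

    The two-sided p is multiplied by ``bonferroni_m`` and capped at 1.
    Cohen's d uses the pooled standard deviation.
    """
    a, b = _clean(group_a), _clean(group_b)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValidationError("zero variance in both groups")
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    t = float((a.mean() - b.mean()) / math.sqrt(se2))
    df = se2**2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    p_raw = float(2 * sps.t.sf(abs(t), df))
    p = min(1.0, p_raw * bonferroni_m)
    sp = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    d = (a.mean() - b.mean()) / sp if sp > 0 else math.nan
    h = sps.t.ppf(0.975, df) * math.sqrt(se2)
    diff = a.mean() - b.mean()
    return ContrastResult(
        measure=measure,
        statistic=t,
        df=(float(df),),
        p=p,
        effect_size=float(d),
        effect_kind="cohen_d",
        means={"A": float(a.mean()), "B": float(b.mean())},
        sds={"A": float(a.std(ddof=1)), "B": float(b.std(ddof=1))},
        ci=(float(diff - h), float(diff + h)),
        adjustment="bonferroni" if bonferroni_m > 1 else "none",
    )


def recall_organization_correlation(
    n_correct: Sequence[float],
    factor: Sequence[float],
    measure: str = "recall_x_organization",
) -> ContrastResult:
    """Pearson correlation with two-sided p and Fisher-z 95% CI."""
    x = np.asarray(n_correct, dtype=float)
    y = np.asarray(factor, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValidationError("fewer than 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero variance in a correlated variable")
    r, p = sps.pearsonr(x, y)
    z = math.atanh(r)
    h = sps.norm.ppf(0.975) / math.sqrt(n - 3)
    ci = (math.tanh(z - h), math.tanh(z + h))
    return ContrastResult(
        measure=measure,
        statistic=float(r),
        df=(float(n - 2),),
        p=float(p),
        effect_size=float(r),
        effect_kind="pearson_r",
        ci=ci,
    )


def analyze_measures(
    measures: pd.DataFrame,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Run the standard battery of contrasts on a measures table.

    Expects the per-subject measures CSV dialect (columns
    ``subject_id, condition, condition_order, n_correct,
    temporal_factor, semantic_factor, n_ELI``). Returns a long-format
    contrasts table.
    """
    rows: list[dict] = []

    def push(name: str, res: ContrastResult) -> None:
        rows.append(
            {
                "contrast": name,
                "statistic": res.statistic,
                "df1": res.df[0],
                "df2": res.df[1] if len(res.df) > 1 else math.nan,
                "p": res.p,
                "effect_size": res.effect_size,
                "effect_kind": res.effect_kind,
                "adjustment": res.adjustment,
                "n_perm": res.n_perm,
            }
        )

    conditions = [
        c for c in ("same_context", "different_context") if c in set(measures["condition"])
    ]
    for factor in ("semantic_factor", "temporal_factor"):
        for cond in conditions:
            scores = measures.loc[measures["condition"] == cond, factor]
            try:
                push(
                    f"{factor}[{cond}] > chance",
                    one_sample_vs_chance(scores, measure=factor),
                )
            except ValidationError:
                pass
    two_cond = measures[measures["condition"].isin(conditions)]
    if len(conditions) == 2:
        for dv in ("semantic_factor", "temporal_factor", "n_correct", "n_ELI"):
            try:
                for label, res in mixed_anova_2x2(two_cond, dv).items():
                    push(f"{dv}:{label}", res)
            except ValidationError:
                pass
            wide = two_cond.pivot_table(
                index="subject_id", columns="condition", values=dv
            ).dropna()
            if len(wide) >= 6:
                push(
                    f"{dv}:paired_permutation",
                    paired_permutation(
                        wide[conditions[0]],
                        wide[conditions[1]],
                        n_perm=n_perm,
                        seed=seed,
                        measure=dv,
                    ),
                )
        for cond in conditions:
            sub = measures[measures["condition"] == cond]
            try:
                push(
                    f"recall_x_semantic[{cond}]",
                    recall_organization_correlation(
                        sub["n_correct"], sub["semantic_factor"]
                    ),
                )
            except ValidationError:
                pass
    return pd.DataFrame(rows)
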