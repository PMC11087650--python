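"""Group-level inference for the SNc measurements.

Implements the study-style statistical battery: one-way ANOVA and chi-square
for demographics, ANCOVA (group effect controlling age and sex) for imaging
measures, gated post-hoc Student t-tests, percentage changes between group
means, ROC AUC for pairwise diagnostic separation, Pearson correlations with
max-statistic permutation control of the family-wise error rate, and the
mutation-subtype t-test within the carrier group.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

import statsmodels.api as sm

__all__ = [
    "anova_oneway",
    "chi_square_proportion",
    "AncovaResult",
    "ancova_group_effect",
    "posthoc_ttests",
    "percent_change",
    "roc_auc",
    "PermCorrelationResult",
    "permutation_corrected_correlations",
    "subgroup_ttest",
    "GROUP_PAIRS",
    "trend_flag",
]

GROUP_PAIRS = (("HC", "LRRK2"), ("HC", "PD"), ("LRRK2", "PD"))

#: p-values in this half-open band (lo, hi] are flagged as trends.
TREND_BAND = (0.05, 0.09)


def trend_flag(p: float, alpha: float = 0.05, band: tuple[float, float] = TREND_BAND) -> str:
    """'*' for significant, '#' for a trend, '' otherwise."""
    if p < alpha:
        return "*"
    if band[0] < p <= band[1]:
        return "#"
    return ""


def anova_oneway(values, group_labels) -> tuple[float, float]:
    """Classical one-way ANOVA across the label groups; returns (F, p)."""
    values = np.asarray(values, float)
    labels = np.asarray(group_labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    for g, arr in zip(pd.unique(labels), groups):
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def chi_square_proportion(counts) -> tuple[float, float]:
    """Pearson chi-square on a contingency table of counts, no continuity
    correction, df = (r-1)(c-1); returns (chi2, p)."""
    table = np.asarray(counts, float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    if np.any(expected <= 0):
        raise ValueError("all expected counts must be positive")
    return float(chi2), float(p)


@dataclass
class AncovaResult:
    measure: str
    f_stat: float
    p_value: float
    df_num: int
    df_den: int
    adjusted_means: dict[str, float] = field(default_factory=dict)


def ancova_group_effect(measure, group, age, sex, measure_name: str = "measure") -> AncovaResult:
    """ANCOVA: measure ~ group + age + sex; partial F-test for the group term.

    ``sex`` may be 'M'/'F' strings (coded M=1) or a binary numeric indicator.
    Group indicators use HC as the reference when present.  Covariate-adjusted
    group means are evaluated at the sample mean age and sex mix.
    """
    y = np.asarray(measure, float)
    labels = np.asarray(group)
    age = np.asarray(age, float)
    sex = np.asarray(sex)
    if sex.dtype.kind in "UO":
        sex_num = (sex == "M").astype(float)
    else:
        sex_num = sex.astype(float)
    keep = np.isfinite(y) & np.isfinite(age) & np.isfinite(sex_num)
    y, labels, age, sex_num = y[keep], labels[keep], age[keep], sex_num[keep]

    level_order = [g for g in ("HC", "LRRK2", "PD") if g in set(labels)]
    for g in pd.unique(labels):
        if g not in level_order:
            level_order.append(g)
    dummies = np.column_stack([(labels == g).astype(float) for g in level_order[1:]])
    covars = np.column_stack([age, sex_num])
    x_full = np.column_stack([np.ones(len(y)), dummies, covars])
    if len(y) <= x_full.shape[1]:
        raise ValueError(
            f"n = {len(y)} too small for {x_full.shape[1]} model parameters"
        )
    rank = np.linalg.matrix_rank(x_full)
    if rank < x_full.shape[1]:
        raise ValueError(
            "rank-deficient ANCOVA design (collinear columns among group "
            "indicators, age, sex)"
        )
    full = sm.OLS(y, x_full).fit()
    x_reduced = np.column_stack([np.ones(len(y)), covars])
    reduced = sm.OLS(y, x_reduced).fit()
    df_num = len(level_order) - 1
    df_den = int(full.df_resid)
    f = ((reduced.ssr - full.ssr) / df_num) / (full.ssr / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    beta = full.params
    adj = {}
    mean_cov = covars.mean(axis=0)
    for k, g in enumerate(level_order):
        x_pred = np.concatenate(
            [[1.0], np.eye(len(level_order) - 1)[k - 1] if k > 0 else np.zeros(len(level_order) - 1), mean_cov]
        )
        adj[g] = float(x_pred @ beta)
    return AncovaResult(
        measure=measure_name,
        f_stat=float(f),
        p_value=p,
        df_num=df_num,
        df_den=df_den,
        adjusted_means=adj,
    )


def posthoc_ttests(
    values,
    group_labels,
    gate_p: float,
    alpha: float = 0.05,
    pairs=GROUP_PAIRS,
) -> dict[tuple[str, str], float]:
    """Pairwise two-sided pooled-variance Student t-tests, gated on an omnibus p.

    When ``gate_p >= alpha`` the comparisons are not performed and every pair is
    reported missing (NaN) — post-hoc tests only follow a significant group
    effect.  Unadjusted pairwise tests after a significant omnibus are Fisher's
    least-significant-difference procedure.
    """
    values = np.asarray(values, float)
    labels = np.asarray(group_labels)
    out: dict[tuple[str, str], float] = {}
    if not np.isfinite(gate_p):
        raise ValueError("gate_p must be a finite probability")
    for a, b in pairs:
        if gate_p >= alpha:
            out[(a, b)] = float("nan")
            continue
        xa, xb = values[labels == a], values[labels == b]
        if xa.size < 2 or xb.size < 2:
            raise ValueError(f"groups {a!r}/{b!r} need >= 2 observations each")
        _, p = stats.ttest_ind(xa, xb, equal_var=True)
        out[(a, b)] = float(p)
    return out


def percent_change(mean_ref: float, mean_cmp: float) -> float:
    """100 * (cmp - ref) / ref."""
    if mean_ref == 0:
        raise ValueError("reference mean is zero; percent change undefined")
    return 100.0 * (mean_cmp - mean_ref) / mean_ref


def roc_auc(scores, binary_labels, positive_lower: bool = True) -> float:
    """ROC AUC via the rank (Mann-Whitney) formulation with midranks for ties.

    ``binary_labels`` marks the disease-positive class with 1/True.  With
    ``positive_lower`` (the default) a *lower* score indicates disease — the
    SNc measures all decrease with degeneration — so the score sign is flipped
    before ranking and an effective marker yields AUC >= 0.5.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(binary_labels).astype(int)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, -scores if positive_lower else scores))


@dataclass
class PermCorrelationResult:
    group: str
    score: str
    measure: str
    n: int
    r: float
    p_fwe: float
    n_perm: int
    seed: int | None = None


def _pearson_with_nan(x: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Pearson r of ``x`` against each score column, pairwise-complete."""
    out = np.full(scores.shape[1], np.nan)
    for j in range(scores.shape[1]):
        s = scores[:, j]
        keep = np.isfinite(s) & np.isfinite(x)
        if keep.sum() < 3:
            continue
        xs, ss = x[keep], s[keep]
        if xs.std() == 0 or ss.std() == 0:
            continue
        out[j] = np.corrcoef(xs, ss)[0, 1]
    return out


def permutation_corrected_correlations(
    scores: pd.DataFrame,
    measure,
    n_perm: int = 10_000,
    seed: int | None = 0,
    group: str = "",
    measure_name: str = "",
    exact: bool = False,
) -> list[PermCorrelationResult]:
    """Pearson correlations of one measure against a family of clinical scores,
    with max-statistic permutation control of the family-wise error rate.

    The family is the set of score columns tested against this measure within
    one group.  The null is built by permuting the subject order of the
    measure; each permutation records the maximum |r| over the family, and

        p_fwe(score) = (1 + #{perm max |r| >= |r_obs|}) / (n_perm + 1).

    With ``exact=True`` all n! permutations are enumerated instead (tiny n
    only) and p_fwe = #{perm max |r| >= |r_obs|} / n!.  Scores that are
    constant or have < 5 complete cases with the measure are reported missing.
    """
    x = np.asarray(measure, float)
    score_mat = scores.to_numpy(float)
    names = list(scores.columns)
    n = len(x)
    min_cases = 3 if exact else 5  # enumeration is exact at any n
    valid = []
    for j, name in enumerate(names):
        keep = np.isfinite(score_mat[:, j]) & np.isfinite(x)
        if keep.sum() >= min_cases and np.nanstd(score_mat[keep, j]) > 0 and x[keep].std() > 0:
            valid.append(j)
    obs = _pearson_with_nan(x, score_mat)

    if exact:
        perms = list(itertools.permutations(range(n)))
        max_abs = np.empty(len(perms))
        for i, perm in enumerate(perms):
            r_perm = _pearson_with_nan(x[list(perm)], score_mat)
            max_abs[i] = np.nanmax(np.abs(r_perm[valid])) if valid else np.nan
        n_used = len(perms)
        add_one = 0
    else:
        rng = np.random.default_rng(seed)
        max_abs = np.empty(n_perm)
        for i in range(n_perm):
            r_perm = _pearson_with_nan(x[rng.permutation(n)], score_mat)
            max_abs[i] = np.nanmax(np.abs(r_perm[valid])) if valid else np.nan
        n_used = n_perm
        add_one = 1

    results = []
    for j, name in enumerate(names):
        if j not in valid or not np.isfinite(obs[j]):
            results.append(
                PermCorrelationResult(
                    group=group,
                    score=name,
                    measure=measure_name,
                    n=int(np.isfinite(score_mat[:, j]).sum()),
                    r=float("nan"),
                    p_fwe=float("nan"),
                    n_perm=n_used,
                    seed=seed,
                )
            )
            continue
        exceed = int(np.sum(max_abs >= abs(obs[j]) - 1e-12))
        p = (add_one + exceed) / (n_used + add_one)
        results.append(
            PermCorrelationResult(
                group=group,
                score=name,
                measure=measure_name,
                n=int((np.isfinite(score_mat[:, j]) & np.isfinite(x)).sum()),
                r=float(obs[j]),
                p_fwe=float(p),
                n_perm=n_used,
                seed=seed,
            )
        )
    return results


def subgroup_ttest(measures: pd.DataFrame, mutation_labels) -> dict[str, float]:
    """Two-sided Student t-test between the G2385R and R1628P carriers for
    each whole-SNc measure column of ``measures``; returns measure -> p."""
    labels = np.asarray(mutation_labels)
    a_idx = labels == "G2385R"
    b_idx = labels == "R1628P"
    if a_idx.sum() < 2 or b_idx.sum() < 2:
        raise ValueError(
            f"both mutation subgroups need >= 2 subjects, got {int(a_idx.sum())} "
            f"G2385R and {int(b_idx.sum())} R1628P"
        )
    out = {}
    for col in measures.columns:
        vals = measures[col].to_numpy(float)
        _, p = stats.ttest_ind(vals[a_idx], vals[b_idx], equal_var=True)
        out[col] = float(p)
    return out
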