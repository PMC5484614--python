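"""Cohort statistics: densities, labelling indices, litter normalization,
normality-gated group comparison and step-down multiple-testing correction.

Two-group comparisons are gated by the Shapiro-Wilk test at alpha = 0.05
on each group: both normal -> two-tailed t-test (Welch's correction when
an F-test rejects equal variances), otherwise Mann-Whitney U.  For three
or more groups the same gate routes to one-way ANOVA with Bonferroni
post-hoc t-tests or Kruskal-Wallis with Dunn's post-hoc test.

The multiple-comparison correction multiplies the most significant of N
p-values by N, the next by N-1, and so on (a step-down Holm-Bonferroni
scheme).  By default corrected values are additionally made monotone
non-decreasing in the sorted order and capped at 1 — the bare
multiplication rule can invert the ordering; ``enforce_monotone=False``
reproduces the literal rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "count_metrics",
    "labelling_index",
    "caspase_litter_normalization",
    "ComparisonResult",
    "compare_groups",
    "compare_multiple",
    "holm_bonferroni_variant",
]

ALPHA_NORMALITY = 0.05
ALPHA_VARIANCE = 0.05

COUNT_COLUMNS = ["litter_id", "animal_id", "genotype", "field_id", "area_mm2", "marker", "count"]


def _validate_count_table(table: pd.DataFrame) -> None:
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    if (table["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    if (table["area_mm2"] <= 0).any():
        raise ValueError("field areas must be positive")
    geno = table.groupby("animal_id")[["genotype", "litter_id"]].nunique()
    if (geno > 1).any().any():
        raise ValueError("every animal must map to exactly one litter and genotype")


def count_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Per-animal density (cells/mm^2) for each marker, pooling fields.

    Density is total counts over total area per animal (count-weighted
    pooling, so densities are additive over fields).
    """
    _validate_count_table(table)
    g = table.groupby(["litter_id", "animal_id", "genotype", "marker"], sort=False)
    out = g.agg(count=("count", "sum"), area_mm2=("area_mm2", "sum")).reset_index()
    out["density_per_mm2"] = out["count"] / out["area_mm2"]
    return out


def labelling_index(
    table: pd.DataFrame,
    double_marker: str = "EdU+Pdgfra",
    reference_marker: str = "Pdgfra",
) -> pd.DataFrame:
    """Per-animal labelling index: 100 x double-positive / reference counts.

    Counts are pooled over fields per animal.  Animals with a zero
    reference count get index NaN and are reported via the ``defined``
    column rather than dropped silently.
    """
    _validate_count_table(table)
    pooled = table.groupby(["litter_id", "animal_id", "genotype", "marker"])["count"].sum().unstack("marker")
    for m in (double_marker, reference_marker):
        if m not in pooled.columns:
            raise ValueError(f"marker {m!r} not present in the table")
    ref = pooled[reference_marker]
    idx = 100.0 * pooled[double_marker] / ref.where(ref > 0)
    out = idx.rename("labelling_index_pct").reset_index()
    out["defined"] = ref.to_numpy() > 0
    return out


def caspase_litter_normalization(
    table: pd.DataFrame,
    control_label: str = "control",
) -> tuple[float, pd.DataFrame, list]:
    """Two-step litter normalization of per-animal apoptotic fractions.

    ``table`` columns: litter_id, animal_id, genotype, fraction.  Step 1:
    the pooled control mean fraction (averaged across litters).  Step 2:
    within each litter, every animal's fraction is divided by that
    litter's control mean (controls average to 1 by construction).  Step
    3: normalized mutant values are averaged across litters to give the
    fold-change per mutant genotype.

    Returns ``(control_mean_fraction, folds, excluded_litters)`` where
    ``folds`` has one row per non-control genotype (fold, sem, n) and
    litters lacking controls are excluded and reported.
    """
    req = {"litter_id", "genotype", "fraction"}
    if not req.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(req)}")
    excluded = []
    normed = []
    ctrl_means = []
    for lit, sub in table.groupby("litter_id"):
        ctrl = sub.loc[sub["genotype"] == control_label, "fraction"]
        if ctrl.empty:
            excluded.append(lit)
            continue
        ctrl_means.append(ctrl.mean())
        s = sub.copy()
        s["normalized"] = s["fraction"] / ctrl.mean()
        normed.append(s)
    if not normed:
        raise ValueError("no litter contains control animals")
    alln = pd.concat(normed, ignore_index=True)
    control_mean = float(np.mean(ctrl_means))
    mut = alln[alln["genotype"] != control_label]
    folds = (
        mut.groupby("genotype")["normalized"]
        .agg(fold="mean", sem="sem", n="count")
        .reset_index()
    )
    return control_mean, folds, excluded


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    effect_pct: float  # 100 * (mean_b - mean_a) / mean_a
    n: tuple[int, ...]
    normal: tuple[bool, ...]


def _shapiro_ok(x: np.ndarray) -> bool:
    if len(x) < 3 or np.ptp(x) == 0:
        return False
    return sps.shapiro(x).pvalue > ALPHA_NORMALITY


def compare_groups(a, b, paired: bool = False) -> ComparisonResult:
    """Normality-gated two-group comparison.

    Both groups Shapiro-Wilk-normal -> two-tailed t-test (paired or
    unpaired; Welch's correction when a two-sided F-test rejects variance
    equality at alpha = 0.05); otherwise Mann-Whitney U (Wilcoxon
    signed-rank when paired).  Effect size is the percent change of group
    means, B relative to A.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per group")
    norm_a, norm_b = _shapiro_ok(a), _shapiro_ok(b)
    effect = 100.0 * (b.mean() - a.mean()) / a.mean() if a.mean() != 0 else np.nan
    if norm_a and norm_b:
        if paired:
            res = sps.ttest_rel(a, b)
            name = "paired t-test"
        else:
            f = np.var(a, ddof=1) / np.var(b, ddof=1)
            p_f = 2 * min(
                sps.f.cdf(f, len(a) - 1, len(b) - 1),
                sps.f.sf(f, len(a) - 1, len(b) - 1),
            )
            welch = p_f < ALPHA_VARIANCE
            res = sps.ttest_ind(a, b, equal_var=not welch)
            name = "Welch t-test" if welch else "Student t-test"
    else:
        if paired:
            res = sps.wilcoxon(a, b)
            name = "Wilcoxon signed-rank"
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            name = "Mann-Whitney U"
    return ComparisonResult(
        test=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_pct=float(effect),
        n=(len(a), len(b)),
        normal=(norm_a, norm_b),
    )


def _dunn_posthoc(groups: list[np.ndarray]) -> pd.DataFrame:
    """Dunn's z-test on pooled ranks with a tie correction, Bonferroni-adjusted."""
    k = len(groups)
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts**3 - counts).sum() / (12.0 * (n - 1))
    sizes = [len(g) for g in groups]
    mean_ranks = []
    start = 0
    for s in sizes:
        mean_ranks.append(ranks[start : start + s].mean())
        start += s
    n_comp = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt((n * (n + 1) / 12.0 - tie) * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = min(1.0, 2 * sps.norm.sf(abs(z)) * n_comp)
            rows.append((i, j, z, p))
    return pd.DataFrame(rows, columns=["group_i", "group_j", "z", "p_adj"])


def compare_multiple(groups: list) -> tuple[ComparisonResult, pd.DataFrame]:
    """Normality-gated comparison of three or more groups.

    All groups normal -> one-way ANOVA with Bonferroni-corrected pairwise
    t-tests; otherwise Kruskal-Wallis with Dunn's post-hoc test.  Returns
    the omnibus result and the pairwise table.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("use compare_groups for two groups")
    normal = [_shapiro_ok(g) for g in groups]
    k = len(groups)
    n_comp = k * (k - 1) // 2
    if all(normal):
        res = sps.f_oneway(*groups)
        name = "one-way ANOVA + Bonferroni"
        rows = []
        for i in range(k):
            for j in range(i + 1, k):
                t = sps.ttest_ind(groups[i], groups[j])
                rows.append((i, j, float(t.statistic), min(1.0, float(t.pvalue) * n_comp)))
        pairs = pd.DataFrame(rows, columns=["group_i", "group_j", "stat", "p_adj"])
    else:
        res = sps.kruskal(*groups)
        name = "Kruskal-Wallis + Dunn"
        pairs = _dunn_posthoc(groups)
    omnibus = ComparisonResult(
        test=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_pct=np.nan,
        n=tuple(len(g) for g in groups),
        normal=tuple(normal),
    )
    return omnibus, pairs


def holm_bonferroni_variant(
    pvals, enforce_monotone: bool = True
) -> np.ndarray:
    """Step-down correction: rank-i p-value (ascending) multiplied by N-i+1.

    With ``enforce_monotone`` (default) corrected values are made
    non-decreasing along the sorted order and capped at 1, which is the
    standard Holm step-down adjustment; disabling it reproduces the bare
    multiplication rule.  Ties are multiplied by their individual ranks.
    Returns corrected p-values in the original order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    mult = n - np.arange(n)  # N, N-1, ..., 1
    corrected_sorted = p[order] * mult
    if enforce_monotone:
        corrected_sorted = np.maximum.accumulate(corrected_sorted)
    corrected_sorted = np.minimum(corrected_sorted, 1.0)
    out = np.empty(n)
    out[order] = corrected_sorted
    return out
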