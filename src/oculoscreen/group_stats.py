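"""Normality-gated two-group comparisons with effect sizes.

Each feature is compared between the two cohorts with a Shapiro-Wilk gate:
if both groups look normal (p >= alpha on both), an independent two-sample
t-test with Cohen's d; otherwise a two-sided Mann-Whitney U test with the
rank-biserial correlation r = 1 - 2U/(n_a * n_b).  Effect-size confidence
intervals come from a seeded percentile bootstrap.  Significance is
two-tailed at p < 0.05 and no multiple-testing correction is applied by
default (a Holm option exists).

The unit of analysis defaults to subjects (each observation = a subject's
mean over retained trials), which respects the nesting of trials within
subjects; a trial-level mode (each trial an observation) is provided for
comparison with analyses that treat trials as independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["ComparisonResult", "compare_groups", "compare_feature_table"]


@dataclass(frozen=True)
class ComparisonResult:
    feature: str
    test: str                 # "t" | "mann-whitney" | "skipped"
    statistic: float
    p_two_tailed: float
    effect_size: float        # Cohen's d (t) or rank-biserial r (MWU)
    effect_size_name: str
    ci_95: tuple[float, float]
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    n_a: int
    n_b: int


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def _rank_biserial(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    u, _ = stats.mannwhitneyu(a, b, alternative="two-sided")
    r = 1.0 - 2.0 * u / (len(a) * len(b))
    return float(u), float(r)


def compare_groups(
    values_a,
    values_b,
    feature: str = "",
    alpha_normality: float = 0.05,
    equal_var: bool = True,
    n_boot: int = 10_000,
    seed: int = 0,
) -> ComparisonResult:
    """Normality-gated comparison of two samples.

    Requires >= 3 observations per group.  ``n_boot=0`` skips the bootstrap
    CI (reported as NaN), which is useful inside large simulations.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 finite observations")

    def describe():
        return dict(mean_a=float(a.mean()), sem_a=float(stats.sem(a)),
                    mean_b=float(b.mean()), sem_b=float(stats.sem(b)),
                    n_a=len(a), n_b=len(b))

    if a.var() == 0 and b.var() == 0:
        return ComparisonResult(feature=feature, test="skipped",
                                statistic=np.nan, p_two_tailed=np.nan,
                                effect_size=0.0, effect_size_name="none",
                                ci_95=(np.nan, np.nan), **describe())

    normal_a = a.var() > 0 and stats.shapiro(a).pvalue >= alpha_normality
    normal_b = b.var() > 0 and stats.shapiro(b).pvalue >= alpha_normality

    if normal_a and normal_b:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        test, stat, p = "t", float(res.statistic), float(res.pvalue)
        effect, effect_name = _cohens_d(a, b), "cohens_d"
        point = _cohens_d
    else:
        u, r = _rank_biserial(a, b)
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        test, stat, effect, effect_name = "mann-whitney", u, r, "rank_biserial_r"
        point = lambda x, y: _rank_biserial(x, y)[1]  # noqa: E731

    ci = (np.nan, np.nan)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            ra = a[rng.integers(0, len(a), len(a))]
            rb = b[rng.integers(0, len(b), len(b))]
            boots[i] = point(ra, rb)
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    return ComparisonResult(feature=feature, test=test, statistic=stat,
                            p_two_tailed=float(p), effect_size=float(effect),
                            effect_size_name=effect_name, ci_95=ci, **describe())


def compare_feature_table(
    features: pd.DataFrame,
    groups: dict[str, str],
    group_a: str,
    group_b: str,
    feature_names: list[str],
    unit: str = "subject",
    alpha_normality: float = 0.05,
    n_boot: int = 10_000,
    seed: int = 0,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-feature group comparison over a tidy (subject, trial) feature table.

    ``unit="subject"`` averages each subject's retained trials first (the
    statistically preferred default); ``unit="trial"`` treats every trial
    as an observation.
    """
    if unit not in ("subject", "trial"):
        raise ValueError("unit must be 'subject' or 'trial'")
    df = features.copy()
    df["group"] = df["subject_id"].map(groups)
    if unit == "subject":
        df = df.groupby(["subject_id", "group"], as_index=False)[feature_names].mean()

    rows = []
    for i, name in enumerate(feature_names):
        a = df.loc[df["group"] == group_a, name].to_numpy(dtype=float)
        b = df.loc[df["group"] == group_b, name].to_numpy(dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 3 or len(b) < 3:
            rows.append(ComparisonResult(
                feature=name, test="skipped", statistic=np.nan,
                p_two_tailed=np.nan, effect_size=np.nan, effect_size_name="none",
                ci_95=(np.nan, np.nan),
                mean_a=float(a.mean()) if len(a) else np.nan, sem_a=np.nan,
                mean_b=float(b.mean()) if len(b) else np.nan, sem_b=np.nan,
                n_a=len(a), n_b=len(b)).__dict__)
            continue
        res = compare_groups(a, b, feature=name, alpha_normality=alpha_normality,
                             n_boot=n_boot, seed=seed + i)
        rows.append(res.__dict__)
    out = pd.DataFrame(rows)
    if holm:
        mask = out["p_two_tailed"].notna()
        adj = np.full(len(out), np.nan)
        adj[mask.to_numpy()] = multipletests(out.loc[mask, "p_two_tailed"], method="holm")[1]
        out["p_holm"] = adj
    return out
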