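"""Group inference: chi-squared, ANOVA (raw or from summaries),
Tukey-Kramer post-hocs, covariate-adjusted ANCOVA and BH-FDR.

Demographic comparisons (sex by chi-squared, age and ICV by one-way
ANOVA) can be reconstructed from published per-group summary statistics
(mean, SD, n). Network metrics are compared by ANCOVA — a linear model
of the metric on group plus age, sex and ICV, with a joint F-test on the
group term — applied at each analysis level (whole brain, module, node,
hub rank) with Benjamini-Hochberg FDR within the level and Tukey-Kramer
pairwise post-hocs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import GROUPS, CohortTable


def chi_squared_2x2(counts) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, df = 1, no continuity correction."""
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin")
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def _summary_ss(means, sds, ns):
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if len(means) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(sds < 0):
        raise ValueError("negative SD")
    if np.any(ns < 2):
        raise ValueError("all group sizes must be >= 2")
    big_n = ns.sum()
    grand = (ns * means).sum() / big_n
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    return ss_between, ss_within, big_n, len(means)


def anova_from_summary(means, sds, ns) -> tuple[float, float]:
    """One-way ANOVA F and p reconstructed from per-group (mean, SD, n)."""
    ssb, ssw, big_n, k = _summary_ss(means, sds, ns)
    df_b, df_w = k - 1, big_n - k
    if ssw == 0:
        return (np.inf, 0.0) if ssb > 0 else (0.0, 1.0)
    f = (ssb / df_b) / (ssw / df_w)
    return float(f), float(sps.f.sf(f, df_b, df_w))


@dataclass(frozen=True)
class PosthocResult:
    """Tukey-Kramer pairwise comparisons, one entry per unordered pair."""

    pairs: tuple[tuple[str, str], ...]
    diffs: np.ndarray
    p_values: np.ndarray


def tukey_kramer_from_summary(
    means, sds, ns, labels: tuple[str, ...] | None = None
) -> PosthocResult:
    """Studentized-range pairwise p-values with Tukey-Kramer standard
    errors for unequal group sizes, df = N - k."""
    ssb, ssw, big_n, k = _summary_ss(means, sds, ns)
    df_w = big_n - k
    msw = ssw / df_w
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if labels is None:
        labels = tuple(f"group{i + 1}" for i in range(k))
    pairs, diffs, pvals = [], [], []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            if msw == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df_w))
            pairs.append((labels[i], labels[j]))
            diffs.append(diff)
            pvals.append(min(1.0, p))
    return PosthocResult(
        pairs=tuple(pairs), diffs=np.asarray(diffs), p_values=np.asarray(pvals)
    )


@dataclass(frozen=True)
class AncovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    adjusted_means: dict[str, float]  # per group, at mean covariates
    posthoc: PosthocResult


def ancova_group_test(y: np.ndarray, cohort: CohortTable) -> AncovaResult:
    """Covariate-adjusted group comparison of one per-subject quantity.

    Fits ``y ~ group + age + sex + icv`` by OLS and tests the group term
    with a partial (extra-sum-of-squares) F-test; the post-hoc entry
    carries Tukey-Kramer p-values on the covariate-adjusted group means,
    with the residual mean square of the full model.
    """
    y = np.asarray(y, dtype=float)
    df = cohort.table
    if len(y) != len(df):
        raise ValueError("y length does not match cohort size")
    groups_present = [g for g in GROUPS if (df["group"] == g).any()]
    k = len(groups_present)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n = len(y)

    cov = np.column_stack(
        [df["age"].to_numpy(float), df["sex"].to_numpy(float), df["icv"].to_numpy(float)]
    )
    dummies = np.column_stack(
        [(df["group"] == g).to_numpy(float) for g in groups_present[1:]]
    )
    x_full = np.column_stack([np.ones(n), dummies, cov])
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError("collinear design (constant covariate or confounded groups)")
    x_red = np.column_stack([np.ones(n), cov])

    def _ssr(x):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r = y - x @ beta
        return float(r @ r), beta

    ssr_full, beta_full = _ssr(x_full)
    ssr_red, _ = _ssr(x_red)
    df_b = k - 1
    df_w = n - x_full.shape[1]
    mse = ssr_full / df_w
    if mse == 0:
        f = np.inf if ssr_red > ssr_full else 0.0
        p = 0.0 if f > 0 else 1.0
    else:
        f = ((ssr_red - ssr_full) / df_b) / mse
        p = float(sps.f.sf(f, df_b, df_w))

    # adjusted (least-squares) means: prediction at sample-mean covariates
    cov_mean = cov.mean(axis=0)
    adj = {}
    for gi, g in enumerate(groups_present):
        row = np.concatenate(
            [[1.0], np.eye(k - 1)[gi - 1] if gi > 0 else np.zeros(k - 1), cov_mean]
        )
        adj[g] = float(row @ beta_full)

    ns = np.array([(df["group"] == g).sum() for g in groups_present], dtype=float)
    adj_means = np.array([adj[g] for g in groups_present])
    pairs, diffs, pvals = [], [], []
    for i in range(k):
        for j in range(i + 1, k):
            diff = adj_means[i] - adj_means[j]
            if mse == 0:
                pt = 1.0 if diff == 0 else 0.0
            else:
                se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(diff) / se
                pt = float(sps.studentized_range.sf(q, k, df_w))
            pairs.append((groups_present[i], groups_present[j]))
            diffs.append(diff)
            pvals.append(min(1.0, pt))
    posthoc = PosthocResult(
        pairs=tuple(pairs), diffs=np.asarray(diffs), p_values=np.asarray(pvals)
    )
    return AncovaResult(
        f_stat=float(f),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        adjusted_means=adj,
        posthoc=posthoc,
    )


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (significance mask, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def ancova_table(
    values: np.ndarray, cohort: CohortTable, unit_labels: list[str], q: float = 0.05
) -> pd.DataFrame:
    """ANCOVA per network unit (column of ``values``) with FDR within the
    level; one row per unit with F, p, adjusted p and adjusted means."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == len(cohort) and values.shape[1] == len(unit_labels):
        pass
    elif values.shape == (len(unit_labels), len(cohort)):
        values = values.T
    else:
        raise ValueError("values shape does not match cohort x units")
    results = [ancova_group_test(values[:, k], cohort) for k in range(len(unit_labels))]
    pvals = np.array([r.p_value for r in results])
    sig, p_adj = fdr_bh(pvals, q=q)
    rows = []
    for lab, r, pa, s in zip(unit_labels, results, p_adj, sig):
        row = {
            "unit": lab,
            "F": r.f_stat,
            "p": r.p_value,
            "p_fdr": pa,
            "significant": bool(s),
        }
        for g, m in r.adjusted_means.items():
            row[f"adj_mean_{g}"] = m
        rows.append(row)
    return pd.DataFrame(rows)
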