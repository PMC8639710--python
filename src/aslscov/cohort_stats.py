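"""Classical cohort statistics from raw data or printed summaries.

One-way ANOVA and pairwise post-hoc t tests reconstructed from group
summary statistics (mean, SD, n) — which lets published demographic tables
be re-analysed without raw data — plus chi-square independence tests for
categorical variables, the four-factor vascular-risk score, and Pearson and
partial correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "anova_from_summary",
    "chi_square_independence",
    "counts_from_percent",
    "vascular_risk_score",
    "pearson_corr",
    "partial_corr",
    "pairwise_posthoc",
]


@dataclass
class GroupSummary:
    """Per-group mean, SD and n for one continuous variable."""

    groups: tuple
    means: tuple
    sds: tuple
    ns: tuple

    def __post_init__(self) -> None:
        k = len(self.groups)
        if not (len(self.means) == len(self.sds) == len(self.ns) == k):
            raise ValueError("groups, means, sds and ns must have equal length")

    @classmethod
    def from_data(cls, values, groups) -> "GroupSummary":
        df = pd.DataFrame({"v": np.asarray(values, float), "g": groups})
        agg = df.groupby("g", sort=True)["v"].agg(["mean", "std", "count"])
        return cls(
            groups=tuple(agg.index),
            means=tuple(agg["mean"]),
            sds=tuple(agg["std"]),
            ns=tuple(int(n) for n in agg["count"]),
        )


def anova_from_summary(summary: GroupSummary):
    """One-way ANOVA F statistic from group means, SDs and sizes.

    ``F = [sum n_i (m_i - m)^2 / (k-1)] / [sum (n_i-1) s_i^2 / (N-k)]`` with
    ``m`` the size-weighted grand mean.  Returns ``(F, df_between,
    df_within, p)``.  Equivalent to a raw-data one-way ANOVA whenever the
    summaries were computed from the raw data.
    """
    ns = np.asarray(summary.ns, dtype=float)
    if len(ns) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    means = np.asarray(summary.means, dtype=float)
    sds = np.asarray(summary.sds, dtype=float)
    k, N = len(ns), ns.sum()
    grand = float((ns * means).sum() / N)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_b, df_w = k - 1, int(N - k)
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return F, df_b, df_w, p


def chi_square_independence(counts):
    """Pearson chi-square test of independence on a 2 x k count table.

    No continuity correction.  Returns ``(chi2, df, p)``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("expected a 2-D count table")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero marginal in count table")
    chi2, p, df, expected = stats.chi2_contingency(counts, correction=False)
    if np.any(expected <= 0):
        raise ValueError("non-positive expected count")
    return float(chi2), int(df), float(p)


def counts_from_percent(percents, ns):
    """Integer positive counts from printed group percentages.

    Rounds ``percent/100 * n`` to the nearest integer, the convention under
    which published percentage tables round-trip to whole participants.
    """
    out = []
    for pct, n in zip(percents, ns):
        if not (0 <= pct <= 100):
            raise ValueError("percentage outside [0, 100]")
        out.append(int(round(pct / 100.0 * n)))
    return tuple(out)


def vascular_risk_score(
    hypertension: bool, dyslipidaemia: bool, diabetes: bool, smoking_history: bool
):
    """Aggregate vascular-risk score (0-4) and its >= 2 threshold indicator.

    One point per present (or treated) factor: hypertension, dyslipidaemia,
    diabetes and a positive smoking history.
    """
    score = int(hypertension) + int(dyslipidaemia) + int(diabetes) + int(
        smoking_history
    )
    return score, score >= 2


def pearson_corr(x, y):
    """Pearson product-moment correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def partial_corr(x, y, covariates):
    """Partial correlation of x and y given covariate columns.

    Both variables are residualised against the covariates (with intercept)
    by least squares; the Pearson correlation of the residuals is reported
    with a t-based p-value on ``n - 2 - q`` degrees of freedom for ``q``
    covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.column_stack([np.ones(len(x)), np.asarray(covariates, dtype=float)])
    q = C.shape[1] - 1
    if len(x) <= q + 2:
        raise ValueError("need n > number of covariates + 2")
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate design is singular")
    rx = x - C @ np.linalg.lstsq(C, x, rcond=None)[0]
    ry = y - C @ np.linalg.lstsq(C, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("a variable is fully explained by the covariates")
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = len(x) - 2 - q
    t = r * np.sqrt(df / max(1.0 - r**2, 1e-300))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p


def pairwise_posthoc(
    summary: GroupSummary, correction: str = "bonferroni", welch: bool = False
) -> pd.DataFrame:
    """Pairwise two-sample t tests from summary statistics.

    Pooled-variance t by default (``welch=True`` switches to the
    Welch-Satterthwaite test).  Bonferroni correction multiplies each
    p-value by the number of pairs, capped at 1; a single comparison is
    left uncorrected.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    pairs = list(combinations(range(len(summary.groups)), 2))
    n_pairs = len(pairs)
    rows = []
    for i, j in pairs:
        n1, n2 = summary.ns[i], summary.ns[j]
        if n1 < 2 or n2 < 2:
            raise ValueError("every tested group needs n >= 2")
        m1, m2 = summary.means[i], summary.means[j]
        s1, s2 = summary.sds[i], summary.sds[j]
        if welch:
            se2_1, se2_2 = s1**2 / n1, s2**2 / n2
            se = np.sqrt(se2_1 + se2_2)
            df = (se2_1 + se2_2) ** 2 / (
                se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1)
            )
        else:
            sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
            se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
            df = n1 + n2 - 2
        t = (m1 - m2) / se
        p = float(2 * stats.t.sf(abs(t), df))
        p_corr = p if (correction == "none" or n_pairs == 1) else min(1.0, p * n_pairs)
        rows.append(
            {
                "group1": summary.groups[i],
                "group2": summary.groups[j],
                "t": float(t),
                "df": float(df),
                "p": p,
                "p_corrected": p_corr,
            }
        )
    return pd.DataFrame(rows)
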