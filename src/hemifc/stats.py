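"""Hypothesis tests and multiple-comparison corrections.

Everything here is deliberately written from the closed-form definitions
(with scipy supplying only the reference distributions) so that each test
can be checked against brute-force oracles and against scipy's own
implementations independently.

Families for the FDR corrections are an explicit pipeline choice, logged
into the output tables: lateralization q-values are computed within group
across ROIs, AI-ANOVA q-values across ROIs, and clinical-correlation
q-values across all tested (feature, covariate) pairs.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError

__all__ = [
    "paired_t",
    "anova_oneway",
    "bonferroni_posthoc",
    "bh_fdr",
    "clinical_correlation",
    "mann_whitney_u",
    "demographics",
    "lateralization_table",
    "ai_group_table",
    "clinical_correlation_table",
]


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns ``(t, df, p)``.

    Pairs where either value is missing are dropped. Differences with zero
    variance are a degenerate input (the t statistic is undefined), not a
    p of 0 or 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DegenerateInputError("paired samples must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    d = x[keep] - y[keep]
    n = d.size
    if n < 2:
        raise DegenerateInputError(f"need >= 2 complete pairs, got {n}")
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero-variance differences; paired t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def anova_oneway(values_by_group: Mapping[str, Sequence[float]]
                 ) -> tuple[float, int, int, float]:
    """Classical one-way fixed-effects ANOVA; returns ``(F, df_b, df_w, p)``."""
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise DegenerateInputError("need >= 2 groups with >= 2 values each")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0:
        raise DegenerateInputError("all values identical; ANOVA undefined")
    grand = allv.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = allv.size - len(groups)
    if ssw == 0:
        raise DegenerateInputError("zero within-group variance; F undefined")
    f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), df_b, df_w, p


def bonferroni_posthoc(
    values_by_group: Mapping[str, Sequence[float]],
    pairs: Sequence[tuple[str, str]] | None = None,
    pooled: bool = True,
) -> list[tuple[tuple[str, str], float, float]]:
    """Pairwise post hoc comparisons with Bonferroni-adjusted p-values.

    By default each pairwise t uses the pooled within-group mean square
    from the omnibus ANOVA (the classical post hoc convention); with
    ``pooled=False`` a per-pair Welch t is used instead. Adjusted p is
    ``min(1, raw_p * n_pairs)``.
    """
    clean = {
        k: np.asarray(v, dtype=float)[~np.isnan(np.asarray(v, dtype=float))]
        for k, v in values_by_group.items()
    }
    anova_oneway(clean)  # validates eligibility
    if pairs is None:
        pairs = list(combinations(clean.keys(), 2))
    n_pairs = len(pairs)
    if pooled:
        df_w = sum(g.size for g in clean.values()) - len(clean)
        msw = sum(((g - g.mean()) ** 2).sum() for g in clean.values()) / df_w
    out = []
    for a, b in pairs:
        ga, gb = clean[a], clean[b]
        diff = ga.mean() - gb.mean()
        if pooled:
            se = np.sqrt(msw * (1.0 / ga.size + 1.0 / gb.size))
            df = df_w
        else:
            se = np.sqrt(ga.var(ddof=1) / ga.size + gb.var(ddof=1) / gb.size)
            df = se**4 / (
                (ga.var(ddof=1) / ga.size) ** 2 / (ga.size - 1)
                + (gb.var(ddof=1) / gb.size) ** 2 / (gb.size - 1)
            )
        raw = 2.0 * sps.t.sf(abs(diff / se), df)
        out.append(((a, b), float(diff), float(min(1.0, raw * n_pairs))))
    return out


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    NaN entries pass through as NaN and do not count toward the family
    size. Monotonicity is enforced (cumulative minimum from the largest p
    down), and q-values are capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    q = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(ranked, 1.0)
    q[valid] = qv
    return q


def clinical_correlation(feature_values: Sequence[float],
                         clinical: Sequence[float]) -> tuple[float, float]:
    """Pearson r with the two-sided p from ``t = r sqrt((n-2)/(1-r^2))``.

    Complete pairs only; ``|r| = 1`` is guarded (p underflows to 0 rather
    than dividing by zero).
    """
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(clinical, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise DegenerateInputError(f"need >= 3 complete pairs, got {n}")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("constant input vector; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    denom = max(1.0 - r * r, np.finfo(float).tiny)
    t = r * np.sqrt((n - 2) / denom)
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return r, p


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   exact_max_n: int = 8) -> tuple[float, float]:
    """Mann-Whitney U; returns ``(U, p two-sided)``.

    Convention: U counts pairs where the first sample exceeds the second
    (ties count one half), i.e. scipy's U1. Exact enumeration when both
    groups have at most ``exact_max_n`` observations and there are no
    ties; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise DegenerateInputError("both groups must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= exact_max_n and y.size <= exact_max_n
                         and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def demographics(manifest: pd.DataFrame, patient_groups: Sequence[str] = ("LMTLE", "RMTLE")
                 ) -> pd.DataFrame:
    """Cohort-level demographic tests, one tidy row per test.

    ANOVA on age across all groups, chi-squared (no continuity correction)
    on the sex x group table, and Mann-Whitney U between the two patient
    groups for onset age and duration.
    """
    rows = []
    by_group = {g: sub for g, sub in manifest.groupby("group", sort=False)}

    ages = {g: sub["age"].to_numpy(dtype=float) for g, sub in by_group.items()}
    f, df_b, df_w, p = anova_oneway(ages)
    rows.append({"variable": "age", "test": "anova", "statistic": f,
                 "df": f"{df_b},{df_w}", "p": p, "note": ""})

    table = pd.crosstab(manifest["group"], manifest["sex"])
    if (table.to_numpy() == 0).any():
        rows.append({"variable": "sex", "test": "chi2", "statistic": np.nan,
                     "df": "", "p": np.nan,
                     "note": "empty cell in contingency table; test skipped"})
    else:
        chi2, p, dof, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
        rows.append({"variable": "sex", "test": "chi2", "statistic": float(chi2),
                     "df": str(dof), "p": float(p), "note": ""})

    ga, gb = patient_groups
    for var in ("onset_age", "duration"):
        u, p = mann_whitney_u(
            by_group[ga][var].to_numpy(dtype=float),
            by_group[gb][var].to_numpy(dtype=float),
        )
        rows.append({"variable": var, "test": "mann-whitney",
                     "statistic": u, "df": "", "p": p,
                     "note": f"U of {ga} vs {gb} (pairs where {ga} > {gb})"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# table builders on asymmetry profiles
# ---------------------------------------------------------------------------


def lateralization_table(profiles: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-group, per-ROI paired t of rFC against lFC with within-group BH.

    ``profiles`` is the long-format cohort table (columns ``subject_id``,
    ``group``, ``roi_id``, ``rFC``, ``lFC``). ROIs whose differences are
    degenerate in a group get NaN statistics and are excluded from that
    group's FDR family. ``direction`` is rightward/leftward when
    ``q_fdr < alpha``, else none.
    """
    rows = []
    for group, sub in profiles.groupby("group", sort=False):
        for roi_id, roi_sub in sub.groupby("roi_id", sort=False):
            rfc = roi_sub["rFC"].to_numpy(dtype=float)
            lfc = roi_sub["lFC"].to_numpy(dtype=float)
            try:
                t, df, p = paired_t(rfc, lfc)
            except DegenerateInputError:
                t, df, p = np.nan, len(rfc) - 1, np.nan
            rows.append({"group": group, "roi_id": roi_id,
                         "mean_rFC": np.nanmean(rfc), "mean_lFC": np.nanmean(lfc),
                         "t_stat": t, "df": df, "p": p})
    out = pd.DataFrame(rows)
    out["q_fdr"] = np.nan
    for group in out["group"].unique():
        mask = out["group"] == group
        out.loc[mask, "q_fdr"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    sig = out["q_fdr"] < alpha
    out["direction"] = "none"
    out.loc[sig & (out["mean_rFC"] > out["mean_lFC"]), "direction"] = "rightward"
    out.loc[sig & (out["mean_rFC"] < out["mean_lFC"]), "direction"] = "leftward"
    return out


def ai_group_table(profiles: pd.DataFrame, alpha: float = 0.05,
                   pooled_posthoc: bool = True) -> pd.DataFrame:
    """Per-ROI one-way ANOVA of AI across groups, BH across ROIs, plus
    Bonferroni post hoc pairwise comparisons.

    Undefined AI values are dropped listwise per ROI; the number dropped is
    reported in ``n_dropped``.
    """
    rows = []
    for roi_id, sub in profiles.groupby("roi_id", sort=False):
        values = {g: gsub["AI"].to_numpy(dtype=float)
                  for g, gsub in sub.groupby("group", sort=False)}
        n_dropped = int(sum(np.isnan(v).sum() for v in values.values()))
        try:
            f, df_b, df_w, p = anova_oneway(values)
            posthoc = bonferroni_posthoc(values, pooled=pooled_posthoc)
        except DegenerateInputError:
            f, df_b, df_w, p, posthoc = np.nan, np.nan, np.nan, np.nan, []
        rows.append({"roi_id": roi_id, "F_stat": f, "df_between": df_b,
                     "df_within": df_w, "p": p, "n_dropped": n_dropped,
                     "posthoc": posthoc})
    out = pd.DataFrame(rows)
    out["q_fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q_fdr"] < alpha
    return out


def clinical_correlation_table(features: pd.DataFrame, clinical: pd.DataFrame,
                               covariates: Sequence[str] = ("onset_age", "duration"),
                               ) -> pd.DataFrame:
    """Pearson correlations of every feature column against every clinical
    covariate, one BH family across all tested pairs.

    ``features`` is indexed by subject_id with one column per feature;
    ``clinical`` is indexed by subject_id with the covariate columns.
    """
    rows = []
    merged = features.join(clinical[list(covariates)], how="inner")
    for feat in features.columns:
        for cov in covariates:
            try:
                r, p = clinical_correlation(merged[feat], merged[cov])
            except DegenerateInputError:
                r, p = np.nan, np.nan
            rows.append({"feature": feat, "covariate": cov, "r": r, "p": p})
    out = pd.DataFrame(rows)
    out["q_fdr"] = bh_fdr(out["p"].to_numpy())
    return out
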