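"""Group x hemisphere inference for hemispheric connectome metrics.

Implements the hemispheric asymmetry score

    AS(X) = 100 * (X_R - X_L) / (X_R + X_L),

negative values meaning a left-hemisphere advantage; a two-level
repeated-measures (mixed) ANOVA with group as the between-subject factor
and hemisphere as the within-subject factor, covariates entering the
between-subject stratum (ANCOVA form, reproducing denominator df
N - 2 - c); gated post hoc paired/independent t-tests; Bonferroni
correction; covariate-adjusted (partial) Spearman correlation; and an
edge-wise census of aberrant connections per rich-club/feeder/local
class.

With two within-subject levels the mixed ANOVA decomposes exactly into
two orthogonal strata: subject means m_i = (L_i + R_i)/2 carry the
between-subject (group) information, and contrasts d_i = R_i - L_i carry
the hemisphere main effect (intercept) and the group-by-hemisphere
interaction (group difference in d). Both strata are fitted by ordinary
least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .richclub import EdgeClassification, EDGE_CLASSES

__all__ = [
    "AnovaResult",
    "asymmetry_score",
    "mixed_anova",
    "posthoc_tests",
    "asymmetry_tests",
    "bonferroni",
    "partial_spearman",
    "edgewise_census",
    "residualize",
    "significance_stars",
]


@dataclass
class AnovaResult:
    """F, df and p for group, hemisphere and their interaction."""

    F_group: float
    df_group: tuple
    p_group: float
    F_hemisphere: float
    df_hemisphere: tuple
    p_hemisphere: float
    F_interaction: float
    df_interaction: tuple
    p_interaction: float

    def as_dict(self) -> dict:
        return {
            "F_group": self.F_group,
            "df_group": self.df_group,
            "p_group": self.p_group,
            "F_hemisphere": self.F_hemisphere,
            "df_hemisphere": self.df_hemisphere,
            "p_hemisphere": self.p_hemisphere,
            "F_interaction": self.F_interaction,
            "df_interaction": self.df_interaction,
            "p_interaction": self.p_interaction,
        }


def asymmetry_score(x_right, x_left):
    """AS(X) = 100 (R - L)/(R + L); NaN (with a warning) when both zero.

    Accepts scalars or arrays of nonnegative metric values. Bounded in
    [-100, 100]; zero iff the two sides are equal; antisymmetric under
    swapping hemispheres.
    """
    r = np.asarray(x_right, dtype=float)
    l = np.asarray(x_left, dtype=float)
    total = r + l
    both_zero = total == 0
    if np.any(both_zero):
        warnings.warn(
            "asymmetry score undefined where both hemispheres are zero; "
            "returning NaN",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(both_zero, np.nan, 100.0 * (r - l) / np.where(both_zero, 1, total))
    out = np.clip(out, -100.0, 100.0)  # guard float overshoot at the bounds
    return float(out) if out.ndim == 0 else out


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    cols = [np.ones(n)]
    if covariates is not None and covariates.size:
        cols.append(covariates)
    return np.column_stack(cols)


def residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """OLS residuals of y on [intercept, covariates] (intercept kept out
    of the residual, i.e. residuals are centered)."""
    y = np.asarray(y, dtype=float)
    X = _design(len(y), covariates)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _ols_rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.sum((y - X @ beta) ** 2))


def _prep_covariates(wide: pd.DataFrame, covariates) -> np.ndarray | None:
    if not covariates:
        return None
    cols = []
    for c in covariates:
        col = wide[c]
        if col.dtype == object or str(col.dtype) == "category":
            vals = pd.factorize(col)[0].astype(float)  # e.g. sex M/F -> 0/1
        else:
            vals = col.to_numpy(dtype=float)
        cols.append(vals)
    X = np.column_stack(cols)
    if np.isnan(X).any():
        raise ValueError("missing covariate values")
    return X


def _to_wide(table: pd.DataFrame, covariates) -> pd.DataFrame:
    """Long metric table -> one row per subject with L, R, group, covs."""
    required = {"subject_id", "group", "hemisphere", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"metric table missing columns: {sorted(missing)}")
    keep = ["subject_id", "group"] + [c for c in covariates or []]
    meta = table[keep].drop_duplicates("subject_id").set_index("subject_id")
    piv = table.pivot_table(
        index="subject_id", columns="hemisphere", values="value", aggfunc="first"
    )
    if not {"L", "R"} <= set(piv.columns) or piv[["L", "R"]].isna().any().any():
        raise ValueError("each subject needs exactly one L and one R value")
    wide = piv[["L", "R"]].join(meta)
    return wide.reset_index()


def mixed_anova(table: pd.DataFrame, covariates=()) -> AnovaResult:
    """Repeated-measures ANOVA: group (between) x hemisphere (within).

    ``table`` is long format with columns subject_id, group, hemisphere
    ('L'/'R'), value, plus any covariate columns. Covariates enter the
    between-subject stratum only, so with N subjects and c covariates
    the group test has df (1, N - 2 - c); the hemisphere and interaction
    tests have df (1, N - 2).
    """
    wide = _to_wide(table, covariates)
    groups = wide["group"].to_numpy()
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(levels)}")
    g = (groups == levels[1]).astype(float)
    n1, n2 = int(np.sum(g == 0)), int(np.sum(g == 1))
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 subjects per group")
    N = len(wide)
    cov = _prep_covariates(wide, covariates)
    c = 0 if cov is None else cov.shape[1]

    m = (wide["L"].to_numpy() + wide["R"].to_numpy()) / 2.0
    d = wide["R"].to_numpy() - wide["L"].to_numpy()

    # between stratum: ANCOVA partial F for group on subject means
    X_full = np.column_stack([_design(N, cov), g])
    X_red = _design(N, cov)
    rss_f = _ols_rss(m, X_full)
    rss_r = _ols_rss(m, X_red)
    df_b = N - 2 - c
    num = max(rss_r - rss_f, 0.0)
    if rss_f > 0:
        F_group = num / (rss_f / df_b)
    else:  # perfectly fitted means: no residual variance
        F_group = np.inf if num > 0 else 0.0
    p_group = float(sps.f.sf(F_group, 1, df_b))

    # within stratum on contrasts d = R - L
    df_w = N - 2
    d1, d2 = d[g == 0], d[g == 1]
    s2 = (np.sum((d1 - d1.mean()) ** 2) + np.sum((d2 - d2.mean()) ** 2)) / df_w
    # hemisphere main effect: unweighted mean of the two group means of d
    mu = (d1.mean() + d2.mean()) / 2.0
    var_mu = s2 / 4.0 * (1.0 / n1 + 1.0 / n2)
    F_hemi = mu**2 / var_mu if var_mu > 0 else (np.inf if mu != 0 else 0.0)
    p_hemi = float(sps.f.sf(F_hemi, 1, df_w))
    # interaction: group difference in d
    diff = d2.mean() - d1.mean()
    var_diff = s2 * (1.0 / n1 + 1.0 / n2)
    F_int = diff**2 / var_diff if var_diff > 0 else (np.inf if diff != 0 else 0.0)
    p_int = float(sps.f.sf(F_int, 1, df_w))

    return AnovaResult(
        float(F_group), (1, df_b), p_group,
        float(F_hemi), (1, df_w), p_hemi,
        float(F_int), (1, df_w), p_int,
    )


def _adjusted_t_ind(x: np.ndarray, y: np.ndarray, c: int):
    """Independent-samples t with df reduced by c residualized covariates."""
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2 - c
    s2 = (np.sum((x - x.mean()) ** 2) + np.sum((y - y.mean()) ** 2)) / df
    se = np.sqrt(s2 * (1 / n1 + 1 / n2))
    t = (x.mean() - y.mean()) / se if se > 0 else 0.0
    return float(t), df, float(2 * sps.t.sf(abs(t), df))


def posthoc_tests(table: pd.DataFrame, covariates=()) -> pd.DataFrame:
    """Paired t-tests (L vs R within each group) and independent t-tests
    (NC vs BD within each hemisphere), covariates residualized out.

    Intended to be run only for metrics whose omnibus ANOVA reached
    p < 0.05 — the gating lives in the pipeline, not here.
    """
    wide = _to_wide(table, covariates)
    cov = _prep_covariates(wide, covariates)
    c = 0 if cov is None else cov.shape[1]
    groups = wide["group"].to_numpy()
    rows = []
    for grp in pd.unique(groups):
        sel = groups == grp
        if sel.sum() < 2:
            raise ValueError(f"group {grp} has fewer than 2 subjects")
        d = wide.loc[sel, "R"].to_numpy() - wide.loc[sel, "L"].to_numpy()
        if cov is not None:
            d = residualize(d, cov[sel]) + d.mean()  # keep the mean, drop cov trend
        n = len(d)
        df = n - 1 - c
        if df < 1:
            warnings.warn(
                f"group {grp}: no residual df after covariate adjustment",
                stacklevel=2,
            )
            rows.append({"comparison": "hemisphere", "stratum": grp,
                         "t": np.nan, "df": df, "p": np.nan})
            continue
        s2 = np.sum((d - d.mean()) ** 2) / df
        se = np.sqrt(s2 / n)
        t = d.mean() / se if se > 0 else 0.0
        rows.append(
            {"comparison": "hemisphere", "stratum": grp,
             "t": float(t), "df": df, "p": float(2 * sps.t.sf(abs(t), df))}
        )
    levels = list(pd.unique(groups))
    for hemi in ("L", "R"):
        v = wide[hemi].to_numpy().astype(float)
        if cov is not None:
            v = residualize(v, cov) + v.mean()
        x = v[groups == levels[0]]
        y = v[groups == levels[1]]
        t, df, p = _adjusted_t_ind(x, y, c)
        rows.append({"comparison": "group", "stratum": hemi, "t": t, "df": df, "p": p})
    return pd.DataFrame(rows)


def asymmetry_tests(records: pd.DataFrame, covariates=()) -> pd.DataFrame:
    """Per-group one-sample t of AS against 0 (df = n - 1) and the
    between-group independent t on AS (covariates residualized).

    ``records`` needs columns subject_id, group, as_value plus covariate
    columns; NaN AS values are dropped per test.
    """
    req = {"subject_id", "group", "as_value"}
    if not req <= set(records.columns):
        raise ValueError(f"records missing columns: {sorted(req - set(records.columns))}")
    rec = records.dropna(subset=["as_value"])
    if rec.empty:
        warnings.warn("all AS values missing; skipping tests", stacklevel=2)
        return pd.DataFrame(columns=["comparison", "stratum", "t", "df", "p", "mean_as"])
    rows = []
    for grp, sub in rec.groupby("group", sort=False):
        a = sub["as_value"].to_numpy(dtype=float)
        df = len(a) - 1
        se = a.std(ddof=1) / np.sqrt(len(a)) if len(a) > 1 else 0.0
        t = a.mean() / se if se > 0 else 0.0
        rows.append(
            {"comparison": "one_sample", "stratum": grp,
             "t": float(t), "df": df,
             "p": float(2 * sps.t.sf(abs(t), df)), "mean_as": float(a.mean())}
        )
    levels = list(pd.unique(rec["group"]))
    if len(levels) == 2:
        cov = _prep_covariates(rec, covariates) if covariates else None
        c = 0 if cov is None else cov.shape[1]
        v = rec["as_value"].to_numpy(dtype=float)
        if cov is not None:
            v = residualize(v, cov) + v.mean()
        gsel = rec["group"].to_numpy()
        t, df, p = _adjusted_t_ind(v[gsel == levels[0]], v[gsel == levels[1]], c)
        rows.append(
            {"comparison": "group_difference", "stratum": f"{levels[0]}-{levels[1]}",
             "t": t, "df": df, "p": p, "mean_as": np.nan}
        )
    return pd.DataFrame(rows)


def bonferroni(p_values, m: int):
    """p_adj = min(1, m * p); never decreases a p-value."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.minimum(1.0, m * p)
    return float(out) if out.ndim == 0 else out


def partial_spearman(x, y, covariates=None):
    """Covariate-adjusted Spearman correlation.

    Rank-transforms x and y, residualizes both ranks on the covariates,
    and returns the Pearson correlation of the residuals with a
    two-sided p from the t distribution on n - 2 - c df. With no (or
    constant) covariates this reduces to the plain Spearman rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(x):
            cov = cov.T
        ok &= ~np.isnan(cov).any(axis=1)
        cov = cov[ok]
    else:
        cov = None
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input; correlation undefined", stacklevel=2)
        return np.nan, np.nan
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    c = 0
    if cov is not None:
        c = cov.shape[1]
        rx = residualize(rx, cov)
        ry = residualize(ry, cov)
    else:
        rx = rx - rx.mean()
        ry = ry - ry.mean()
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom == 0:
        warnings.warn("residual ranks constant; correlation undefined", stacklevel=2)
        return np.nan, np.nan
    rho = float(np.sum(rx * ry) / denom)
    df = n - 2 - c
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1 - rho**2))
    return rho, float(2 * sps.t.sf(abs(t), df))


def edgewise_census(
    left_edges: np.ndarray,
    right_edges: np.ndarray,
    groups: np.ndarray,
    classification: EdgeClassification,
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-class census of edges with significant group differences,
    hemisphere differences, and group differences in edge asymmetry.

    Parameters
    ----------
    left_edges, right_edges : (n_subjects, n_edges) arrays
        FA of each classified edge in the left / homologue-aligned right
        hemisphere; absent edges are true zeros, not missing data.
    groups : (n_subjects,) array of group labels (two levels).
    classification : edge labels aligned with the edge axis.
    alpha : per-edge significance level (uncorrected by default, in
        keeping with the exploratory framing of the census).
    correction : None (default) or "fdr_bh" for Benjamini-Hochberg
        adjustment of each effect's p-values across edges.

    Returns a table with, per edge class, the number of edges showing
    (a) group differences, (b) L/R hemisphere differences, (c) group
    differences in the edge asymmetry score, plus totals and the
    proportion 100 * observed / total per class.
    """
    left_edges = np.asarray(left_edges, dtype=float)
    right_edges = np.asarray(right_edges, dtype=float)
    if left_edges.shape != right_edges.shape:
        raise ValueError("left/right edge arrays misaligned")
    if left_edges.shape[1] != classification.n_edges:
        raise ValueError("edge axis does not match classification")
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    ga, gb = groups == levels[0], groups == levels[1]

    mean_lr = (left_edges + right_edges) / 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # (a) group difference on hemisphere-mean edge FA
        p_group = sps.ttest_ind(mean_lr[ga], mean_lr[gb], axis=0).pvalue
        # (b) hemisphere difference, paired over subjects
        p_hemi = sps.ttest_rel(left_edges, right_edges, axis=0).pvalue
        # (c) group difference in per-edge asymmetry score
        tot = left_edges + right_edges
        with np.errstate(invalid="ignore", divide="ignore"):
            as_edge = np.where(tot > 0, 100.0 * (right_edges - left_edges) / np.where(tot > 0, tot, 1), np.nan)
        p_as = sps.ttest_ind(
            as_edge[ga], as_edge[gb], axis=0, nan_policy="omit"
        ).pvalue
    p_group = np.nan_to_num(np.asarray(p_group, dtype=float), nan=1.0)
    p_hemi = np.nan_to_num(np.asarray(p_hemi, dtype=float), nan=1.0)
    p_as = np.nan_to_num(np.asarray(p_as, dtype=float), nan=1.0)
    if correction == "fdr_bh":
        p_group = sps.false_discovery_control(p_group, method="bh")
        p_hemi = sps.false_discovery_control(p_hemi, method="bh")
        p_as = sps.false_discovery_control(p_as, method="bh")
    elif correction is not None:
        raise ValueError(f"unknown correction: {correction!r}")

    rows = []
    for cls_label in EDGE_CLASSES:
        m = classification.mask(cls_label)
        total = int(np.sum(m))
        for effect, pvals in (
            ("group", p_group), ("hemisphere", p_hemi), ("asymmetry_group", p_as)
        ):
            sig = int(np.sum(pvals[m] < alpha))
            rows.append(
                {"effect": effect, "class": cls_label, "n_significant": sig,
                 "n_total": total,
                 "proportion_pct": 100.0 * sig / total if total else 0.0}
            )
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """The conventional star coding: * <0.05, ** <0.01, *** <0.001."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
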