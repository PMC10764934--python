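"""Covariate-adjusted group inference, symptom correlations, and FDR control.

Group contrasts on dynamic metrics are two-tailed tests of the group
coefficient in an OLS model ``value ~ group + age + sex + education + site +
mean_fd`` (sex and site dummy-coded against the alphabetically first level),
the standard regression formulation of "t-test after controlling for
covariates". Symptom correlations are partial Pearson correlations between
metric and HAMD after residualizing both on the same covariates. Multiple
comparisons are corrected with Benjamini-Hochberg step-up FDR within metric
families (per-CAP metrics within the K CAPs; path metrics within the K*K
paths), mirroring family-wise correction per dynamic property.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ["age", "sex", "education", "site", "mean_fd"]
CATEGORICAL_COVARIATES = {"sex", "site"}


@dataclass
class AdjustedTestResult:
    t: float
    df: int
    p: float
    adjusted_means: dict[str, float]  # group level -> covariate-adjusted mean
    n: int
    group_levels: tuple[str, str]


def build_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code categorical covariates (reference = first level
    alphabetically) and passthrough numeric ones."""
    cols = []
    for name in covariates.columns:
        col = covariates[name]
        if name in CATEGORICAL_COVARIATES or col.dtype == object:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                cols.append(
                    pd.Series((col.astype(str) == lev).astype(float), name=f"{name}[{lev}]")
                )
        else:
            cols.append(col.astype(float))
    if not cols:
        return pd.DataFrame(index=covariates.index)
    return pd.concat(cols, axis=1)


def adjusted_group_test(
    values: np.ndarray | pd.Series,
    group: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
) -> AdjustedTestResult:
    """Two-tailed test of a binary group difference, adjusted for covariates.

    With no covariates this reduces exactly to the classical pooled-variance
    two-sample t test. Rows with missing values are dropped listwise (logged).
    """
    values = pd.Series(np.asarray(values, dtype=float)).reset_index(drop=True)
    group = pd.Series(group).reset_index(drop=True).astype(str)
    if covariates is not None:
        covariates = covariates.reset_index(drop=True)
        design = build_design(covariates)
        keep = values.notna() & design.notna().all(axis=1)
    else:
        design = pd.DataFrame(index=values.index)
        keep = values.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("adjusted_group_test: dropped %d row(s) with missing data", n_dropped)
    values, group, design = values[keep], group[keep], design.loc[keep]

    levels = sorted(group.unique())
    if len(levels) != 2:
        raise ValueError(f"group must be binary, got levels {levels}")
    g = (group == levels[1]).astype(float)
    n = len(values)
    if n < design.shape[1] + 3:
        raise ValueError(f"too few complete observations (n={n}) for the design")

    x = np.column_stack([np.ones(n), g.to_numpy(), design.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            "rank-deficient design; check collinearity among columns "
            f"{['intercept', 'group', *design.columns]}"
        )
    fit = sm.OLS(values.to_numpy(), x).fit()
    t, p = float(fit.tvalues[1]), float(fit.pvalues[1])
    df = int(fit.df_resid)

    # adjusted means: predictions at the covariate means for each group
    xbar = x.mean(axis=0)
    x0, x1 = xbar.copy(), xbar.copy()
    x0[1], x1[1] = 0.0, 1.0
    beta = fit.params
    adjusted = {levels[0]: float(x0 @ beta), levels[1]: float(x1 @ beta)}
    return AdjustedTestResult(
        t=t, df=df, p=p, adjusted_means=adjusted, n=n, group_levels=tuple(levels)
    )


def partial_pearson(
    x: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
) -> tuple[float, float, int]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on [intercept, covariates] by OLS and the
    residuals correlated; p comes from t = r sqrt((n - 2 - c) / (1 - r^2))
    with c the number of covariate design columns.
    """
    x = pd.Series(np.asarray(x, dtype=float)).reset_index(drop=True)
    y = pd.Series(np.asarray(y, dtype=float)).reset_index(drop=True)
    if covariates is not None:
        design = build_design(covariates.reset_index(drop=True))
        keep = x.notna() & y.notna() & design.notna().all(axis=1)
        design = design.loc[keep]
    else:
        design = None
        keep = x.notna() & y.notna()
    x, y = x[keep].to_numpy(), y[keep].to_numpy()
    n = x.size
    c = 0 if design is None else design.shape[1]
    if n < c + 4:
        raise ValueError(f"too few complete observations (n={n}) for {c} covariates")

    if design is None:
        rx, ry = x - x.mean(), y - y.mean()
    else:
        z = np.column_stack([np.ones(n), design.to_numpy(dtype=float)])
        proj = z @ np.linalg.lstsq(z, np.column_stack([x, y]), rcond=None)[0]
        rx, ry = x - proj[:, 0], y - proj[:, 1]
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("constant residuals; correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - c
    if abs(r) >= 1.0:
        return r, 0.0, n
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p), n


def fdr_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q values).

    q_(i) = min_{j >= i} (p_(j) * m / j), capped at 1; NaN entries are
    passed through and excluded from m.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    qv = np.empty(m)
    qv[order] = q
    out[mask] = qv
    return out


def chisq_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square test (df=1, no continuity correction) on a 2x2
    count table."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in 2x2 table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Mann-Whitney U with the two-sided tie-corrected normal approximation.

    Returns (U, z, p) where U counts pairs (x_i, y_j) with x_i > y_j plus
    half the ties, and z is the standardized U (0 for identical samples).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    u = float(stats.mannwhitneyu(x, y, alternative="two-sided").statistic)
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return u, 0.0, 1.0
    z = (u - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return u, float(z), min(float(p), 1.0)


def _metric_families(long_df: pd.DataFrame) -> pd.Series:
    """Family id per row: vector metrics form per-CAP families of size K;
    transition/persistence and trajectory entropy form K*K path families."""
    fam = long_df["metric"].map(
        {
            "dwell": "dwell",
            "total_dwell": "total_dwell",
            "occurrence": "occurrence",
            "transition": "paths_transition",
            "persistence": "paths_transition",
            "traj_entropy": "paths_entropy",
        }
    )
    return fam


def dynamics_stat_table(
    long_df: pd.DataFrame,
    manifest: pd.DataFrame,
    contrast: tuple[str, str],
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Group StatTable over all dynamic metrics with per-family BH-FDR.

    ``long_df`` is the long-format metrics table (see
    :func:`capdyn.dynamics.profiles_to_long`); ``contrast`` names the two
    group levels to compare (reference first). One row per metric/path with
    group means +/- SEM, t, df, raw p, q, family id and n.
    """
    if covariates is None:
        covariates = DEFAULT_COVARIATES
    man = manifest.set_index("subject_id")
    sel = man["group"].isin(contrast)
    man = man[sel]
    df = long_df[long_df["subject_id"].isin(man.index)]

    rows = []
    fam_ids = _metric_families(df)
    for (metric, cf, ct), grp in df.groupby(
        ["metric", "cap_from", "cap_to"], dropna=False, sort=True
    ):
        merged = grp.set_index("subject_id").join(man, how="inner")
        vals = merged["value"]
        groups = merged["group"]
        ok = vals.notna()
        if ok.sum() < len(covariates) + 6 or groups[ok].nunique() < 2:
            continue
        cov = merged.loc[:, [c for c in covariates if c in merged.columns]]
        try:
            res = adjusted_group_test(vals, groups, cov if len(covariates) else None)
        except ValueError:
            continue
        fam = fam_ids.loc[grp.index].iloc[0]
        stats_by_group = {}
        for g_level in contrast:
            gv = vals[ok][groups[ok] == g_level]
            stats_by_group[g_level] = (gv.mean(), gv.sem())
        rows.append(
            {
                "metric": metric,
                "cap_from": cf,
                "cap_to": ct,
                "family": fam,
                "mean_a": stats_by_group[contrast[0]][0],
                "sem_a": stats_by_group[contrast[0]][1],
                "mean_b": stats_by_group[contrast[1]][0],
                "sem_b": stats_by_group[contrast[1]][1],
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "n": res.n,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q"] = np.nan
    for fam, idx in table.groupby("family").groups.items():
        table.loc[idx, "q"] = fdr_bh(table.loc[idx, "p"].to_numpy())
    return table


def symptom_correlation_table(
    long_df: pd.DataFrame,
    manifest: pd.DataFrame,
    patient_group: str,
    score_column: str = "hamd",
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Partial correlations between each dynamic metric and a symptom score
    within the patient group, BH-FDR corrected within families."""
    if covariates is None:
        covariates = DEFAULT_COVARIATES
    man = manifest.set_index("subject_id")
    man = man[man["group"] == patient_group]
    df = long_df[long_df["subject_id"].isin(man.index)]
    rows = []
    fam_ids = _metric_families(df)
    for (metric, cf, ct), grp in df.groupby(
        ["metric", "cap_from", "cap_to"], dropna=False, sort=True
    ):
        merged = grp.set_index("subject_id").join(man, how="inner")
        ok = merged["value"].notna() & merged[score_column].notna()
        if ok.sum() < len(covariates) + 6:
            continue
        cov = merged.loc[ok, [c for c in covariates if c in merged.columns]]
        try:
            r, p, n = partial_pearson(
                merged.loc[ok, "value"], merged.loc[ok, score_column], cov
            )
        except ValueError:
            continue
        rows.append(
            {
                "metric": metric,
                "cap_from": cf,
                "cap_to": ct,
                "family": fam_ids.loc[grp.index].iloc[0],
                "r": r,
                "p": p,
                "n": n,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table["q"] = np.nan
    for fam, idx in table.groupby("family").groups.items():
        table.loc[idx, "q"] = fdr_bh(table.loc[idx, "p"].to_numpy())
    return table
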