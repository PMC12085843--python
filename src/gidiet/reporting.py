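"""Descriptive tables and small summary helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import KCAL_TO_KJ


def kcal_to_kj(kcal):
    """Energy unit conversion for reporting (1 kcal = 4.184 kJ)."""
    return np.asarray(kcal, dtype=float) * KCAL_TO_KJ


def incidence_proportion(n_cases: int, n_total: int, decimals: int = 2) -> float:
    """Percentage of the analytic sample with an incident event."""
    if n_total <= 0 or n_cases < 0 or n_cases > n_total:
        raise ValueError("need 0 <= n_cases <= n_total with n_total > 0")
    return round(100.0 * n_cases / n_total, decimals)


def baseline_table(
    cohort: pd.DataFrame,
    by: str = "digm_group",
    continuous: tuple[str, ...] = ("age", "bmi", "total_energy_kcal", "townsend"),
    categorical: tuple[str, ...] = (
        "sex",
        "income",
        "education",
        "smoking",
        "alcohol",
        "family_history",
        "physical_activity",
    ),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptive characteristics by exposure group.

    Returns a long-format table (one row per variable/level/group with n,
    mean, sd or count, percent) and a per-variable p-value table
    (Kruskal-Wallis across groups for continuous variables, chi-square on
    the contingency table for categorical ones). Empty groups yield zero
    counts and a warning-free column.
    """
    groups = (
        list(cohort[by].cat.categories)
        if isinstance(cohort[by].dtype, pd.CategoricalDtype)
        else sorted(cohort[by].dropna().unique())
    )
    col = cohort[by].astype(str)
    rows, pvals = [], []

    for var in continuous:
        if var not in cohort.columns:
            continue
        samples = []
        for g in list(map(str, groups)) + ["total"]:
            sub = cohort[var] if g == "total" else cohort.loc[col == g, var]
            rows.append(
                {
                    "variable": var,
                    "level": "",
                    "group": g,
                    "n": int(sub.notna().sum()),
                    "mean": float(sub.mean()) if len(sub) else np.nan,
                    "sd": float(sub.std(ddof=1)) if len(sub) > 1 else np.nan,
                    "count": np.nan,
                    "percent": np.nan,
                }
            )
            if g != "total" and sub.notna().sum() > 0:
                samples.append(sub.dropna().to_numpy())
        if len(samples) >= 2 and all(len(np.unique(np.concatenate(samples))) > 1 for _ in [0]):
            try:
                p = float(stats.kruskal(*samples).pvalue)
            except ValueError:  # all values identical
                p = 1.0
        else:
            p = np.nan
        pvals.append({"variable": var, "test": "kruskal", "p": p})

    for var in categorical:
        if var not in cohort.columns:
            continue
        levels = sorted(cohort[var].dropna().astype(str).unique())
        table = np.zeros((len(levels), len(groups)))
        for j, g in enumerate(map(str, groups)):
            sub = cohort.loc[col == g, var].astype(str)
            denom = len(sub)
            for i, lev in enumerate(levels):
                cnt = int((sub == lev).sum())
                table[i, j] = cnt
                rows.append(
                    {
                        "variable": var,
                        "level": lev,
                        "group": g,
                        "n": denom,
                        "mean": np.nan,
                        "sd": np.nan,
                        "count": cnt,
                        "percent": 100.0 * cnt / denom if denom else 0.0,
                    }
                )
        for i, lev in enumerate(levels):
            cnt = int((cohort[var].astype(str) == lev).sum())
            rows.append(
                {
                    "variable": var,
                    "level": lev,
                    "group": "total",
                    "n": len(cohort),
                    "mean": np.nan,
                    "sd": np.nan,
                    "count": cnt,
                    "percent": 100.0 * cnt / len(cohort) if len(cohort) else 0.0,
                }
            )
        keep = table.sum(axis=1) > 0
        tbl = table[keep][:, table[keep].sum(axis=0) > 0]
        if tbl.shape[0] > 1 and tbl.shape[1] > 1:
            p = float(stats.chi2_contingency(tbl).pvalue)
        else:
            p = np.nan
        pvals.append({"variable": var, "test": "chi2", "p": p})

    return pd.DataFrame(rows), pd.DataFrame(pvals)


def format_baseline(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long table into a 'mean ± SD' / 'n (%)' display table."""
    def fmt(r):
        if not np.isnan(r["mean"]):
            return f"{r['mean']:.2f} ± {r['sd']:.2f}"
        return f"{int(r['count'])} ({r['percent']:.2f})"

    work = table.copy()
    work["cell"] = work.apply(fmt, axis=1)
    return work.pivot_table(
        index=["variable", "level"],
        columns="group",
        values="cell",
        aggfunc="first",
    )


def cox_summary_table(fits: dict[str, "object"]) -> pd.DataFrame:
    """Tidy one-row-per-term table over named Cox fits (forest-plot ready)."""
    frames = []
    for name, fit in fits.items():
        s = fit.summary.copy()
        s.insert(0, "model", name)
        s.insert(1, "term", s.index)
        s["n"] = fit.n
        s["n_events"] = fit.n_events
        frames.append(s.reset_index(drop=True))
    return pd.concat(frames, ignore_index=True)
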