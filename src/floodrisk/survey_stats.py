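"""Descriptive summaries and scale reliability for the survey data."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SummaryTable", "summarize_demographics", "cronbach_alpha", "drop_incomplete"]


@dataclass
class SummaryTable:
    """Per-variable category counts/percentages and numeric summaries.

    Categorical rows carry (variable, category, count, percentage); numeric
    rows carry either mean/SD (near-normal variables) or median/min/max.
    """

    rows: pd.DataFrame
    n: int

    def to_csv(self, path_or_buf) -> None:
        self.rows.to_csv(path_or_buf, index=False)

    def to_text(self) -> str:
        lines = [f"Respondents: n = {self.n}", ""]
        for var, grp in self.rows.groupby("variable", sort=False):
            lines.append(var)
            for _, r in grp.iterrows():
                if pd.notna(r.get("count")):
                    lines.append(f"  {r['category']:<32} {int(r['count']):>6} {r['percentage']:>6.1f}%")
                elif pd.notna(r.get("mean")):
                    lines.append(f"  mean = {r['mean']:.2f}, SD = {r['sd']:.2f}")
                else:
                    lines.append(
                        f"  median = {r['median']:g}, min = {r['min']:g}, max = {r['max']:g}"
                    )
            lines.append("")
        return "\n".join(lines)


def drop_incomplete(df: pd.DataFrame) -> pd.DataFrame:
    """Exclude respondents with any missing entry (listwise deletion; returned
    questionnaires are screened for missing data before analysis)."""
    return df.dropna(axis=0, how="any")


def summarize_demographics(
    demographics: pd.DataFrame, *, skew_threshold: float = 1.0
) -> SummaryTable:
    """Frequency/percentage table for categorical variables plus numeric
    summaries: mean/SD when |skewness| < ``skew_threshold`` (the normality
    screen), otherwise median/min/max.  Percentages are rounded to 1 decimal.
    """
    if demographics is None or len(demographics) == 0:
        raise ValueError("demographic table is empty")
    demographics = drop_incomplete(demographics)
    n = len(demographics)
    rows: list[dict] = []
    for col in demographics.columns:
        series = demographics[col]
        if pd.api.types.is_numeric_dtype(series):
            vals = series.to_numpy(dtype=float)
            skew = stats.skew(vals) if np.ptp(vals) > 0 else 0.0
            if abs(skew) < skew_threshold:
                rows.append(
                    {"variable": col, "mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1)) if n > 1 else 0.0}
                )
            else:
                rows.append(
                    {
                        "variable": col,
                        "median": float(np.median(vals)),
                        "min": float(np.min(vals)),
                        "max": float(np.max(vals)),
                    }
                )
        elif series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            counts = series.value_counts()
            for cat, cnt in counts.items():
                rows.append(
                    {
                        "variable": col,
                        "category": str(cat),
                        "count": int(cnt),
                        "percentage": round(100.0 * cnt / n, 1),
                    }
                )
        else:
            raise ValueError(f"cannot summarize variable '{col}' of dtype {series.dtype}")
    return SummaryTable(rows=pd.DataFrame(rows), n=n)


def cronbach_alpha(items: pd.DataFrame | np.ndarray) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / total variance).

    Requires k >= 2 complete items.  Undefined (raises) when the total score
    has zero variance.
    """
    arr = np.asarray(items, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("alpha needs a respondent x items matrix with k >= 2")
    if np.isnan(arr).any():
        raise ValueError("alpha requires complete data; drop incomplete rows first")
    k = arr.shape[1]
    item_vars = arr.var(axis=0, ddof=1)
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))
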