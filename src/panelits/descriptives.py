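"""Descriptive summaries: pre/post medians, IQRs and crude relative change,
per province and for the national (province-summed) daily series."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd

from .design import STRATA
from .errors import ValidationError

__all__ = [
    "PRE_END",
    "POST_START",
    "POST_END",
    "split_periods",
    "median_iqr",
    "relative_change",
    "descriptives_table",
    "render_markdown",
]

PRE_END = date(2019, 12, 30)
POST_START = date(2019, 12, 31)
POST_END = date(2021, 3, 15)


def split_periods(
    panel: pd.DataFrame,
    cut_pre_end: date = PRE_END,
    cut_post_start: date = POST_START,
    post_end: date = POST_END,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a panel at the outbreak boundary (both cut days inclusive in
    their respective periods)."""
    dates = pd.to_datetime(panel["date"])
    pre = panel[dates <= pd.Timestamp(cut_pre_end)]
    post = panel[(dates >= pd.Timestamp(cut_post_start)) & (dates <= pd.Timestamp(post_end))]
    return pre.reset_index(drop=True), post.reset_index(drop=True)


def median_iqr(values) -> tuple[float, float]:
    """Median and Q3-Q1 with linear-interpolation quantiles."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("median_iqr of empty collection")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q3 - q1)


def relative_change(pre_median: float, post_median: float) -> int:
    """Crude percent change of the median, rounded half away from zero."""
    if not pre_median > 0:
        raise ValidationError(f"pre-period median must be > 0, got {pre_median}")
    # decimal arithmetic so e.g. 203/200 yields exactly 1.5% (binary floats
    # round it just below and would truncate the half-away tie)
    from decimal import ROUND_HALF_UP, Decimal

    pct = 100 * (Decimal(repr(float(post_median))) / Decimal(repr(float(pre_median))) - 1)
    return int(pct.to_integral_value(rounding=ROUND_HALF_UP))


def _summarize(pre_vals, post_vals) -> dict:
    pre_med, pre_iqr = median_iqr(pre_vals)
    post_med, post_iqr = median_iqr(post_vals)
    return {
        "pre_median": pre_med,
        "pre_iqr": pre_iqr,
        "post_median": post_med,
        "post_iqr": post_iqr,
        "relative_change_pct": relative_change(pre_med, post_med),
    }


def descriptives_table(panel: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """One row per province (grouped low/middle/high, in metadata order)
    plus a ``national`` row computed on the province-summed daily index."""
    meta_idx = meta.set_index("province") if "province" in meta.columns else meta
    pre, post = split_periods(panel)
    if len(pre) == 0 or len(post) == 0:
        raise ValidationError("both pre and post periods must be non-empty")

    rows = []
    order = {cat: i for i, cat in enumerate(STRATA)}
    provinces = [p for p in meta_idx.index if p in set(panel["province"])]
    provinces.sort(key=lambda p: (order.get(meta_idx.loc[p, "hdi_category"], 99),))
    for prov in provinces:
        row = {"province": prov, "hdi_category": meta_idx.loc[prov, "hdi_category"]}
        row.update(
            _summarize(
                pre.loc[pre["province"] == prov, "index"],
                post.loc[post["province"] == prov, "index"],
            )
        )
        rows.append(row)

    nat_pre = pre.groupby("date")["index"].sum()
    nat_post = post.groupby("date")["index"].sum()
    nat = {"province": "national", "hdi_category": ""}
    nat.update(_summarize(nat_pre, nat_post))
    rows.append(nat)
    return pd.DataFrame(rows)


def render_markdown(table: pd.DataFrame) -> str:
    lines = [
        "| province | pre median | pre IQR | post median | post IQR | relative change (%) |",
        "|---|---|---|---|---|---|",
    ]
    current = None
    for _, r in table.iterrows():
        if r["hdi_category"] and r["hdi_category"] != current:
            current = r["hdi_category"]
            lines.append(f"| **{current.capitalize()} HDI** | | | | | |")
        lines.append(
            f"| {r['province']} | {r['pre_median']:.0f} | {r['pre_iqr']:.0f} | "
            f"{r['post_median']:.0f} | {r['post_iqr']:.0f} | {r['relative_change_pct']} |"
        )
    return "\n".join(lines)
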