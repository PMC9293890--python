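"""Reported quantities from a fitted model: level-change RRs, time-rescaled
slope RRs, ratio-of-RR contrasts between strata (or per SD of a continuous
covariate), Wald intervals/p-values and Holm-Bonferroni decisions.

Effect families are addressed by identifier: ``trend`` for the pre-exposure
secular trend, ``<label>:step`` for an exposure's level change and
``<label>:slope`` for its post-peak slope change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import STRATA, ExposureSchedule
from .errors import ValidationError
from .lmm import FitResult

__all__ = [
    "EffectEstimate",
    "ContrastResult",
    "HolmResult",
    "Z975",
    "TIMESCALE_DAYS",
    "level_change_rr",
    "slope_rr",
    "ratio_of_rr",
    "per_sd_contrast",
    "holm_bonferroni",
    "effects_table",
    "render_markdown",
    "round_half_up",
]

#: 97.5% normal quantile used for all intervals
Z975 = 1.959964

TIMESCALE_DAYS = {
    "immediate": 1.0,
    "per_day": 1.0,
    "per_week": 7.0,
    "per_month": 30.0,
    "per_year": 365.0,
}


@dataclass(frozen=True)
class EffectEstimate:
    label: str
    stratum: str
    timescale: str
    rr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class ContrastResult:
    label: str
    stratum_num: str
    stratum_ref: str
    ratio_rr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class HolmResult:
    order: tuple[str, ...]  # test ids sorted by ascending p
    p_sorted: tuple[float, ...]
    thresholds: tuple[float, ...]  # alpha / (m - rank + 1), rank starting at 1
    reject: Mapping[str, bool]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal rounding with ties away from zero, applied to the shortest
    decimal representation of ``x`` (so 1.335 stored as 1.33499...96 still
    rounds to 1.34)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _wald_p(est: float, se: float) -> float:
    if se == 0.0:
        return 1.0 if est == 0.0 else 0.0
    return float(2.0 * stats.norm.sf(abs(est) / se))


def _combo(fit: FitResult, weights: Mapping[str, float]) -> tuple[float, float]:
    """Estimate and SE of a linear combination of coefficients."""
    missing = [k for k in weights if k not in fit.beta.index]
    if missing:
        raise ValidationError(f"coefficient(s) not in fit: {missing}")
    names = list(weights)
    w = np.array([weights[k] for k in names])
    est = float(w @ fit.beta.loc[names].to_numpy())
    V = fit.cov_beta.loc[names, names].to_numpy()
    var = float(w @ V @ w)
    return est, math.sqrt(max(var, 0.0))


def _family_weights(fit: FitResult, family: str, stratum: str) -> dict[str, float]:
    """Coefficient weights selecting one effect family in one stratum."""
    if stratum not in STRATA:
        raise ValidationError(f"unknown stratum {stratum!r}")
    if family == "trend":
        w = {"trend": 1.0}
        if stratum != "low":
            w[f"trend:hdi[{stratum}]"] = 1.0
        return w
    return {f"{family}[{stratum}]": 1.0}


def _exp_interval(est: float, se: float, k: float = 1.0) -> tuple[float, float, float]:
    rr = math.exp(k * est)
    half = Z975 * abs(k) * se
    return rr, math.exp(k * est - half), math.exp(k * est + half)


def level_change_rr(fit: FitResult, exposure: str, stratum: str) -> EffectEstimate:
    """Immediate multiplicative level change at an exposure's step date."""
    est, se = _combo(fit, _family_weights(fit, f"{exposure}:step", stratum))
    rr, lo, hi = _exp_interval(est, se)
    return EffectEstimate(
        label=f"{exposure}:step",
        stratum=stratum,
        timescale="immediate",
        rr=rr,
        ci_low=lo,
        ci_high=hi,
        p=_wald_p(est, se),
    )


def slope_rr(
    fit: FitResult, segment: str, stratum: str, timescale: str = "per_week"
) -> EffectEstimate:
    """Multiplicative change per timescale unit for a slope family
    (``trend`` or ``<label>:slope``); daily coefficients are rescaled by the
    timescale's day multiplier (week 7, month 30, year 365)."""
    if timescale not in TIMESCALE_DAYS:
        raise ValidationError(
            f"unknown timescale {timescale!r}; choose from {sorted(TIMESCALE_DAYS)}"
        )
    family = segment if segment == "trend" or segment.endswith(":slope") else f"{segment}:slope"
    est, se = _combo(fit, _family_weights(fit, family, stratum))
    k = TIMESCALE_DAYS[timescale]
    rr, lo, hi = _exp_interval(est, se, k)
    return EffectEstimate(
        label=family,
        stratum=stratum,
        timescale=timescale,
        rr=rr,
        ci_low=lo,
        ci_high=hi,
        p=_wald_p(est, se),
    )


def ratio_of_rr(
    fit: FitResult,
    family: str,
    stratum_num: str,
    stratum_ref: str = "low",
    timescale: str | None = None,
) -> ContrastResult:
    """Ratio of two strata's RRs for one effect family.

    The point estimate is exp(k * (beta_num - beta_ref)); the SE of the
    difference uses the full coefficient covariance. ``timescale`` applies
    only to slope families (default ``per_week``; steps are immediate).
    """
    if stratum_num == stratum_ref:
        raise ValidationError("contrast requires two distinct strata")
    is_slope = family == "trend" or family.endswith(":slope")
    if timescale is None:
        if family == "trend":
            timescale = "per_year"
        else:
            timescale = "per_week" if is_slope else "immediate"
    k = TIMESCALE_DAYS[timescale] if is_slope else 1.0

    w = dict(_family_weights(fit, family, stratum_num))
    for name, weight in _family_weights(fit, family, stratum_ref).items():
        w[name] = w.get(name, 0.0) - weight
    w = {name: weight for name, weight in w.items() if weight != 0.0}
    est, se = _combo(fit, w)
    ratio, lo, hi = _exp_interval(est, se, k)
    return ContrastResult(
        label=family,
        stratum_num=stratum_num,
        stratum_ref=stratum_ref,
        ratio_rr=ratio,
        ci_low=lo,
        ci_high=hi,
        p=_wald_p(est, se),
    )


def per_sd_contrast(
    fit: FitResult, family: str, timescale: str = "immediate"
) -> ContrastResult:
    """Ratio of RRs between two provinces one standard deviation apart on the
    continuous covariate (fit must use a continuous hdi_mode, where the
    covariate is z-scored so 1 SD = 1 unit)."""
    if fit.hdi_mode == "categorical":
        raise ValidationError("per_sd_contrast requires a continuous-mode fit")
    name = "trend:z" if family == "trend" else f"{family}:z"
    est, se = _combo(fit, {name: 1.0})
    is_slope = family == "trend" or family.endswith(":slope")
    k = TIMESCALE_DAYS[timescale] if is_slope else 1.0
    ratio, lo, hi = _exp_interval(est, se, k)
    return ContrastResult(
        label=family,
        stratum_num="+1 SD",
        stratum_ref="reference",
        ratio_rr=ratio,
        ci_low=lo,
        ci_high=hi,
        p=_wald_p(est, se),
    )


def holm_bonferroni(
    tests: Sequence[tuple[str, float]], alpha: float = 0.05
) -> HolmResult:
    """Step-down Holm procedure: sort p ascending, reject while
    p(r) <= alpha / (m - r + 1); the first failure stops the procedure."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0,1), got {alpha}")
    for tid, p in tests:
        if not 0 <= p <= 1:
            raise ValidationError(f"p-value out of [0,1] for {tid!r}: {p}")
    m = len(tests)
    ordered = sorted(tests, key=lambda t: t[1])
    thresholds = tuple(alpha / (m - r + 1) for r in range(1, m + 1))
    reject: dict[str, bool] = {tid: False for tid, _ in tests}
    for (tid, p), thr in zip(ordered, thresholds):
        if p <= thr:
            reject[tid] = True
        else:
            break
    return HolmResult(
        order=tuple(tid for tid, _ in ordered),
        p_sorted=tuple(p for _, p in ordered),
        thresholds=thresholds,
        reject=reject,
    )


def effects_table(
    fit: FitResult,
    schedule: ExposureSchedule,
    strata: Sequence[str] = STRATA,
    timescale: str = "per_week",
    include_trend: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full report: one row per (effect family x stratum) plus ratio-of-RR
    contrasts against the first stratum, with Holm flags over the contrast
    family.

    With the default five-exposure schedule and ``include_trend=False`` this
    yields 27 effect rows and 18 contrast rows.
    """
    ref = strata[0]
    families = list(schedule.effect_families())
    if include_trend:
        families = ["trend"] + families

    def _present(family: str) -> bool:
        if family == "trend":
            return "trend" in fit.beta.index
        return all(f"{family}[{s}]" in fit.beta.index for s in strata)

    # families whose columns were identically zero on the fitted window are
    # absent from the fit; skip them rather than fail
    families = [f for f in families if _present(f)]

    rows: list[dict] = []
    contrast_tests: list[tuple[str, float]] = []
    for family in families:
        is_slope = family == "trend" or family.endswith(":slope")
        ts = ("per_year" if family == "trend" else timescale) if is_slope else "immediate"
        for stratum in strata:
            if is_slope:
                est = slope_rr(fit, family, stratum, ts)
            else:
                exposure = family.rsplit(":", 1)[0]
                est = level_change_rr(fit, exposure, stratum)
            rows.append(
                {
                    "label": family,
                    "row_type": "effect",
                    "stratum": stratum,
                    "timescale": est.timescale,
                    "rr": est.rr,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "p": est.p,
                }
            )
            if stratum != ref:
                con = ratio_of_rr(fit, family, stratum, ref, timescale=ts)
                test_id = f"{family}|{stratum}/{ref}"
                contrast_tests.append((test_id, con.p))
                rows.append(
                    {
                        "label": family,
                        "row_type": "contrast",
                        "stratum": f"{stratum}/{ref}",
                        "timescale": ts if is_slope else "immediate",
                        "rr": con.ratio_rr,
                        "ci_low": con.ci_low,
                        "ci_high": con.ci_high,
                        "p": con.p,
                    }
                )

    holm = holm_bonferroni(contrast_tests, alpha) if contrast_tests else None
    table = pd.DataFrame(rows)
    flags = []
    for _, row in table.iterrows():
        if row["row_type"] != "contrast" or holm is None:
            flags.append(np.nan)
        else:
            stratum = row["stratum"].split("/")[0]
            flags.append(bool(holm.reject[f"{row['label']}|{stratum}/{ref}"]))
    table["holm_significant"] = flags
    return table


def _fmt_p(p: float) -> str:
    return "<0.0001" if p < 1e-4 else f"{p:.4f}"


def render_markdown(table: pd.DataFrame) -> str:
    """Markdown rendering of an effects table, block per effect family."""
    lines = ["| effect | row | stratum | RR (95% CI) | p | Holm |", "|---|---|---|---|---|---|"]
    for _, r in table.iterrows():
        holm = "" if pd.isna(r["holm_significant"]) else ("yes" if r["holm_significant"] else "no")
        lines.append(
            f"| {r['label']} | {r['row_type']} | {r['stratum']} | "
            f"{r['rr']:.2f} ({r['ci_low']:.2f}, {r['ci_high']:.2f}) | "
            f"{_fmt_p(r['p'])} | {holm} |"
        )
    return "\n".join(lines)
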