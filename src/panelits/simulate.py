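"""Synthetic provincial daily search-index panels with known ground truth.

The generative model mirrors the analysis model: on the log scale,

    ln Index_it = x_it' beta + b0_i + b1_i * T_it + eps_it,

with (b0_i, b1_i) ~ N(0, G), eps an AR(1) process stationary at marginal
variance sigma2 (innovation variance sigma2 * (1 - rho^2), eps_0 drawn from
the stationary distribution), and the index obtained by exponentiation.
A single seeded generator drives all draws; provinces are processed in
alphabetical order, so identical (config, seed) gives identical panels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import (
    ExposureSchedule,
    STRATA,
    STUDY_END,
    STUDY_START,
    build_design,
    build_segments,
    default_schedule,
)
from .errors import ConfigurationError, ValidationError

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_panel",
    "default_published_truth",
    "make_default_metadata",
    "PUBLISHED_RR",
]

# Published point estimates used as simulation defaults: per effect family,
# (low, middle, high) stratum RRs. Slope families are weekly RRs except the
# pre-exposure trend, which is annual.
PUBLISHED_RR: dict[str, tuple[float, float, float]] = {
    "trend": (1.10, 1.11, 1.13),  # per year
    "covid:step": (1.41, 1.62, 1.58),
    "covid1:step": (106.80, 124.55, 125.31),
    "covid1:slope": (0.90, 0.89, 0.89),  # per week
    "covid2:step": (1.91, 1.34, 2.12),
    "covid2:slope": (0.96, 1.02, 0.94),
    "covid3:step": (1.31, 1.34, 1.41),
    "covid3:slope": (1.01, 1.02, 1.02),
    "covid4:step": (2.00, 2.67, 2.45),
    "covid4:slope": (0.83, 0.80, 0.78),
}

# Published stratum membership (category is authoritative; the continuous
# columns produced by make_default_metadata are documented placeholders,
# NOT real indicator values).
_PROVINCES: dict[str, tuple[str, ...]] = {
    "low": (
        "Tibet", "Yunnan", "Guizhou", "Gansu", "Qinghai",
        "Xinjiang", "Guangxi", "Sichuan", "Anhui", "Ningxia",
    ),
    "middle": (
        "Jiangxi", "Henan", "Hebei", "Hunan", "Shanxi", "Hainan", "Chongqing",
        "Heilongjiang", "Shaanxi", "Hubei", "Fujian", "Inner Mongolia", "Jilin",
    ),
    "high": (
        "Shandong", "Guangdong", "Liaoning", "Zhejiang",
        "Jiangsu", "Tianjin", "Shanghai", "Beijing",
    ),
}


@dataclass
class SimulationConfig:
    """Parameters of the generative model.

    ``true_coefficients`` maps design-column names (see design module naming:
    ``intercept``, ``hdi[middle]``, ``trend``, ``covid:step[low]``, ...) to
    log-scale values; unlisted columns are zero. ``month_effects`` covers
    February..December (January reference), ``dow_effects`` the six
    non-Friday days in Monday..Sunday order skipping Friday.
    """

    date_range: tuple[date, date] = (STUDY_START, STUDY_END)
    n_provinces_per_category: Mapping[str, int] | None = None
    true_coefficients: Mapping[str, float] = field(default_factory=dict)
    month_effects: Sequence[float] = (0.0,) * 11
    dow_effects: Sequence[float] = (0.0,) * 6
    sigma2: float = 0.04
    rho: float = 0.6
    G: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    seed: int = 0
    round_to_integer: bool = False

    def validate(self, schedule: ExposureSchedule) -> None:
        start, end = self.date_range
        if not start < end:
            raise ConfigurationError(f"date_range start {start} must precede end {end}")
        if not self.sigma2 >= 0:
            raise ConfigurationError(f"sigma2 must be >= 0, got {self.sigma2}")
        if not abs(self.rho) < 1:
            raise ConfigurationError(f"|rho| must be < 1, got {self.rho}")
        G = np.asarray(self.G, dtype=float)
        if G.shape != (2, 2) or not np.allclose(G, G.T):
            raise ConfigurationError("G must be a symmetric 2x2 matrix")
        if np.min(np.linalg.eigvalsh(G)) < -1e-10:
            raise ConfigurationError("G must have nonnegative eigenvalues")
        if len(self.month_effects) != 11:
            raise ConfigurationError("month_effects must have 11 entries (Feb..Dec)")
        if len(self.dow_effects) != 6:
            raise ConfigurationError("dow_effects must have 6 entries (non-Friday days)")
        valid = _valid_coefficient_names(schedule)
        unknown = set(self.true_coefficients) - valid
        if unknown:
            raise ConfigurationError(
                f"true_coefficients refer to unknown design columns: {sorted(unknown)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "date_range" in kwargs:
            a, b = kwargs["date_range"]
            kwargs["date_range"] = (
                a if isinstance(a, date) else date.fromisoformat(str(a)),
                b if isinstance(b, date) else date.fromisoformat(str(b)),
            )
        if "G" in kwargs:
            kwargs["G"] = np.asarray(kwargs["G"], dtype=float)
        return cls(**kwargs)


@dataclass
class SimulationTruth:
    """Ground-truth record for recovery tests."""

    coefficients: pd.Series
    random_effects: pd.DataFrame  # index province, columns b0, b1
    sigma2: float
    rho: float
    G: np.ndarray
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "coefficients": self.coefficients.to_dict(),
            "random_effects": {
                p: [float(r["b0"]), float(r["b1"])]
                for p, r in self.random_effects.iterrows()
            },
            "sigma2": self.sigma2,
            "rho": self.rho,
            "G": np.asarray(self.G).tolist(),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _valid_coefficient_names(schedule: ExposureSchedule) -> set[str]:
    names = {
        "intercept",
        "hdi[middle]",
        "hdi[high]",
        "trend",
        "trend:hdi[middle]",
        "trend:hdi[high]",
    }
    for family in schedule.effect_families():
        for s in STRATA:
            names.add(f"{family}[{s}]")
    return names


def default_published_truth(category_scheme: str = "categorical") -> dict[str, float]:
    """Published point estimates as log-scale simulation defaults.

    Steps are used as-is (ln RR); weekly slope RRs are divided back to the
    per-day scale (ln RR / 7) and the annual pre-trend to ln RR / 365.
    The trend uses reference coding (low as reference), the step/slope
    families full stratum-specific coding, matching the design module.
    """
    if category_scheme != "categorical":
        raise ConfigurationError(f"unsupported category scheme {category_scheme!r}")
    out: dict[str, float] = {}
    low, mid, high = PUBLISHED_RR["trend"]
    out["trend"] = math.log(low) / 365.0
    out["trend:hdi[middle]"] = (math.log(mid) - math.log(low)) / 365.0
    out["trend:hdi[high]"] = (math.log(high) - math.log(low)) / 365.0
    for family, rrs in PUBLISHED_RR.items():
        if family == "trend":
            continue
        divisor = 7.0 if family.endswith(":slope") else 1.0
        for stratum, rr in zip(STRATA, rrs):
            out[f"{family}[{stratum}]"] = math.log(rr) / divisor
    return out


def make_default_metadata() -> pd.DataFrame:
    """31 provinces with their published stratum assignment and synthetic
    placeholder continuous indicators.

    The continuous columns are deterministic placeholders constructed to be
    strictly increasing from the low to the high stratum (real per-province
    values are not published with the analysis); override from file for real
    data.
    """
    rows = []
    ranges = {"low": (0.560, 0.008), "middle": (0.700, 0.0046), "high": (0.790, 0.009)}
    for cat in STRATA:
        base, step = ranges[cat]
        for i, prov in enumerate(sorted(_PROVINCES[cat])):
            hdi = base + step * i
            rows.append(
                {
                    "province": prov,
                    "hdi": round(hdi, 4),
                    "hdi_category": cat,
                    "gnppp": round(15000 + 90000 * (hdi - 0.55), 0),
                    "education_years": round(7.0 + 8.0 * (hdi - 0.55), 2),
                    "life_expectancy": round(70.0 + 25.0 * (hdi - 0.55), 2),
                }
            )
    return pd.DataFrame(rows)


def subset_metadata(meta: pd.DataFrame, n_per_category: Mapping[str, int]) -> pd.DataFrame:
    """First n provinces (alphabetical) of each stratum — a deterministic
    reduced-scale metadata set."""
    parts = []
    for cat, n in n_per_category.items():
        sub = meta[meta["hdi_category"] == cat].sort_values("province").head(n)
        if len(sub) < n:
            raise ConfigurationError(
                f"not enough provinces in category {cat!r}: wanted {n}, have {len(sub)}"
            )
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)


def _assemble_beta(config: SimulationConfig, columns: Sequence[str]) -> pd.Series:
    beta = pd.Series(0.0, index=list(columns))
    for name, value in config.true_coefficients.items():
        if name in beta.index:
            beta[name] = float(value)
    for m, value in zip(range(2, 13), config.month_effects):
        col = f"month[{m}]"
        if col in beta.index:
            beta[col] = float(value)
    dow_names = [d for d in ("Mon", "Tue", "Wed", "Thu", "Sat", "Sun")]
    for name, value in zip(dow_names, config.dow_effects):
        col = f"dow[{name}]"
        if col in beta.index:
            beta[col] = float(value)
    return beta


def _ar1_series(rng: np.random.Generator, n: int, sigma2: float, rho: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal variance sigma2."""
    z = rng.standard_normal(n)
    if sigma2 == 0.0:
        return np.zeros(n)
    sd = math.sqrt(sigma2)
    eps = np.empty(n)
    eps[0] = sd * z[0]
    innov_sd = sd * math.sqrt(1.0 - rho**2)
    for t in range(1, n):
        eps[t] = rho * eps[t - 1] + innov_sd * z[t]
    return eps


def simulate_panel(
    config: SimulationConfig,
    schedule: ExposureSchedule | None = None,
    meta: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate one long-format panel plus its ground truth.

    Returns ``(panel, truth)`` where the panel has one row per province per
    day of ``config.date_range`` (inclusive), ``index`` strictly positive.
    """
    schedule = schedule if schedule is not None else default_schedule()
    config.validate(schedule)
    meta = meta if meta is not None else make_default_metadata()
    if config.n_provinces_per_category is not None:
        for cat, n in config.n_provinces_per_category.items():
            have = int((meta["hdi_category"] == cat).sum())
            if have != n:
                raise ConfigurationError(
                    f"metadata has {have} provinces in category {cat!r}, config wants {n}"
                )

    provinces = sorted(meta["province"])
    start, end = config.date_range
    dates = pd.date_range(start, end, freq="D")
    n_days = len(dates)
    if n_days == 0:
        raise ValidationError("empty date range")

    skeleton = pd.DataFrame(
        {
            "province": np.repeat(provinces, n_days),
            "date": np.tile(dates, len(provinces)),
            "index": 1.0,
        }
    )
    segments = build_segments(schedule, dates, study_start=start)
    dm = build_design(skeleton, meta, segments, hdi_mode="categorical", drop_empty=False)
    beta = _assemble_beta(config, dm.X.columns)
    lp = dm.X.to_numpy() @ beta.to_numpy()

    rng = np.random.default_rng(config.seed)
    G = np.asarray(config.G, dtype=float)
    if np.allclose(G, 0.0):
        b = np.zeros((len(provinces), 2))
    else:
        w, v = np.linalg.eigh(G)
        L = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        b = rng.standard_normal((len(provinces), 2)) @ L.T

    T = dm.times
    log_index = lp.copy()
    for j, prov in enumerate(provinces):
        sl = slice(j * n_days, (j + 1) * n_days)
        eps = _ar1_series(rng, n_days, config.sigma2, config.rho)
        log_index[sl] += b[j, 0] + b[j, 1] * T[sl] + eps

    values = np.exp(log_index)
    if config.round_to_integer:
        values = np.maximum(np.rint(values), 1.0)

    panel = skeleton.copy()
    panel["index"] = values
    truth = SimulationTruth(
        coefficients=beta,
        random_effects=pd.DataFrame(b, index=provinces, columns=["b0", "b1"]),
        sigma2=config.sigma2,
        rho=config.rho,
        G=G,
        seed=config.seed,
    )
    return panel, truth
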