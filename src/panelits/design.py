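"""Design matrices for segmented interrupted-time-series regression.

Builds the fixed-effect matrix X (segment steps and slope clocks interacted
with a three-level development stratum or a standardized continuous
covariate, plus month-of-year and day-of-week dummies) and the random-effect
design Z (per-province intercept and linear day trend).

Conventions
-----------
* ``T`` counts days since the study start (study start itself is day 0).
* A step indicator is 1 from its ``step_date`` onward and never switches off.
* A slope clock is 0 up to and including its ``slope_start_date`` and then
  increases by 1 per day.
* Reference levels: month January, day-of-week Friday, stratum ``low``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "Exposure",
    "ExposureSchedule",
    "DesignMatrix",
    "default_schedule",
    "build_segments",
    "build_design",
    "standardize",
    "categorize_by_tertile",
    "STUDY_START",
    "STUDY_END",
    "STRATA",
    "CONTINUOUS_FIELDS",
]

STUDY_START = date(2017, 1, 1)
STUDY_END = date(2021, 3, 15)

STRATA = ("low", "middle", "high")

#: metadata column used for each continuous hdi_mode
CONTINUOUS_FIELDS = {
    "continuous:hdi": "hdi",
    "continuous:gnppp": "gnppp",
    "continuous:education": "education_years",
    "continuous:life_expectancy": "life_expectancy",
}

_DOW_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
_DOW_REFERENCE = "Fri"


@dataclass(frozen=True)
class Exposure:
    """One interruption: a persistent level step and an optional slope clock."""

    label: str
    step_date: date
    slope_start_date: date | None = None

    def __post_init__(self) -> None:
        if self.slope_start_date is not None and self.slope_start_date < self.step_date:
            raise ValidationError(
                f"exposure {self.label!r}: slope_start_date {self.slope_start_date} "
                f"precedes step_date {self.step_date}"
            )


@dataclass(frozen=True)
class ExposureSchedule:
    """Ordered collection of exposures, chronological by step date."""

    exposures: tuple[Exposure, ...]

    def __post_init__(self) -> None:
        labels = [e.label for e in self.exposures]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate exposure labels in schedule: {labels}")
        steps = [e.step_date for e in self.exposures]
        if steps != sorted(steps):
            raise ValidationError("exposures must be chronological by step_date")

    def __iter__(self):
        return iter(self.exposures)

    def __len__(self) -> int:
        return len(self.exposures)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.exposures)

    def effect_families(self) -> tuple[str, ...]:
        """Identifiers of estimable effect families: '<label>:step' for every
        exposure and '<label>:slope' for exposures with a slope clock."""
        out: list[str] = []
        for e in self.exposures:
            out.append(f"{e.label}:step")
            if e.slope_start_date is not None:
                out.append(f"{e.label}:slope")
        return tuple(out)


def default_schedule() -> ExposureSchedule:
    """The five-exposure COVID-19 schedule used throughout.

    covid   step 2019-12-31 (first-wave onset, level only)
    covid1  step 2020-01-25, slope clock from 2020-01-25 (post-peak decline)
    covid2  step 2020-06-11, slope clock from 2020-06-17 (Beijing outbreak)
    covid3  step 2020-10-12, slope clock from 2020-10-12 (Qingdao outbreak)
    covid4  step 2021-01-03, slope clock from 2021-01-07 (Shijiazhuang outbreak)
    """
    return ExposureSchedule(
        (
            Exposure("covid", date(2019, 12, 31)),
            Exposure("covid1", date(2020, 1, 25), date(2020, 1, 25)),
            Exposure("covid2", date(2020, 6, 11), date(2020, 6, 17)),
            Exposure("covid3", date(2020, 10, 12), date(2020, 10, 12)),
            Exposure("covid4", date(2021, 1, 3), date(2021, 1, 7)),
        )
    )


@dataclass
class DesignMatrix:
    """Row-aligned fixed/random design with named columns.

    Attributes
    ----------
    X : fixed-effect matrix, one row per panel record.
    Z : random-effect design (columns ``intercept`` and ``T``).
    groups : province label per row.
    times : day offset ``T`` per row (used for AR(1) gap handling).
    reference : reference levels of the dummy coding.
    dropped : names of columns removed because they were identically zero.
    hdi_mode : the mode the matrix was built under.
    """

    X: pd.DataFrame
    Z: pd.DataFrame
    groups: pd.Series
    times: np.ndarray
    reference: dict = field(default_factory=dict)
    dropped: tuple[str, ...] = ()
    hdi_mode: str = "categorical"


def build_segments(
    schedule: ExposureSchedule,
    dates: Iterable,
    study_start: date | None = None,
) -> pd.DataFrame:
    """Per-date segment covariates: T, step indicators, slope clocks,
    month and day-of-week indices.

    Returns a DataFrame indexed by (normalized) date with columns ``T``,
    ``month``, ``dow`` and per exposure ``<label>:step`` / ``<label>:slope``.
    """
    idx = pd.DatetimeIndex(pd.to_datetime(list(dates))).normalize()
    if len(idx) == 0:
        raise ValidationError("empty date collection")
    start = pd.Timestamp(study_start if study_start is not None else STUDY_START)
    if idx.min() < start:
        raise ValidationError(
            f"date {idx.min().date()} precedes study start {start.date()}"
        )
    out = pd.DataFrame(index=idx)
    out["T"] = (idx - start).days.astype(float)
    out["month"] = idx.month
    out["dow"] = idx.dayofweek  # Monday=0 .. Sunday=6
    for e in schedule:
        step_ts = pd.Timestamp(e.step_date)
        out[f"{e.label}:step"] = (idx >= step_ts).astype(float)
        if e.slope_start_date is not None:
            origin = pd.Timestamp(e.slope_start_date)
            clock = (idx - origin).days.astype(float)
            out[f"{e.label}:slope"] = np.maximum(clock, 0.0)
    return out


def standardize(values) -> np.ndarray:
    """Z-score with sample (n-1) standard deviation."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValidationError("standardize requires a 1-d array of length >= 2")
    if np.unique(arr).size < 2:
        raise ValidationError("cannot standardize: all values identical (zero variance)")
    sd = arr.std(ddof=1)
    return (arr - arr.mean()) / sd


def categorize_by_tertile(
    values: Mapping[str, float] | pd.Series,
    cut_ranks: tuple[int, int] | None = None,
) -> pd.Series:
    """Assign low/middle/high by rank of a continuous value.

    Ties are broken by province name order. ``cut_ranks=(a, b)`` forces the
    first ``a`` ranked provinces into ``low`` and the next ``b - a`` into
    ``middle`` (e.g. ``(10, 23)`` reproduces a 10/13/8 split for n=31);
    by default thirds are used.
    """
    s = pd.Series(values, dtype=float)
    n = len(s)
    if n < 3:
        raise ValidationError("need at least 3 provinces to form tertiles")
    order = sorted(s.index, key=lambda p: (s[p], p))
    if cut_ranks is None:
        a = n // 3
        b = n - n // 3
    else:
        a, b = cut_ranks
        if not (0 < a < b < n):
            raise ValidationError(f"cut_ranks {cut_ranks} invalid for n={n}")
    cats = {}
    for rank, prov in enumerate(order):
        cats[prov] = "low" if rank < a else ("middle" if rank < b else "high")
    return pd.Series(cats).loc[s.index]


def _month_dummies(segments_rows: pd.DataFrame) -> pd.DataFrame:
    cols = {}
    for m in range(2, 13):
        cols[f"month[{m}]"] = (segments_rows["month"].to_numpy() == m).astype(float)
    return pd.DataFrame(cols, index=segments_rows.index)


def _dow_dummies(segments_rows: pd.DataFrame) -> pd.DataFrame:
    cols = {}
    for d, name in enumerate(_DOW_NAMES):
        if name == _DOW_REFERENCE:
            continue
        cols[f"dow[{name}]"] = (segments_rows["dow"].to_numpy() == d).astype(float)
    return pd.DataFrame(cols, index=segments_rows.index)


def build_design(
    panel: pd.DataFrame,
    meta: pd.DataFrame,
    segments: pd.DataFrame,
    hdi_mode: str = "categorical",
    drop_empty: bool = True,
) -> DesignMatrix:
    """Expand a validated panel into fixed and random design matrices.

    Parameters
    ----------
    panel : DataFrame with columns ``province``, ``date``, ``index`` (one row
        per observation; row order is preserved).
    meta : DataFrame with a ``province`` column plus ``hdi_category`` and the
        continuous indicator columns.
    segments : output of :func:`build_segments` covering every panel date.
    hdi_mode : ``categorical`` or one of ``continuous:hdi``,
        ``continuous:gnppp``, ``continuous:education``,
        ``continuous:life_expectancy``.
    drop_empty : remove identically-zero dummy/effect columns (recorded in
        ``DesignMatrix.dropped``). Disable to keep the full column set.
    """
    if hdi_mode != "categorical" and hdi_mode not in CONTINUOUS_FIELDS:
        raise ValidationError(f"unknown hdi_mode {hdi_mode!r}")

    panel = panel.reset_index(drop=True)

    meta = meta.set_index("province") if "province" in meta.columns else meta
    missing = set(panel["province"].unique()) - set(meta.index)
    if missing:
        raise ValidationError(f"provinces missing from metadata: {sorted(missing)}")

    dates = pd.to_datetime(panel["date"]).dt.normalize()
    seg_missing = set(dates.unique()) - set(segments.index)
    if seg_missing:
        raise ValidationError(
            f"{len(seg_missing)} panel dates missing from segment covariates"
        )
    rows = segments.loc[dates]
    rows.index = panel.index

    seg_cols = [c for c in segments.columns if ":" in c]
    step_cols = [c for c in seg_cols if c.endswith(":step")]
    slope_cols = [c for c in seg_cols if c.endswith(":slope")]

    X = pd.DataFrame(index=panel.index)
    X["intercept"] = 1.0
    T = rows["T"].to_numpy()

    if hdi_mode == "categorical":
        cat = panel["province"].map(meta["hdi_category"])
        bad = cat.isna()
        if bad.any():
            raise ValidationError("hdi_category missing for some panel provinces")
        ind = {s: (cat.to_numpy() == s).astype(float) for s in STRATA}
        X["hdi[middle]"] = ind["middle"]
        X["hdi[high]"] = ind["high"]
        X["trend"] = T
        X["trend:hdi[middle]"] = T * ind["middle"]
        X["trend:hdi[high]"] = T * ind["high"]
        # fully stratum-specific step/slope columns: each stratum's effect
        # is directly a single coefficient
        for col in step_cols + slope_cols:
            base = rows[col].to_numpy()
            for s in STRATA:
                X[f"{col}[{s}]"] = base * ind[s]
        reference = {"month": "January", "dow": _DOW_REFERENCE, "hdi_category": "low"}
    else:
        fname = CONTINUOUS_FIELDS[hdi_mode]
        if fname not in meta.columns or meta.loc[
            panel["province"].unique(), fname
        ].isna().any():
            raise ValidationError(
                f"continuous mode {hdi_mode!r} requires column {fname!r} "
                "for every panel province"
            )
        by_prov = meta.loc[sorted(panel["province"].unique()), fname]
        z_by_prov = pd.Series(standardize(by_prov.to_numpy()), index=by_prov.index)
        z = panel["province"].map(z_by_prov).to_numpy()
        X[f"{fname}_z"] = z
        X["trend"] = T
        X["trend:z"] = T * z
        for col in step_cols + slope_cols:
            base = rows[col].to_numpy()
            X[col] = base
            X[f"{col}:z"] = base * z
        reference = {"month": "January", "dow": _DOW_REFERENCE, "covariate": fname}

    X = pd.concat([X, _month_dummies(rows), _dow_dummies(rows)], axis=1)

    dropped: tuple[str, ...] = ()
    if drop_empty:
        zero = [c for c in X.columns if c != "intercept" and not np.any(X[c].to_numpy())]
        dropped = tuple(zero)
        X = X.drop(columns=list(zero))

    Z = pd.DataFrame({"intercept": np.ones(len(panel)), "T": T}, index=panel.index)
    return DesignMatrix(
        X=X,
        Z=Z,
        groups=panel["province"].reset_index(drop=True),
        times=T.copy(),
        reference=reference,
        dropped=dropped,
        hdi_mode=hdi_mode,
    )
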