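"""Reading, validating and writing panel, metadata, schedule and result files.

All validation is total: malformed input raises a typed error and never
yields a partially constructed object.
"""

from __future__ import annotations

import json
import logging
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import Exposure, ExposureSchedule, STRATA, STUDY_END, STUDY_START, default_schedule
from .errors import FormatError, ValidationError

__all__ = [
    "read_panel",
    "validate_panel",
    "write_panel",
    "read_metadata",
    "write_metadata",
    "read_schedule",
    "write_results",
]

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ["province", "date", "index"]
META_COLUMNS = [
    "province",
    "hdi",
    "hdi_category",
    "gnppp",
    "education_years",
    "life_expectancy",
]


def _parse_dates(raw: pd.Series) -> pd.Series:
    try:
        parsed = pd.to_datetime(raw, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"unparseable date in panel: {exc}") from exc
    return parsed.dt.normalize()


def validate_panel(df: pd.DataFrame, study_window: tuple[date, date] | None = None) -> pd.DataFrame:
    """Validate a long-format panel DataFrame in place of a file.

    Checks column presence, strictly positive index values, and uniqueness of
    (province, date). Rows outside ``study_window`` (inclusive) are dropped
    with a logged count. Returns a normalized copy sorted by (province, date).
    """
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"panel is missing columns {missing}; expected {PANEL_COLUMNS}")
    out = df[PANEL_COLUMNS].copy()
    out["date"] = _parse_dates(out["date"])
    out["index"] = pd.to_numeric(out["index"], errors="coerce")

    bad = out.index[~(out["index"] > 0)].tolist()
    if bad:
        raise ValidationError(
            f"index must be strictly positive (log is taken); offending rows: {bad[:20]}"
        )
    dup = out.duplicated(subset=["province", "date"], keep=False)
    if dup.any():
        pairs = (
            out.loc[dup, ["province", "date"]]
            .drop_duplicates()
            .apply(lambda r: (r["province"], r["date"].date().isoformat()), axis=1)
            .tolist()
        )
        raise ValidationError(f"duplicate (province, date) pairs: {pairs[:20]}")

    if study_window is not None:
        lo, hi = pd.Timestamp(study_window[0]), pd.Timestamp(study_window[1])
        keep = (out["date"] >= lo) & (out["date"] <= hi)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropped %d rows outside study window %s..%s", n_dropped, lo.date(), hi.date())
        out = out[keep]

    return out.sort_values(["province", "date"]).reset_index(drop=True)


def read_panel(path, study_window: tuple[date, date] | None = (STUDY_START, STUDY_END)) -> pd.DataFrame:
    """Read a `province,date,index` CSV and validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"panel not found: {path}")
    return validate_panel(pd.read_csv(path), study_window)


def write_panel(panel: pd.DataFrame, path) -> None:
    out = panel.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    """Read province metadata; categories normalized to lower case."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata not found: {path}")
    df = pd.read_csv(path)
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    required = ["province", "hdi_category"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"metadata is missing columns {missing}")
    out = df.copy()
    for col in META_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[META_COLUMNS]
    dup = out["province"].duplicated(keep=False)
    if dup.any():
        raise ValidationError(
            f"repeated provinces in metadata: {sorted(out.loc[dup, 'province'].unique())}"
        )
    out["hdi_category"] = out["hdi_category"].astype(str).str.strip().str.lower()
    bad = set(out["hdi_category"]) - set(STRATA)
    if bad:
        raise ValidationError(f"unknown hdi_category labels: {sorted(bad)}; expected {STRATA}")
    for col in ["hdi", "gnppp", "education_years", "life_expectancy"]:
        out[col] = pd.to_numeric(out[col], errors="coerce")
    return out.reset_index(drop=True)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)


def _parse_iso(d, label: str) -> date:
    try:
        return date.fromisoformat(str(d))
    except ValueError as exc:
        raise FormatError(f"{label}: bad date {d!r}") from exc


def read_schedule(path=None) -> ExposureSchedule:
    """Read an exposure schedule from YAML/JSON; ``None`` gives the default
    five-exposure schedule.

    Expected layout: a list of mappings with keys ``label``, ``step_date``
    and optional ``slope_start_date``.
    """
    if path is None:
        return default_schedule()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"schedule not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return default_schedule()
    if not isinstance(raw, list):
        raise FormatError("schedule file must contain a list of exposures")
    exposures = []
    for item in raw:
        if "label" not in item or "step_date" not in item:
            raise FormatError(f"schedule entry missing label/step_date: {item}")
        slope = item.get("slope_start_date")
        exposures.append(
            Exposure(
                label=str(item["label"]),
                step_date=_parse_iso(item["step_date"], item["label"]),
                slope_start_date=None if slope is None else _parse_iso(slope, item["label"]),
            )
        )
    exposures.sort(key=lambda e: e.step_date)
    return ExposureSchedule(tuple(exposures))


def write_results(fit, effects_table: pd.DataFrame, out_dir) -> dict[str, Path]:
    """Write fit coefficients, the effects table and variance components.

    Produces ``coefficients.csv`` (term, estimate, se), ``effects.csv``
    (the effects table as-is) and ``fit.json`` (variance components,
    log-likelihood, AIC/BIC, convergence).
    Returns a mapping of artifact name to path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    se = np.sqrt(np.diag(fit.cov_beta.to_numpy()))
    coef = pd.DataFrame(
        {"term": fit.beta.index, "estimate": fit.beta.to_numpy(), "se": se}
    )
    coef_path = out_dir / "coefficients.csv"
    coef.to_csv(coef_path, index=False, float_format="%.17g")

    eff_path = out_dir / "effects.csv"
    effects_table.to_csv(eff_path, index=False, float_format="%.17g")

    payload = {
        "sigma2": fit.vc.sigma2,
        "rho": fit.vc.rho,
        "G": np.asarray(fit.vc.G).tolist(),
        "loglik": fit.loglik,
        "aic": fit.aic,
        "bic": fit.bic,
        "n_obs": fit.n_obs,
        "n_params": fit.n_params,
        "converged": bool(fit.converged),
        "method": fit.method,
    }
    fit_path = out_dir / "fit.json"
    with open(fit_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)

    return {"coefficients": coef_path, "effects": eff_path, "fit": fit_path}
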