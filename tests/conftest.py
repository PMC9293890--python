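import numpy as np
import pandas as pd
import pytest

from panelits.design import Exposure, ExposureSchedule, build_design, build_segments, default_schedule
from panelits.lmm import FitResult, VarianceComponents
from panelits.simulate import make_default_metadata, subset_metadata


@pytest.fixture(scope="session")
def default_sched():
    return default_schedule()


@pytest.fixture(scope="session")
def meta31():
    return make_default_metadata()


@pytest.fixture(scope="session")
def meta9(meta31):
    return subset_metadata(meta31, {"low": 3, "middle": 3, "high": 3})


@pytest.fixture(scope="session")
def meta6(meta31):
    return subset_metadata(meta31, {"low": 2, "middle": 2, "high": 2})


def make_fake_fit(beta: dict, cov: pd.DataFrame | None = None, hdi_mode="categorical") -> FitResult:
    """FitResult with given coefficients (zero covariance unless supplied);
    used to exercise the effects layer without a model fit."""
    s = pd.Series(beta, dtype=float)
    if cov is None:
        cov = pd.DataFrame(0.0, index=s.index, columns=s.index)
    return FitResult(
        beta=s,
        cov_beta=cov,
        vc=VarianceComponents(sigma2=1.0, rho=0.0, G=np.zeros((2, 2))),
        loglik=0.0,
        aic=0.0,
        bic=0.0,
        n_obs=1,
        n_params=len(s),
        converged=True,
        hdi_mode=hdi_mode,
    )


@pytest.fixture()
def single_exposure_sched():
    return ExposureSchedule(
        (Exposure("shock", pd.Timestamp("2020-01-15").date(), pd.Timestamp("2020-01-20").date()),)
    )


def small_sim_panel(meta, date_range=("2019-11-01", "2020-03-15"), seed=0, **cfg_kwargs):
    """Short-window simulated panel for fast fitting tests."""
    from datetime import date

    from panelits.cli import default_simulation_config
    from panelits.simulate import simulate_panel

    cfg = default_simulation_config(
        seed,
        date_range=(date.fromisoformat(date_range[0]), date.fromisoformat(date_range[1])),
    )
    for k, v in cfg_kwargs.items():
        setattr(cfg, k, v)
    panel, truth = simulate_panel(cfg, meta=meta)
    return cfg, panel, truth


def design_for(panel, meta, schedule, start, hdi_mode="categorical"):
    dates = pd.to_datetime(panel["date"]).unique()
    segments = build_segments(schedule, dates, study_start=start)
    return build_design(panel, meta, segments, hdi_mode=hdi_mode)


@pytest.fixture(scope="session")
def recovery_result():
    """Five-seed simulate-and-refit study shared by recovery-related tests
    (the most expensive fixture in the suite)."""
    from panelits.cli import recovery_experiment

    return recovery_experiment(5, seed=1, n_per_category=3)
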