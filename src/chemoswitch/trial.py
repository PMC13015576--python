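"""Synthetic individual-patient data and parametric survival fitting.

The model's survival backbone was calibrated on a randomized trial whose
patient-level data are not deposited.  This module stands in for that
calibration step: it simulates right-censored overall-survival (OS) and
time-to-progression (TTP) data at trial scale, fits exponential and Weibull
models by censored maximum likelihood, compares them by AIC, bootstraps the
correlation between the Weibull shape and scale estimates, and refits on
patients surviving a landmark (left truncation / delayed entry).

All simulated IPD tables are explicitly synthetic; they emulate the
structure of a phase-III trial (default n = 160, uniform accrual over
2 years, 3 years total follow-up) but none of their values derive from real
patients.

OS and TTP are simulated as independent Weibull processes and then ordered
(TTP is capped at OS, with death before progression censoring TTP), which
induces a mild dependence; no joint model is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import ExponentialFitter, WeibullFitter

from .survival import WeibullParams

__all__ = [
    "FitResult",
    "simulate_ipd",
    "simulate_salto_like",
    "fit_parametric",
    "bootstrap_shape_scale_corr",
    "refit_conditional",
    "read_ipd",
    "write_ipd",
]

IPD_COLUMNS = ["id", "os_weeks", "os_event", "ttp_weeks", "ttp_event"]

DEFAULT_OS = WeibullParams(shape=1.473, scale=79.4)
DEFAULT_TTP = WeibullParams(shape=1.560, scale=53.9)


@dataclass(frozen=True)
class FitResult:
    """Parametric survival fit: estimates, standard errors, loglik, AIC.

    ``shape`` is fixed at 1 (with zero SE) for the exponential family.
    ``corr_shape_scale`` is the correlation implied by the fit's covariance
    matrix (0 for the exponential).
    """

    family: str
    shape: float
    scale: float
    shape_se: float
    scale_se: float
    corr_shape_scale: float
    loglik: float
    aic: float
    n_used: int
    n_events: int

    @property
    def params(self) -> WeibullParams:
        return WeibullParams(shape=self.shape, scale=self.scale)


def simulate_ipd(n: int, os_params: WeibullParams = DEFAULT_OS,
                 ttp_params: WeibullParams = DEFAULT_TTP,
                 censor_time: Optional[float] = None,
                 accrual_weeks: Optional[float] = None,
                 seed: Optional[int] = None) -> pd.DataFrame:
    """Simulate a right-censored OS/TTP patient table.

    OS and TTP are drawn independently from their Weibull distributions;
    TTP is truncated at OS (death before progression censors TTP at the
    death time).  ``censor_time`` is the administrative follow-up in weeks;
    if ``accrual_weeks`` is also given, per-patient follow-up is
    ``censor_time`` minus a uniform accrual offset, emulating staggered
    trial entry with a common data cutoff.
    """
    if n < 10:
        raise ValueError("need at least 10 patients")
    rng = np.random.default_rng(seed)
    os_raw = os_params.scale * rng.weibull(os_params.shape, n)
    ttp_raw = ttp_params.scale * rng.weibull(ttp_params.shape, n)
    if censor_time is None:
        follow = np.full(n, np.inf)
    elif accrual_weeks is None:
        follow = np.full(n, float(censor_time))
    else:
        if accrual_weeks >= censor_time:
            raise ValueError("accrual period must be shorter than total follow-up")
        follow = censor_time - rng.uniform(0.0, accrual_weeks, n)
    os_time = np.minimum(os_raw, follow)
    os_event = (os_raw <= follow).astype(int)
    ttp_time = np.minimum.reduce([ttp_raw, os_raw, follow])
    ttp_event = ((ttp_raw <= os_raw) & (ttp_raw <= follow)).astype(int)
    eps = 1e-6  # event times must stay strictly positive
    return pd.DataFrame({
        "id": np.arange(1, n + 1),
        "os_weeks": np.maximum(os_time, eps),
        "os_event": os_event,
        "ttp_weeks": np.maximum(ttp_time, eps),
        "ttp_event": ttp_event,
    })


def simulate_salto_like(n: int = 160, os_params: WeibullParams = DEFAULT_OS,
                        ttp_params: WeibullParams = DEFAULT_TTP,
                        seed: Optional[int] = None) -> pd.DataFrame:
    """Phase-III-like synthetic trial: uniform accrual over 2 years and a
    data cutoff 3 years after the first enrolment."""
    return simulate_ipd(n, os_params, ttp_params, censor_time=156.0,
                        accrual_weeks=104.0, seed=seed)


def _validate_ipd(ipd: pd.DataFrame) -> None:
    missing = [c for c in IPD_COLUMNS if c not in ipd.columns]
    if missing:
        raise ValueError(f"IPD table missing columns {missing}")
    if (ipd["ttp_weeks"] > ipd["os_weeks"] + 1e-9).any():
        raise ValueError("ttp_weeks must not exceed os_weeks")


def fit_parametric(ipd: pd.DataFrame, endpoint: str = "os",
                   family: str = "weibull",
                   entry: Optional[np.ndarray] = None) -> FitResult:
    """Fit an exponential or Weibull model by censored maximum likelihood.

    The likelihood is the standard right-censored one (with optional
    delayed-entry adjustment through ``entry``); estimation is delegated to
    lifelines.  AIC = 2k - 2 loglik with k the number of free parameters.
    """
    _validate_ipd(ipd)
    if endpoint not in ("os", "ttp"):
        raise ValueError("endpoint must be 'os' or 'ttp'")
    durations = ipd[f"{endpoint}_weeks"].to_numpy(dtype=float)
    events = ipd[f"{endpoint}_event"].to_numpy(dtype=int)
    if events.sum() < 2:
        raise ValueError("need at least 2 observed events to fit")
    kwargs = {"entry": entry} if entry is not None else {}
    if family == "weibull":
        fitter = WeibullFitter()
        fitter.fit(durations, events, **kwargs)
        var = fitter.variance_matrix_
        scale_se = float(np.sqrt(var.loc["lambda_", "lambda_"]))
        shape_se = float(np.sqrt(var.loc["rho_", "rho_"]))
        corr = float(var.loc["lambda_", "rho_"] / (scale_se * shape_se))
        if not np.isfinite(corr):
            raise RuntimeError("Weibull fit did not converge to a valid covariance")
        return FitResult(family="weibull", shape=float(fitter.rho_),
                         scale=float(fitter.lambda_), shape_se=shape_se,
                         scale_se=scale_se, corr_shape_scale=corr,
                         loglik=float(fitter.log_likelihood_),
                         aic=float(fitter.AIC_), n_used=len(ipd),
                         n_events=int(events.sum()))
    if family == "exponential":
        fitter = ExponentialFitter()
        fitter.fit(durations, events, **kwargs)
        var = fitter.variance_matrix_
        scale_se = float(np.sqrt(var.loc["lambda_", "lambda_"]))
        return FitResult(family="exponential", shape=1.0,
                         scale=float(fitter.lambda_), shape_se=0.0,
                         scale_se=scale_se, corr_shape_scale=0.0,
                         loglik=float(fitter.log_likelihood_),
                         aic=float(fitter.AIC_), n_used=len(ipd),
                         n_events=int(events.sum()))
    raise ValueError("family must be 'weibull' or 'exponential'")


def bootstrap_shape_scale_corr(ipd: pd.DataFrame, endpoint: str = "os",
                               B: int = 1000, seed: Optional[int] = None) -> float:
    """Non-parametric bootstrap correlation of the Weibull shape and scale.

    Patients are resampled with replacement B times and the Weibull refit;
    the Pearson correlation of the B (shape, scale) estimate pairs is
    returned.  Raises if more than 5% of the refits fail.
    """
    if B < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    rng = np.random.default_rng(seed)
    n = len(ipd)
    shapes, scales, failures = [], [], 0
    for _ in range(B):
        sample = ipd.iloc[rng.integers(0, n, n)].reset_index(drop=True)
        try:
            fit = fit_parametric(sample, endpoint, "weibull")
            shapes.append(fit.shape)
            scales.append(fit.scale)
        except Exception:
            failures += 1
    if failures > 0.05 * B:
        raise RuntimeError(f"{failures} of {B} bootstrap fits failed")
    return float(np.corrcoef(shapes, scales)[0, 1])


def refit_conditional(ipd: pd.DataFrame, endpoint: str = "os",
                      landmark: float = 9.0, family: str = "weibull") -> FitResult:
    """Refit on patients who survived the landmark, by delayed entry.

    Patients with ``os_weeks`` below the landmark are dropped; the
    remaining ones enter the risk set at the landmark (left truncation), so
    the model keeps its original time origin rather than resetting time.
    """
    _validate_ipd(ipd)
    if landmark < 0:
        raise ValueError("landmark must be >= 0")
    sub = ipd[ipd["os_weeks"] >= landmark].reset_index(drop=True)
    if len(sub) == 0 or sub[f"{endpoint}_event"].sum() < 2:
        raise ValueError(f"fewer than 2 events beyond the {landmark}-week landmark")
    entry = np.full(len(sub), float(landmark))
    return fit_parametric(sub, endpoint, family, entry=entry)


def write_ipd(ipd: pd.DataFrame, path) -> None:
    """Write a patient table as CSV with the canonical column header."""
    _validate_ipd(ipd)
    ipd[IPD_COLUMNS].to_csv(path, index=False)


def read_ipd(path) -> pd.DataFrame:
    """Read a patient table written by :func:`write_ipd`."""
    ipd = pd.read_csv(path)
    _validate_ipd(ipd)
    return ipd
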