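"""Paralyzable dead-time model: forward/inverse rate maps, window-fraction
scaling, loss metric, and estimation of tau_w and eta.

The paralyzable (extendable) model relates true and observed count rates in
an energy window through

    R_wo = R_wt * exp(-R_wt * tau_w),

where tau_w is the *apparent* dead time of that window.  Restricting the
analysis to a window containing the fraction wf of all counts stretches the
dead time as

    tau_w = tau / wf**eta,

with tau the full-window dead time and eta a positive camera-dependent
exponent (reported values range from 1 to 1.83; 1.4 is the most common).
The dead-time loss reported throughout is

    loss(%) = (true primary rate - observed primary rate) / true * 100.

Estimation is exposed both as plain functions (``fit_tau``, ``fit_eta``) and
as model classes whose ``fit()`` returns a results object with standard
errors and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import lambertw

__all__ = [
    "CountRatePair",
    "LossResult",
    "paralyzable_observed",
    "paralyzable_true",
    "apparent_dead_time",
    "apparent_dead_time_single",
    "deadtime_loss",
    "fit_tau",
    "fit_eta",
    "eta_single",
    "ParalyzableDeadTimeModel",
    "DeadTimeResults",
    "WindowScalingModel",
    "WindowScalingResults",
]

_INV_E = np.exp(-1.0)


@dataclass(frozen=True)
class CountRatePair:
    """True and observed count rates in one window (counts/s)."""

    r_true: float
    r_obs: float

    def __post_init__(self) -> None:
        if self.r_true < 0 or self.r_obs < 0:
            raise ValueError("rates must be non-negative")
        if self.r_obs > self.r_true:
            raise ValueError("observed rate cannot exceed true rate")


@dataclass(frozen=True)
class LossResult:
    true_rate: float
    observed_rate: float
    loss_percent: float


def paralyzable_observed(r_true, tau_w_s) -> np.ndarray | float:
    """Forward map of the paralyzable model: R_wo = R_wt exp(-R_wt tau_w)."""
    r = np.asarray(r_true, dtype=float)
    tau = np.asarray(tau_w_s, dtype=float)
    if np.any(r < 0) or np.any(tau < 0):
        raise ValueError("rates and dead times must be non-negative")
    out = r * np.exp(-r * tau)
    return out if out.ndim else float(out)


def paralyzable_true(r_obs, tau_w_s) -> np.ndarray | float:
    """Invert the paralyzable model on the physical branch (R_wt tau_w <= 1).

    Uses the principal branch of the Lambert W function:
    R_wt = -W0(-R_wo tau_w) / tau_w.  Rates with R_wo tau_w > 1/e have no
    solution (the forward map peaks at 1/(e tau_w)) and raise.
    """
    r = np.asarray(r_obs, dtype=float)
    tau = np.asarray(tau_w_s, dtype=float)
    if np.any(r < 0) or np.any(tau < 0):
        raise ValueError("rates and dead times must be non-negative")
    x = r * tau
    if np.any(x > _INV_E * (1.0 + 1e-12)):
        raise ValueError(
            "observed rate exceeds the paralyzable maximum 1/(e tau); no physical solution"
        )
    # values within float noise of the peak 1/e map to the peak rate 1/tau
    at_peak = x > _INV_E - 1e-12
    x = np.minimum(x, _INV_E)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(at_peak, -1.0, np.real(lambertw(-np.where(at_peak, 0.0, x), k=0)))
        out = np.where(tau > 0, -w / np.where(tau > 0, tau, 1.0), r)
    return out if out.ndim else float(out)


def apparent_dead_time(tau_s: float, wf, eta: float = 1.4) -> np.ndarray | float:
    """Window-fraction scaling of dead time: tau_w = tau / wf**eta."""
    if tau_s < 0:
        raise ValueError("tau must be non-negative")
    if eta <= 0:
        raise ValueError("eta must be positive")
    w = np.asarray(wf, dtype=float)
    if np.any(w <= 0) or np.any(w > 1):
        raise ValueError("window fraction must lie in (0, 1]")
    out = tau_s / w**eta
    return out if out.ndim else float(out)


def apparent_dead_time_single(r_true: float, r_obs: float) -> float:
    """Solve one (R_wt, R_wo) pair for tau_w: tau_w = ln(R_wt/R_wo)/R_wt.

    This is the per-second estimator: each second of a measurement gives one
    pair and hence one apparent-dead-time sample.
    """
    if r_true <= 0:
        raise ValueError("true rate must be positive")
    if r_obs <= 0:
        raise ValueError("observed rate must be positive")
    return float(np.log(r_true / r_obs) / r_true)


def deadtime_loss(true_rate, observed_rate) -> np.ndarray | float:
    """Dead-time loss in percent, (true - observed)/true * 100."""
    t = np.asarray(true_rate, dtype=float)
    o = np.asarray(observed_rate, dtype=float)
    if np.any(t <= 0):
        raise ValueError("true rate must be positive")
    if np.any(o > t):
        raise ValueError("observed rate cannot exceed true rate")
    out = (t - o) / t * 100.0
    return out if out.ndim else float(out)


# ----------------------------------------------------------------------
# Estimators
# ----------------------------------------------------------------------

def _origin_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least squares through the origin; returns (slope, standard error)."""
    sxx = float(np.dot(x, x))
    slope = float(np.dot(x, y)) / sxx
    resid = y - slope * x
    dof = max(x.size - 1, 1)
    se = float(np.sqrt(np.dot(resid, resid) / dof / sxx))
    return slope, se


def fit_tau(
    pairs: Sequence[CountRatePair] | tuple[np.ndarray, np.ndarray],
) -> tuple[float, float]:
    """Estimate tau_w from (true, observed) rate pairs.

    Least squares of ln(R_wo/R_wt) = -tau_w R_wt through the origin -- the
    rate-sweep analogue of the decaying-source method.  Returns the estimate
    and its standard error.
    """
    if isinstance(pairs, tuple):
        r_true, r_obs = (np.asarray(a, dtype=float) for a in pairs)
    else:
        r_true = np.array([p.r_true for p in pairs], dtype=float)
        r_obs = np.array([p.r_obs for p in pairs], dtype=float)
    if r_true.size < 2 or np.unique(r_true).size < 2:
        raise ValueError("need at least two pairs with distinct true rates")
    if np.any(r_true <= 0) or np.any(r_obs <= 0):
        raise ValueError("rates must be positive")
    y = np.log(r_obs / r_true)
    slope, se = _origin_regression(r_true, y)
    return -slope, se


def fit_eta(wf, tau_w, tau_s: float) -> float:
    """Estimate eta from window fractions and apparent dead times.

    Regression through the origin of ln(tau_w/tau) on ln(1/wf).  A window
    fraction of exactly 1 with tau_w != tau is inconsistent with the scaling
    law and raises.
    """
    w = np.asarray(wf, dtype=float)
    t = np.asarray(tau_w, dtype=float)
    if tau_s <= 0:
        raise ValueError("tau must be positive")
    if np.any(w <= 0) or np.any(w > 1):
        raise ValueError("window fractions must lie in (0, 1]")
    at_one = w == 1.0
    if np.any(at_one) and not np.allclose(t[at_one], tau_s, rtol=1e-9):
        raise ValueError("wf = 1 with tau_w != tau is inconsistent with the model")
    keep = ~at_one
    x = np.log(1.0 / w[keep])
    y = np.log(t[keep] / tau_s)
    slope, _ = _origin_regression(x, y)
    return slope


def eta_single(wf: float, tau_w_s: float, tau_s: float) -> float:
    """Closed-form eta from a single (wf, tau_w) pair."""
    if not 0 < wf < 1:
        raise ValueError("window fraction must lie in (0, 1)")
    return float(np.log(tau_w_s / tau_s) / np.log(1.0 / wf))


# ----------------------------------------------------------------------
# Model / Results interface
# ----------------------------------------------------------------------

class ParalyzableDeadTimeModel:
    """Paralyzable dead-time model for (true, observed) count-rate data.

    Parameters
    ----------
    r_true, r_obs : array-like
        Paired true and observed rates (counts/s) in one energy window,
        e.g. one pair per recorded second.
    """

    def __init__(self, r_true, r_obs) -> None:
        self.r_true = np.asarray(r_true, dtype=float)
        self.r_obs = np.asarray(r_obs, dtype=float)
        if self.r_true.shape != self.r_obs.shape:
            raise ValueError("r_true and r_obs must have the same shape")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, true_col: str = "true_rate", obs_col: str = "observed_rate"
    ) -> "ParalyzableDeadTimeModel":
        return cls(df[true_col].to_numpy(), df[obs_col].to_numpy())

    def fit(self, method: str = "ols") -> "DeadTimeResults":
        """Fit tau_w.  ``method='ols'`` regresses over all pairs;
        ``method='single'`` averages the per-pair closed-form solutions."""
        if method == "ols":
            tau, se = fit_tau((self.r_true, self.r_obs))
            fitted = paralyzable_observed(self.r_true, tau)
            return DeadTimeResults(self, float(tau), se, np.atleast_1d(fitted), method)
        if method == "single":
            taus = np.array(
                [
                    apparent_dead_time_single(t, o)
                    for t, o in zip(np.atleast_1d(self.r_true), np.atleast_1d(self.r_obs))
                ]
            )
            tau = float(taus.mean())
            se = float(taus.std(ddof=1) / np.sqrt(taus.size)) if taus.size > 1 else np.nan
            fitted = paralyzable_observed(self.r_true, tau)
            return DeadTimeResults(self, tau, se, np.atleast_1d(fitted), method)
        raise ValueError(f"unknown method {method!r}")


@dataclass
class DeadTimeResults:
    """Fit results for the paralyzable model."""

    model: ParalyzableDeadTimeModel
    tau_w: float
    bse: float
    fittedvalues: np.ndarray
    method: str

    @property
    def nobs(self) -> int:
        return int(np.atleast_1d(self.model.r_true).size)

    @property
    def resid(self) -> np.ndarray:
        return np.atleast_1d(self.model.r_obs) - self.fittedvalues

    def predict(self, r_true) -> np.ndarray | float:
        return paralyzable_observed(r_true, self.tau_w)

    def correct(self, r_obs) -> np.ndarray | float:
        """Dead-time-correct observed rates with the fitted tau_w."""
        return paralyzable_true(r_obs, self.tau_w)

    def summary(self) -> str:
        lines = [
            "Paralyzable dead-time model",
            "===========================",
            f"method:          {self.method}",
            f"n pairs:         {self.nobs}",
            f"tau_w:           {self.tau_w:.4e} s ({self.tau_w * 1e6:.3f} us)",
            f"std err:         {self.bse:.3e} s",
            f"max loss seen:   {np.max(deadtime_loss(self.model.r_true, self.model.r_obs)):.2f} %",
        ]
        return "\n".join(lines)


class WindowScalingModel:
    """Window-fraction scaling model tau_w = tau / wf**eta.

    Fits eta given the full-window dead time tau and per-configuration
    (wf, tau_w) observations.
    """

    def __init__(self, wf, tau_w, tau_s: float) -> None:
        self.wf = np.asarray(wf, dtype=float)
        self.tau_w = np.asarray(tau_w, dtype=float)
        self.tau_s = float(tau_s)

    def fit(self) -> "WindowScalingResults":
        eta = fit_eta(self.wf, self.tau_w, self.tau_s)
        x = np.log(1.0 / self.wf)
        y = np.log(self.tau_w / self.tau_s)
        _, se = _origin_regression(x, y)
        fitted = self.tau_s / self.wf**eta
        return WindowScalingResults(self, float(eta), float(se), fitted)


@dataclass
class WindowScalingResults:
    model: WindowScalingModel
    eta: float
    bse: float
    fittedvalues: np.ndarray

    def predict(self, wf) -> np.ndarray | float:
        return apparent_dead_time(self.model.tau_s, wf, self.eta)

    def summary(self) -> str:
        lines = [
            "Window-fraction dead-time scaling",
            "=================================",
            f"tau (full window): {self.model.tau_s * 1e6:.3f} us",
            f"eta:               {self.eta:.3f}",
            f"std err:           {self.bse:.3f}",
            f"n configurations:  {self.model.wf.size}",
        ]
        return "\n".join(lines)
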