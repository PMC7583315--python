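"""K_D estimation from saturation-binding kinetics.

EMSA association-rate measurements at a handful of probe
concentrations follow single-site hyperbolic saturation,

    v(c) = Vmax * c / (K_D + c),

the standard "one site - specific binding" analysis. ``fit_kd`` /
``SaturationKinetics`` estimate (K_D, Vmax) by nonlinear least squares
with standard errors from the curvature of the objective at the
optimum. When the largest probe concentration is below the fitted
K_D, no saturation was observed and the estimate is flagged as poorly
identified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


class InsufficientDataError(ValueError):
    """Fewer than three distinct concentrations."""


@dataclass
class KineticsDataset:
    """(concentration nM, rate) points; replicates allowed."""

    concentrations_nM: Sequence[float]
    rates: Sequence[float]
    tbp_concentration_nM: float = 2.0

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations_nM, dtype=float)
        v = np.asarray(self.rates, dtype=float)
        if c.shape != v.shape or c.ndim != 1:
            raise ValueError("concentrations and rates must be equal-length")
        if np.any(c <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(v < 0):
            raise ValueError("rates must be non-negative")
        if len(np.unique(c)) < 3:
            raise InsufficientDataError(
                "need at least 3 distinct concentrations"
            )
        self.concentrations_nM = c
        self.rates = v


@dataclass
class KdFit:
    kd_nM: float
    kd_sem_nM: float
    vmax: float
    vmax_sem: float
    converged: bool
    identifiability_warning: bool
    rss: float = float("nan")


def _hyperbola(c, vmax, kd):
    return vmax * c / (kd + c)


class SaturationKinetics(BaseEstimator, RegressorMixin):
    """One-site saturation-binding fit (scikit-learn interface).

    ``fit(c, v)`` estimates K_D and Vmax; fitted attributes are
    ``kd_nM_``, ``kd_sem_nM_``, ``vmax_``, ``vmax_sem_``,
    ``converged_`` and ``identifiability_warning_``. Initialisation:
    Vmax0 = max rate, K_D0 = concentration nearest half-max; both
    parameters bounded positive.
    """

    def __init__(self, max_nfev: int = 10000):
        self.max_nfev = max_nfev

    def fit(self, X, y) -> "SaturationKinetics":
        data = KineticsDataset(np.ravel(X), np.asarray(y, dtype=float))
        c, v = data.concentrations_nM, data.rates
        vmax0 = float(v.max()) or 1.0
        kd0 = float(c[np.argmin(np.abs(v - vmax0 / 2))])
        self.converged_ = True
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    _hyperbola, c, v, p0=(vmax0, kd0),
                    bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                    max_nfev=self.max_nfev,
                )
        except RuntimeError:
            self.converged_ = False
            popt = np.array([vmax0, kd0])
            pcov = np.full((2, 2), np.nan)
        self.vmax_, self.kd_nM_ = float(popt[0]), float(popt[1])
        sems = np.sqrt(np.diag(pcov))
        self.vmax_sem_, self.kd_sem_nM_ = float(sems[0]), float(sems[1])
        self.identifiability_warning_ = bool(c.max() < self.kd_nM_)
        self.rss_ = float(np.sum((v - _hyperbola(c, *popt)) ** 2))
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "kd_nM_")
        return _hyperbola(np.ravel(np.asarray(X, dtype=float)),
                          self.vmax_, self.kd_nM_)


def fit_kd(data: KineticsDataset) -> KdFit:
    """Fit the one-site saturation model to a kinetics dataset."""
    model = SaturationKinetics().fit(data.concentrations_nM, data.rates)
    return KdFit(
        kd_nM=model.kd_nM_,
        kd_sem_nM=model.kd_sem_nM_,
        vmax=model.vmax_,
        vmax_sem=model.vmax_sem_,
        converged=model.converged_,
        identifiability_warning=model.identifiability_warning_,
        rss=model.rss_,
    )
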