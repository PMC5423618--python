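"""Deterministic growth mathematics.

The height of a plant at age ``T`` (years since fire) follows the Hillslope
equation, a three-parameter re-parameterisation of the logistic curve::

    mu(T) = alpha / (1 + exp(-b * (T - c)))

with ``alpha`` the asymptotic height (cm), ``b`` the maximum relative growth
rate (cm cm^-1 yr^-1) and ``c`` the age at which absolute growth peaks (yrs).
Observed heights scatter around the curve with multiplicative (lognormal)
noise; the curve value is the *median* of the observation distribution (the
lognormal's log-scale location is ``log mu``).

Derived rates:

* absolute growth rate  AGR(T) = dmu/dT = alpha * b * s * (1 - s)
* relative growth rate  RGR(T) = (1/mu) dmu/dT = b * (1 - mu/alpha)

where ``s = 1 / (1 + exp(-b (T - c)))``.  AGR peaks at ``T = c`` with value
``alpha * b / 4``; RGR decreases monotonically with age and approaches ``b``
as ``mu -> 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

_LOG_2PI = float(np.log(2.0 * np.pi))

__all__ = [
    "GrowthParams",
    "PredictedTrajectory",
    "hillslope_height",
    "absolute_growth_rate",
    "relative_growth_rate",
    "lognormal_loglik",
    "log_sd_to_precision",
    "precision_to_log_sd",
]


@dataclass(frozen=True)
class GrowthParams:
    """Species-level growth parameters of the Hillslope curve.

    All three parameters are strictly positive; in the hierarchical model
    they are formed through an exponential link, which guarantees this.
    """

    alpha: float  #: asymptotic height, cm
    b: float  #: maximum relative growth rate, cm cm^-1 yr^-1
    c: float  #: age at maximum (absolute) growth, yrs

    def __post_init__(self) -> None:
        for name in ("alpha", "b", "c"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"GrowthParams.{name} must be finite and > 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.b, self.c], dtype=float)


def _check_age(age):
    age = np.asarray(age, dtype=float)
    if not np.all(np.isfinite(age)):
        raise ValueError("age must be finite (no NaN/inf)")
    return age


def hillslope_height(params: GrowthParams, age) -> np.ndarray | float:
    """Median height (cm) at ``age`` years, stable for any |b*(T-c)|."""
    age = _check_age(age)
    out = params.alpha * expit(params.b * (age - params.c))
    return out if out.ndim else float(out)


def absolute_growth_rate(params: GrowthParams, age) -> np.ndarray | float:
    """dmu/dT in cm yr^-1; maximal at ``T = c`` where it equals alpha*b/4."""
    age = _check_age(age)
    s = expit(params.b * (age - params.c))
    out = params.alpha * params.b * s * (1.0 - s)
    return out if out.ndim else float(out)


def relative_growth_rate(params: GrowthParams, age) -> np.ndarray | float:
    """(1/mu) dmu/dT in cm cm^-1 yr^-1; decreasing in age, supremum ``b``."""
    age = _check_age(age)
    s = expit(params.b * (age - params.c))
    out = params.b * (1.0 - s)
    return out if out.ndim else float(out)


def lognormal_loglik(height_cm, mu_cm, sigma_log) -> np.ndarray | float:
    """Log density of a lognormal with median ``mu_cm`` and log-sd ``sigma_log``.

    Summed over a dataset this is the observation log likelihood of the
    growth model.  ``mu_cm`` is the median of the distribution (log-scale
    location = ``log mu_cm``), matching the process-model convention.
    """
    h = np.asarray(height_cm, dtype=float)
    mu = np.asarray(mu_cm, dtype=float)
    if np.any(h <= 0) or np.any(~np.isfinite(h)):
        raise ValueError("height_cm must be finite and > 0")
    if np.any(mu <= 0) or np.any(~np.isfinite(mu)):
        raise ValueError("mu_cm must be finite and > 0")
    if np.any(np.asarray(sigma_log) <= 0):
        raise ValueError("sigma_log must be > 0")
    z = (np.log(h) - np.log(mu)) / sigma_log
    out = -0.5 * z * z - np.log(sigma_log) - 0.5 * _LOG_2PI - np.log(h)
    return out if out.ndim else float(out)


def log_sd_to_precision(sigma_log: float) -> float:
    """Convert log-scale sd to the precision (sigma^-2) convention."""
    if sigma_log <= 0:
        raise ValueError("sigma_log must be > 0")
    return sigma_log**-2


def precision_to_log_sd(tau: float) -> float:
    """Convert a precision (sigma^-2) to the log-scale sd."""
    if tau <= 0:
        raise ValueError("precision must be > 0")
    return tau**-0.5


@dataclass
class PredictedTrajectory:
    """A growth trajectory on an age grid with optional credible band."""

    ages: np.ndarray
    expected_height: np.ndarray  #: posterior-median height, cm
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    species: str | None = None
    draws: np.ndarray | None = field(default=None, repr=False)  #: (n_draws, n_ages)

    def to_frame(self) -> pd.DataFrame:
        d = {"age_yrs": self.ages, "height_cm": self.expected_height}
        if self.lower is not None:
            d["lower_cm"] = self.lower
        if self.upper is not None:
            d["upper_cm"] = self.upper
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
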