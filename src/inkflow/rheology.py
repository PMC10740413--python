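"""Power-law (Ostwald-de Waele) rheology of shear-thinning bioprinting inks.

A printable hydrogel ink is characterised here by the two-parameter
constitutive model

    eta(gamma_dot) = K * gamma_dot**(n - 1)

where ``eta`` is the apparent viscosity in Pa*s, ``gamma_dot`` the shear
rate in 1/s, ``K`` the consistency coefficient in Pa*s**n (the viscosity at
unit shear rate) and ``n`` the dimensionless power-law index.  ``n < 1``
means shear thinning, the property that lets a viscous ink flow through a
fine nozzle.

Fitting is done by ordinary least squares in log-log space, where the model
is exactly linear: ``log eta = log K + (n - 1) * log gamma_dot``.  On
noise-free power-law data the fit recovers the generating parameters to
machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PowerLawParams",
    "ShearViscosityCurve",
    "PowerLawFit",
    "power_law_viscosity",
    "fit_power_law",
    "read_curve_csv",
    "write_curve_csv",
]


class InsufficientDataError(ValueError):
    """Fewer points than the fit requires."""


class DegenerateDesignError(ValueError):
    """No variance in log shear rate; slope is unidentifiable."""


@dataclass(frozen=True)
class PowerLawParams:
    """Power-law constitutive parameters.

    Attributes
    ----------
    n : float
        Power-law index (dimensionless), > 0.  Shear-thinning iff n < 1
        (not enforced).
    K : float
        Consistency coefficient in Pa*s**n, > 0.
    """

    n: float
    K: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.n) and self.n > 0):
            raise ValueError(f"power-law index must be finite and > 0, got {self.n}")
        if not (np.isfinite(self.K) and self.K > 0):
            raise ValueError(f"consistency coefficient must be finite and > 0, got {self.K}")


@dataclass(frozen=True)
class ShearViscosityCurve:
    """A measured (or synthesised) shear-rate/viscosity flow curve.

    ``shear_rates`` (1/s) must be strictly increasing and positive;
    ``viscosities`` (Pa*s) positive and of equal length (>= 2).
    ``temperature_c`` is carried as an annotation only.
    """

    shear_rates: np.ndarray
    viscosities: np.ndarray
    temperature_c: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        g = np.asarray(self.shear_rates, dtype=float)
        v = np.asarray(self.viscosities, dtype=float)
        object.__setattr__(self, "shear_rates", g)
        object.__setattr__(self, "viscosities", v)
        if g.ndim != 1 or v.ndim != 1 or g.shape != v.shape:
            raise ValueError("shear_rates and viscosities must be 1-D of equal length")
        if g.size < 2:
            raise InsufficientDataError("a flow curve needs at least 2 points")
        if not (np.all(np.isfinite(g)) and np.all(np.isfinite(v))):
            raise ValueError("flow-curve values must be finite")
        if np.any(g <= 0) or np.any(v <= 0):
            raise ValueError("shear rates and viscosities must be positive")
        if np.any(np.diff(g) <= 0):
            raise ValueError("shear rates must be strictly increasing")

    def __len__(self) -> int:
        return int(self.shear_rates.size)


@dataclass(frozen=True)
class PowerLawFit:
    """Result of :func:`fit_power_law`: parameters plus log-log goodness of fit."""

    params: PowerLawParams
    r_squared: float


def power_law_viscosity(params: PowerLawParams, shear_rate):
    """Apparent viscosity eta = K * gamma_dot**(n-1) in Pa*s.

    ``shear_rate`` (1/s) may be a scalar or array; all values must be > 0.
    At unit shear rate the viscosity equals K for any n.
    """
    g = np.asarray(shear_rate, dtype=float)
    if np.any(g <= 0) or not np.all(np.isfinite(g)):
        raise ValueError("shear rate must be finite and > 0")
    out = params.K * g ** (params.n - 1.0)
    return float(out) if np.isscalar(shear_rate) else out


def fit_power_law(curve: ShearViscosityCurve) -> PowerLawFit:
    """Fit (n, K) by unweighted OLS of log viscosity on log shear rate.

    Returns the parameters and the coefficient of determination of the
    straight-line fit in log-log space.  Raises
    :class:`DegenerateDesignError` when all shear rates coincide in log
    space (cannot happen for a valid curve, kept for defensive clarity).
    """
    x = np.log(curve.shear_rates)
    y = np.log(curve.viscosities)
    if np.ptp(x) == 0.0:
        raise DegenerateDesignError("zero variance in log shear rate")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(params=PowerLawParams(n=slope + 1.0, K=float(np.exp(intercept))),
                       r_squared=r2)


_CURVE_COLUMNS = ["shear_rate_per_s", "viscosity_pa_s"]


def read_curve_csv(path) -> ShearViscosityCurve:
    """Read a flow curve from CSV with columns ``shear_rate_per_s, viscosity_pa_s``."""
    df = pd.read_csv(path)
    missing = [c for c in _CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"curve CSV missing columns: {missing}")
    return ShearViscosityCurve(df["shear_rate_per_s"].to_numpy(),
                               df["viscosity_pa_s"].to_numpy())


def write_curve_csv(curve: ShearViscosityCurve, path) -> None:
    pd.DataFrame({
        "shear_rate_per_s": curve.shear_rates,
        "viscosity_pa_s": curve.viscosities,
    }).to_csv(path, index=False)
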