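"""Capacity scaling of capital expense and staffing.

Capital cost engineering conventionally relates plant cost to capacity
through a power law, ``cost = a * capacity^b`` with ``b < 1`` expressing
economy of scale.  The same form is used here for full-time-equivalent
staffing (FTEs).  Models are fitted by ordinary least squares on the
log-log scale, where the power law is linear and the noise on published
build costs is plausibly multiplicative.

Fermentation plants fed directly with sugars need no preprocessing train,
which removes about 25% of equipment cost, roughly a 14% cut in total
capital expenditure (multiplier 0.86).  Simple waste streams (cassava,
bread waste) need only grinding/blending/centrifugation and are credited
half of that saving (0.93).  Lignocellulosic feeds retain the full plant
(1.00).  The multiplier travels with the feedstock profile and is applied
to the fitted prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from pydantic import BaseModel, ConfigDict

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .assumptions import FeedstockProfile, PlantSpec, RegionProfile

logger = logging.getLogger(__name__)

#: Fermentation working-volume range (L) the cost relations were built for.
MODELED_CAPACITY_RANGE = (5e4, 1.5e7)


@dataclass(frozen=True)
class BuildRecord:
    """One observed plant build: capacity (L) and inflation-adjusted CapEx (USD).

    ``ftes`` is optional staffing for the same plant, used when fitting the
    labor model; ``region`` is informational only (location shows no clear
    relation to build cost and is excluded as a covariate).
    """

    capacity_l: float
    capex_usd: float
    ftes: Optional[float] = None
    region: Optional[str] = None


class ScalingModel(BaseModel):
    """Fitted log-log (power-law) relation of a cost driver vs capacity.

    ``prediction = exp(log_intercept) * capacity ** exponent``.
    ``r_squared`` is the coefficient of determination on the log scale,
    i.e. in the residual space of the fit.
    """

    model_config = ConfigDict(extra="forbid")

    log_intercept: float
    exponent: float
    r_squared: float
    n_points: int

    def predict(self, capacity_l: float) -> float:
        if self.n_points < 2:
            raise ValueError("scaling model is not fitted (n_points < 2)")
        return float(np.exp(self.log_intercept) * capacity_l**self.exponent)


def fit_power_law(x: Sequence[float], y: Sequence[float]) -> ScalingModel:
    """OLS fit of log(y) on log(x); both inputs must be strictly positive."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.unique(x).size < 2:
        raise ValueError("degenerate fit: need >= 2 distinct capacities")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive data")
    res = sm.OLS(np.log(y), sm.add_constant(np.log(x))).fit()
    # rsquared is NaN for a perfect 2-point fit (zero total variation in
    # residual dof terms is fine, but guard the exactly-determined case).
    r2 = float(res.rsquared) if np.isfinite(res.rsquared) else 1.0
    return ScalingModel(
        log_intercept=float(res.params[0]),
        exponent=float(res.params[1]),
        r_squared=min(max(r2, 0.0), 1.0),
        n_points=int(x.size),
    )


def fit_scaling_model(builds: Sequence[BuildRecord]) -> ScalingModel:
    """Fit the CapEx-vs-capacity power law from observed plant builds."""
    if len(builds) < 2:
        raise ValueError("degenerate fit: need >= 2 build records")
    return fit_power_law(
        [b.capacity_l for b in builds], [b.capex_usd for b in builds]
    )


def fit_labor_model(builds: Sequence[BuildRecord]) -> ScalingModel:
    """Fit the FTE-vs-capacity power law from builds carrying staffing data."""
    staffed = [b for b in builds if b.ftes is not None]
    if len(staffed) < 2:
        raise ValueError("degenerate fit: need >= 2 records with FTE data")
    return fit_power_law(
        [b.capacity_l for b in staffed], [b.ftes for b in staffed]
    )


def predict_capex(
    model: ScalingModel, plant: "PlantSpec", feedstock: "FeedstockProfile"
) -> float:
    """Predicted total CapEx (USD) for a plant, feedstock multiplier applied.

    Capacities outside the modeled range are extrapolated with a logged
    warning rather than rejected.
    """
    cap = plant.fermentation_capacity_l
    lo, hi = MODELED_CAPACITY_RANGE
    if not (lo <= cap <= hi):
        logger.warning(
            "capacity %.3g L outside modeled range [%.3g, %.3g]; extrapolating",
            cap,
            lo,
            hi,
        )
    return model.predict(cap) * feedstock.capex_multiplier


def annual_depreciation(capex_usd: float, years: int) -> float:
    """Straight-line depreciation: CapEx spread evenly over ``years``."""
    if capex_usd <= 0:
        raise ValueError("capex_usd must be positive")
    if years <= 0:
        raise ValueError("depreciation years must be positive")
    return capex_usd / years


def predict_ftes(labor_model: ScalingModel, capacity_l: float) -> float:
    """Predicted staffing at a capacity, as a positive real (not rounded)."""
    if labor_model.n_points < 2:
        raise ValueError("labor model is not fitted")
    return labor_model.predict(capacity_l)


def annual_labor_cost(ftes: float, region: "RegionProfile") -> float:
    """Annual labor cost: FTEs x salary multiplier x regional operator salary.

    The multiplier (default 2x) covers the skilled-technician premium plus
    overhead relative to the average machine-operator salary.
    """
    if ftes < 0:
        raise ValueError("ftes must be non-negative")
    return ftes * region.salary_multiplier * region.operator_salary_usd_per_year
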