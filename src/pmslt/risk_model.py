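"""BMI exposure distributions and the potential impact fraction.

BMI in each stratum follows a lognormal distribution parameterized from
its arithmetic mean and standard deviation.  The distribution is divided
into five categories at cutpoints 25, 30, 35 and 40 BMI units; each
category carries a proportion ``p_i`` (integral of the density between
the cutpoints) and a representative exposure level (mean of the lognormal
truncated to the category).  Relative risk per BMI unit ``rr_unit``
induces category relative risks ``RR_i = rr_unit**(m_i - m_1)`` relative
to the reference (lowest) category.  An intervention that removes
``delta_bmi`` units from eligible categories shifts their relative risks
down (floored at 1), and the resulting potential impact fraction

    PIF = (sum p_i RR_i - sum p_i RR'_i) / (sum p_i RR_i)

is the proportional reduction in average disease incidence.

All numeric helpers broadcast over leading axes so the pipeline can
evaluate whole stratum-by-year grids at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr

#: Category cutpoints on the BMI scale; categories are
#: (0,25], (25,30], (30,35], (35,40], (40, inf).
CUTPOINTS: tuple[float, ...] = (25.0, 30.0, 35.0, 40.0)
N_CATEGORIES = 5

#: kg of body weight per BMI unit (30 kg ~ 10 BMI units).
KG_PER_BMI_UNIT = 3.2

#: Eligible BMI categories (1-based) per intervention scenario.
ELIGIBLE_CATEGORIES = {"bmi40": frozenset({5}), "bmi35": frozenset({4, 5})}

#: Years over which the secular BMI trend keeps accumulating.
BMI_TREND_HORIZON_YEARS = 20.0


def lognormal_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    """Lognormal ``(mu, sigma)`` matching an arithmetic mean and SD.

    ``sigma**2 = ln(1 + sd**2 / mean**2)`` and
    ``mu = ln(mean) - sigma**2 / 2``, so the back-transformed arithmetic
    moments reproduce the inputs exactly.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(mean <= 0) or np.any(sd < 0):
        raise ValueError("mean must be > 0 and sd >= 0")
    sigma2 = np.log1p(sd**2 / mean**2)
    sigma = np.sqrt(sigma2)
    mu = np.log(mean) - sigma2 / 2.0
    if mu.ndim == 0:
        return float(mu), float(sigma)
    return mu, sigma


def _lognorm_cdf(x, mu, sigma):
    """CDF of the lognormal, vectorized; handles sigma == 0 point mass."""
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.log(x) - mu) / sigma
    degenerate = sigma == 0
    if np.any(degenerate):
        point = np.where(np.log(x) >= mu, 1.0, 0.0)
        return np.where(degenerate, point, ndtr(np.where(degenerate, 0.0, z)))
    return ndtr(z)


def _category_bounds() -> tuple[np.ndarray, np.ndarray]:
    lower = np.array([0.0, *CUTPOINTS])
    upper = np.array([*CUTPOINTS, np.inf])
    return lower, upper


def category_proportions(mu, sigma) -> np.ndarray:
    """Proportion of the population in each of the five BMI categories.

    ``p_i = CDF(upper_i) - CDF(lower_i)``; the five values telescope to 1.
    Broadcasts: for array ``mu``/``sigma`` of shape S the result has shape
    ``S + (5,)``.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    lower, upper = _category_bounds()
    cdf_lo = np.empty(mu.shape + (N_CATEGORIES,))
    cdf_hi = np.empty(mu.shape + (N_CATEGORIES,))
    for i in range(N_CATEGORIES):
        cdf_lo[..., i] = 0.0 if lower[i] == 0.0 else _lognorm_cdf(lower[i], mu, sigma)
        cdf_hi[..., i] = 1.0 if np.isinf(upper[i]) else _lognorm_cdf(upper[i], mu, sigma)
    p = np.clip(cdf_hi - cdf_lo, 0.0, 1.0)
    return p


def category_means(mu, sigma) -> np.ndarray:
    """Mean BMI of the lognormal truncated to each category.

    E[X | a < X <= b] = exp(mu + sigma^2/2)
        * (Phi((ln b - mu - sigma^2)/sigma) - Phi((ln a - mu - sigma^2)/sigma))
        / (CDF(b) - CDF(a))

    Empty categories (p_i ~ 0) fall back to the interval midpoint (lower
    bound + half the reference width for the open top category) so that
    downstream relative-risk powers remain finite; they carry no weight.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    lower, upper = _category_bounds()
    p = category_proportions(mu, sigma)
    shifted_mu = mu + sigma**2  # lognormal partial-moment shift
    arith_mean = np.exp(mu + sigma**2 / 2.0)
    out = np.empty(mu.shape + (N_CATEGORIES,))
    for i in range(N_CATEGORIES):
        lo, hi = lower[i], upper[i]
        f_lo = 0.0 if lo == 0.0 else _lognorm_cdf(lo, shifted_mu, sigma)
        f_hi = 1.0 if np.isinf(hi) else _lognorm_cdf(hi, shifted_mu, sigma)
        with np.errstate(divide="ignore", invalid="ignore"):
            m = arith_mean * (f_hi - f_lo) / p[..., i]
        fallback = (lo + hi) / 2.0 if np.isfinite(hi) else lo + 5.0
        out[..., i] = np.where(p[..., i] > 1e-300, m, fallback)
    return out


@dataclass(frozen=True)
class BMIExposure:
    """Lognormal BMI exposure for one stratum, with its category partition."""

    mean: float
    sd: float
    mu: float = field(init=False)
    sigma: float = field(init=False)

    def __post_init__(self) -> None:
        mu, sigma = lognormal_from_mean_sd(self.mean, self.sd)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    @property
    def proportions(self) -> np.ndarray:
        return category_proportions(self.mu, self.sigma)

    @property
    def means(self) -> np.ndarray:
        return category_means(self.mu, self.sigma)


@dataclass(frozen=True)
class ExposureShift:
    """An intervention removing ``delta_bmi`` units from eligible categories."""

    delta_bmi: float
    eligible_categories: frozenset[int]

    def __post_init__(self) -> None:
        if self.delta_bmi < 0:
            raise ValueError("delta_bmi must be >= 0")
        if not self.eligible_categories <= set(range(1, N_CATEGORIES + 1)):
            raise ValueError("eligible categories must be within 1..5")


@dataclass(frozen=True)
class DiseaseRisk:
    """Category relative risks for one disease, before and after shifting."""

    rr_unit: float
    rr: np.ndarray
    rr_shifted: np.ndarray | None = None


def category_relative_risks(rr_unit: float, exposure: BMIExposure) -> np.ndarray:
    """RR_i = rr_unit ** (m_i - m_1), with the lowest category as reference."""
    if rr_unit < 1.0:
        raise ValueError("rr_unit must be >= 1 (protective exposures out of scope)")
    m = exposure.means
    return rr_unit ** (m - m[..., 0:1])


def shift_relative_risks(
    risk: DiseaseRisk, shift: ExposureShift
) -> np.ndarray:
    """Post-intervention RR'_i = max(1, RR_i * rr_unit**(-delta_bmi)).

    Only eligible categories are shifted; the floor at 1 prevents treated
    risk from dropping below the reference category.
    """
    rr = np.asarray(risk.rr, dtype=float)
    shifted = rr.copy()
    factor = risk.rr_unit ** (-shift.delta_bmi)
    for cat in shift.eligible_categories:
        shifted[..., cat - 1] = np.maximum(1.0, rr[..., cat - 1] * factor)
    return shifted


def potential_impact_fraction(p, rr, rr_shifted) -> float | np.ndarray:
    """PIF = (sum p RR - sum p RR') / (sum p RR); sums over the last axis."""
    p = np.asarray(p, dtype=float)
    rr = np.asarray(rr, dtype=float)
    rr_shifted = np.asarray(rr_shifted, dtype=float)
    before = np.sum(p * rr, axis=-1)
    after = np.sum(p * rr_shifted, axis=-1)
    if np.any(before == 0):
        raise ValueError("sum(p * RR) is zero; PIF undefined")
    pif = (before - after) / before
    if pif.ndim == 0:
        return float(pif)
    return pif


def adjust_incidence(incidence, pif):
    """Post-intervention incidence I' = I * (1 - PIF)."""
    return np.asarray(incidence, dtype=float) * (1.0 - np.asarray(pif, dtype=float))


def apply_bmi_trend(
    exposure: BMIExposure,
    years_elapsed: float,
    annual_increment: float,
    horizon_years: float = BMI_TREND_HORIZON_YEARS,
) -> BMIExposure:
    """Shift the arithmetic mean by the secular trend, capped at the horizon.

    SD is held fixed; lognormal parameters are re-derived from the new
    mean.  The trend stops accumulating after ``horizon_years``.
    """
    if years_elapsed < 0:
        raise ValueError("years_elapsed must be >= 0")
    shift = annual_increment * min(years_elapsed, horizon_years)
    if shift == 0.0:
        return exposure
    return replace(exposure, mean=exposure.mean + shift)


def kg_to_bmi_units(kg: float, kg_per_unit: float = KG_PER_BMI_UNIT) -> float:
    """Convert absolute weight loss in kg to BMI units."""
    return kg / kg_per_unit
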