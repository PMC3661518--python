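"""The master proportional multi-state life table.

All-cause mortality ``m+`` and disability ``w+`` are decomposed into
"all other causes" residuals ``m-``/``w-`` by subtracting the modelled
diseases' pre-intervention contributions; revised post-intervention
disease terms are added back, and the recomposed rates drive an abridged
cohort life table (annual cycles, half-cycle person-years, closure at
age 100).  Comparing disability-adjusted life years between the
intervention and reference arms, discounted from the intervention start,
gives DALYs averted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InputConsistencyError",
    "CohortResult",
    "decompose_other_causes",
    "recompose_total",
    "run_master_lifetable",
    "dalys_averted",
    "discount_factors",
]


class InputConsistencyError(ValueError):
    """Raised when modelled-disease terms exceed the all-cause totals."""


def decompose_other_causes(
    m_total: np.ndarray,
    w_total: np.ndarray,
    disease_mortality: np.ndarray,
    disease_pyld: np.ndarray,
    ages: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Residual mortality and pYLD rates excluding the modelled diseases.

    ``disease_mortality``/``disease_pyld`` have shape ``(n_diseases,
    n_ages)`` (a single disease may be passed as 1-D).  Raises
    :class:`InputConsistencyError` naming the first offending age and
    quantity if a residual would go negative.
    """
    m_total = np.asarray(m_total, dtype=float)
    w_total = np.asarray(w_total, dtype=float)
    md = np.atleast_2d(np.asarray(disease_mortality, dtype=float))
    wd = np.atleast_2d(np.asarray(disease_pyld, dtype=float))
    m_minus = m_total - md.sum(axis=0)
    w_minus = w_total - wd.sum(axis=0)
    if ages is None:
        ages = np.arange(len(m_total))
    for name, resid in (("mortality", m_minus), ("pYLD", w_minus)):
        bad = np.flatnonzero(resid < 0)
        if bad.size:
            raise InputConsistencyError(
                f"modelled-disease {name} exceeds the all-cause rate at age "
                f"{int(ages[bad[0]])}"
            )
    return m_minus, w_minus


def recompose_total(
    m_minus: np.ndarray,
    w_minus: np.ndarray,
    disease_mortality: np.ndarray,
    disease_pyld: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Add revised disease terms back onto the all-other-cause residuals."""
    md = np.atleast_2d(np.asarray(disease_mortality, dtype=float))
    wd = np.atleast_2d(np.asarray(disease_pyld, dtype=float))
    return (
        np.asarray(m_minus, dtype=float) + md.sum(axis=0),
        np.asarray(w_minus, dtype=float) + wd.sum(axis=0),
    )


@dataclass
class CohortResult:
    """One simulated cohort: survivorship and (disability-adjusted) life years.

    Arrays are indexed by year of simulation; year ``t`` (1-based) covers
    age ``start_age + t - 1``.  ``survivors`` has one extra trailing entry
    (the count entering the year after closure, forced to 0 at age 101).
    """

    start_age: int
    cohort_size: float
    ages: np.ndarray
    survivors: np.ndarray  # l_x, length n_years + 1
    person_years: np.ndarray  # L_x
    adjusted_person_years: np.ndarray  # Lw_x
    life_expectancy: np.ndarray  # e_x
    dale: np.ndarray  # disability-adjusted life expectancy

    @property
    def n_years(self) -> int:
        return len(self.ages)

    @property
    def total_life_years(self) -> float:
        return float(self.person_years.sum())

    @property
    def total_adjusted_life_years(self) -> float:
        return float(self.adjusted_person_years.sum())

    def discounted_adjusted_life_years(self, rate: float) -> float:
        return float(self.adjusted_person_years @ discount_factors(rate, self.n_years))


def discount_factors(rate: float, n_years: int) -> np.ndarray:
    """Factors (1+rate)^-t for years t = 1..n_years.

    Life years lived during simulation year t are discounted one full
    year per elapsed year; the intervention outlay at t = 0 is not
    discounted.
    """
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    t = np.arange(1, n_years + 1, dtype=float)
    return (1.0 + rate) ** (-t)


def run_master_lifetable(
    mortality: np.ndarray,
    pyld: np.ndarray,
    start_age: int,
    cohort_size: float = 1.0,
    extra_mortality: np.ndarray | None = None,
) -> CohortResult:
    """Run the abridged cohort life table from ``start_age`` to age 100.

    ``mortality`` and ``pyld`` are per-age rates for ages ``start_age``
    through 100.  ``extra_mortality`` is an optional vector of annual
    death *probabilities* (e.g. post-surgical risk in years 1-2) combined
    with the rate-derived probability as independent risks.  The table is
    closed at age 100 (everyone alive at 100 dies during that year);
    person-years use the half-cycle convention ``L = (l_x + l_{x+1})/2``.
    """
    m = np.asarray(mortality, dtype=float)
    w = np.asarray(pyld, dtype=float)
    n = len(m)
    if w.shape != (n,):
        raise ValueError("mortality and pyld must have equal length")
    ages = np.arange(start_age, start_age + n)
    if ages[-1] != 100:
        raise ValueError("rates must extend exactly to age 100")
    if np.any(m < 0) or np.any(w < 0) or np.any(w >= 1):
        raise ValueError("rates out of range: need m >= 0 and 0 <= w < 1")

    q = -np.expm1(-m)
    if extra_mortality is not None:
        qx = np.zeros(n)
        extra = np.asarray(extra_mortality, dtype=float)
        qx[: len(extra)] = extra[:n]
        q = 1.0 - (1.0 - q) * (1.0 - qx)
    q[-1] = 1.0  # closure: nobody survives past age 100

    survivors = np.empty(n + 1)
    survivors[0] = cohort_size
    survivors[1:] = cohort_size * np.cumprod(1.0 - q)
    L = (survivors[:-1] + survivors[1:]) / 2.0
    Lw = L * (1.0 - w)

    rev_L = np.cumsum(L[::-1])[::-1]
    rev_Lw = np.cumsum(Lw[::-1])[::-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(survivors[:-1] > 0, rev_L / survivors[:-1], 0.0)
        dale = np.where(survivors[:-1] > 0, rev_Lw / survivors[:-1], 0.0)

    return CohortResult(
        start_age=start_age,
        cohort_size=cohort_size,
        ages=ages,
        survivors=survivors,
        person_years=L,
        adjusted_person_years=Lw,
        life_expectancy=e,
        dale=dale,
    )


def dalys_averted(
    reference: CohortResult, intervention: CohortResult, discount_rate: float = 0.0
) -> float:
    """Discounted gain in disability-adjusted life years, intervention vs reference."""
    if (
        reference.start_age != intervention.start_age
        or reference.n_years != intervention.n_years
    ):
        raise ValueError("reference and intervention cohorts do not match")
    diff = intervention.adjusted_person_years - reference.adjusted_person_years
    return float(diff @ discount_factors(discount_rate, reference.n_years))
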