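"""Costs, cost offsets, net cost, ICER with dominance, and budget impact.

Cost accounting follows a single identity per run: total net cost equals
the initial surgery outlay plus the discounted stream of maintenance and
complication costs, plus the (negative) cost offsets from averted
disease, plus — in the relevant costing scenario only — the cost of
unrelated diseases during added life years.

The initial surgery cost (which bundles two years of follow-up) is booked
undiscounted at t = 0; annual maintenance/complication costs apply to
operated survivors from year three onwards; all later flows are
discounted annually.  Dominance: an intervention that saves money while
gaining healthy life years is labelled "dominant"; one that costs money
and loses health is "dominated".
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import Decimal

import numpy as np

from pmslt.lifetable import discount_factors

__all__ = [
    "CostSet",
    "BASELINE_COSTS",
    "TIME_TRAVEL_COSTS",
    "CEOutcome",
    "discount",
    "intervention_costs",
    "cost_offsets",
    "unrelated_disease_costs",
    "icer",
    "budget_impact",
    "run_scenario_grid",
]

#: Maintenance and complication costs start in this (1-based) year.
MAINTENANCE_START_YEAR = 3


@dataclass(frozen=True)
class CostSet:
    """Unit costs of one costing scenario (2003 AU$ per person)."""

    initial_surgery: float = 11_290.0
    annual_maintenance: float = 330.0
    annual_complications: float = 90.0

    def __post_init__(self) -> None:
        for name in ("initial_surgery", "annual_maintenance", "annual_complications"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


BASELINE_COSTS = CostSet(11_290.0, 330.0, 90.0)
#: Variant additionally valuing patients' time and travel.
TIME_TRAVEL_COSTS = CostSet(12_452.0, 1_126.0, 105.0)


@dataclass
class CEOutcome:
    """Aggregate cost-effectiveness result of one model evaluation."""

    scenario: str
    intervention_cost: float
    maintenance_cost: float
    cost_offsets: float  # signed: <= 0 when disease is averted
    unrelated_cost: float
    dalys_averted: float
    n_operated: float = 0.0
    label: str = "baseline"

    @property
    def net_cost(self) -> float:
        return (
            self.intervention_cost
            + self.maintenance_cost
            + self.cost_offsets
            + self.unrelated_cost
        )

    @property
    def icer(self) -> float | str:
        return icer(self.net_cost, self.dalys_averted)


def discount(value: float, rate: float, t_years: float) -> float:
    """Present value of ``value`` occurring ``t_years`` from now."""
    if rate < 0 or t_years < 0:
        raise ValueError("rate and t_years must be >= 0")
    return value / (1.0 + rate) ** t_years


def intervention_costs(
    operated_person_years: np.ndarray,
    n_operated: float,
    costs: CostSet,
    rate: float,
    complication_multiplier: float = 1.0,
) -> tuple[float, float]:
    """(initial outlay, discounted maintenance + complications).

    ``operated_person_years[t-1]`` is the person-years lived by operated
    survivors during (1-based) year ``t``; the annual maintenance +
    complication cost applies from year 3 to the end of the cohort.  The
    complication component scales with the complication-risk multiplier.
    """
    if complication_multiplier < 0:
        raise ValueError("complication_multiplier must be >= 0")
    initial = costs.initial_surgery * n_operated
    py = np.asarray(operated_person_years, dtype=float)
    annual = (
        costs.annual_maintenance
        + costs.annual_complications * complication_multiplier
    )
    factors = discount_factors(rate, len(py))
    mask = np.arange(1, len(py) + 1) >= MAINTENANCE_START_YEAR
    maintenance = float(annual * np.sum(py * factors * mask))
    return initial, maintenance


def cost_offsets(
    prevalent_averted: dict[str, np.ndarray],
    incident_averted: dict[str, np.ndarray],
    unit_costs: dict[str, float],
    cancer_flags: dict[str, bool],
    rate: float,
) -> float:
    """Signed cost offsets (negative = savings) from averted disease.

    Chronic diseases are costed per prevalent case-year averted; cancers
    per incident case averted (one-off at the incident year).  Inputs are
    per-disease arrays by (1-based) year: reference minus intervention.
    """
    if set(prevalent_averted) | set(incident_averted) != set(unit_costs):
        raise ValueError("disease sets of quantities and unit costs differ")
    total = 0.0
    for disease, cost in unit_costs.items():
        if cancer_flags[disease]:
            series = np.asarray(incident_averted[disease], dtype=float)
        else:
            series = np.asarray(prevalent_averted[disease], dtype=float)
        total += cost * float(series @ discount_factors(rate, len(series)))
    return -total


def unrelated_disease_costs(
    extra_person_years: np.ndarray, unit_cost_per_year: np.ndarray, rate: float
) -> float:
    """Cost of unrelated disease during added life years (scenario 4 only)."""
    py = np.asarray(extra_person_years, dtype=float)
    cost = np.asarray(unit_cost_per_year, dtype=float)
    if py.shape != cost.shape:
        raise ValueError("person-year and unit-cost vectors must align")
    return float((py * cost) @ discount_factors(rate, len(py)))


def icer(net_cost: float, dalys_averted: float) -> float | str:
    """ICER in AU$/DALY averted, or a dominance label.

    Negative net cost with positive health gain is "dominant"; positive
    net cost with health loss is "dominated".  Zero DALYs with nonzero
    net cost has no defined ratio and returns "undefined".
    """
    if dalys_averted == 0:
        return 0.0 if net_cost == 0 else "undefined"
    if net_cost < 0 and dalys_averted > 0:
        return "dominant"
    if net_cost > 0 and dalys_averted < 0:
        return "dominated"
    return net_cost / dalys_averted


def budget_impact(
    eligible_count: int | float,
    cost_per_person: int | float,
    govt_expenditure: int | float,
) -> tuple[float, float]:
    """(total outlay AU$, share of government health expenditure in %).

    Computed with decimal arithmetic so integer inputs give exact
    products.
    """
    if eligible_count < 0 or cost_per_person < 0 or govt_expenditure <= 0:
        raise ValueError("counts and costs must be >= 0, expenditure > 0")
    total = Decimal(str(eligible_count)) * Decimal(str(cost_per_person))
    percent = 100 * total / Decimal(str(govt_expenditure))
    return float(total), float(percent)


#: Rows of the sensitivity/costing grid, mirroring the published layout.
GRID_ROWS: tuple[tuple[str, dict], ...] = (
    ("baseline", {}),
    ("discount_0", {"discount_rate": 0.0}),
    ("discount_6", {"discount_rate": 0.06}),
    ("time_travel", {"costing": "time_travel"}),
    ("exclude_offsets", {"costing": "exclude_offsets"}),
    ("unrelated_costs", {"costing": "unrelated_costs"}),
    ("complications_x10", {"complication_multiplier": 10.0}),
    ("attenuation_15y", {"attenuation": 0.007}),
)


def run_scenario_grid(config) -> "pd.DataFrame":
    """Point-estimate runs of every sensitivity/costing row, both arms.

    Takes a :class:`pmslt.interface.RunConfig`; returns a tidy frame with
    one row per (scenario, sensitivity row).
    """
    import pandas as pd

    from pmslt.interface import build_reference, run_pipeline

    reference = build_reference(config.load_dataset())
    records = []
    for scenario in ("bmi40", "bmi35"):
        for label, overrides in GRID_ROWS:
            row_config = replace(config, scenario=scenario, **overrides)
            outcome = run_pipeline(row_config, reference=reference).outcome
            outcome.label = label
            records.append(
                {
                    "scenario": scenario,
                    "row": label,
                    "intervention_cost": outcome.intervention_cost,
                    "maintenance_cost": outcome.maintenance_cost,
                    "cost_offsets": outcome.cost_offsets,
                    "unrelated_cost": outcome.unrelated_cost,
                    "net_cost": outcome.net_cost,
                    "dalys_averted": outcome.dalys_averted,
                    "icer": outcome.icer,
                }
            )
    return pd.DataFrame(records)
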