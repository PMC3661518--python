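"""The surgical intervention layer: eligibility, weight loss, risks.

Weight loss after banding surgery rises piecewise-linearly from nothing
at surgery to 27.4 kg at two years and a 32.0 kg peak at three years,
then stays flat (or, in the attenuation sensitivity, decays geometrically
until year 15).  Post-surgical mortality applies in the first two years
only; small annual maintenance/complication risks run from year three.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pmslt.risk_model import (
    ELIGIBLE_CATEGORIES,
    KG_PER_BMI_UNIT,
    BMIExposure,
)

__all__ = [
    "InterventionSpec",
    "weight_loss_at",
    "attenuated_weight_loss_at",
    "bmi_loss_at",
    "surgical_mortality_for_year",
    "eligible_fraction",
]

#: Annual long-term complication risks per person-year from year three.
DEFAULT_COMPLICATION_RISKS: dict[str, float] = {
    "gastric_prolapse": 0.01,
    "band_erosion": 0.001,
    "port_infection": 0.002,
    "band_removal": 0.004,
}

#: Weight loss is assumed stable after this many years in the
#: attenuation sensitivity.
ATTENUATION_HORIZON_YEARS = 15.0
PEAK_YEAR = 3.0
TWO_YEAR = 2.0


@dataclass
class InterventionSpec:
    """Parameters of one surgery-provision scenario."""

    scenario: str = "bmi40"  # 'bmi40' (BMI > 40) or 'bmi35' (BMI > 35)
    peak_loss_kg: float = 32.0
    peak_loss_se: float = 1.62
    two_year_loss_kg: float = 27.4
    mortality_30d: float = 0.0006
    mortality_30d_se: float = 0.0003
    mortality_30d_2y: float = 0.0
    mortality_30d_2y_se: float = 0.0002
    complication_risks: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPLICATION_RISKS)
    )
    complication_risk_n: int = 1120  # denominator behind the beta PSA draws
    attenuation: float = 0.0  # annual fractional decay of peak loss, years 3-15
    kg_per_bmi_unit: float = KG_PER_BMI_UNIT
    band_removal_reverts: bool = False  # efficacy loss on band removal (off: cost only)

    def __post_init__(self) -> None:
        if self.scenario not in ELIGIBLE_CATEGORIES:
            raise ValueError(f"scenario must be one of {sorted(ELIGIBLE_CATEGORIES)}")
        for name, p in (
            ("mortality_30d", self.mortality_30d),
            ("mortality_30d_2y", self.mortality_30d_2y),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if not 0.0 <= self.attenuation < 1.0:
            raise ValueError("attenuation fraction must be in [0, 1)")
        if not self.peak_loss_kg >= self.two_year_loss_kg >= 0.0:
            raise ValueError("need peak loss >= two-year loss >= 0")

    @property
    def eligible_categories(self) -> frozenset[int]:
        return ELIGIBLE_CATEGORIES[self.scenario]


def weight_loss_at(t: float, spec: InterventionSpec) -> float:
    """Weight loss (kg) ``t`` years after surgery, stable-plateau variant."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t <= TWO_YEAR:
        return spec.two_year_loss_kg * t / TWO_YEAR
    if t <= PEAK_YEAR:
        frac = (t - TWO_YEAR) / (PEAK_YEAR - TWO_YEAR)
        return spec.two_year_loss_kg + frac * (spec.peak_loss_kg - spec.two_year_loss_kg)
    return spec.peak_loss_kg


def attenuated_weight_loss_at(
    t: float, spec: InterventionSpec, annual_attenuation: float
) -> float:
    """Weight loss with geometric decay of the peak between years 3 and 15."""
    if not 0.0 <= annual_attenuation < 1.0:
        raise ValueError("annual_attenuation must be in [0, 1)")
    if t <= PEAK_YEAR:
        return weight_loss_at(t, spec)
    years_decaying = min(t, ATTENUATION_HORIZON_YEARS) - PEAK_YEAR
    return spec.peak_loss_kg * (1.0 - annual_attenuation) ** years_decaying


def bmi_loss_at(t: float, spec: InterventionSpec) -> float:
    """BMI-unit reduction ``t`` years after surgery (honours attenuation)."""
    if spec.attenuation > 0.0:
        kg = attenuated_weight_loss_at(t, spec, spec.attenuation)
    else:
        kg = weight_loss_at(t, spec)
    return kg / spec.kg_per_bmi_unit


def surgical_mortality_for_year(year_since_surgery: int, spec: InterventionSpec) -> float:
    """Post-surgical death probability applied in a given (1-based) year."""
    if year_since_surgery < 1:
        raise ValueError("year_since_surgery must be >= 1")
    if year_since_surgery == 1:
        return spec.mortality_30d
    if year_since_surgery == 2:
        return spec.mortality_30d_2y
    return 0.0


def eligible_fraction(exposure: BMIExposure, scenario: str) -> float:
    """Fraction of a stratum above the scenario's BMI threshold."""
    p = exposure.proportions
    cats = ELIGIBLE_CATEGORIES[scenario]
    return float(sum(p[c - 1] for c in cats))
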