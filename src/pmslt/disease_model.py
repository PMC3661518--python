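"""Per-disease illness-death life tables.

Each modelled disease gets a three-state life table (well -> diseased ->
dead of the disease) run conditionally on survival from all other causes
(the proportional assumption): annual rates of incidence ``i``, case
fatality ``f`` and remission ``r`` are converted to probabilities with
``P = 1 - exp(-rate)`` and iterated over single years of age:

    S[x+1] = S[x] * (1 - Pi) + C[x] * Pr
    C[x+1] = C[x] * (1 - Pf - Pr) + S[x] * Pi

The trajectory yields prevalence ``p = C / (S + C)``, disease-specific
mortality ``m_d = f * p`` and disability-adjusted prevalence
``pYLD_d = p * w_d`` by age — the quantities that are subtracted from and
added back to the master life table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pmslt.core import AGE_MIN, N_AGES

__all__ = [
    "DiseaseEpidemiology",
    "DiseaseTrajectory",
    "burn_in_prevalence",
    "run_disease_lifetable",
    "disease_mortality_and_pyld",
]

#: Years of the pre-adult burn-in used to seed prevalence at age 20.
BURN_IN_YEARS = 20


@dataclass
class DiseaseEpidemiology:
    """Rates for one disease on the shared age grid, per sex.

    ``incidence``, ``case_fatality`` and ``remission`` map sex to arrays
    over ages 20..100 (events per person-year).  Cancers are flagged for
    incidence-based costing; the remaining (chronic) diseases are costed
    per prevalent case-year.
    """

    disease_id: str
    cancer: bool
    incidence: dict[str, np.ndarray]
    case_fatality: dict[str, np.ndarray]
    remission: dict[str, np.ndarray]
    disability_weight: float
    offset_cost: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.disability_weight < 1.0:
            raise ValueError("disability weight must be in (0, 1)")
        for name, table in (
            ("incidence", self.incidence),
            ("case_fatality", self.case_fatality),
            ("remission", self.remission),
        ):
            for sex, arr in table.items():
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (N_AGES,):
                    raise ValueError(
                        f"{name}[{sex}] must have {N_AGES} ages, got {arr.shape}"
                    )
                if np.any(arr < 0):
                    raise ValueError(f"{name}[{sex}] has negative rates")
                table[sex] = arr


@dataclass
class DiseaseTrajectory:
    """State fractions and derived rates by age for one disease run."""

    ages: np.ndarray
    susceptible: np.ndarray  # S_x, fraction of the (alive) cohort
    diseased: np.ndarray  # C_x
    prevalence: np.ndarray  # p_x = C / (S + C)
    mortality: np.ndarray  # m_dx = f_x * p_x
    pyld: np.ndarray  # p_x * w_d
    incident: np.ndarray = field(default=None)  # new cases per person alive, per year

    def __post_init__(self) -> None:
        if self.incident is None:
            self.incident = np.zeros_like(self.prevalence)


def _rate_to_prob(rate):
    return -np.expm1(-np.asarray(rate, dtype=float))


def burn_in_prevalence(
    incidence: float, case_fatality: float, remission: float, years: int = BURN_IN_YEARS
) -> float:
    """Seed prevalence at age 20 from a burn-in at constant young-adult rates.

    Iterates the illness-death recursion ``years`` times starting from a
    fully susceptible cohort.
    """
    p_i = _rate_to_prob(incidence)
    p_f = _rate_to_prob(case_fatality)
    p_r = _rate_to_prob(remission)
    s, c = 1.0, 0.0
    for _ in range(years):
        s, c = s * (1.0 - p_i) + c * p_r, c * (1.0 - p_f - p_r) + s * p_i
    total = s + c
    return float(c / total) if total > 0 else 0.0


def run_disease_lifetable(
    epi: DiseaseEpidemiology,
    sex: str,
    incidence_override: np.ndarray | None = None,
    p_init: float | None = None,
    start_age: int = AGE_MIN,
    start_state: tuple[float, float] | None = None,
) -> DiseaseTrajectory:
    """Run the annual illness-death recursion from ``start_age`` to 100.

    ``incidence_override`` (e.g. post-PIF incidence) replaces the baseline
    incidence on the same age grid.  The initial state defaults to the
    burn-in prevalence at the start-age rates; ``p_init`` or a full
    ``start_state = (S, C)`` may be supplied instead (the latter is how
    cohorts starting above age 20 inherit the baseline trajectory state).
    """
    i_full = epi.incidence[sex] if incidence_override is None else np.asarray(
        incidence_override, dtype=float
    )
    if i_full.shape != (N_AGES,):
        raise ValueError(f"incidence must cover all {N_AGES} ages")
    f_full = epi.case_fatality[sex]
    r_full = epi.remission[sex]

    lo = start_age - AGE_MIN
    i, f, r = i_full[lo:], f_full[lo:], r_full[lo:]
    n = len(i)
    ages = np.arange(start_age, start_age + n)

    p_i = _rate_to_prob(i)
    p_f = _rate_to_prob(f)
    p_r = _rate_to_prob(r)
    bad = np.flatnonzero(p_f + p_r > 1.0)
    if bad.size:
        age = int(ages[bad[0]])
        raise ValueError(
            f"case-fatality + remission probabilities exceed 1 at age {age}"
        )

    if start_state is not None:
        s0, c0 = start_state
    else:
        if p_init is None:
            p_init = burn_in_prevalence(float(i[0]), float(f[0]), float(r[0]))
        s0, c0 = 1.0 - p_init, p_init

    S = np.empty(n)
    C = np.empty(n)
    incident = np.empty(n)
    S[0], C[0] = s0, c0
    for k in range(n - 1):
        new_cases = S[k] * p_i[k]
        incident[k] = new_cases
        S[k + 1] = S[k] * (1.0 - p_i[k]) + C[k] * p_r[k]
        C[k + 1] = C[k] * (1.0 - p_f[k] - p_r[k]) + new_cases
    incident[n - 1] = S[n - 1] * p_i[n - 1]

    with np.errstate(invalid="ignore", divide="ignore"):
        alive = S + C
        prevalence = np.where(alive > 0, C / alive, 0.0)
        # new cases per person alive (the master table's alive counts
        # already net out disease deaths, so normalize by S + C)
        incident = np.where(alive > 0, incident / alive, 0.0)
    mortality = f * prevalence
    pyld = prevalence * epi.disability_weight
    return DiseaseTrajectory(
        ages=ages,
        susceptible=S,
        diseased=C,
        prevalence=prevalence,
        mortality=mortality,
        pyld=pyld,
        incident=incident,
    )


def disease_mortality_and_pyld(traj: DiseaseTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """The per-age terms this disease contributes to the master table."""
    return traj.mortality, traj.pyld
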