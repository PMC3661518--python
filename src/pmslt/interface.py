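"""Configuration and end-to-end orchestration of the pipeline.

``run_pipeline`` wires the stages together: synthetic inputs (generated
from the seed, or read from ``input_dir``) -> exposure distributions and
potential impact fractions -> per-disease life tables in both arms ->
master life tables -> costs, offsets and the ICER.

The reference arm depends only on the input dataset, never on sampled
intervention parameters, so it is built once (:class:`ReferenceState`)
and reused across sensitivity rows and Monte Carlo iterations.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from pmslt.core import AGE_MIN, N_AGES, SEXES, Stratum, all_strata
from pmslt.disease_model import DiseaseEpidemiology, run_disease_lifetable
from pmslt.economics import (
    BASELINE_COSTS,
    TIME_TRAVEL_COSTS,
    CEOutcome,
    CostSet,
    cost_offsets,
    intervention_costs,
    unrelated_disease_costs,
)
from pmslt.intervention import InterventionSpec, bmi_loss_at, eligible_fraction
from pmslt.lifetable import (
    dalys_averted,
    decompose_other_causes,
    recompose_total,
    run_master_lifetable,
)
from pmslt.risk_model import (
    BMI_TREND_HORIZON_YEARS,
    BMIExposure,
    category_means,
    category_proportions,
    lognormal_from_mean_sd,
    potential_impact_fraction,
)
from pmslt.synthetic_data import (
    SyntheticConfig,
    SyntheticDataset,
    generate_dataset,
    read_dataset,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReferenceState", "PipelineResult", "build_reference",
           "evaluate_intervention", "run_pipeline"]

COSTING_SCENARIOS = ("baseline", "time_travel", "exclude_offsets", "unrelated_costs")

#: Potential impact fractions stop changing once both the weight-loss
#: trajectory (stable by year 3, or 15 with attenuation) and the secular
#: BMI trend (capped at 20 years) have plateaued.
PIF_HORIZON_YEARS = int(BMI_TREND_HORIZON_YEARS)


@dataclass(frozen=True)
class RunConfig:
    """One fully specified model run."""

    scenario: str = "bmi40"
    discount_rate: float = 0.03
    costing: str = "baseline"
    complication_multiplier: float = 1.0
    attenuation: float = 0.0
    seed: int = 0
    n_iterations: int = 3000
    input_dir: str | None = None
    n_diseases: int = 9

    def __post_init__(self) -> None:
        if self.costing not in COSTING_SCENARIOS:
            raise ValueError(f"costing must be one of {COSTING_SCENARIOS}")
        if not 0.0 <= self.discount_rate <= 1.0:
            raise ValueError("discount_rate must be in [0, 1]")
        if self.complication_multiplier < 0:
            raise ValueError("complication_multiplier must be >= 0")

    @property
    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(seed=self.seed, n_diseases=self.n_diseases)

    @property
    def cost_set(self) -> CostSet:
        return TIME_TRAVEL_COSTS if self.costing == "time_travel" else BASELINE_COSTS

    def intervention_spec(self) -> InterventionSpec:
        return InterventionSpec(scenario=self.scenario, attenuation=self.attenuation)

    def load_dataset(self) -> SyntheticDataset:
        if self.input_dir is not None:
            path = Path(self.input_dir)
            if not path.exists():
                raise FileNotFoundError(
                    f"input directory {path} not found; run the synth command first"
                )
            return read_dataset(path)
        return generate_dataset(self.synthetic_config)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class _StratumReference:
    """Cached reference-arm quantities for one cohort."""

    stratum: Stratum
    n_years: int
    exposure: BMIExposure
    eligible_fraction_by_scenario: dict[str, float]
    # trend-shifted category grids for PIF years 1..horizon: shape (T, 5)
    trend_proportions: np.ndarray
    trend_means: np.ndarray
    cohort: "object"  # reference CohortResult
    # per-disease, per-year person-quantities in the reference arm
    prevalent_py: dict[str, np.ndarray]
    incident_cases: dict[str, np.ndarray]
    # per-disease start states at the cohort's first age
    start_states: dict[str, tuple[float, float]]
    mortality_slice: np.ndarray  # all-cause m+ for ages a0..100
    pyld_slice: np.ndarray
    m_minus: np.ndarray  # residuals for ages a0..100
    w_minus: np.ndarray
    unrelated_cost_slice: np.ndarray


@dataclass
class ReferenceState:
    """Everything about the model that does not depend on the intervention."""

    dataset: SyntheticDataset
    strata: dict[Stratum, _StratumReference]
    baseline_trajectories: dict[tuple[str, str], "object"]  # (disease, sex)

    @property
    def diseases(self) -> list[DiseaseEpidemiology]:
        return self.dataset.diseases


def build_reference(dataset: SyntheticDataset) -> ReferenceState:
    """Run the reference arm once and cache all intervention-independent state."""
    pop = dataset.population
    diseases = dataset.diseases

    baseline: dict[tuple[str, str], object] = {}
    m_minus_by_sex: dict[str, np.ndarray] = {}
    w_minus_by_sex: dict[str, np.ndarray] = {}
    for sex in SEXES:
        md = np.empty((len(diseases), N_AGES))
        wd = np.empty((len(diseases), N_AGES))
        for k, epi in enumerate(diseases):
            traj = run_disease_lifetable(epi, sex)
            baseline[(epi.disease_id, sex)] = traj
            md[k] = traj.mortality
            wd[k] = traj.pyld
        m_minus_by_sex[sex], w_minus_by_sex[sex] = decompose_other_causes(
            pop.mortality[sex], pop.pyld[sex], md, wd, ages=np.arange(AGE_MIN, 101)
        )

    strata: dict[Stratum, _StratumReference] = {}
    for stratum in all_strata():
        sex, a0 = stratum.sex, stratum.age_group
        lo = a0 - AGE_MIN
        n_years = 101 - a0
        count = pop.counts[stratum]

        exposure = BMIExposure(dataset.bmi.mean[stratum], dataset.bmi.sd[stratum])
        trend = dataset.bmi.trend[stratum]
        T = min(n_years, PIF_HORIZON_YEARS)
        t_grid = np.arange(1, T + 1, dtype=float)
        means_t = exposure.mean + trend * np.minimum(t_grid, BMI_TREND_HORIZON_YEARS)
        mu_t, sigma_t = lognormal_from_mean_sd(means_t, np.full(T, exposure.sd))
        p_t = category_proportions(mu_t, sigma_t)
        m_t = category_means(mu_t, sigma_t)

        cohort = run_master_lifetable(
            pop.mortality[sex][lo:], pop.pyld[sex][lo:], a0, cohort_size=count
        )
        prevalent_py, incident_cases, start_states = {}, {}, {}
        for epi in diseases:
            traj = baseline[(epi.disease_id, sex)]
            prev = traj.prevalence[lo:]
            inc = traj.incident[lo:]
            prevalent_py[epi.disease_id] = prev * cohort.person_years
            incident_cases[epi.disease_id] = inc * cohort.person_years
            start_states[epi.disease_id] = (
                float(traj.susceptible[lo]),
                float(traj.diseased[lo]),
            )

        strata[stratum] = _StratumReference(
            stratum=stratum,
            n_years=n_years,
            exposure=exposure,
            eligible_fraction_by_scenario={
                s: eligible_fraction(exposure, s) for s in ("bmi40", "bmi35")
            },
            trend_proportions=p_t,
            trend_means=m_t,
            cohort=cohort,
            prevalent_py=prevalent_py,
            incident_cases=incident_cases,
            start_states=start_states,
            mortality_slice=pop.mortality[sex][lo:],
            pyld_slice=pop.pyld[sex][lo:],
            m_minus=m_minus_by_sex[sex][lo:],
            w_minus=w_minus_by_sex[sex][lo:],
            unrelated_cost_slice=pop.unrelated_cost[sex][lo:],
        )
    return ReferenceState(dataset=dataset, strata=strata,
                          baseline_trajectories=baseline)


def _pif_grid(
    ref: _StratumReference,
    spec: InterventionSpec,
    rr_units: dict[str, float],
    disease_ids: list[str],
    complication_multiplier: float,
) -> np.ndarray:
    """PIF by (disease, year) for one stratum; rows constant past the horizon."""
    T = ref.trend_proportions.shape[0]
    t_grid = np.arange(1, T + 1, dtype=float)
    delta = np.array([bmi_loss_at(t, spec) for t in t_grid])
    if spec.band_removal_reverts:
        # fraction of recipients still carrying the band (removals from year 3)
        removal = min(
            1.0, spec.complication_risks["band_removal"] * complication_multiplier
        )
        retain = (1.0 - removal) ** np.maximum(0.0, t_grid - 2.0)
        delta = delta * retain
    eligible = sorted(spec.eligible_categories)

    p = ref.trend_proportions  # (T, 5)
    m = ref.trend_means
    out = np.empty((len(disease_ids), ref.n_years))
    for k, disease_id in enumerate(disease_ids):
        rr_unit = rr_units[disease_id]
        rr = rr_unit ** (m - m[:, 0:1])  # (T, 5)
        shifted = rr.copy()
        factor = rr_unit ** (-delta)  # (T,)
        for cat in eligible:
            shifted[:, cat - 1] = np.maximum(1.0, rr[:, cat - 1] * factor)
        pif = potential_impact_fraction(p, rr, shifted)
        out[k, :T] = pif
        out[k, T:] = pif[-1] if T else 0.0
    return out


def _batch_illness_death(i, f, r, s0, c0):
    """Vectorized annual illness-death recursion over (n_years, n_diseases)."""
    p_i = -np.expm1(-i)
    p_f = -np.expm1(-f)
    p_r = -np.expm1(-r)
    n, d = i.shape
    S = np.empty((n, d))
    C = np.empty((n, d))
    incident = np.empty((n, d))
    S[0], C[0] = s0, c0
    for k in range(n - 1):
        new = S[k] * p_i[k]
        incident[k] = new
        S[k + 1] = S[k] * (1.0 - p_i[k]) + C[k] * p_r[k]
        C[k + 1] = C[k] * (1.0 - p_f[k] - p_r[k]) + new
    incident[n - 1] = S[n - 1] * p_i[n - 1]
    alive = S + C
    with np.errstate(invalid="ignore", divide="ignore"):
        prev = np.where(alive > 0, C / alive, 0.0)
        incident = np.where(alive > 0, incident / alive, 0.0)
    return prev, incident


def evaluate_intervention(
    reference: ReferenceState,
    spec: InterventionSpec,
    costs: CostSet,
    discount_rate: float,
    costing: str = "baseline",
    complication_multiplier: float = 1.0,
    rr_units: dict[str, float] | None = None,
    complication_cost_scale: float = 1.0,
    initial_cost_override: float | None = None,
) -> CEOutcome:
    """Evaluate the intervention arm against the cached reference arm.

    ``rr_units``/``initial_cost_override``/``complication_cost_scale``
    exist so the Monte Carlo layer can rerun the model with sampled
    parameters without touching the reference state.
    """
    diseases = reference.diseases
    disease_ids = [epi.disease_id for epi in diseases]
    if rr_units is None:
        rr_units = reference.dataset.bmi.rr_unit
    if initial_cost_override is not None:
        costs = CostSet(
            initial_cost_override, costs.annual_maintenance, costs.annual_complications
        )
    cancer_flags = {epi.disease_id: epi.cancer for epi in diseases}
    unit_costs = {epi.disease_id: epi.offset_cost for epi in diseases}
    surgical_q = np.array([spec.mortality_30d, spec.mortality_30d_2y])

    total_dalys = 0.0
    total_initial = 0.0
    total_maintenance = 0.0
    total_offsets = 0.0
    total_unrelated = 0.0
    total_operated = 0.0

    for stratum, ref in reference.strata.items():
        sex, a0 = stratum.sex, stratum.age_group
        lo = a0 - AGE_MIN
        n = ref.n_years
        elig = ref.eligible_fraction_by_scenario[spec.scenario]

        pif = _pif_grid(ref, spec, rr_units, disease_ids, complication_multiplier)

        i_base = np.stack(
            [epi.incidence[sex][lo:] for epi in diseases], axis=1
        )  # (n, D)
        f_base = np.stack([epi.case_fatality[sex][lo:] for epi in diseases], axis=1)
        r_base = np.stack([epi.remission[sex][lo:] for epi in diseases], axis=1)
        i_new = i_base * (1.0 - pif.T)
        s0 = np.array([ref.start_states[d][0] for d in disease_ids])
        c0 = np.array([ref.start_states[d][1] for d in disease_ids])
        prev, incident = _batch_illness_death(i_new, f_base, r_base, s0, c0)

        f_weights = np.array([epi.disability_weight for epi in diseases])
        m_d = (f_base * prev).T  # (D, n)
        w_d = (prev * f_weights).T
        m_plus, w_plus = recompose_total(ref.m_minus, ref.w_minus, m_d, w_d)

        count = ref.cohort.cohort_size
        arm = run_master_lifetable(
            m_plus, w_plus, a0, cohort_size=count, extra_mortality=elig * surgical_q
        )
        n_operated = count * elig
        operated = run_master_lifetable(
            m_plus, w_plus, a0, cohort_size=n_operated, extra_mortality=surgical_q
        )

        total_dalys += dalys_averted(ref.cohort, arm, discount_rate)
        initial, maintenance = intervention_costs(
            operated.person_years,
            n_operated,
            costs,
            discount_rate,
            complication_multiplier=complication_multiplier * complication_cost_scale,
        )
        total_initial += initial
        total_maintenance += maintenance
        total_operated += n_operated

        prevalent_averted = {}
        incident_averted = {}
        for k, disease_id in enumerate(disease_ids):
            prevalent_averted[disease_id] = ref.prevalent_py[disease_id] - (
                prev[:, k] * arm.person_years
            )
            incident_averted[disease_id] = ref.incident_cases[disease_id] - (
                incident[:, k] * arm.person_years
            )
        total_offsets += cost_offsets(
            prevalent_averted, incident_averted, unit_costs, cancer_flags,
            discount_rate,
        )
        if costing == "unrelated_costs":
            extra_py = arm.person_years - ref.cohort.person_years
            total_unrelated += unrelated_disease_costs(
                extra_py, ref.unrelated_cost_slice, discount_rate
            )

    if costing == "exclude_offsets":
        total_offsets = 0.0
    return CEOutcome(
        scenario=spec.scenario,
        intervention_cost=total_initial,
        maintenance_cost=total_maintenance,
        cost_offsets=total_offsets,
        unrelated_cost=total_unrelated,
        dalys_averted=total_dalys,
        n_operated=total_operated,
    )


@dataclass
class PipelineResult:
    config: RunConfig
    outcome: CEOutcome
    reference: ReferenceState
    config_hash: str = ""

    def __post_init__(self) -> None:
        if not self.config_hash:
            self.config_hash = self.config.config_hash


def run_pipeline(
    config: RunConfig,
    dataset: SyntheticDataset | None = None,
    reference: ReferenceState | None = None,
) -> PipelineResult:
    """Run the full deterministic pipeline at point estimates."""
    if reference is None:
        if dataset is None:
            dataset = config.load_dataset()
        logger.info("building reference arm [config %s]", config.config_hash)
        reference = build_reference(dataset)
    spec = config.intervention_spec()
    logger.info(
        "evaluating intervention: scenario=%s discount=%s costing=%s [config %s]",
        config.scenario, config.discount_rate, config.costing, config.config_hash,
    )
    outcome = evaluate_intervention(
        reference,
        spec,
        config.cost_set,
        config.discount_rate,
        costing=config.costing,
        complication_multiplier=config.complication_multiplier,
    )
    return PipelineResult(config=config, outcome=outcome, reference=reference)


def write_outcome(result: PipelineResult, out_dir: str | Path) -> Path:
    """Serialize the outcome (with config hash) as JSON; returns the path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    o = result.outcome
    payload = {
        "config_hash": result.config_hash,
        "scenario": o.scenario,
        "intervention_cost": o.intervention_cost,
        "maintenance_cost": o.maintenance_cost,
        "cost_offsets": o.cost_offsets,
        "unrelated_cost": o.unrelated_cost,
        "net_cost": o.net_cost,
        "dalys_averted": o.dalys_averted,
        "n_operated": o.n_operated,
        "icer": o.icer,
    }
    path = out / "outcome.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def write_lifetables(result: PipelineResult, out_dir: str | Path) -> Path:
    """Audit CSV of the reference-arm master life table per stratum."""
    import pandas as pd

    rows = []
    for stratum, ref in result.reference.strata.items():
        c = ref.cohort
        for k in range(c.n_years):
            rows.append(
                {
                    "config_hash": result.config_hash,
                    "sex": stratum.sex,
                    "cohort": stratum.age_group,
                    "age": int(c.ages[k]),
                    "l": c.survivors[k],
                    "L": c.person_years[k],
                    "Lw": c.adjusted_person_years[k],
                    "e": c.life_expectancy[k],
                    "dale": c.dale[k],
                }
            )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "reference_lifetables.csv"
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    return path
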