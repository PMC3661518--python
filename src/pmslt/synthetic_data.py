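"""Synthetic model inputs with the structure of a national burden-of-disease study.

Generates internally consistent reference-population epidemiology
(counts, Gompertz-like all-cause mortality, disability rates), a set of
obesity-related diseases (chronic conditions plus incidence-costed
cancers), lognormal BMI distribution parameters with a secular trend, and
relative risks per BMI unit — everything the downstream pipeline needs,
reproducible from a single seed and round-trippable through plain CSV.

No attempt is made to match any real country's values; only the shapes
that the proportional life table requires (age-increasing mortality,
modelled-disease mortality strictly inside the all-cause envelope, BMI
means around 27 with SD around 5, relative risks between 1.0 and 1.4 per
unit) are enforced.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from pmslt.core import AGES, N_AGES, SEXES, Stratum, all_strata
from pmslt.disease_model import DiseaseEpidemiology, run_disease_lifetable

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticConfig",
    "PopulationInputs",
    "BMIInputs",
    "SyntheticDataset",
    "generate_population",
    "generate_disease_set",
    "generate_bmi_inputs",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

_FLOAT_FMT = "%.17g"  # full round-trip precision in CSV


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the generator; a fixed seed gives byte-identical output."""

    seed: int = 0
    n_diseases: int = 9
    bmi_mean_range: tuple[float, float] = (24.0, 30.0)
    bmi_sd_range: tuple[float, float] = (3.0, 6.0)
    rr_range: tuple[float, float] = (1.0, 1.4)
    incidence_scale: float = 1.0
    mortality_scale_range: tuple[float, float] = (2e-5, 6e-5)  # Gompertz a
    mortality_shape_range: tuple[float, float] = (0.085, 0.105)  # Gompertz b
    pyld_cap: float = 0.3
    sex_specific_pyld: bool = True
    enable_remission: bool = False
    bmi_trend_per_year: float = 0.05  # additive BMI units/year, central value

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        if self.n_diseases < 1:
            raise ValueError("n_diseases must be >= 1")
        if self.incidence_scale < 0:
            raise ValueError("incidence_scale must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        """A named, seed-derived substream (stable across processes)."""
        ss = np.random.SeedSequence(
            self.seed, spawn_key=(zlib.crc32(stream.encode("utf-8")),)
        )
        return np.random.default_rng(ss)


@dataclass
class PopulationInputs:
    """Reference-population counts, mortality, disability, unrelated costs."""

    counts: dict[Stratum, float]
    mortality: dict[str, np.ndarray]  # per sex, ages 20..100
    pyld: dict[str, np.ndarray]
    unrelated_cost: dict[str, np.ndarray]  # AU$ per life-year, per sex by age

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("empty stratum set")
        for stratum, count in self.counts.items():
            if count < 0:
                raise ValueError(f"negative population count for {stratum}")


@dataclass
class BMIInputs:
    """Per-stratum exposure parameters plus per-disease relative risks."""

    mean: dict[Stratum, float]
    sd: dict[Stratum, float]
    trend: dict[Stratum, float]  # BMI units per calendar year
    rr_unit: dict[str, float]  # per disease, stratum-independent
    rr_ci: dict[str, tuple[float, float]]  # synthetic 95% CI for the PSA


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    population: PopulationInputs
    diseases: list[DiseaseEpidemiology]
    bmi: BMIInputs


def generate_population(config: SyntheticConfig) -> PopulationInputs:
    """Population counts and Gompertz all-cause mortality/pYLD schedules.

    Mortality follows ``a * exp(b * age)`` (clipped into (0, 1]); the
    pYLD rate rises with age but stays below ``config.pyld_cap``.
    """
    rng = config.rng("population")
    a_lo, a_hi = config.mortality_scale_range
    b_lo, b_hi = config.mortality_shape_range

    mortality: dict[str, np.ndarray] = {}
    pyld: dict[str, np.ndarray] = {}
    unrelated: dict[str, np.ndarray] = {}
    shared_pyld: np.ndarray | None = None
    for sex in SEXES:
        a = rng.uniform(a_lo, a_hi)
        b = rng.uniform(b_lo, b_hi)
        rates = np.clip(a * np.exp(b * AGES), 0.0, 1.0)
        mortality[sex] = rates

        base = rng.uniform(0.04, 0.08)
        slope = rng.uniform(0.10, 0.18)
        w = base + slope * ((AGES - 20) / 80.0) ** 1.2
        w = np.clip(w, 0.0, config.pyld_cap * 0.999)
        if config.sex_specific_pyld or shared_pyld is None:
            shared_pyld = w
        pyld[sex] = w if config.sex_specific_pyld else shared_pyld

        cost_base = rng.uniform(1500.0, 2500.0)
        unrelated[sex] = cost_base + rng.uniform(30.0, 60.0) * (AGES - 20)

    counts = {}
    for stratum in all_strata():
        scale = np.exp(-0.02 * (stratum.age_group - 20))
        counts[stratum] = float(np.round(rng.uniform(450_000, 750_000) * scale))
    return PopulationInputs(
        counts=counts, mortality=mortality, pyld=pyld, unrelated_cost=unrelated
    )


def _n_cancers(n_diseases: int) -> int:
    # four of the nine default diseases are cancers; scale down for
    # smaller synthetic disease sets
    return min(4, max(0, n_diseases - 5))


def generate_disease_set(
    config: SyntheticConfig, population: PopulationInputs | None = None
) -> list[DiseaseEpidemiology]:
    """Per-disease incidence/case-fatality/remission tables + weights + costs.

    The generated set is checked against the all-cause envelope: the sum
    over diseases of implied mortality (prevalence x case fatality) and
    disability must stay strictly below the all-cause rates at every age,
    otherwise incidence is scaled down and the check repeated (logged).
    """
    rng = config.rng("diseases")
    if population is None:
        population = generate_population(config)
    n_cancer = _n_cancers(config.n_diseases)

    diseases: list[DiseaseEpidemiology] = []
    for d in range(config.n_diseases):
        cancer = d >= config.n_diseases - n_cancer
        disease_id = f"{'cancer' if cancer else 'chronic'}_{d:02d}"
        incidence, case_fatality, remission = {}, {}, {}
        for sex in SEXES:
            i0 = rng.uniform(5e-5, 2.5e-4) * config.incidence_scale
            gi = rng.uniform(0.02, 0.04)
            incidence[sex] = i0 * np.exp(gi * (AGES - 20))
            f0 = rng.uniform(0.002, 0.008)
            gf = rng.uniform(0.01, 0.02)
            case_fatality[sex] = np.clip(f0 * np.exp(gf * (AGES - 20)), 0.0, 0.3)
            if config.enable_remission and not cancer:
                remission[sex] = np.full(N_AGES, rng.uniform(0.005, 0.02))
            else:
                remission[sex] = np.zeros(N_AGES)
        weight = rng.uniform(0.05, 0.25)
        offset_cost = (
            rng.uniform(15_000.0, 40_000.0) if cancer else rng.uniform(1_000.0, 6_000.0)
        )
        diseases.append(
            DiseaseEpidemiology(
                disease_id=disease_id,
                cancer=cancer,
                incidence=incidence,
                case_fatality=case_fatality,
                remission=remission,
                disability_weight=weight,
                offset_cost=offset_cost,
            )
        )

    # envelope check: keep total disease mortality / disability strictly
    # inside the all-cause rates (required by the master-table subtraction)
    for _ in range(30):
        ok = True
        for sex in SEXES:
            total_m = np.zeros(N_AGES)
            total_w = np.zeros(N_AGES)
            for epi in diseases:
                traj = run_disease_lifetable(epi, sex)
                total_m += traj.mortality
                total_w += traj.pyld
            if np.any(total_m >= 0.95 * population.mortality[sex]) or np.any(
                total_w >= 0.95 * population.pyld[sex]
            ):
                ok = False
                break
        if ok:
            break
        logger.warning(
            "disease-attributable mortality/disability exceeded the all-cause "
            "envelope; rescaling incidence by 0.5"
        )
        for epi in diseases:
            for sex in SEXES:
                epi.incidence[sex] = epi.incidence[sex] * 0.5
    else:
        raise RuntimeError("could not fit diseases inside the all-cause envelope")
    return diseases


def generate_bmi_inputs(config: SyntheticConfig) -> BMIInputs:
    """Lognormal BMI parameters per stratum and relative risks per disease."""
    rng = config.rng("bmi")
    mean, sd, trend = {}, {}, {}
    for stratum in all_strata():
        mean[stratum] = float(rng.uniform(*config.bmi_mean_range))
        sd[stratum] = float(rng.uniform(*config.bmi_sd_range))
        trend[stratum] = float(config.bmi_trend_per_year * rng.uniform(0.5, 1.5))

    n_cancer = _n_cancers(config.n_diseases)
    rr_unit, rr_ci = {}, {}
    for d in range(config.n_diseases):
        cancer = d >= config.n_diseases - n_cancer
        disease_id = f"{'cancer' if cancer else 'chronic'}_{d:02d}"
        rr = float(rng.uniform(*config.rr_range))
        rr_unit[disease_id] = rr
        # synthetic symmetric-on-log CI with ~5% half-width
        half = float(rng.uniform(0.02, 0.08))
        rr_ci[disease_id] = (rr * np.exp(-half), rr * np.exp(half))
    return BMIInputs(mean=mean, sd=sd, trend=trend, rr_unit=rr_unit, rr_ci=rr_ci)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full, internally consistent input bundle."""
    population = generate_population(config)
    diseases = generate_disease_set(config, population)
    bmi = generate_bmi_inputs(config)
    return SyntheticDataset(
        config=config, population=population, diseases=diseases, bmi=bmi
    )


# ---------------------------------------------------------------------------
# CSV serialization (long format, full float precision)
# ---------------------------------------------------------------------------


def _population_frame(pop: PopulationInputs) -> pd.DataFrame:
    rows = []
    for stratum, count in sorted(pop.counts.items()):
        rows.append(
            {"sex": stratum.sex, "age": stratum.age_group, "quantity": "count",
             "value": count}
        )
    for quantity, table in (
        ("mortality", pop.mortality),
        ("pyld", pop.pyld),
        ("unrelated_cost", pop.unrelated_cost),
    ):
        for sex in SEXES:
            for age, value in zip(AGES, table[sex]):
                rows.append(
                    {"sex": sex, "age": int(age), "quantity": quantity, "value": value}
                )
    return pd.DataFrame(rows)


def _diseases_frame(diseases: list[DiseaseEpidemiology]) -> pd.DataFrame:
    rows = []
    for epi in diseases:
        rows.append(
            {"disease": epi.disease_id, "sex": "", "age": -1, "quantity": "cancer",
             "value": float(epi.cancer)}
        )
        rows.append(
            {"disease": epi.disease_id, "sex": "", "age": -1,
             "quantity": "disability_weight", "value": epi.disability_weight}
        )
        rows.append(
            {"disease": epi.disease_id, "sex": "", "age": -1,
             "quantity": "offset_cost", "value": epi.offset_cost}
        )
        for quantity, table in (
            ("incidence", epi.incidence),
            ("case_fatality", epi.case_fatality),
            ("remission", epi.remission),
        ):
            for sex in SEXES:
                for age, value in zip(AGES, table[sex]):
                    rows.append(
                        {"disease": epi.disease_id, "sex": sex, "age": int(age),
                         "quantity": quantity, "value": value}
                    )
    return pd.DataFrame(rows)


def _bmi_frame(bmi: BMIInputs) -> pd.DataFrame:
    rows = []
    for quantity, table in (("mean", bmi.mean), ("sd", bmi.sd), ("trend", bmi.trend)):
        for stratum in sorted(table):
            rows.append(
                {"sex": stratum.sex, "age": stratum.age_group, "quantity": quantity,
                 "value": table[stratum]}
            )
    return pd.DataFrame(rows)


def _rr_frame(bmi: BMIInputs) -> pd.DataFrame:
    rows = []
    for disease in sorted(bmi.rr_unit):
        lo, hi = bmi.rr_ci[disease]
        rows.append(
            {"disease": disease, "rr_unit": bmi.rr_unit[disease],
             "rr_lo": lo, "rr_hi": hi}
        )
    return pd.DataFrame(rows)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write population.csv, diseases.csv, bmi.csv, rr.csv and a config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "population": out / "population.csv",
        "diseases": out / "diseases.csv",
        "bmi": out / "bmi.csv",
        "rr": out / "rr.csv",
        "config": out / "config.json",
    }
    _population_frame(dataset.population).to_csv(
        paths["population"], index=False, float_format=_FLOAT_FMT
    )
    _diseases_frame(dataset.diseases).to_csv(
        paths["diseases"], index=False, float_format=_FLOAT_FMT
    )
    _bmi_frame(dataset.bmi).to_csv(paths["bmi"], index=False, float_format=_FLOAT_FMT)
    _rr_frame(dataset.bmi).to_csv(paths["rr"], index=False, float_format=_FLOAT_FMT)
    paths["config"].write_text(json.dumps(asdict(dataset.config), indent=2) + "\n")
    return paths


def read_dataset(in_dir: str | Path) -> SyntheticDataset:
    """Read a dataset previously written by :func:`write_dataset`."""
    src = Path(in_dir)
    cfg_raw = json.loads((src / "config.json").read_text())
    for key in ("bmi_mean_range", "bmi_sd_range", "rr_range",
                "mortality_scale_range", "mortality_shape_range"):
        cfg_raw[key] = tuple(cfg_raw[key])
    config = SyntheticConfig(**cfg_raw)

    pop_df = pd.read_csv(src / "population.csv", float_precision="round_trip")
    counts: dict[Stratum, float] = {}
    mortality: dict[str, np.ndarray] = {}
    pyld: dict[str, np.ndarray] = {}
    unrelated: dict[str, np.ndarray] = {}
    for _, row in pop_df[pop_df.quantity == "count"].iterrows():
        counts[Stratum(row.sex, int(row.age))] = float(row.value)
    for quantity, dest in (
        ("mortality", mortality), ("pyld", pyld), ("unrelated_cost", unrelated)
    ):
        sub = pop_df[pop_df.quantity == quantity]
        for sex in SEXES:
            dest[sex] = (
                sub[sub.sex == sex].sort_values("age").value.to_numpy(dtype=float)
            )
    population = PopulationInputs(
        counts=counts, mortality=mortality, pyld=pyld, unrelated_cost=unrelated
    )

    dis_df = pd.read_csv(src / "diseases.csv", keep_default_na=False, float_precision="round_trip")
    diseases = []
    for disease_id in dis_df.disease.unique():
        sub = dis_df[dis_df.disease == disease_id]
        scalars = {
            r.quantity: float(r.value) for _, r in sub[sub.age == -1].iterrows()
        }
        tables: dict[str, dict[str, np.ndarray]] = {}
        for quantity in ("incidence", "case_fatality", "remission"):
            q = sub[sub.quantity == quantity]
            tables[quantity] = {
                sex: q[q.sex == sex].sort_values("age").value.to_numpy(dtype=float)
                for sex in SEXES
            }
        diseases.append(
            DiseaseEpidemiology(
                disease_id=disease_id,
                cancer=bool(scalars["cancer"]),
                incidence=tables["incidence"],
                case_fatality=tables["case_fatality"],
                remission=tables["remission"],
                disability_weight=scalars["disability_weight"],
                offset_cost=scalars["offset_cost"],
            )
        )

    bmi_df = pd.read_csv(src / "bmi.csv", float_precision="round_trip")
    mean, sd, trend = {}, {}, {}
    for quantity, dest in (("mean", mean), ("sd", sd), ("trend", trend)):
        for _, row in bmi_df[bmi_df.quantity == quantity].iterrows():
            dest[Stratum(row.sex, int(row.age))] = float(row.value)
    rr_df = pd.read_csv(src / "rr.csv", float_precision="round_trip")
    rr_unit = {r.disease: float(r.rr_unit) for _, r in rr_df.iterrows()}
    rr_ci = {r.disease: (float(r.rr_lo), float(r.rr_hi)) for _, r in rr_df.iterrows()}
    bmi = BMIInputs(mean=mean, sd=sd, trend=trend, rr_unit=rr_unit, rr_ci=rr_ci)
    return SyntheticDataset(
        config=config, population=population, diseases=diseases, bmi=bmi
    )
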