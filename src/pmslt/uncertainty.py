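"""Monte Carlo uncertainty analysis over the cost-effectiveness pipeline.

Each uncertain input carries one of four distribution families:

* ``normal`` — mean and standard error;
* ``beta_count`` — a proportion with an effective sample size,
  parameterized as alpha = p*N, beta = (1-p)*N;
* ``gamma_mean_se`` — moment-matched gamma, shape = (mean/SE)^2,
  scale = SE^2/mean; a zero mean cannot be a proper gamma and degrades
  to a half-normal with scale SE (logged);
* ``relative_risk`` — lognormal on ln RR with sigma from the 95% CI
  width divided by 2 * 1.96.

Draws are independent (no correlation structure is specified by the
inputs).  Each iteration redraws the full parameter vector, rebuilds the
intervention-side spec/costs, and reruns the pipeline against the cached
reference arm; summaries report percentile intervals, cost-saving and
threshold probabilities, and a rank-based ICER interval in which
cost-saving iterations sort below every positive-ICER iteration and are
labelled "dominant".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pmslt.interface import ReferenceState, RunConfig, build_reference, evaluate_intervention

logger = logging.getLogger(__name__)

__all__ = [
    "UncertainParameter",
    "SimulationSummary",
    "sample",
    "build_parameters",
    "run_monte_carlo",
    "summarize_icer",
    "probability_below",
]

FAMILIES = ("normal", "beta_count", "gamma_mean_se", "relative_risk")

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

#: Synthetic unit prices (AU$) that turn the follow-up frequencies and
#: short-term complication risks of the initial package into its variable
#: cost component.  Calibrated so the point-estimate package cost equals
#: the configured initial surgery cost.
INITIAL_PACKAGE_ITEMS: tuple[tuple[str, str, float, float, float], ...] = (
    # (name, family, point, spread/N, unit price)
    ("consult_surgeon", "gamma_mean_se", 11.60, 4.10, 120.0),
    ("consult_surgeon_adjust", "gamma_mean_se", 10.27, 4.58, 150.0),
    ("consult_respiratory", "gamma_mean_se", 0.43, 1.14, 140.0),
    ("consult_dietician", "gamma_mean_se", 0.10, 0.31, 60.0),
    ("early_removal_replace", "beta_count", 0.07, 30.0, 4000.0),
    ("early_port_infection", "beta_count", 0.03, 30.0, 3000.0),
    ("early_removal", "beta_count", 0.03, 30.0, 3500.0),
)


@dataclass(frozen=True)
class UncertainParameter:
    """One sampled model input."""

    name: str
    family: str
    mean: float = 0.0
    se: float = 0.0
    proportion: float = 0.0
    n: float = 0.0
    rr: float = 1.0
    ci: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in ("normal", "gamma_mean_se") and self.se < 0:
            raise ValueError("SE must be >= 0")
        if self.family == "beta_count":
            if not 0.0 <= self.proportion <= 1.0 or self.n < 1:
                raise ValueError("need proportion in [0,1] and N >= 1")
        if self.family == "relative_risk":
            lo, hi = self.ci
            if not lo <= self.rr <= hi:
                raise ValueError("CI bounds must bracket the RR")

    @property
    def point(self) -> float:
        if self.family == "beta_count":
            return self.proportion
        if self.family == "relative_risk":
            return self.rr
        return self.mean


def sample(param: UncertainParameter, rng: np.random.Generator) -> float:
    """One draw from the parameter's distribution."""
    if param.family == "normal":
        if param.se == 0.0:
            return param.mean
        return float(rng.normal(param.mean, param.se))
    if param.family == "beta_count":
        alpha = param.proportion * param.n
        beta = (1.0 - param.proportion) * param.n
        if alpha == 0.0 or beta == 0.0:
            return param.proportion
        return float(rng.beta(alpha, beta))
    if param.family == "gamma_mean_se":
        if param.se == 0.0:
            return param.mean
        if param.mean == 0.0:
            # zero mean has no proper gamma; fall back to half-normal
            logger.debug("parameter %s: zero-mean gamma -> half-normal", param.name)
            return float(abs(rng.normal(0.0, param.se)))
        shape = (param.mean / param.se) ** 2
        scale = param.se**2 / param.mean
        if shape < 1.0:
            logger.debug(
                "parameter %s: SE exceeds mean, gamma shape %.3f < 1",
                param.name, shape,
            )
        return float(rng.gamma(shape, scale))
    # relative_risk
    lo, hi = param.ci
    if lo == hi:
        return param.rr
    sigma = (math.log(hi) - math.log(lo)) / (2.0 * Z_95)
    return float(math.exp(rng.normal(math.log(param.rr), sigma)))


def build_parameters(reference: ReferenceState, config: RunConfig) -> list[UncertainParameter]:
    """The Table-of-uncertain-inputs for a run: weight loss, RRs, surgical
    mortality, long-term complication risks, and the variable items of the
    initial package."""
    spec = config.intervention_spec()
    params = [
        UncertainParameter(
            "peak_weight_loss", "normal", mean=spec.peak_loss_kg, se=spec.peak_loss_se
        ),
        UncertainParameter(
            "mortality_30d", "gamma_mean_se",
            mean=spec.mortality_30d, se=spec.mortality_30d_se,
        ),
        UncertainParameter(
            "mortality_30d_2y", "gamma_mean_se",
            mean=spec.mortality_30d_2y, se=spec.mortality_30d_2y_se,
        ),
    ]
    for disease_id, rr in sorted(reference.dataset.bmi.rr_unit.items()):
        params.append(
            UncertainParameter(
                f"rr::{disease_id}", "relative_risk",
                rr=rr, ci=reference.dataset.bmi.rr_ci[disease_id],
            )
        )
    for name, risk in sorted(spec.complication_risks.items()):
        params.append(
            UncertainParameter(
                f"complication::{name}", "beta_count",
                proportion=risk, n=spec.complication_risk_n,
            )
        )
    for name, family, point, spread, _price in INITIAL_PACKAGE_ITEMS:
        if family == "beta_count":
            params.append(
                UncertainParameter(f"package::{name}", family,
                                   proportion=point, n=spread)
            )
        else:
            params.append(
                UncertainParameter(f"package::{name}", family,
                                   mean=point, se=spread)
            )
    return params


def _initial_cost_from_package(values: dict[str, float], base_initial: float) -> float:
    """Initial package cost with sampled follow-up/complication items.

    The variable component is the price-weighted sum of the package
    items; at the point estimates the total equals ``base_initial``.
    """
    point_var = sum(point * price for _n, _f, point, _s, price in INITIAL_PACKAGE_ITEMS)
    sampled_var = sum(
        values[f"package::{name}"] * price
        for name, _f, _p, _s, price in INITIAL_PACKAGE_ITEMS
    )
    return base_initial - point_var + sampled_var


@dataclass
class SimulationSummary:
    """Percentile summaries of the Monte Carlo cost-effectiveness outputs."""

    n_iterations: int
    n_failed: int
    means: dict[str, float]
    percentiles: dict[str, tuple[float, float]]  # (2.5th, 97.5th)
    probability_cost_saving: float
    probability_below_threshold: dict[float, float]
    icer_mean: float | str
    icer_interval: tuple[float | str, float | str]
    points: pd.DataFrame = field(repr=False, default=None)


def run_monte_carlo(
    config: RunConfig,
    n_iter: int | None = None,
    seed: int | None = None,
    reference: ReferenceState | None = None,
    thresholds: tuple[float, ...] = (10_000.0, 50_000.0),
) -> SimulationSummary:
    """Propagate parameter uncertainty through the full pipeline.

    Deterministic given the seed.  Iterations failing input validation
    are skipped and counted; more than 1% failures aborts the run.
    """
    from dataclasses import replace as _replace

    if n_iter is None:
        n_iter = config.n_iterations
    if seed is None:
        seed = config.seed
    if reference is None:
        reference = build_reference(config.load_dataset())
    params = build_parameters(reference, config)
    base_spec = config.intervention_spec()
    point_risk_total = sum(base_spec.complication_risks.values())
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(77,)))

    records = []
    n_failed = 0
    for it in range(n_iter):
        values = {p.name: sample(p, rng) for p in params}
        try:
            peak = max(0.0, values["peak_weight_loss"])
            two_year = base_spec.two_year_loss_kg * (
                peak / base_spec.peak_loss_kg if base_spec.peak_loss_kg else 0.0
            )
            spec = _replace(
                base_spec,
                peak_loss_kg=peak,
                two_year_loss_kg=min(two_year, peak),
                mortality_30d=min(1.0, values["mortality_30d"]),
                mortality_30d_2y=min(1.0, values["mortality_30d_2y"]),
                complication_risks={
                    name: values[f"complication::{name}"]
                    for name in base_spec.complication_risks
                },
            )
            rr_units = {
                disease_id: max(1.0, values[f"rr::{disease_id}"])
                for disease_id in reference.dataset.bmi.rr_unit
            }
            risk_total = sum(spec.complication_risks.values())
            comp_cost_scale = (
                risk_total / point_risk_total if point_risk_total > 0 else 1.0
            )
            initial_cost = _initial_cost_from_package(
                values, config.cost_set.initial_surgery
            )
            outcome = evaluate_intervention(
                reference,
                spec,
                config.cost_set,
                config.discount_rate,
                costing=config.costing,
                complication_multiplier=config.complication_multiplier,
                rr_units=rr_units,
                complication_cost_scale=comp_cost_scale,
                initial_cost_override=initial_cost,
            )
        except ValueError as err:
            n_failed += 1
            logger.warning("iteration %d skipped: %s", it, err)
            if n_failed > max(1, 0.01 * n_iter):
                raise RuntimeError(
                    f"more than 1% of iterations failed ({n_failed}/{it + 1})"
                )
            continue
        records.append(
            {
                "iteration": it,
                "dalys_averted": outcome.dalys_averted,
                "intervention_cost": outcome.intervention_cost,
                "maintenance_cost": outcome.maintenance_cost,
                "cost_offsets": outcome.cost_offsets,
                "net_cost": outcome.net_cost,
            }
        )
    points = pd.DataFrame(records)

    means = {}
    percentiles = {}
    for col in ("dalys_averted", "intervention_cost", "maintenance_cost",
                "cost_offsets", "net_cost"):
        means[col] = float(points[col].mean())
        percentiles[col] = (
            float(np.percentile(points[col], 2.5)),
            float(np.percentile(points[col], 97.5)),
        )
    prob_saving = probability_below(points, 0.0)
    icer_mean, icer_lo, icer_hi = summarize_icer(points)
    return SimulationSummary(
        n_iterations=len(points),
        n_failed=n_failed,
        means=means,
        percentiles=percentiles,
        probability_cost_saving=prob_saving,
        probability_below_threshold={
            thr: probability_below(points, thr) for thr in thresholds
        },
        icer_mean=icer_mean,
        icer_interval=(icer_lo, icer_hi),
        points=points,
    )


def summarize_icer(points: pd.DataFrame) -> tuple[float | str, float | str, float | str]:
    """(mean, 2.5th, 97.5th) of the ICER with dominance labels.

    Iterations are ranked on the cost-effectiveness plane: cost-saving
    iterations (net cost < 0, DALYs > 0) sort — most cost-saving first —
    below all positive-net-cost iterations (sorted by ICER).  Percentile
    positions that land on cost-saving iterations are reported as
    "dominant".  Iterations with non-positive DALYs are excluded from the
    ranking (reported via their count in logs).
    """
    if len(points) < 2:
        raise ValueError("need at least two iterations to summarize an ICER")
    gain = points[points.dalys_averted > 0]
    n_flagged = len(points) - len(gain)
    if n_flagged:
        logger.warning("%d iterations with non-positive DALYs excluded", n_flagged)
    dominant = gain[gain.net_cost < 0]
    paying = gain[gain.net_cost >= 0]
    ordered: list[float | str] = (
        ["dominant"] * len(dominant)
        + sorted(paying.net_cost / paying.dalys_averted)
    )
    # rank the dominant block internally by how cost-saving it is so the
    # lower tail reads "most dominant"; labels are identical anyway.

    def at_percentile(q: float) -> float | str:
        idx = int(round(q / 100.0 * (len(ordered) - 1)))
        return ordered[idx]

    mean_net = float(points.net_cost.mean())
    mean_daly = float(points.dalys_averted.mean())
    if mean_net < 0 and mean_daly > 0:
        mean: float | str = "dominant"
    elif mean_daly != 0:
        mean = mean_net / mean_daly
    else:
        mean = "undefined"
    return mean, at_percentile(2.5), at_percentile(97.5)


def probability_below(points: pd.DataFrame, threshold: float) -> float:
    """Fraction of iterations cost-effective at a willingness-to-pay threshold.

    Counts iterations that are cost-saving (net < 0) or have positive
    health gain with net cost below ``threshold * dalys_averted``.
    """
    if len(points) == 0:
        raise ValueError("no iterations")
    net = points.net_cost.to_numpy()
    daly = points.dalys_averted.to_numpy()
    ok = (net < 0) | ((daly > 0) & (net < threshold * daly))
    return float(ok.mean())


def write_summary(summary: SimulationSummary, out_dir) -> None:
    """JSON summary + CE-plane CSV (one (DALY, cost) point per iteration)."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "n_iterations": summary.n_iterations,
        "n_failed": summary.n_failed,
        "means": summary.means,
        "percentiles": summary.percentiles,
        "probability_cost_saving": summary.probability_cost_saving,
        "probability_below_threshold": {
            str(k): v for k, v in summary.probability_below_threshold.items()
        },
        "icer_mean": summary.icer_mean,
        "icer_interval": list(summary.icer_interval),
    }
    (out / "psa_summary.json").write_text(json.dumps(payload, indent=2) + "\n")
    summary.points.to_csv(out / "ce_plane.csv", index=False)
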