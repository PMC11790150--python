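"""Cohort simulation: the full pipeline for N independent flowers.

Each flower's bloom is simulated as daily Poisson visits -> pollen
deposition -> age-dependent binomial fertilization -> one weight draw,
with flowers fully independent (no plant-level clustering or shared bee
budget).  A single seeded generator drives the whole cohort, so the same
config and seed reproduce the cohort exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .pollination import VisitModel
from .fertilization import FertilizationModel, fertilization_prob
from .growth import GrowthModel
from . import dist_stats


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of one cohort run, plus the RNG seed."""

    visit_model: VisitModel = field(default_factory=VisitModel)
    fert_model: FertilizationModel = field(default_factory=FertilizationModel)
    growth_model: GrowthModel = field(default_factory=GrowthModel)
    n_flowers: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_flowers) != self.n_flowers or self.n_flowers < 1:
            raise ValueError(f"n_flowers must be an integer >= 1, got {self.n_flowers}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class FlowerRecord:
    """One simulated flower: daily visits/pollen/fertilized, total, weight."""

    flower_id: int
    visits_by_day: tuple[int, ...]
    pollen_by_day: tuple[int, ...]
    fertilized_by_day: tuple[int, ...]
    achene_total: int
    weight: float
    marketable: bool


@dataclass(frozen=True)
class CohortResult:
    """Per-flower table plus summary statistics for one cohort run.

    ``records`` holds one row per flower with columns flower_id,
    x1..x<d> (visits), y1..y<d> (pollen), z1..z<d> (fertilized), z_sum,
    weight, marketable.  ``summary`` carries mean/SD/skewness/SE/z for
    z_sum and weight, the marketable fraction, the count of non-positive
    weights (an artifact of the unbounded Gaussian residual), and a
    config echo for provenance.
    """

    records: pd.DataFrame
    summary: dict
    config: SimulationConfig

    def iter_records(self):
        d = self.config.visit_model.bloom_days
        xc = [f"x{i}" for i in range(1, d + 1)]
        yc = [f"y{i}" for i in range(1, d + 1)]
        zc = [f"z{i}" for i in range(1, d + 1)]
        for row in self.records.itertuples(index=False):
            r = row._asdict()
            yield FlowerRecord(
                flower_id=int(r["flower_id"]),
                visits_by_day=tuple(int(r[c]) for c in xc),
                pollen_by_day=tuple(int(r[c]) for c in yc),
                fertilized_by_day=tuple(int(r[c]) for c in zc),
                achene_total=int(r["z_sum"]),
                weight=float(r["weight"]),
                marketable=bool(r["marketable"]),
            )


def _variable_summary(values: np.ndarray) -> dict:
    out = {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)),
    }
    if np.ptp(values) == 0:
        # a constant variable (e.g. z_sum under zero compatibility) has no asymmetry
        out.update(skewness=0.0, se_skewness=dist_stats.se_skewness(values.size), skewness_z=0.0)
    else:
        rep = dist_stats.skewness_report(values)
        out.update(skewness=rep.skewness, se_skewness=rep.se_skewness, skewness_z=rep.z_score)
    return out


def run_cohort(config: SimulationConfig) -> CohortResult:
    """Simulate ``n_flowers`` independent flowers and summarize the cohort.

    Draw order (all flowers vectorized): every day's visit counts, then
    fertilization day by day, then one weight residual per flower —
    matching the model's dependency graph.  Deterministic given the seed.
    """
    vm, fm, gm = config.visit_model, config.fert_model, config.growth_model
    n, days = config.n_flowers, vm.bloom_days
    rng = np.random.default_rng(config.seed)

    visits = rng.poisson(vm.lambda_visits, size=(n, days))
    pollen = vm.grains_per_visit * visits
    probs = fertilization_prob(np.arange(1, days + 1), fm)
    fertilized = rng.binomial(pollen, probs[np.newaxis, :])
    z_sum = fertilized.sum(axis=1)
    bias = rng.normal(0.0, gm.bias_sd, size=n) if gm.bias_sd > 0 else np.zeros(n)
    weight = gm.slope * z_sum + gm.intercept + bias
    marketable = weight > gm.marketable_threshold

    data = {"flower_id": np.arange(n)}
    for i in range(days):
        data[f"x{i + 1}"] = visits[:, i]
    for i in range(days):
        data[f"y{i + 1}"] = pollen[:, i]
    for i in range(days):
        data[f"z{i + 1}"] = fertilized[:, i]
    data["z_sum"] = z_sum
    data["weight"] = weight
    data["marketable"] = marketable
    records = pd.DataFrame(data)

    summary = {
        "n_flowers": n,
        "seed": config.seed,
        "z_sum": _variable_summary(z_sum.astype(float)),
        "weight": _variable_summary(weight),
        "marketable_fraction": float(marketable.mean()),
        "n_nonpositive_weights": int(np.sum(weight <= 0)),
        "config": config.to_dict(),
    }
    return CohortResult(records=records, summary=summary, config=config)


def expected_summaries(config: SimulationConfig) -> dict:
    """Closed-form means and variances implied by the model parameters.

    Per day n: E[Y_n] = grains * lambda and Var(Y_n) = grains^2 * lambda
    (pollen is a scaled Poisson count); thinning by p_n gives
    E[Z_n] = p_n E[Y_n] and Var(Z_n) = E[Y_n] p_n (1 - p_n) + p_n^2 Var(Y_n).
    Days are independent, so Z_sum's moments are the daily sums, and
    E[W] = slope E[Z_sum] + intercept, Var(W) = slope^2 Var(Z_sum) + bias_sd^2.
    """
    vm, fm, gm = config.visit_model, config.fert_model, config.growth_model
    days = np.arange(1, vm.bloom_days + 1)
    p = fertilization_prob(days, fm)
    e_y = vm.grains_per_visit * vm.lambda_visits
    var_y = vm.grains_per_visit**2 * vm.lambda_visits
    e_z = p * e_y
    var_z = e_y * p * (1.0 - p) + p**2 * var_y
    e_zsum = float(e_z.sum())
    var_zsum = float(var_z.sum())
    return {
        "e_pollen_per_day": float(e_y),
        "var_pollen_per_day": float(var_y),
        "e_fertilized_by_day": e_z.tolist(),
        "var_fertilized_by_day": var_z.tolist(),
        "e_z_sum": e_zsum,
        "var_z_sum": var_zsum,
        "e_weight": gm.slope * e_zsum + gm.intercept,
        "var_weight": gm.slope**2 * var_zsum + gm.bias_sd**2,
    }
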