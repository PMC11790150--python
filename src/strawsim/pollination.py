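"""Bee visitation and pollen deposition.

Bee visits to an open flower are rare, short events within a long daily
foraging window, so the number of visits X_n a flower receives on day n
of its bloom is modelled as Poisson with a constant daily rate; the rate
is identical across the days of the bloom (flower age does not change
bee behaviour).  Every visit deposits a fixed number of viable pollen
grains on the stigma, so the daily pollen load is Y_n = grains_per_visit
x X_n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class VisitModel:
    """Daily bee-visitation process for a single flower.

    Parameters
    ----------
    lambda_visits : float
        Mean bee visits per flower per day (Poisson rate). Default 4.5,
        typical of a greenhouse stocked with about one hive bee per plant.
    grains_per_visit : int
        Viable pollen grains deposited on the stigma per visit. Default 25.
    bloom_days : int
        Flower lifespan in days; the stigma is pollinated on each of these
        days. Default 5.
    """

    lambda_visits: float = 4.5
    grains_per_visit: int = 25
    bloom_days: int = 5

    def __post_init__(self) -> None:
        if not self.lambda_visits > 0:
            raise ValueError(f"lambda_visits must be > 0, got {self.lambda_visits}")
        if int(self.grains_per_visit) != self.grains_per_visit or self.grains_per_visit < 1:
            raise ValueError(f"grains_per_visit must be an integer >= 1, got {self.grains_per_visit}")
        if int(self.bloom_days) != self.bloom_days or self.bloom_days < 1:
            raise ValueError(f"bloom_days must be an integer >= 1, got {self.bloom_days}")


def visit_pmf(k, lambda_visits: float):
    """Probability that a flower receives exactly ``k`` bee visits in a day.

    Evaluates the Poisson mass function lambda^k e^-lambda / k!.
    ``k`` may be a scalar or an array of non-negative integers.
    """
    if not lambda_visits > 0:
        raise ValueError(f"lambda_visits must be > 0, got {lambda_visits}")
    karr = np.asarray(k)
    if np.any(karr < 0) or not np.issubdtype(karr.dtype, np.integer) and np.any(karr != np.floor(karr)):
        raise ValueError("k must be a non-negative integer")
    out = stats.poisson.pmf(karr, lambda_visits)
    return float(out) if np.isscalar(k) else out


def sample_visits(model: VisitModel, rng: np.random.Generator) -> np.ndarray:
    """Draw one bloom's worth of daily visit counts, X_1..X_bloom_days.

    Each day is an independent Poisson(lambda_visits) draw; the marginal
    distribution is identical across days.
    """
    return rng.poisson(model.lambda_visits, size=model.bloom_days)


def deposit_pollen(visits, grains_per_visit: int):
    """Pollen grains deposited for a given visit count: grains_per_visit * visits.

    Accepts a scalar or array of non-negative visit counts; output is
    always divisible by ``grains_per_visit``.
    """
    varr = np.asarray(visits)
    if np.any(varr < 0):
        raise ValueError("visits must be non-negative")
    if int(grains_per_visit) != grains_per_visit or grains_per_visit < 1:
        raise ValueError(f"grains_per_visit must be an integer >= 1, got {grains_per_visit}")
    out = int(grains_per_visit) * varr
    return int(out) if np.isscalar(visits) else out
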