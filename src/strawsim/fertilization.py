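"""Age-dependent ovule fertilization by deposited pollen.

A grain deposited on day n of the bloom fertilizes an ovule only if the
ageing stigma is still receptive and the (partially self-incompatible)
pollen is accepted.  Receptivity decays with flower age n as
exp(-decay_coeff * n**decay_power); the two stages multiply into a single
per-grain fertilization probability

    P_n = compatibility * exp(-decay_coeff * n**decay_power),

and the day's fertilized count is a binomial thinning Z_n ~ B(Y_n, P_n)
of the day's pollen load.  Each fertilized grain matures into one achene,
so the bloom's achene count is the sum of the daily Z_n.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .pollination import VisitModel


@dataclass(frozen=True)
class FertilizationModel:
    """Receptivity decay and self-compatibility of a cultivar.

    ``compatibility`` is the probability that compatible pollen on a
    receptive stigma proceeds to fertilization (0.8 for the Beni hoppe
    cultivar).  ``decay_coeff``/``decay_power`` shape the receptivity
    decline with flower age: near-full receptivity for the first three
    days, sharp loss by day five under the defaults (0.01, 3.6).
    """

    compatibility: float = 0.8
    decay_coeff: float = 0.01
    decay_power: float = 3.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.compatibility <= 1.0:
            raise ValueError(f"compatibility must be in [0, 1], got {self.compatibility}")
        if not self.decay_coeff > 0:
            raise ValueError(f"decay_coeff must be > 0, got {self.decay_coeff}")
        if not self.decay_power > 0:
            raise ValueError(f"decay_power must be > 0, got {self.decay_power}")


def _check_day(day) -> np.ndarray:
    darr = np.asarray(day)
    if np.any(darr < 1):
        raise ValueError("day (flower age) is 1-based and must be >= 1")
    return darr


def stigma_receptivity(day, model: FertilizationModel = FertilizationModel()):
    """Probability that the stigma can still receive pollen at age ``day``.

    exp(-decay_coeff * day**decay_power); strictly decreasing in day,
    in (0, 1].  ``day`` is 1-based (1 = first bloom day).
    """
    darr = _check_day(day)
    out = np.exp(-model.decay_coeff * np.power(darr, model.decay_power, dtype=float))
    return float(out) if np.isscalar(day) else out


def fertilization_prob(day, model: FertilizationModel = FertilizationModel()):
    """Per-grain fertilization probability on bloom day ``day``.

    compatibility * stigma_receptivity(day): both the receiving stage
    (receptive stigma) and the accepting stage (self-compatible pollen)
    must succeed.
    """
    out = model.compatibility * stigma_receptivity(day, model)
    return float(out) if np.isscalar(day) else out


def sample_fertilized(pollen, prob, rng: np.random.Generator):
    """Draw the number of grains fertilizing ovules: Binomial(pollen, prob)."""
    parr = np.asarray(pollen)
    if np.any(parr < 0):
        raise ValueError("pollen count must be non-negative")
    if np.any((np.asarray(prob) < 0) | (np.asarray(prob) > 1)):
        raise ValueError(f"fertilization probability must be in [0, 1], got {prob}")
    out = rng.binomial(parr, prob)
    return int(out) if np.isscalar(pollen) and np.isscalar(prob) else out


def accumulate_achenes(daily_fertilized: Sequence[int]) -> int:
    """Total achene count of a flower: the sum of its daily fertilized counts."""
    arr = np.asarray(daily_fertilized)
    if arr.size == 0:
        raise ValueError("daily_fertilized must be non-empty")
    if np.any(arr < 0):
        raise ValueError("daily fertilized counts must be non-negative")
    return int(arr.sum())


def exact_zsum_pmf(
    visit_model: VisitModel,
    fert_model: FertilizationModel,
    max_support: int = 200_000,
    tail_tol: float = 1e-13,
) -> np.ndarray:
    """Exact distribution of the bloom-total fertilized count Z_sum.

    Built by (a) compounding the Poisson visit count with the fixed
    grains-per-visit into each day's pollen-load pmf, (b) binomially
    thinning that load by the day's fertilization probability, and
    (c) convolving the daily pmfs across the bloom.  Intended as a
    brute-force oracle at small parameters; returns ``pmf`` where
    ``pmf[z]`` is P(Z_sum = z) and ``pmf.sum() >= 1 - 1e-8``.

    Raises
    ------
    ValueError
        If the enumerated support would exceed ``max_support`` entries;
        rerun with smaller lambda_visits / grains_per_visit / bloom_days.
    """
    lam = visit_model.lambda_visits
    g = int(visit_model.grains_per_visit)
    days = int(visit_model.bloom_days)

    # Truncate the Poisson visit count where the tail mass drops below tail_tol.
    kmax = int(stats.poisson.ppf(1.0 - tail_tol, lam)) + 1
    support = days * kmax * g + 1
    if support > max_support:
        raise ValueError(
            f"Z_sum support of {support} exceeds max_support={max_support}; "
            "use smaller lambda_visits, grains_per_visit or bloom_days"
        )
    pois = stats.poisson.pmf(np.arange(kmax + 1), lam)

    pmf = np.array([1.0])
    zgrid = np.arange(kmax * g + 1)
    for day in range(1, days + 1):
        p = fertilization_prob(day, fert_model)
        day_pmf = np.zeros(kmax * g + 1)
        for k in range(kmax + 1):
            n_grains = k * g
            day_pmf[: n_grains + 1] += pois[k] * stats.binom.pmf(zgrid[: n_grains + 1], n_grains, p)
        pmf = np.convolve(pmf, day_pmf)
    return pmf
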