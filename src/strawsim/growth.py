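"""Fruit growth: achene count to receptacle weight.

Fertilized achenes secrete the hormones that drive receptacle growth, so
fruit weight is affine in the achene total, W = slope * Z_sum + intercept,
plus a zero-mean Gaussian residual standing in for genotype and
environment effects not otherwise modelled.  Fruits over the marketable
threshold (10 g commercially) count toward marketable yield.

The residual SD is not a measured constant; the default 3.09 g is
calibrated so that the cohort-level weight SD,
sqrt(slope^2 * Var(Z_sum) + bias_sd^2), equals 4.42 g under the default
pollination/fertilization parameters (Var(Z_sum) = 3998.06 in closed
form) — see docs/methods.md for the derivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class GrowthModel:
    slope: float = 0.05  # grams of flesh per achene
    intercept: float = 2.0  # grams at zero achenes
    bias_sd: float = 3.09  # residual SD in grams (calibrated; see module docstring)
    marketable_threshold: float = 10.0  # grams

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")
        if not self.bias_sd >= 0:
            raise ValueError(f"bias_sd must be >= 0, got {self.bias_sd}")
        if not self.marketable_threshold > 0:
            raise ValueError(f"marketable_threshold must be > 0, got {self.marketable_threshold}")


def fruit_weight(achenes, model: GrowthModel, rng: np.random.Generator):
    """Fruit weight in grams for a given achene total.

    slope * achenes + intercept + Normal(0, bias_sd^2).  With bias_sd = 0
    the map is deterministic affine.  The residual is unbounded, so
    weights can (rarely) be non-positive; they are deliberately not
    clamped — cohort summaries count such artifacts instead.
    """
    aarr = np.asarray(achenes)
    if np.any(aarr < 0):
        raise ValueError("achene count must be non-negative")
    bias = rng.normal(0.0, model.bias_sd, size=aarr.shape) if model.bias_sd > 0 else np.zeros(aarr.shape)
    out = model.slope * aarr + model.intercept + bias
    return float(out) if np.isscalar(achenes) else out


def is_marketable(weight, threshold: float = 10.0):
    """Whether a fruit exceeds the marketable weight threshold (strictly 'over')."""
    out = np.asarray(weight) > threshold
    return bool(out) if np.isscalar(weight) else out


def marketable_fraction_normal(
    mean: float, sd: float, threshold: float, round_z: bool = False
) -> float:
    """Marketable fraction implied by a normal weight distribution.

    Returns 1 - Phi((threshold - mean) / sd).  With ``round_z`` the
    standardized score is rounded to two decimals before evaluating Phi,
    reproducing back-of-envelope arithmetic done on printed z tables
    (e.g. mean 14.3, SD 4.42, threshold 10 -> Phi(0.97) = 83.4%).
    """
    if not sd > 0:
        raise ValueError(f"sd must be > 0, got {sd}")
    z = (mean - threshold) / sd
    if round_z:
        z = round(z, 2)
    return float(stats.norm.cdf(z))
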