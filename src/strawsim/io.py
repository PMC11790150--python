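"""Configuration files and structured outputs.

The config format is a flat YAML mapping; every key is optional and
defaults to the standard greenhouse parameterization.  Unknown keys are
hard errors — silently ignoring a misspelled parameter in a simulator
invites silently wrong science.

Recognized keys (defaults in parentheses): lambda_visits (4.5),
grains_per_visit (25), bloom_days (5), compatibility (0.8),
decay_coeff (0.01), decay_power (3.6), slope (0.05), intercept (2.0),
bias_sd (3.09), marketable_threshold (10.0), n_flowers (10000), seed (0).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pollination import VisitModel
from .fertilization import FertilizationModel
from .growth import GrowthModel
from .cohort import SimulationConfig, CohortResult, run_cohort
from . import dist_stats


class ConfigError(ValueError):
    """Invalid, unknown, or out-of-range configuration input."""


_VISIT_KEYS = ("lambda_visits", "grains_per_visit", "bloom_days")
_FERT_KEYS = ("compatibility", "decay_coeff", "decay_power")
_GROWTH_KEYS = ("slope", "intercept", "bias_sd", "marketable_threshold")
_TOP_KEYS = ("n_flowers", "seed")
_ALL_KEYS = _VISIT_KEYS + _FERT_KEYS + _GROWTH_KEYS + _TOP_KEYS


def default_config(seed: int = 0, n_flowers: int = 10_000) -> SimulationConfig:
    """The standard greenhouse parameterization with the given seed."""
    return SimulationConfig(n_flowers=n_flowers, seed=seed)


def build_config(overrides: dict) -> SimulationConfig:
    """Build a validated SimulationConfig from a flat key->value mapping."""
    unknown = sorted(set(overrides) - set(_ALL_KEYS))
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}; valid keys: {', '.join(_ALL_KEYS)}")
    try:
        vm = VisitModel(**{k: overrides[k] for k in _VISIT_KEYS if k in overrides})
        fm = FertilizationModel(**{k: overrides[k] for k in _FERT_KEYS if k in overrides})
        gm = GrowthModel(**{k: overrides[k] for k in _GROWTH_KEYS if k in overrides})
        return SimulationConfig(
            visit_model=vm,
            fert_model=fm,
            growth_model=gm,
            **{k: overrides[k] for k in _TOP_KEYS if k in overrides},
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> SimulationConfig:
    """Load a YAML config file; an empty file yields all defaults."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a flat key: value mapping")
    return build_config(raw)


def config_overrides(config: SimulationConfig) -> dict:
    """Flatten a SimulationConfig back to the flat config-key mapping."""
    out = {}
    for k in _VISIT_KEYS:
        out[k] = getattr(config.visit_model, k)
    for k in _FERT_KEYS:
        out[k] = getattr(config.fert_model, k)
    for k in _GROWTH_KEYS:
        out[k] = getattr(config.growth_model, k)
    for k in _TOP_KEYS:
        out[k] = getattr(config, k)
    return out


def write_cohort_csv(result: CohortResult, path) -> Path:
    """Write the per-flower table as CSV; weights at 6-decimal precision.

    The fixed precision (sub-milligram, far below biological meaning)
    makes repeat runs byte-comparable.
    """
    path = Path(path)
    df = result.records.copy()
    df["weight"] = df["weight"].map(lambda w: f"{w:.6f}")
    df["marketable"] = df["marketable"].astype(int)
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"could not write cohort CSV to {path}: {exc}") from exc
    return path


def read_cohort_csv(path) -> pd.DataFrame:
    """Read back a cohort CSV written by :func:`write_cohort_csv`."""
    return pd.read_csv(path)


def write_summary_json(result: CohortResult, path, fit_weights: bool = True) -> Path:
    """Write the cohort summary (and optional weight-distribution fits) as JSON."""
    path = Path(path)
    summary = dict(result.summary)
    if fit_weights:
        w = result.records["weight"].to_numpy()
        nfit = dist_stats.fit_normal(w)
        lfit = dist_stats.fit_lognormal3(w)
        summary["fits"] = {
            "normal": dataclasses.asdict(nfit),
            "lognormal3": dataclasses.asdict(lfit),
        }
    try:
        path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise OSError(f"could not write summary JSON to {path}: {exc}") from exc
    return path


def write_manifest(config: SimulationConfig, outputs: list, path) -> Path:
    """Record the run's config, seed, tool version and output paths."""
    from . import __version__

    path = Path(path)
    missing = [str(p) for p in outputs if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"manifest refers to missing outputs: {missing}")
    manifest = {
        "tool": "strawsim",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seed": config.seed,
        "config": config_overrides(config),
        "outputs": [str(p) for p in outputs],
    }
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def generate_pseudo_empirical(n: int, seed: int, path=None) -> pd.DataFrame:
    """Synthetic stand-in for an observed fruit-weight sample.

    Draws ``n`` weights from the default generative model under an
    independent seed and (optionally) writes them as a one-column CSV —
    useful for exercising the two-sample comparison workflow when no
    field data are at hand.  It is model output, not data: a two-sample
    test against a fresh default cohort should accept, by construction.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    res = run_cohort(default_config(seed=seed, n_flowers=n))
    df = pd.DataFrame({"weight": np.round(res.records["weight"].to_numpy(), 6)})
    if path is not None:
        df.to_csv(path, index=False, float_format="%.6f")
    return df
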