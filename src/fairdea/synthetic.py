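"""Synthetic province-by-year panels with known ground truth.

The generator emulates the shape of a provincial healthcare panel —
31 units in three macro-regions observed over 6 years, strictly
positive right-skewed resource indicators — while planting recoverable
structure for every analysis stage:

* inequality: per-capita resource levels are region multipliers times a
  lognormal within-region dispersion, so between-region and
  within-region Theil components can be dialled independently;
* efficiency: outputs equal a known frontier applied to the inputs,
  shrunk by exp(-u) with u drawn half-normal (the standard one-sided
  inefficiency of stochastic frontier analysis), so true efficiencies
  exp(-u) are recorded;
* determinants: ``generate_tobit_sample`` draws censored-Gaussian
  responses from a known coefficient vector for parameter-recovery
  checks.

All randomness flows through one ``numpy.random.Generator`` seeded
explicitly; no global state is touched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .panel import PanelDataset, REGIONS

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_panel",
    "generate_tobit_sample",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of a generated panel.

    Defaults mirror the study shape: 31 units (11 eastern, 8 central,
    12 western), 6 years starting 2014, moderate one-sided
    inefficiency, and a modest eastern per-capita resource advantage
    on top of a larger within-region dispersion — so, as in observed
    provincial panels, most measured inequality sits within regions
    rather than between them.
    """

    n_units: int = 31
    n_years: int = 6
    region_sizes: tuple[int, int, int] = (11, 8, 12)
    first_year: int = 2014
    seed: int = 0
    technology: str = "cobb_douglas"  # or "linear_crs"
    returns_to_scale: float = 0.95    # Cobb-Douglas elasticity sum
    inefficiency_scale: float = 0.15  # sigma_u of the half-normal
    region_multipliers: tuple[float, float, float] = (1.15, 1.0, 0.95)
    within_dispersion: float = 0.25   # sd of log per-capita resources
    growth_rate: float = 0.03         # common yearly resource growth

    def __post_init__(self) -> None:
        if sum(self.region_sizes) != self.n_units:
            raise ValueError(
                f"region sizes {self.region_sizes} must sum to n_units={self.n_units}"
            )
        if self.inefficiency_scale < 0 or self.within_dispersion < 0:
            raise ValueError("dispersion parameters must be >= 0")
        if any(m <= 0 for m in self.region_multipliers):
            raise ValueError("region multipliers must be > 0")
        if self.technology not in ("linear_crs", "cobb_douglas"):
            raise ValueError(f"unknown technology {self.technology!r}")


@dataclass
class SyntheticTruth:
    """What the generator knows that the estimators must recover."""

    efficiency: pd.DataFrame          # unit_id, year, u, efficiency=exp(-u)
    region_multipliers: dict[str, float]
    technology: str
    returns_to_scale: float


# per-capita base levels (unit-scale magnitudes, cosmetic realism only)
_PER_CAPITA_BASE = {
    "X1": 6.5e-3,   # health technical personnel per person
    "X2": 2.5e-3,
    "X3": 2.8e-3,
    "X4": 6.0e-3,
    "X5": 1.4e-1,   # total assets, 10^4 yuan per person
    "X6": 4.0e-5,   # expenses, 10^8 yuan per person
}


def generate_panel(config: SyntheticConfig) -> tuple[PanelDataset, SyntheticTruth]:
    """Draw one balanced panel plus its ground truth.

    Outputs are frontier(inputs) x exp(-u), u ~ half-normal(sigma_u),
    with all three outputs proportional so the planted efficiency is a
    property of the unit, not of the output mix.
    """
    rng = np.random.default_rng(config.seed)
    years = [config.first_year + k for k in range(config.n_years)]
    unit_ids = []
    unit_regions = []
    for r_idx, (region, size) in enumerate(zip(REGIONS, config.region_sizes)):
        for k in range(size):
            unit_ids.append(f"{region[0].upper()}{k + 1:02d}")
            unit_regions.append(region)

    mult = dict(zip(REGIONS, config.region_multipliers))
    n = config.n_units
    population = np.exp(rng.normal(math.log(4.0e7), 0.6, size=n))  # persons
    # Per-unit per-capita deviation (within-region dispersion): a
    # persistent unit component plus a smaller yearly jitter, so
    # inequality indices move over time as they do in real panels.
    # Under the ray (linear_crs) technology one shared deviation keeps
    # all input bundles proportional across units, so the planted
    # efficiency is exactly the CCR score; Cobb-Douglas mixes freely.
    sigma_w = config.within_dispersion

    def _draw_dev() -> np.ndarray:
        return np.exp(rng.normal(0.0, sigma_w, size=n))

    def _draw_jitter() -> np.ndarray:
        return np.exp(rng.normal(0.0, 0.3 * sigma_w, size=n))

    if config.technology == "linear_crs":
        shared = _draw_dev()
        persistent_dev = {ind: shared for ind in _PER_CAPITA_BASE}
    else:
        persistent_dev = {ind: _draw_dev() for ind in _PER_CAPITA_BASE}
    gdp0 = np.exp(rng.normal(math.log(5.5e4), 0.4, size=n)) * np.array(
        [mult[r] for r in unit_regions]
    )
    density = np.exp(rng.normal(math.log(300.0), 1.0, size=n))
    urban0 = np.clip(stats.norm.cdf(rng.normal(0.3, 0.5, size=n)), 0.2, 0.95)

    rows = []
    truth_rows = []
    for t_idx, year in enumerate(years):
        growth = (1.0 + config.growth_rate) ** t_idx
        u = np.abs(rng.normal(0.0, 1.0, size=n)) * config.inefficiency_scale
        if config.technology == "linear_crs":
            jit = _draw_jitter()
            unit_dev = {ind: persistent_dev[ind] * jit for ind in _PER_CAPITA_BASE}
        else:
            unit_dev = {
                ind: persistent_dev[ind] * _draw_jitter() for ind in _PER_CAPITA_BASE
            }
        for j in range(n):
            region = unit_regions[j]
            pop = population[j]
            inputs = {
                ind: base
                * mult[region]
                * unit_dev[ind][j]
                * growth
                * pop
                for ind, base in _PER_CAPITA_BASE.items()
            }
            frontier = _frontier_output(inputs, config)
            eff = math.exp(-u[j])
            if config.technology == "linear_crs":
                # strictly proportional outputs preserve the ray technology
                y1 = 2.0e-5 * frontier * eff
            else:
                y1 = 88.0 * eff  # bed utilization as a bounded rate, in %
            row = {
                "unit_id": unit_ids[j],
                "region": region,
                "year": year,
                **inputs,
                "Y1": y1,
                "Y2": 6.0 * frontier * eff,
                "Y3": 0.25 * frontier * eff,
                "population": pop,
                "gdp_per_capita": gdp0[j] * growth,
                "population_density": density[j],
                "urbanization_rate": min(urban0[j] * (1.0 + 0.01 * t_idx), 1.0),
            }
            rows.append(row)
            truth_rows.append(
                {"unit_id": unit_ids[j], "year": year, "u": u[j], "efficiency": eff}
            )
    dataset = PanelDataset(pd.DataFrame(rows))
    truth = SyntheticTruth(
        efficiency=pd.DataFrame(truth_rows).sort_values(["unit_id", "year"]).reset_index(drop=True),
        region_multipliers=mult,
        technology=config.technology,
        returns_to_scale=config.returns_to_scale,
    )
    return dataset, truth


def _frontier_output(inputs: dict[str, float], config: SyntheticConfig) -> float:
    """Scalar frontier index of an input bundle.

    linear_crs: a fixed linear aggregate of the inputs (a ray
    technology: doubling all inputs doubles the frontier output).
    cobb_douglas: product of powers with elasticity sum
    ``returns_to_scale`` (< 1 gives decreasing returns).
    """
    names = ("X1", "X2", "X3", "X4", "X6")
    if config.technology == "linear_crs":
        return sum(inputs[k] for k in names) / len(names)
    alpha = config.returns_to_scale / len(names)
    val = 1.0
    for k in names:
        val *= inputs[k] ** alpha
    # rescale so magnitudes stay in a plausible volume range
    return 200.0 * val


def generate_tobit_sample(
    n: int,
    beta: Sequence[float],
    sigma: float,
    seed: int = 0,
    censor_fraction: float | None = None,
    upper: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Censored-Gaussian regression sample y = min(X beta + eps, upper).

    The design has a leading intercept column and standard-normal
    covariates.  When ``censor_fraction`` is given, the intercept is
    shifted so the expected share of censored rows (an average of
    normal upper-tail probabilities over the drawn design) matches it.

    Returns (X, y, truth) where truth records the coefficient vector
    actually used, sigma, the censoring indicator and the analytic
    expected censoring fraction.
    """
    beta = np.asarray(beta, dtype=float)
    p = beta.size
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if n <= p:
        raise ValueError("need more observations than coefficients")
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    beta_used = beta.copy()
    if censor_fraction is not None:
        if not 0.0 < censor_fraction < 1.0:
            raise ValueError("censor_fraction must lie in (0, 1)")
        xb_rest = X[:, 1:] @ beta[1:]

        def expected(delta: float) -> float:
            return float(
                np.mean(stats.norm.sf((upper - (beta[0] + delta) - xb_rest) / sigma))
            ) - censor_fraction

        delta = optimize.brentq(expected, -50.0 * sigma - 10.0, 50.0 * sigma + 10.0)
        beta_used[0] = beta[0] + delta
    xb = X @ beta_used
    latent = xb + sigma * rng.standard_normal(n)
    y = np.minimum(latent, upper)
    truth = {
        "beta": beta_used,
        "sigma": float(sigma),
        "censored": latent >= upper,
        "expected_censor_fraction": float(np.mean(stats.norm.sf((upper - xb) / sigma))),
    }
    return X, y, truth
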