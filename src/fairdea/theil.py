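"""Population-weighted Theil-T inequality of resource allocation with a
two-level within/between-region decomposition.

For resource amounts :math:`Y_j` and weights (population) :math:`W_j`,
with shares :math:`s_j = Y_j/\\sum Y` and :math:`w_j = W_j/\\sum W`,

.. math:: T = \\sum_j s_j \\ln(s_j / w_j),

a Kullback-Leibler divergence of the resource distribution from the
population distribution: 0 under exactly proportional (per-capita equal)
allocation, :math:`\\ln n` when one of n equally weighted units holds
everything.  Grouping units into regions splits T additively,

.. math:: T = T_w + T_b, \\qquad T_w = \\sum_i (Y_i/Y)\\, T_i,

where :math:`T_i` is the within-region index of region i and
:math:`T_b` the index computed on region aggregates.  Contribution
rates report :math:`T_w/T` and :math:`T_b/T` in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import PanelDataset

__all__ = ["TheilDecomposition", "theil_index", "theil_decompose", "theil_table"]


@dataclass(frozen=True)
class TheilDecomposition:
    """Decomposition of one indicator-year's inequality."""

    indicator: str
    year: int
    total: float
    within: float
    between: float
    by_region: dict[str, float]
    #: percent of the total attributable to within-region dispersion;
    #: NaN (undefined) when the total index is exactly 0.
    within_contribution: float
    between_contribution: float


def theil_index(amounts, weights) -> float:
    """Theil-T index of ``amounts`` against ``weights``.

    Zero amounts contribute nothing (x ln x -> 0 limit); negative
    entries, an all-zero amount vector, or a zero weight paired with a
    positive amount are domain errors.
    """
    a = np.asarray(amounts, dtype=float)
    w = np.asarray(weights, dtype=float)
    if a.shape != w.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("amounts and weights must be equal-length 1-d vectors")
    if (a < 0).any() or (w < 0).any():
        raise ValueError("amounts and weights must be non-negative")
    if a.sum() == 0:
        raise ValueError("total amount is zero; Theil index undefined")
    if w.sum() == 0:
        raise ValueError("total weight is zero; Theil index undefined")
    if ((w == 0) & (a > 0)).any():
        raise ValueError("zero weight with positive amount: share ratio undefined")
    s = a / a.sum()
    p = w / w.sum()
    mask = s > 0
    return float(np.sum(s[mask] * np.log(s[mask] / p[mask])))


def theil_decompose(
    dataset: PanelDataset, indicator: str, year: int
) -> TheilDecomposition:
    """Within/between-region decomposition for one indicator and year."""
    if indicator not in dataset.frame.columns:
        raise KeyError(f"unknown indicator {indicator!r}")
    sl = dataset.year_slice(year)
    regions = dataset.regions
    if len(regions) < 2:
        raise ValueError("decomposition needs at least two regions")
    counts = sl["region"].value_counts()
    small = [r for r in regions if counts.get(r, 0) < 2]
    if small:
        raise ValueError(f"regions need >= 2 units for decomposition: {small}")

    amounts = sl[indicator].to_numpy(float)
    weights = sl["population"].to_numpy(float)
    total_amount = amounts.sum()

    by_region: dict[str, float] = {}
    region_amounts = []
    region_weights = []
    within = 0.0
    for r in regions:
        m = (sl["region"] == r).to_numpy()
        t_i = theil_index(amounts[m], weights[m])
        by_region[r] = t_i
        ya = amounts[m].sum()
        region_amounts.append(ya)
        region_weights.append(weights[m].sum())
        within += (ya / total_amount) * t_i
    between = theil_index(region_amounts, region_weights)
    total = within + between
    if total > 0:
        wc = 100.0 * within / total
        bc = 100.0 * between / total
    else:
        wc = bc = float("nan")
    return TheilDecomposition(
        indicator=indicator,
        year=int(year),
        total=total,
        within=within,
        between=between,
        by_region=by_region,
        within_contribution=wc,
        between_contribution=bc,
    )


def theil_table(
    dataset: PanelDataset,
    indicators: Sequence[str],
    years: Sequence[int] | None = None,
) -> pd.DataFrame:
    """One row per indicator-year: overall index, within/between indices
    and their percent contributions."""
    if not list(indicators):
        raise ValueError("no indicators requested")
    years = list(years) if years is not None else list(dataset.years)
    if not years:
        raise ValueError("no years requested")
    rows = []
    for ind in indicators:
        for yr in years:
            d = theil_decompose(dataset, ind, yr)
            rows.append(
                {
                    "indicator": ind,
                    "year": yr,
                    "theil_total": d.total,
                    "theil_within": d.within,
                    "within_contribution_pct": d.within_contribution,
                    "theil_between": d.between,
                    "between_contribution_pct": d.between_contribution,
                }
            )
    return pd.DataFrame(rows)
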