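"""Malmquist total factor productivity index for adjacent year pairs,
with the standard catch-up / frontier-shift / scale decomposition
(FGNZ): tfpch = effch x techch = pech x sech x techch.

All distance functions are input-oriented radial efficiencies.  The
index and effch/techch use CRS distances; pech uses same-period VRS
distances and sech is the residual effch/pech.  Cross-period CRS
distances always exist for positive data and may exceed 1 (a unit
outside the other period's frontier); VRS cross-period programs can be
infeasible and are never needed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dea import solve_envelopment
from .panel import AnalysisConfig, PanelDataset

__all__ = [
    "MalmquistRecord",
    "cross_period_distance",
    "malmquist_decompose",
    "malmquist_panel",
    "malmquist_summary",
]


@dataclass(frozen=True)
class MalmquistRecord:
    unit: str
    period: tuple[int, int]
    d_t_t: float      # D^t(x^t, y^t)
    d_t1_t1: float    # D^{t+1}(x^{t+1}, y^{t+1})
    d_t_t1: float     # D^t(x^{t+1}, y^{t+1})
    d_t1_t: float     # D^{t+1}(x^t, y^t)
    effch: float
    techch: float
    pech: float
    sech: float
    tfpch: float


def cross_period_distance(
    x: np.ndarray,
    y: np.ndarray,
    frontier_X: np.ndarray,
    frontier_Y: np.ndarray,
    vrs: bool = False,
    tolerance: float = 1e-6,
) -> float:
    """Input-oriented radial distance of (x, y) to the given frontier.

    Under CRS the LP is always feasible for positive data; the value is
    <= 1 when the point lies inside the frontier's technology set and
    can exceed 1 otherwise.
    """
    sol = solve_envelopment(
        x, y, frontier_X, frontier_Y, vrs=vrs, tolerance=tolerance, stage2=False
    )
    return sol.theta


def _period_matrices(dataset: PanelDataset, year: int, config: AnalysisConfig):
    return dataset.matrices(year, config.dea_inputs, config.dea_outputs)


def malmquist_decompose(
    dataset: PanelDataset,
    unit: str,
    t: int,
    config: AnalysisConfig | None = None,
) -> MalmquistRecord:
    """Decomposition for one unit over the adjacent pair (t, t+1)."""
    config = config or AnalysisConfig()
    years = list(dataset.years)
    if t not in years or years.index(t) + 1 >= len(years):
        raise KeyError(f"no adjacent period after year {t}")
    t1 = years[years.index(t) + 1]
    units_t, Xt, Yt = _period_matrices(dataset, t, config)
    units_t1, Xt1, Yt1 = _period_matrices(dataset, t1, config)
    j = units_t.index(unit)
    j1 = units_t1.index(unit)
    tol = config.lp_tolerance
    x_t, y_t = Xt[:, j], Yt[:, j]
    x_t1, y_t1 = Xt1[:, j1], Yt1[:, j1]

    d_t_t = cross_period_distance(x_t, y_t, Xt, Yt, vrs=False, tolerance=tol)
    d_t1_t1 = cross_period_distance(x_t1, y_t1, Xt1, Yt1, vrs=False, tolerance=tol)
    d_t_t1 = cross_period_distance(x_t1, y_t1, Xt, Yt, vrs=False, tolerance=tol)
    d_t1_t = cross_period_distance(x_t, y_t, Xt1, Yt1, vrs=False, tolerance=tol)
    v_t = cross_period_distance(x_t, y_t, Xt, Yt, vrs=True, tolerance=tol)
    v_t1 = cross_period_distance(x_t1, y_t1, Xt1, Yt1, vrs=True, tolerance=tol)

    effch = d_t1_t1 / d_t_t
    techch = math.sqrt((d_t_t1 / d_t1_t1) * (d_t_t / d_t1_t))
    pech = v_t1 / v_t
    sech = effch / pech
    tfpch = effch * techch
    return MalmquistRecord(
        unit=unit,
        period=(int(t), int(t1)),
        d_t_t=d_t_t,
        d_t1_t1=d_t1_t1,
        d_t_t1=d_t_t1,
        d_t1_t=d_t1_t,
        effch=effch,
        techch=techch,
        pech=pech,
        sech=sech,
        tfpch=tfpch,
    )


def malmquist_panel(
    dataset: PanelDataset, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """All units x all adjacent year pairs, one record per row."""
    config = config or AnalysisConfig()
    if len(dataset.years) < 2:
        raise ValueError("Malmquist analysis needs at least two years")
    rows = []
    for t in dataset.years[:-1]:
        for unit in dataset.units:
            r = malmquist_decompose(dataset, unit, t, config)
            rows.append(
                {
                    "unit": r.unit,
                    "year_from": r.period[0],
                    "year_to": r.period[1],
                    "effch": r.effch,
                    "techch": r.techch,
                    "pech": r.pech,
                    "sech": r.sech,
                    "tfpch": r.tfpch,
                }
            )
    return pd.DataFrame(rows)


def _gmean(v: pd.Series) -> float:
    return float(np.exp(np.log(v.to_numpy(float)).mean()))


def malmquist_summary(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Geometric-mean summaries: per year pair (across units) and per
    unit (across year pairs).  Components > 1 indicate improvement,
    = 1 no change, < 1 decline."""
    if records is None or len(records) == 0:
        raise ValueError("no Malmquist records to summarise")
    comp = ["effch", "techch", "pech", "sech", "tfpch"]
    by_year = (
        records.groupby(["year_from", "year_to"])[comp].agg(_gmean).reset_index()
    )
    by_unit = records.groupby("unit")[comp].agg(_gmean).reset_index()
    return by_year, by_unit
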