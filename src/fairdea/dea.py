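"""Input-oriented envelopment DEA: CCR (constant returns) and BCC
(variable returns) radial efficiency with slack maximisation,
TE = PTE x SE decomposition, returns-to-scale classification and
projection (input redundancy / output insufficiency) analysis.

The envelopment program for a decision-making unit (x0, y0) against a
reference technology spanned by columns of X (inputs) and Y (outputs):

    min theta
    s.t.  X @ lam + s_minus = theta * x0
          Y @ lam - s_plus  = y0
          sum(lam) = 1          (BCC only)
          lam, s_minus, s_plus >= 0

The non-Archimedean slack penalty of the classical formulation is
realised as the standard two-stage procedure: solve for the radial
theta* first, then re-solve with theta fixed at theta* maximising the
slack sum.  Returns to scale are read off the CCR max-slack solution's
lambda sum: < 1 increasing, > 1 decreasing, otherwise constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .panel import AnalysisConfig, PanelDataset, round_half_up

__all__ = [
    "EnvelopmentSolution",
    "DEAScore",
    "solve_envelopment",
    "score_unit",
    "score_year",
    "projection_table",
    "dea_year_table",
]


class DEASolverError(RuntimeError):
    """The LP solver failed on a problem that should be feasible."""


@dataclass(frozen=True)
class EnvelopmentSolution:
    theta: float
    lambdas: np.ndarray
    slack_inputs: np.ndarray
    slack_outputs: np.ndarray


def solve_envelopment(
    x0: np.ndarray,
    y0: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    vrs: bool,
    tolerance: float = 1e-6,
    stage2: bool = True,
) -> EnvelopmentSolution:
    """Two-stage input-oriented envelopment solve.

    Parameters
    ----------
    x0, y0
        Input/output vectors of the evaluated unit (strictly positive).
    X, Y
        Reference-set matrices, one column per reference unit.
    vrs
        True for BCC (convexity constraint), False for CCR.
    stage2
        When False, only the radial theta is computed (slacks and
        peer weights are returned as zeros); used where only the
        distance-function value is needed.
    """
    x0 = np.asarray(x0, dtype=float).ravel()
    y0 = np.asarray(y0, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    m, n = X.shape
    s, n2 = Y.shape
    if n != n2 or x0.size != m or y0.size != s:
        raise ValueError("inconsistent envelopment problem dimensions")
    if (x0 <= 0).any() or (y0 <= 0).any() or (X <= 0).any() or (Y <= 0).any():
        raise ValueError("DEA requires strictly positive data")

    # Radial efficiency is invariant to the measurement units of each
    # dimension; normalising every row by its reference-set mean keeps
    # the LP well scaled for the simplex solver.  Slacks are mapped back
    # to the original units afterwards.
    x_scale = X.mean(axis=1)
    y_scale = Y.mean(axis=1)
    X = X / x_scale[:, None]
    Y = Y / y_scale[:, None]
    x0 = x0 / x_scale
    y0 = y0 / y_scale

    # Stage 1: min theta over (theta, lam).
    c = np.zeros(1 + n)
    c[0] = 1.0
    A_ub = np.zeros((m + s, 1 + n))
    A_ub[:m, 0] = -x0
    A_ub[:m, 1:] = X
    A_ub[m:, 1:] = -Y
    b_ub = np.concatenate([np.zeros(m), -y0])
    A_eq = b_eq = None
    if vrs:
        A_eq = np.zeros((1, 1 + n))
        A_eq[0, 1:] = 1.0
        b_eq = np.array([1.0])
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=[(0, None)] * (1 + n),
        method="highs",
    )
    if not res.success:
        raise DEASolverError(f"stage-1 envelopment LP failed: {res.message}")
    theta = float(res.x[0])
    if not stage2:
        return EnvelopmentSolution(
            theta=theta,
            lambdas=np.zeros(n),
            slack_inputs=np.zeros(m),
            slack_outputs=np.zeros(s),
        )

    # Stage 2: fix theta, maximise total slack.  Variables (lam, s-, s+).
    nv = n + m + s
    c2 = np.zeros(nv)
    c2[n:] = -1.0
    A_eq2 = np.zeros((m + s + (1 if vrs else 0), nv))
    A_eq2[:m, :n] = X
    A_eq2[:m, n : n + m] = np.eye(m)
    A_eq2[m : m + s, :n] = Y
    A_eq2[m : m + s, n + m :] = -np.eye(s)
    b_eq2 = np.concatenate([theta * x0, y0])
    if vrs:
        A_eq2[m + s, :n] = 1.0
        b_eq2 = np.concatenate([b_eq2, [1.0]])
    res2 = None
    for relax in (0.0, 1e-9, 1e-7):
        b_try = b_eq2.copy()
        b_try[:m] = (theta + relax) * x0
        res2 = linprog(
            c2,
            A_eq=A_eq2,
            b_eq=b_try,
            bounds=[(0, None)] * nv,
            method="highs",
        )
        if res2.success:
            break
    if res2 is None or not res2.success:
        raise DEASolverError(f"stage-2 slack LP failed: {res2.message if res2 else 'n/a'}")
    lam = res2.x[:n].copy()
    s_in = res2.x[n : n + m].copy()
    s_out = res2.x[n + m :].copy()
    s_in[s_in < tolerance] = 0.0
    s_out[s_out < tolerance] = 0.0
    lam[lam < tolerance] = 0.0
    s_in *= x_scale
    s_out *= y_scale
    return EnvelopmentSolution(theta=theta, lambdas=lam, slack_inputs=s_in, slack_outputs=s_out)


@dataclass
class DEAScore:
    """Static efficiency of one unit-year.

    ``te`` is comprehensive (CRS/CCR) efficiency, ``pte`` the pure
    technical (VRS/BCC) efficiency, ``se = te/pte`` scale efficiency.
    Slacks, peers and projections come from the BCC max-slack solution;
    the returns-to-scale label from the CCR lambda sum.
    """

    unit: str
    year: int
    te: float
    pte: float
    se: float
    rts: str  # "irs" | "crs" | "drs"
    efficient: bool
    lambdas: dict[str, float]
    slack_inputs: np.ndarray
    slack_outputs: np.ndarray
    inputs: np.ndarray
    outputs: np.ndarray
    projected_inputs: np.ndarray
    projected_outputs: np.ndarray
    redundancy_value: np.ndarray
    redundancy_rate: np.ndarray
    insufficiency_value: np.ndarray
    insufficiency_rate: np.ndarray

    @property
    def rts_label(self) -> str:
        """Report label: '-' for constant returns to scale."""
        return "-" if self.rts == "crs" else self.rts


def _rts_from_lambda_sum(lam_sum: float, tol: float) -> str:
    if lam_sum < 1.0 - tol:
        return "irs"
    if lam_sum > 1.0 + tol:
        return "drs"
    return "crs"


def score_unit(
    dataset: PanelDataset,
    unit: str,
    year: int,
    config: AnalysisConfig | None = None,
) -> DEAScore:
    """Score one unit-year against all units of that year."""
    config = config or AnalysisConfig()
    units, X, Y = dataset.matrices(year, config.dea_inputs, config.dea_outputs)
    if unit not in units:
        raise KeyError(f"unit {unit!r} not present in year {year}")
    j = units.index(unit)
    return _score_from_matrices(units, X, Y, j, year, config)


def _score_from_matrices(
    units: Sequence[str],
    X: np.ndarray,
    Y: np.ndarray,
    j: int,
    year: int,
    config: AnalysisConfig,
) -> DEAScore:
    tol = config.lp_tolerance
    x0, y0 = X[:, j], Y[:, j]
    ccr = solve_envelopment(x0, y0, X, Y, vrs=False, tolerance=tol)
    bcc = solve_envelopment(x0, y0, X, Y, vrs=True, tolerance=tol)
    te = min(ccr.theta, 1.0)
    pte = min(bcc.theta, 1.0)
    se = te / pte
    if te >= 1.0 - config.effective_threshold:
        rts = "crs"
    else:
        rts = _rts_from_lambda_sum(float(ccr.lambdas.sum()), tol)
    slack_sum = bcc.slack_inputs.sum() + bcc.slack_outputs.sum()
    efficient = pte >= 1.0 - config.effective_threshold and slack_sum <= tol

    if efficient:
        s_in = np.zeros_like(bcc.slack_inputs)
        s_out = np.zeros_like(bcc.slack_outputs)
        proj_in = x0.copy()
        proj_out = y0.copy()
        red_val = np.zeros_like(x0)
        ins_val = np.zeros_like(y0)
    else:
        s_in = bcc.slack_inputs
        s_out = bcc.slack_outputs
        proj_in = pte * x0 - s_in
        proj_out = y0 + s_out
        red_val = (1.0 - pte) * x0 + s_in
        ins_val = s_out.copy()
    return DEAScore(
        unit=str(units[j]),
        year=int(year),
        te=te,
        pte=pte,
        se=se,
        rts=rts,
        efficient=efficient,
        lambdas={str(units[k]): float(v) for k, v in enumerate(bcc.lambdas) if v > 0},
        slack_inputs=s_in,
        slack_outputs=s_out,
        inputs=x0.copy(),
        outputs=y0.copy(),
        projected_inputs=proj_in,
        projected_outputs=proj_out,
        redundancy_value=red_val,
        redundancy_rate=red_val / x0,
        insufficiency_value=ins_val,
        insufficiency_rate=ins_val / y0,
    )


def score_year(
    dataset: PanelDataset, year: int, config: AnalysisConfig | None = None
) -> list[DEAScore]:
    config = config or AnalysisConfig()
    units, X, Y = dataset.matrices(year, config.dea_inputs, config.dea_outputs)
    if len(units) < 2:
        raise ValueError("DEA needs at least two units per year")
    return [
        _score_from_matrices(units, X, Y, j, year, config) for j in range(len(units))
    ]


def projection_table(
    scores: Sequence[DEAScore], config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Redundancy/insufficiency table for non-(pure-technically-)efficient
    units: per input the removable amount (1 - pte) x0 + s- and its rate
    against the observed input; per output the shortfall s+ and its rate."""
    config = config or AnalysisConfig()
    rows = []
    for sc in scores:
        if sc.efficient:
            continue
        row: dict[str, object] = {"unit": sc.unit, "year": sc.year}
        for i, name in enumerate(config.dea_inputs):
            row[f"redundancy_value_{name}"] = sc.redundancy_value[i]
            row[f"redundancy_rate_{name}_pct"] = 100.0 * sc.redundancy_rate[i]
        for r, name in enumerate(config.dea_outputs):
            row[f"insufficient_value_{name}"] = sc.insufficiency_value[r]
            row[f"insufficient_rate_{name}_pct"] = 100.0 * sc.insufficiency_rate[r]
        rows.append(row)
    return pd.DataFrame(rows)


def dea_year_table(
    dataset: PanelDataset, year: int, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-unit TE/PTE/SE/RTS table for one year plus a summary dict
    (arithmetic means rounded per config, count of frontier-efficient
    units)."""
    config = config or AnalysisConfig()
    scores = score_year(dataset, year, config)
    return summarize_scores(scores, config)


def summarize_scores(
    scores: Sequence[DEAScore], config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    config = config or AnalysisConfig()
    if not scores:
        raise ValueError("no scores to summarise")
    table = pd.DataFrame(
        {
            "unit": [s.unit for s in scores],
            "year": [s.year for s in scores],
            "te": [s.te for s in scores],
            "pte": [s.pte for s in scores],
            "se": [s.se for s in scores],
            "rts": [s.rts_label for s in scores],
        }
    )
    d = config.digits
    thr = 1.0 - config.effective_threshold
    summary = {
        "mean_te": round_half_up(table["te"].mean(), d),
        "mean_pte": round_half_up(table["pte"].mean(), d),
        "mean_se": round_half_up(table["se"].mean(), d),
        "effective_count": int((table["te"] >= thr).sum()),
    }
    return table, summary
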