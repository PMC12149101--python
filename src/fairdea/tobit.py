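"""Right-censored (upper limit 1) Tobit regression of DEA efficiency on
development, resource-quantity and allocation-fairness covariates.

The latent model is y* = X beta + eps, eps ~ N(0, sigma^2); the
observed response is y = min(y*, 1), matching DEA scores that pile up
at the frontier.  The log-likelihood sums the Gaussian density term for
uncensored rows and the upper-tail probability Phi((X beta - 1)/sigma)
for rows at the limit.  Estimation is Newton-type maximisation started
at OLS; standard errors come from the inverse observed information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess

from .panel import AnalysisConfig, PanelDataset

__all__ = [
    "RegressionTable",
    "TobitFit",
    "build_regression_table",
    "tobit_loglike",
    "fit_tobit",
    "tobit_report",
]

#: Covariate order of the determinants regression (after the intercept).
COVARIATE_ORDER = (
    "lngdp",
    "lnpd",
    "urban",
    "lnpeople",
    "lnbed",
    "lnassets",
    "people",
    "bed",
    "assets",
)

#: Panel columns whose logs enter the regression, with their target names.
_LOG_MAP = {
    "lngdp": "gdp_per_capita",
    "lnpd": "population_density",
    "lnpeople": "X1",
    "lnbed": "X4",
    "lnassets": "X5",
}

#: Theil fairness covariates: regression name -> indicator column.
_THEIL_MAP = {"people": "X1", "bed": "X4", "assets": "X5"}


@dataclass
class RegressionTable:
    """Design for the two-stage efficiency-determinants regression.

    ``frame`` has one row per unit-year with the response (comprehensive
    efficiency, in (0, 1]) and the nine covariates.
    """

    frame: pd.DataFrame

    @property
    def response(self) -> np.ndarray:
        return self.frame["efficiency"].to_numpy(float)

    @property
    def design(self) -> np.ndarray:
        """n x (1 + p) design matrix with a leading intercept column."""
        X = self.frame.loc[:, list(COVARIATE_ORDER)].to_numpy(float)
        return np.column_stack([np.ones(len(X)), X])

    @property
    def names(self) -> list[str]:
        return ["const", *COVARIATE_ORDER]


def build_regression_table(
    dataset: PanelDataset,
    dea_scores: pd.DataFrame,
    theil_results: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> RegressionTable:
    """Assemble the regression table from the three upstream stages.

    ``dea_scores`` needs columns (unit, year, te); ``theil_results`` is
    the long theil table with per-region indices encoded via
    ``theil_decompose`` outputs — here we re-derive from the panel to
    keep the assignment rule explicit:  each unit-year receives, for
    each fairness indicator, the within-region Theil index of its own
    region (or the national total, per config).
    """
    from .theil import theil_decompose  # local import to avoid a cycle

    config = config or AnalysisConfig()
    df = dataset.frame.copy()
    eff = dea_scores.loc[:, ["unit", "year", "te"]].rename(
        columns={"unit": "unit_id", "te": "efficiency"}
    )
    merged = df.merge(eff, on=["unit_id", "year"], how="left", validate="1:1")
    if merged["efficiency"].isna().any():
        missing = merged.loc[merged["efficiency"].isna(), ["unit_id", "year"]]
        raise ValueError(
            f"DEA scores missing for unit-years: {missing.to_records(index=False).tolist()}"
        )

    out = merged.loc[:, ["unit_id", "region", "year", "efficiency"]].copy()
    for name, src in _LOG_MAP.items():
        vals = merged[src].to_numpy(float)
        if (vals <= 0).any():
            i = int(np.argmax(vals <= 0))
            raise ValueError(
                f"cannot take log of non-positive {src!r} for unit "
                f"{merged['unit_id'].iloc[i]!r}, year {merged['year'].iloc[i]}"
            )
        out[name] = np.log(vals)
    out["urban"] = merged["urbanization_rate"].to_numpy(float)

    # Fairness covariates: one value per (region, year, indicator).
    theil_cov: dict[tuple[str, int, str], float] = {}
    for year in dataset.years:
        for cov_name, indicator in _THEIL_MAP.items():
            d = theil_decompose(dataset, indicator, year)
            for region in dataset.regions:
                key = (region, int(year), cov_name)
                if config.theil_covariate_rule == "region":
                    theil_cov[key] = d.by_region[region]
                else:
                    theil_cov[key] = d.total
    for cov_name in _THEIL_MAP:
        out[cov_name] = [
            theil_cov[(r, int(y), cov_name)]
            for r, y in zip(out["region"], out["year"])
        ]
    cols = ["unit_id", "region", "year", "efficiency", *COVARIATE_ORDER]
    return RegressionTable(frame=out.loc[:, cols].reset_index(drop=True))


@dataclass
class TobitFit:
    names: list[str]
    params: np.ndarray          # beta (incl. intercept)
    sigma: float
    bse: np.ndarray             # SEs for beta then sigma (length p+1)
    sigma_se: float
    zvalues: np.ndarray
    pvalues: np.ndarray
    loglike: float
    n_censored: int
    n_uncensored: int
    score_norm: float           # max |gradient component| at the optimum


def tobit_loglike(
    beta: np.ndarray,
    sigma: float,
    X: np.ndarray,
    y: np.ndarray,
    upper: float = 1.0,
) -> float:
    """Censored-Gaussian log-likelihood at (beta, sigma)."""
    if sigma <= 0:
        return -np.inf
    xb = X @ beta
    cens = y >= upper
    ll = 0.0
    if (~cens).any():
        ll += float(np.sum(stats.norm.logpdf((y[~cens] - xb[~cens]) / sigma) - math.log(sigma)))
    if cens.any():
        ll += float(np.sum(stats.norm.logcdf((xb[cens] - upper) / sigma)))
    return ll


def _negll_and_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray, upper: float):
    p = X.shape[1]
    beta = theta[:p]
    sigma = math.exp(theta[p])
    xb = X @ beta
    cens = y >= upper
    ll = 0.0
    gbeta = np.zeros(p)
    glogs = 0.0
    if (~cens).any():
        e = (y[~cens] - xb[~cens]) / sigma
        ll += float(np.sum(stats.norm.logpdf(e) - math.log(sigma)))
        gbeta += X[~cens].T @ e / sigma
        glogs += float(np.sum(e * e - 1.0))
    if cens.any():
        z = (xb[cens] - upper) / sigma
        logcdf = stats.norm.logcdf(z)
        lam = np.exp(stats.norm.logpdf(z) - logcdf)  # inverse Mills ratio
        ll += float(np.sum(logcdf))
        gbeta += X[cens].T @ lam / sigma
        glogs += float(np.sum(-lam * z))
    grad = np.concatenate([gbeta, [glogs]])
    return -ll, -grad


def fit_tobit(
    table: RegressionTable | tuple[np.ndarray, np.ndarray],
    upper_limit: float = 1.0,
) -> TobitFit:
    """Maximum-likelihood fit of the right-censored Gaussian model.

    Accepts either a :class:`RegressionTable` or a raw ``(X, y)`` pair
    whose design matrix already carries an intercept column.
    """
    if isinstance(table, RegressionTable):
        X, y, names = table.design, table.response, table.names
    else:
        X, y = table
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        names = ["const"] + [f"x{i}" for i in range(1, X.shape[1])]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("more parameters than observations")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify a minimal set of linearly dependent columns by QR pivoting
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[i] for i in np.where(diag < 1e-9 * diag.max())[0]]
        raise ValueError(f"design matrix is rank deficient (collinear columns: {bad or 'unknown'})")
    cens = y >= upper_limit
    if cens.all():
        raise ValueError("all observations censored; parameters not identified")

    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    s0 = float(np.sqrt(np.maximum(resid @ resid / n, 1e-12)))
    theta0 = np.concatenate([beta0, [math.log(s0)]])

    res = optimize.minimize(
        _negll_and_grad,
        theta0,
        args=(X, y, upper_limit),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    # polish with a second pass if the gradient is not tight yet
    if np.max(np.abs(res.jac)) > 1e-6:
        res = optimize.minimize(
            _negll_and_grad,
            res.x,
            args=(X, y, upper_limit),
            jac=True,
            method="BFGS",
            options={"gtol": 1e-12, "maxiter": 1000},
        )
    theta = res.x
    beta = theta[:p]
    sigma = math.exp(theta[p])

    # Observed information in the (beta, sigma) parametrisation.
    def negll_nat(par: np.ndarray) -> float:
        return -tobit_loglike(par[:p], par[p], X, y, upper_limit)

    H = approx_hess(np.concatenate([beta, [sigma]]), negll_nat)
    cov = np.linalg.inv(H)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    z = beta / se[:p]
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    _, grad = _negll_and_grad(theta, X, y, upper_limit)
    return TobitFit(
        names=names,
        params=beta,
        sigma=sigma,
        bse=se,
        sigma_se=float(se[p]),
        zvalues=z,
        pvalues=pvals,
        loglike=-float(res.fun),
        n_censored=int(cens.sum()),
        n_uncensored=int((~cens).sum()),
        score_norm=float(np.max(np.abs(grad))),
    )


def _stars(p: float) -> str:
    if p <= 0.01:
        return "***"
    if p <= 0.05:
        return "**"
    return ""


def tobit_report(fit: TobitFit, digits: int = 3) -> pd.DataFrame:
    """Coefficient table: estimate, SE, z, p and significance stars
    (** at 5%, *** at 1%)."""
    return pd.DataFrame(
        {
            "variable": fit.names,
            "coefficient": fit.params,
            "std_error": fit.bse[: len(fit.params)],
            "z_value": fit.zvalues,
            "p_value": fit.pvalues,
            "signif": [_stars(p) for p in fit.pvalues],
        }
    )
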