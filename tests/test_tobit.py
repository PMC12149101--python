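import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fairdea.panel import AnalysisConfig
from fairdea.synthetic import SyntheticConfig, generate_panel, generate_tobit_sample
from fairdea.theil import theil_decompose, theil_table
from fairdea.tobit import (
    COVARIATE_ORDER,
    RegressionTable,
    build_regression_table,
    fit_tobit,
    tobit_loglike,
    tobit_report,
)


def _uncensored_sample(rng, n=300, p=3):
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    beta = rng.uniform(-0.5, 0.5, p)
    beta[0] -= 3.0  # keep every latent response far below the limit
    y = X @ beta + 0.2 * rng.standard_normal(n)
    assert (y < 1).all()
    return X, y


class TestFit:
    def test_no_censoring_reduces_to_ols(self, rng):
        X, y = _uncensored_sample(rng)
        fit = fit_tobit((X, y))
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma_mle = math.sqrt(np.mean((y - X @ beta_ols) ** 2))
        assert np.allclose(fit.params, beta_ols, atol=1e-6)
        assert fit.sigma == pytest.approx(sigma_mle, abs=1e-6)
        assert fit.n_censored == 0

    def test_loglike_matches_independent_evaluation(self, rng):
        X, y, _ = generate_tobit_sample(400, [0.8, 0.2, -0.3], 0.15, seed=11)
        fit = fit_tobit((X, y))
        # direct evaluation of the censored-Gaussian likelihood
        xb = X @ fit.params
        cens = y >= 1.0
        ll = float(
            np.sum(stats.norm.logpdf(y[~cens], xb[~cens], fit.sigma))
            + np.sum(stats.norm.logsf(1.0, xb[cens], fit.sigma))
        )
        assert fit.loglike == pytest.approx(ll, abs=1e-8)
        assert tobit_loglike(fit.params, fit.sigma, X, y) == pytest.approx(ll, abs=1e-8)

    def test_score_vanishes_at_optimum(self):
        X, y, _ = generate_tobit_sample(500, [0.7, 0.3, -0.2], 0.1, seed=5)
        fit = fit_tobit((X, y))
        assert fit.score_norm <= 1e-5 * len(y)

    def test_ascent_over_ols_start(self):
        X, y, _ = generate_tobit_sample(400, [0.9, 0.2, -0.1], 0.1, seed=9)
        fit = fit_tobit((X, y))
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma_ols = math.sqrt(np.mean((y - X @ beta_ols) ** 2))
        assert fit.loglike >= tobit_loglike(beta_ols, sigma_ols, X, y)

    def test_parameter_recovery_single_seed(self):
        beta = np.array([0.5, 0.2, -0.3])
        X, y, truth = generate_tobit_sample(2000, beta, 0.1, seed=42)
        fit = fit_tobit((X, y))
        for est, se, true in zip(fit.params, fit.bse, truth["beta"]):
            assert abs(est - true) <= 3.0 * se
        assert abs(fit.sigma - 0.1) <= 3.0 * fit.sigma_se

    def test_equivariance_under_covariate_scaling(self):
        X, y, _ = generate_tobit_sample(600, [0.6, 0.25, -0.2], 0.12, seed=3)
        fit0 = fit_tobit((X, y))
        c = 40.0
        X2 = X.copy()
        X2[:, 1] *= c
        fit1 = fit_tobit((X2, y))
        assert fit1.params[1] == pytest.approx(fit0.params[1] / c, rel=1e-6)
        assert fit1.zvalues[1] == pytest.approx(fit0.zvalues[1], rel=1e-5)
        assert fit1.pvalues[1] == pytest.approx(fit0.pvalues[1], abs=1e-6)

    def test_degenerate_designs_rejected(self, rng):
        X = np.column_stack([np.ones(50), rng.standard_normal(50)])
        X = np.column_stack([X, X[:, 1] * 2.0])  # collinear copy
        y = rng.uniform(0.2, 0.8, 50)
        with pytest.raises(ValueError, match="rank"):
            fit_tobit((X, y))
        with pytest.raises(ValueError, match="censored"):
            fit_tobit((np.ones((20, 1)), np.ones(20)))


@pytest.fixture(scope="module")
def panel_and_table():
    cfg = AnalysisConfig()
    ds, _ = generate_panel(SyntheticConfig(seed=7, n_units=12, n_years=3,
                                           region_sizes=(4, 4, 4)))
    scores = pd.DataFrame(
        [
            {"unit": u, "year": y, "te": 0.5 + 0.4 * (((i * 7 + j * 13) % 10) / 10)}
            for i, u in enumerate(ds.units)
            for j, y in enumerate(ds.years)
        ]
    )
    table = build_regression_table(ds, scores, None, cfg)
    return ds, table


class TestRegressionTable:
    def test_cardinality(self, panel_and_table):
        ds, table = panel_and_table
        assert len(table.frame) == len(ds.units) * len(ds.years)
        assert table.design.shape == (len(table.frame), 10)
        assert table.names == ["const", *COVARIATE_ORDER]

    def test_log_transforms_are_exact(self, panel_and_table):
        ds, table = panel_and_table
        row = table.frame.iloc[0]
        src = ds.frame.iloc[0]
        assert row["lngdp"] == pytest.approx(math.log(src["gdp_per_capita"]))
        assert row["lnpeople"] == pytest.approx(math.log(src["X1"]))
        assert row["lnassets"] == pytest.approx(math.log(src["X5"]))
        assert row["urban"] == pytest.approx(src["urbanization_rate"])

    def test_same_region_year_share_theil_covariates(self, panel_and_table):
        ds, table = panel_and_table
        f = table.frame
        for (region, year), grp in f.groupby(["region", "year"]):
            for cov in ("people", "bed", "assets"):
                assert grp[cov].nunique() == 1

    def test_region_rule_matches_decomposition(self, panel_and_table):
        ds, table = panel_and_table
        f = table.frame
        d = theil_decompose(ds, "X1", ds.years[0])
        sub = f[f.year == ds.years[0]]
        for region in ds.regions:
            got = sub.loc[sub.region == region, "people"].iloc[0]
            assert got == pytest.approx(d.by_region[region], abs=1e-12)

    def test_missing_scores_rejected(self, panel_and_table):
        ds, _ = panel_and_table
        short = pd.DataFrame({"unit": [ds.units[0]], "year": [ds.years[0]], "te": [1.0]})
        with pytest.raises(ValueError):
            build_regression_table(ds, short, None, AnalysisConfig())


class TestReport:
    def test_stars_at_conventional_levels(self):
        X, y, _ = generate_tobit_sample(500, [0.7, 0.3, -0.2], 0.1, seed=5)
        fit = fit_tobit((X, y))
        report = tobit_report(fit)
        assert len(report) == 3
        for _, row in report.iterrows():
            if row["p_value"] <= 0.01:
                assert row["signif"] == "***"
            elif row["p_value"] <= 0.05:
                assert row["signif"] == "**"
            else:
                assert row["signif"] == ""

    def test_zero_coefficient_yields_p_one(self):
        fit = fit_tobit(generate_tobit_sample(500, [0.7, 0.3, -0.2], 0.1, seed=5)[:2])
        fit.params = np.array([0.0, 0.0, 0.0])
        fit.zvalues = fit.params / fit.bse[:3]
        fit.pvalues = 2.0 * stats.norm.sf(np.abs(fit.zvalues))
        report = tobit_report(fit)
        assert np.allclose(report["p_value"], 1.0)
        assert (report["signif"] == "").all()
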