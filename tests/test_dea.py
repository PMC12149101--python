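import numpy as np
import pytest

from fairdea.dea import (
    dea_year_table,
    projection_table,
    score_unit,
    score_year,
    solve_envelopment,
    summarize_scores,
)
from fairdea.panel import AnalysisConfig

from conftest import make_panel, random_panel
from _oracles import ccr_ratio_oracle, envelopment_vertex_oracle

CFG_1x1 = AnalysisConfig(dea_inputs=("X1",), dea_outputs=("Y1",))


def _panel_1x1(x, y, year=2014):
    units = [f"u{j}" for j in range(len(x))]
    recs = []
    for j, u in enumerate(units):
        recs.append(
            {"unit_id": u, "region": "eastern" if j % 2 else "western",
             "year": year, "X1": x[j], "Y1": y[j]}
        )
    return make_panel(recs), units


class TestSolveEnvelopment:
    def test_self_reference_is_efficient(self):
        sol = solve_envelopment([2.0, 3.0], [1.0], [[2.0], [3.0]], [[1.0]], vrs=True)
        assert sol.theta == pytest.approx(1.0, abs=1e-9)
        assert sol.lambdas[0] == pytest.approx(1.0, abs=1e-9)
        assert sol.slack_inputs.sum() + sol.slack_outputs.sum() == pytest.approx(0.0, abs=1e-9)

    def test_ccr_three_unit_worked_example(self):
        X = np.array([[2.0, 4.0, 5.0]])
        Y = np.array([[2.0, 2.0, 10.0]])
        expected = {0: 0.5, 1: 0.25, 2: 1.0}
        for j, theta in expected.items():
            sol = solve_envelopment(X[:, j], Y[:, j], X, Y, vrs=False)
            assert sol.theta == pytest.approx(theta, abs=1e-9)

    def test_bcc_three_unit_worked_example(self):
        X = np.array([[2.0, 4.0, 5.0]])
        Y = np.array([[2.0, 2.0, 10.0]])
        expected = {0: 1.0, 1: 0.5, 2: 1.0}
        for j, theta in expected.items():
            sol = solve_envelopment(X[:, j], Y[:, j], X, Y, vrs=True)
            assert sol.theta == pytest.approx(theta, abs=1e-9)

    def test_dimension_and_positivity_errors(self):
        with pytest.raises(ValueError):
            solve_envelopment([1.0], [1.0], [[1.0, 2.0]], [[1.0]], vrs=False)
        with pytest.raises(ValueError):
            solve_envelopment([0.0], [1.0], [[1.0]], [[1.0]], vrs=False)


class TestScoreUnit:
    def test_worked_example_scores_and_rts(self):
        ds, units = _panel_1x1([2.0, 4.0, 5.0], [2.0, 2.0, 10.0])
        a = score_unit(ds, "u0", 2014, CFG_1x1)
        assert a.te == pytest.approx(0.5, abs=1e-9)
        assert a.pte == pytest.approx(1.0, abs=1e-9)
        assert a.se == pytest.approx(0.5, abs=1e-9)
        assert a.rts == "irs"  # CCR peer is u2 with lambda = 0.2

    def test_efficient_unit_is_flagged_constant(self):
        ds, units = _panel_1x1([2.0, 4.0, 5.0], [2.0, 2.0, 10.0])
        c = score_unit(ds, "u2", 2014, CFG_1x1)
        assert c.te == c.pte == c.se == 1.0
        assert c.rts_label == "-"
        assert c.efficient

    def test_te_never_exceeds_pte(self, rng):
        cfg = AnalysisConfig(dea_inputs=("X1", "X2"), dea_outputs=("Y1", "Y2"))
        for _ in range(10):
            ds = random_panel(rng)
            for s in score_year(ds, 2014, cfg):
                assert s.te <= s.pte + 1e-9
                assert 0.0 < s.se <= 1.0 + 1e-9


class TestOracleAgreement:
    def test_ccr_matches_ratio_closed_form(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 8))
            x = rng.uniform(0.5, 5.0, n)
            y = rng.uniform(0.5, 5.0, n)
            expected = ccr_ratio_oracle(x, y)
            X, Y = x[None, :], y[None, :]
            for j in range(n):
                sol = solve_envelopment(X[:, j], Y[:, j], X, Y, vrs=False)
                assert sol.theta == pytest.approx(expected[j], abs=1e-6)

    @pytest.mark.parametrize("vrs", [False, True])
    def test_matches_vertex_enumeration_on_small_panels(self, rng, vrs):
        for _ in range(8):
            n = int(rng.integers(3, 7))
            m = int(rng.integers(1, 4))
            s = int(rng.integers(1, 3))
            X = rng.uniform(0.5, 5.0, (m, n))
            Y = rng.uniform(0.5, 5.0, (s, n))
            for j in range(n):
                sol = solve_envelopment(X[:, j], Y[:, j], X, Y, vrs=vrs)
                oracle = envelopment_vertex_oracle(X[:, j], Y[:, j], X, Y, vrs=vrs)
                assert sol.theta == pytest.approx(oracle, abs=1e-4)


class TestInvariances:
    def test_units_invariance(self, rng):
        n = 6
        X = rng.uniform(0.5, 5.0, (2, n))
        Y = rng.uniform(0.5, 5.0, (2, n))
        base = [solve_envelopment(X[:, j], Y[:, j], X, Y, vrs=False).theta for j in range(n)]
        X2 = X.copy()
        X2[1] *= 1000.0  # remeasure one input in different units
        Y2 = Y.copy()
        Y2[0] *= 0.001
        for j in range(n):
            theta = solve_envelopment(X2[:, j], Y2[:, j], X2, Y2, vrs=False).theta
            assert theta == pytest.approx(base[j], abs=1e-7)

    def test_dominated_unit_changes_no_scores(self, rng):
        n = 5
        X = rng.uniform(1.0, 5.0, (2, n))
        Y = rng.uniform(1.0, 5.0, (2, n))
        base = [solve_envelopment(X[:, j], Y[:, j], X, Y, vrs=True).theta for j in range(n)]
        # dominated: more input than unit 0, less output
        X2 = np.column_stack([X, X[:, 0] * 2.0])
        Y2 = np.column_stack([Y, Y[:, 0] * 0.5])
        for j in range(n):
            theta = solve_envelopment(X2[:, j], Y2[:, j], X2, Y2, vrs=True).theta
            assert theta == pytest.approx(base[j], abs=1e-7)


class TestProjection:
    def test_efficient_unit_has_zero_projection(self):
        ds, _ = _panel_1x1([2.0, 4.0, 5.0], [2.0, 2.0, 10.0])
        c = score_unit(ds, "u2", 2014, CFG_1x1)
        assert np.all(c.redundancy_value == 0)
        assert np.all(c.insufficiency_value == 0)
        assert np.allclose(c.projected_inputs, c.inputs)

    def test_radial_redundancy_of_inefficient_unit(self):
        ds, _ = _panel_1x1([2.0, 4.0, 5.0], [2.0, 2.0, 10.0])
        b = score_unit(ds, "u1", 2014, CFG_1x1)
        assert b.pte == pytest.approx(0.5, abs=1e-9)
        # redundancy = (1 - pte) * x0 + slack = 0.5 * 4 = 2, rate 50%
        assert b.redundancy_value[0] == pytest.approx(2.0, abs=1e-6)
        assert b.redundancy_rate[0] == pytest.approx(0.5, abs=1e-6)
        assert b.projected_inputs[0] <= b.inputs[0]
        assert b.projected_outputs[0] >= b.outputs[0]

    def test_rates_invariant_to_input_rescaling(self, rng):
        cfg = AnalysisConfig(dea_inputs=("X1", "X2"), dea_outputs=("Y1",))
        ds = random_panel(rng)
        scores = {s.unit: s for s in score_year(ds, 2014, cfg)}
        df = ds.frame.copy()
        df["X2"] *= 100.0
        from fairdea.panel import PanelDataset

        rescored = {s.unit: s for s in score_year(PanelDataset(df), 2014, cfg)}
        for u, s0 in scores.items():
            s1 = rescored[u]
            assert np.allclose(s1.redundancy_rate, s0.redundancy_rate, atol=1e-6)
            # the rescaled input's redundancy *value* scales with it
            if not s0.efficient:
                assert s1.redundancy_value[1] == pytest.approx(
                    100.0 * s0.redundancy_value[1], rel=1e-4, abs=1e-4
                )

    def test_projection_table_only_lists_inefficient_units(self, rng):
        ds, _ = _panel_1x1([2.0, 4.0, 5.0], [2.0, 2.0, 10.0])
        scores = score_year(ds, 2014, CFG_1x1)
        table = projection_table(scores, CFG_1x1)
        assert set(table["unit"]) == {"u1"}  # u0 and u2 are BCC-efficient


class TestYearTable:
    def test_summary_means_and_effective_count(self):
        ds, _ = _panel_1x1([2.0, 4.0, 5.0], [2.0, 2.0, 10.0])
        table, summary = dea_year_table(ds, 2014, CFG_1x1)
        assert len(table) == 3
        assert summary["effective_count"] == 1
        assert summary["mean_te"] == pytest.approx(
            round((0.5 + 0.25 + 1.0) / 3, 3), abs=1e-9
        )

    def test_requires_two_units(self):
        ds, _ = _panel_1x1([2.0], [2.0])
        with pytest.raises(ValueError):
            dea_year_table(ds, 2014, CFG_1x1)
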