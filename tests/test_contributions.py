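"""Contribution decomposition: closed forms against an independent
root-finding oracle, error propagation, and round-trip identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import fsolve

import qcniche as q
from qcniche.contributions import (
    AttenuationFactors,
    DivisionData,
    OBSERVED_DIVISION_DATA,
    bernoulli_error,
    monte_carlo_errors,
    predict_frequencies,
    solve_contributions,
    sweep_qB,
)

# Frozen oracle values for the measured frequencies at qB=0.5, qW=0.8,
# obtained by numerically solving the three stationary ratio equations
# F^bravo/F^WT = b/a, F^wox5/F^WT = c/a, F^dm/F^WT = d/a with fsolve
# (residual < 5e-16), independent of the closed forms under test.
ORACLE_T = (0.19231722428748466, 0.016319285387082216, 1.0371111420136794)


class TestBernoulliError:
    @pytest.mark.parametrize("p", [0.0, 1.0])
    def test_degenerate_proportions_have_zero_error(self, p):
        assert bernoulli_error(p, 15) == 0.0

    @pytest.mark.parametrize(
        "p, n, expected",
        [(0.5, 15, 0.12909944487358055), (0.3939, 15, 0.12615936746829387)],
    )
    def test_direct_formula(self, p, n, expected):
        assert bernoulli_error(p, n) == pytest.approx(expected, rel=1e-12)

    def test_matches_monte_carlo_proportion_spread(self):
        rng = np.random.default_rng(0)
        draws = rng.binomial(15, 0.5, size=10**6) / 15
        assert draws.std() == pytest.approx(bernoulli_error(0.5, 15), rel=5e-3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bernoulli_error(1.2, 15)
        with pytest.raises(ValueError):
            bernoulli_error(0.5, 0)


class TestSolveContributions:
    def test_equal_frequencies_give_zero_contributions(self):
        data = DivisionData(a=0.6, b=0.6, c=0.6, d=0.6)
        est = solve_contributions(data)
        assert est.T_B == est.T_W == est.T_BW == 0.0
        assert est.F0 == 0.6

    def test_measured_data_matches_root_finding_oracle(self, division_data):
        est = solve_contributions(division_data, AttenuationFactors(0.8, 0.5))
        assert est.T_B == pytest.approx(ORACLE_T[0], rel=1e-12)
        assert est.T_W == pytest.approx(ORACLE_T[1], rel=1e-12)
        assert est.T_BW == pytest.approx(ORACLE_T[2], rel=1e-12)
        assert est.F0 == division_data.d

    def test_oracle_recomputation(self, division_data):
        # re-derive the frozen oracle inside the suite: solve the ratio
        # equations numerically and confirm the closed forms agree
        a, b, c, d = division_data.as_tuple()
        qB, qW = 0.5, 0.8

        def eqs(v):
            TB, TW, TBW = v
            FWT = d / (1 + TB + TW + TBW)
            return [
                d / (1 + TW * qW) / FWT - b / a,
                d / (1 + TB * qB) / FWT - c / a,
                d / FWT - d / a,
            ]

        oracle = fsolve(eqs, [0.1, 0.1, 1.0])
        est = solve_contributions(division_data)
        np.testing.assert_allclose(
            [est.T_B, est.T_W, est.T_BW], oracle, rtol=1e-9
        )

    def test_negative_contributions_are_allowed(self):
        # d < c means WOX5 removal lowers division: T_B comes out negative
        data = DivisionData(a=0.5, b=0.6, c=0.8, d=0.7)
        est = solve_contributions(data)
        assert est.T_B < 0


class TestPredictFrequencies:
    def test_zero_contributions_give_baseline_everywhere(self):
        assert predict_frequencies(0.6, 0, 0, 0) == (0.6, 0.6, 0.6, 0.6)

    def test_round_trip_on_measured_data(self, division_data):
        est = solve_contributions(division_data)
        freqs = predict_frequencies(est.F0, est.T_B, est.T_W, est.T_BW, est.q)
        np.testing.assert_allclose(freqs, division_data.as_tuple(), rtol=1e-15)

    def test_round_trip_on_random_valid_inputs(self):
        rng = np.random.default_rng(12)
        n_ok = 0
        while n_ok < 1000:
            vals = rng.uniform(0.05, 0.95, size=4)
            qs = AttenuationFactors(*rng.uniform(0.1, 1.5, size=2))
            data = DivisionData(*vals)
            est = solve_contributions(data, qs)
            try:
                freqs = predict_frequencies(est.F0, est.T_B, est.T_W, est.T_BW, qs)
            except ValueError:
                continue  # degenerate draw: a predicted denominator <= 0
            np.testing.assert_allclose(freqs, data.as_tuple(), rtol=1e-12)
            n_ok += 1

    @settings(max_examples=200, derandomize=True)
    @given(
        freqs=st.tuples(*[st.floats(0.05, 0.95) for _ in range(4)]),
        qW=st.floats(0.1, 1.5),
        qB=st.floats(0.1, 1.5),
    )
    def test_round_trip_property(self, freqs, qW, qB):
        # solve_contributions and predict_frequencies are exact algebraic
        # inverses wherever the forward model is defined
        qs = AttenuationFactors(qW_bravo=qW, qB_wox5=qB)
        data = DivisionData(*freqs)
        est = solve_contributions(data, qs)
        try:
            out = predict_frequencies(est.F0, est.T_B, est.T_W, est.T_BW, qs)
        except ValueError:
            return  # degenerate: a contribution sum reaches -1
        np.testing.assert_allclose(out, freqs, rtol=1e-10)

    def test_repression_sign_convention(self):
        # a lone positive joint contribution lowers the WT frequency below dm
        wt, _, _, dm = predict_frequencies(0.8, 0.0, 0.0, 1.5)
        assert wt < dm
        # increasing any single T strictly decreases its predicted frequency
        base = predict_frequencies(0.8, 0.2, 0.3, 0.5)
        up_B = predict_frequencies(0.8, 0.4, 0.3, 0.5)
        up_W = predict_frequencies(0.8, 0.2, 0.5, 0.5)
        assert up_B[0] < base[0] and up_B[2] < base[2]
        assert up_W[0] < base[0] and up_W[1] < base[1]

    def test_undefined_frequency_rejected(self):
        with pytest.raises(ValueError):
            predict_frequencies(0.8, -2.0, 0.0, 0.0)


class TestErrorPropagation:
    def test_analytic_deltas_match_linearized_monte_carlo(self, division_data):
        est = solve_contributions(division_data)
        mc = monte_carlo_errors(division_data, est.q, n_draws=200_000, seed=1)
        assert mc["delta_T_B"] == pytest.approx(est.delta_T_B, rel=0.02)
        assert mc["delta_T_W"] == pytest.approx(est.delta_T_W, rel=0.02)
        assert mc["delta_T_BW"] == pytest.approx(est.delta_T_BW, rel=0.02)

    def test_deltas_scale_with_sqrt_n_eff(self):
        d15 = solve_contributions(DivisionData(*OBSERVED_DIVISION_DATA.as_tuple(), n_eff=15))
        d60 = solve_contributions(DivisionData(*OBSERVED_DIVISION_DATA.as_tuple(), n_eff=60))
        assert d60.delta_T_B == pytest.approx(d15.delta_T_B / 2, rel=1e-12)
        assert d60.delta_T_BW == pytest.approx(d15.delta_T_BW / 2, rel=1e-12)


class TestSweep:
    def test_tb_scales_inversely_with_qb_and_tw_constant(self, division_data):
        df = sweep_qB(division_data, qW=0.8, qB_grid=np.linspace(0.1, 1.0, 10))
        np.testing.assert_allclose(
            df.T_B * df.qB_wox5, df.T_B.iloc[0] * df.qB_wox5.iloc[0], rtol=1e-12
        )
        assert df.T_W.nunique() == 1
        assert df.T_BW.nunique() == len(df)  # T_BW varies through T_B

    def test_reference_row_matches_single_solve(self, division_data):
        df = sweep_qB(division_data, qW=0.8, qB_grid=[0.5])
        est = solve_contributions(division_data, AttenuationFactors(0.8, 0.5))
        row = df.iloc[0]
        assert row.T_B == est.T_B and row.T_W == est.T_W and row.T_BW == est.T_BW
        assert row.delta_T_BW == est.delta_T_BW

    def test_invalid_grid_rejected(self, division_data):
        with pytest.raises(ValueError):
            sweep_qB(division_data, qB_grid=[0.5, -0.1])


class TestModelResultsInterface:
    def test_fit_reproduces_observations_exactly(self):
        res = q.QCDivisionModel().fit()
        np.testing.assert_allclose(
            res.fitted, OBSERVED_DIVISION_DATA.as_tuple(), rtol=1e-15
        )
        assert "T_BW" in res.summary()

    def test_from_counts(self):
        model = q.QCDivisionModel.from_counts(
            n_divided={"WT": 4, "bravo": 13, "wox5": 12, "bravo_wox5": 13},
            n_roots={"WT": 10, "bravo": 15, "wox5": 15, "bravo_wox5": 15},
        )
        assert model.data.a == pytest.approx(0.4)
        assert model.data.n_eff == 15
        res = model.fit()
        assert res.estimate.F0 == pytest.approx(13 / 15)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            DivisionData(a=0.0, b=0.5, c=0.5, d=0.5)
        with pytest.raises(ValueError):
            AttenuationFactors(qW_bravo=-0.1)
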