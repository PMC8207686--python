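"""Dynamics right-hand sides, genotype clamping, and the complex model's
mass-action structure."""

import numpy as np
import pytest

import qcniche as q
from qcniche.models import free_fraction_report
from qcniche.parameters import ValidationError


class TestTwoVariableRhs:
    def test_wt_at_origin_gives_basal_rates(self, params):
        m = q.get_model("alleviation", params)
        np.testing.assert_allclose(
            m.rhs([0, 0], q.GENOTYPES["WT"]), [params.alpha, params.gamma]
        )

    def test_bravo_clamp_forces_zero_derivative_and_zero_B(self, params):
        m = q.get_model("alleviation", params)
        g = q.GENOTYPES["bravo"]
        for state in ([0.7, 2.0], [5.0, 0.1]):
            dB, dW = m.rhs(state, g)
            assert dB == 0.0
            # W dynamics must be evaluated at B = 0 regardless of the state's B
            _, dW_at_zero = m.rhs([0.0, state[1]], q.GENOTYPES["WT"])
            assert dW == pytest.approx(dW_at_zero)

    def test_double_mutant_promoters_report_basal(self, params):
        m = q.get_model("activation", params)
        g = q.GENOTYPES["bravo_wox5"]
        assert np.all(m.rhs([3.0, 4.0], g) == 0.0)
        pB, pW = m.promoter_activities([3.0, 4.0], g)
        assert pB == pytest.approx(params.alpha)
        assert pW == pytest.approx(params.gamma)

    def test_clamping_idempotent_and_order_independent(self, params):
        m = q.get_model("alleviation", params)
        g = q.GENOTYPES["bravo"]
        s = np.array([2.0, 3.0])
        once = m.apply_clamps(s, g)
        twice = m.apply_clamps(once, g)
        np.testing.assert_array_equal(once, twice)
        # overexpression of the other gene composes with the clamp
        g_mixed = q.GenotypeSpec("bravo_Woe", clamp_B=True, G0=10.0)
        dB, dW = m.rhs(s, g_mixed)
        assert dB == 0.0
        assert dW == pytest.approx(
            params.gamma * 10.0 + m._pw(0.0, 3.0) - params.d_W * 3.0
        )

    def test_unknown_variant_rejected(self, params):
        with pytest.raises(ValidationError):
            q.get_model("suppression", params)


class TestComplexRhs:
    def test_stationary_heterodimer_balance(self, complex_params):
        # Setting the C_BW equation to zero gives C_BW = lam*B*W/(mu+d)
        m = q.get_model("complex", complex_params)
        ss = q.solve_stationary(m, q.GENOTYPES["WT"], q.SolverOptions(multistart=0))
        B, W, S, C_BW, C_BS, C_WS = ss.state
        p = complex_params
        assert C_BW == pytest.approx(
            p.lambda_BW * B * W / (p.mu_BW + p.d_BW), rel=1e-8
        )
        assert C_BS == pytest.approx(p.lambda_BS * B * S / (p.mu_BS + p.d_BS), rel=1e-8)
        assert C_WS == pytest.approx(p.lambda_WS * W * S / (p.mu_WS + p.d_WS), rel=1e-8)

    def test_no_binding_reduces_to_two_variable_system(self):
        # beta = 0 and all binding off: B, W follow the two-variable dynamics
        # with pure WOX5 self-repression (vanishing-B1 limit)
        cp = q.ComplexParameterSet(beta=0.0, lambda_BW=0, lambda_BS=0, lambda_WS=0)
        m6 = q.get_model("complex", cp)
        ss6 = q.solve_stationary(m6, q.GENOTYPES["WT"], q.SolverOptions(multistart=0))
        p2 = q.ParameterSet(
            **{
                n: getattr(cp, n)
                for n in q.ParameterSet.field_names()
                if n not in ("B1",)
            },
            B1=1e-12,
        )
        m2 = q.get_model("alleviation", p2)
        ss2 = q.solve_stationary(m2, q.GENOTYPES["WT"], q.SolverOptions(multistart=0))
        np.testing.assert_allclose(ss6.state[:2], ss2.state, rtol=1e-7)
        assert np.all(ss6.state[2:] == 0.0)

    def test_knockout_clamps_protein_and_its_complexes(self, complex_params):
        m = q.get_model("complex", complex_params)
        g = q.GENOTYPES["bravo"]
        state = np.ones(6)
        clamped = m.apply_clamps(state, g)
        np.testing.assert_array_equal(clamped[[0, 3, 4]], 0.0)  # B, C_BW, C_BS
        assert np.all(clamped[[1, 2, 5]] == 1.0)  # W, S, C_WS evolve
        deriv = m.rhs(state, g)
        assert np.all(deriv[[0, 3, 4]] == 0.0)
        ss = q.solve_stationary(m, g, q.SolverOptions(multistart=0))
        assert np.all(ss.state[[0, 3, 4]] == 0.0)
        assert ss.state[1] > 0 and ss.state[5] > 0

    def test_flux_balance_species_by_species(self, complex_params):
        # production equals total consumption for every species at steady state
        m = q.get_model("complex", complex_params)
        for gid in ("WT", "bravo", "wox5"):
            ss = q.solve_stationary(
                m, q.GENOTYPES[gid], q.SolverOptions(multistart=0)
            )
            resid = m.rhs(ss.state, q.GENOTYPES[gid])
            assert np.max(np.abs(resid)) < 1e-8

    def test_free_levels_depend_only_on_net_consumption_factor(self, complex_params):
        # At stationarity C_XY = lam*X*Y/(mu+d), so each complex drains the
        # free proteins at net rate lam*d/(mu+d)*X*Y.  Reparametrizations
        # preserving lam*d_XY/(mu_XY+d_XY) leave free B and W unchanged
        # (the redundancy that justifies freezing mu and d in exploration).
        base = complex_params

        def matched(lam, mu, d, mu2, d2):
            # choose lam2 so lam2*d2/(mu2+d2) == lam*d/(mu+d)
            return lam * d / (mu + d) * (mu2 + d2) / d2

        shifted = base.replace(
            lambda_BW=matched(base.lambda_BW, base.mu_BW, base.d_BW, 0.7, 0.9),
            mu_BW=0.7,
            d_BW=0.9,
            lambda_BS=matched(base.lambda_BS, base.mu_BS, base.d_BS, 2.0, 0.5),
            mu_BS=2.0,
            d_BS=0.5,
            lambda_WS=matched(base.lambda_WS, base.mu_WS, base.d_WS, 0.3, 1.4),
            mu_WS=0.3,
            d_WS=1.4,
        )
        opts = q.SolverOptions(multistart=0)
        wt_a = q.solve_stationary(q.get_model("complex", base), q.GENOTYPES["WT"], opts)
        wt_b = q.solve_stationary(
            q.get_model("complex", shifted), q.GENOTYPES["WT"], opts
        )
        np.testing.assert_allclose(wt_a.state[:3], wt_b.state[:3], rtol=1e-7)

    def test_sequestration_monotone_in_competitor_production(self, complex_params):
        opts = q.SolverOptions(multistart=0)
        free_B, free_W = [], []
        for beta in (0.0, 5.0, 20.0, 80.0):
            cp = complex_params.replace(beta=beta)
            ss = q.solve_stationary(q.get_model("complex", cp), q.GENOTYPES["WT"], opts)
            free_B.append(ss.state[0])
            free_W.append(ss.state[1])
        assert all(x >= y - 1e-9 for x, y in zip(free_B, free_B[1:]))
        assert all(x >= y - 1e-9 for x, y in zip(free_W, free_W[1:]))

    def test_alleviation_like_behaviour_with_active_binding(self, complex_params):
        # with lambda_BW > 0 the bravo knockout must not raise pW above WT
        opts = q.SolverOptions(multistart=0)
        m = q.get_model("complex", complex_params)
        wt = q.solve_stationary(m, q.GENOTYPES["WT"], opts)
        br = q.solve_stationary(m, q.GENOTYPES["bravo"], opts)
        assert br.pW <= wt.pW + 1e-9


class TestFreeFractionReport:
    def test_no_binding_gives_unit_free_fractions(self):
        cp = q.ComplexParameterSet(beta=0.0, lambda_BW=0, lambda_BS=0, lambda_WS=0)
        m = q.get_model("complex", cp)
        ss = q.solve_stationary(m, q.GENOTYPES["WT"], q.SolverOptions(multistart=0))
        rep = free_fraction_report(ss)
        assert rep["free_fraction_B"] == pytest.approx(1.0)
        assert rep["free_fraction_W"] == pytest.approx(1.0)

    def test_totals_count_every_containing_complex(self, complex_params):
        m = q.get_model("complex", complex_params)
        ss = q.solve_stationary(m, q.GENOTYPES["WT"], q.SolverOptions(multistart=0))
        B, W, S, C_BW, C_BS, C_WS = ss.state
        rep = free_fraction_report(ss)
        assert rep["total_B"] == pytest.approx(B + C_BW + C_BS)
        assert rep["total_W"] == pytest.approx(W + C_BW + C_WS)

    def test_non_converged_input_rejected(self, complex_params):
        bogus = q.SteadyState(
            state=np.ones(6),
            pB=1.0,
            pW=1.0,
            residual_norm=10.0,
            stable=False,
            provenance="root_find",
            genotype="WT",
        )
        with pytest.raises(ValueError):
            free_fraction_report(bogus)

    def test_free_bravo_drops_in_wox5_mutant_with_competitor(self, complex_params):
        # the competitor sequesters BRAVO more once WOX5 no longer binds S
        opts = q.SolverOptions(multistart=0)
        m = q.get_model("complex", complex_params)
        wt = free_fraction_report(q.solve_stationary(m, q.GENOTYPES["WT"], opts))
        w5 = free_fraction_report(q.solve_stationary(m, q.GENOTYPES["wox5"], opts))
        assert w5["free_B"] < wt["free_B"]
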