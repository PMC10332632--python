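"""Clone expectations, PGF solution, and the two hazard solvers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

import fivehit as fh
from fivehit.hazard import (
    ModelParameters,
    detection_probability,
    expected_mutant_clones,
    expected_premalignant,
    hazard_approx,
    hazard_exact,
    solve_pgf,
)

AGES = np.arange(85.0)


def fig2_params(alpha_val, Tlag=0.0):
    """Solver-comparison settings: N=1e7, all mu 1e-5, lam = .1,.15,.2,.25."""
    lam = np.array([0.1 + i * 0.05 for i in range(4)])
    alpha = np.full(4, float(alpha_val))
    return ModelParameters(
        N=1e7, muN=1e-5, mu=(1e-5,) * 4,
        alpha=tuple(alpha), beta=tuple(alpha - lam), Tlag=Tlag,
    )


# ---------------------------------------------------------------------------
# expected clone sizes
# ---------------------------------------------------------------------------

class TestExpectedPremalignant:
    def test_zero_at_time_zero_and_without_influx(self):
        p = fig2_params(0.5)
        out = expected_premalignant(p, [0.0]).expected
        assert np.all(out == 0)
        p0 = ModelParameters(N=1e7, muN=0.0, mu=(0.0,) * 4,
                             alpha=p.alpha, beta=p.beta)
        assert np.all(expected_premalignant(p0, AGES).expected == 0)

    def test_single_stage_closed_form(self):
        p = ModelParameters(N=1.0, muN=0.1, mu=(0, 0, 0, 0),
                            alpha=(0.1, 0, 0, 0), beta=(0, 0, 0, 0))
        e1 = expected_premalignant(p, [10.0]).expected[0, 0]
        assert e1 == pytest.approx((0.1 / 0.1) * (np.exp(1.0) - 1.0), rel=1e-10)

    def test_matches_independent_ode_integrator(self):
        """Cross-check against scipy's adaptive integrator at tight tolerance."""
        p = fig2_params(0.5)

        def rhs(t, y):
            lam = np.array(p.lam)
            dy = lam * y
            dy[0] += p.v
            dy[1:] += np.array(p.mu[:3]) * y[:3]
            return dy

        sol = solve_ivp(rhs, (0, 84), np.zeros(4), t_eval=AGES[1:],
                        rtol=1e-11, atol=1e-30, method="LSODA")
        ours = expected_premalignant(p, AGES[1:]).expected
        assert np.allclose(ours, sol.y.T, rtol=1e-7)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            expected_premalignant(fig2_params(0.5), [-1.0, 2.0])


# ---------------------------------------------------------------------------
# approximate hazard
# ---------------------------------------------------------------------------

class TestHazardApprox:
    def test_zero_at_and_below_lag(self):
        p = fig2_params(0.5, Tlag=5.0)
        h = hazard_approx(p, AGES).hazard
        assert np.all(h[AGES <= 5.0] == 0)
        assert np.all(h[AGES > 5.0] > 0)

    def test_closed_form_equals_cascade_path(self):
        p = fig2_params(0.5)
        hc = hazard_approx(p, AGES, method="closed").hazard
        ho = hazard_approx(p, AGES, method="cascade").hazard
        pos = hc > 0
        assert np.max(np.abs(hc[pos] - ho[pos]) / ho[pos]) < 1e-6

    def test_confluent_lambdas_need_cascade_path(self, table1_params):
        # every printed pathway has repeated lambdas: closed form must refuse
        with pytest.raises(ValueError):
            hazard_approx(table1_params, AGES, method="closed")
        h = hazard_approx(table1_params, AGES).hazard  # auto falls back
        assert np.all(np.isfinite(h))
        assert h[-1] > 0

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            hazard_approx(fig2_params(0.5), AGES, method="magic")


# ---------------------------------------------------------------------------
# backward PGF solution
# ---------------------------------------------------------------------------

class TestSolvePGF:
    def test_stationary_when_nothing_happens(self):
        p = ModelParameters(N=1.0, muN=0.0, mu=(0,) * 4,
                            alpha=(1.0,) * 4, beta=(1.0,) * 4)
        st_ = solve_pgf(p, 5.0)
        assert np.allclose(st_.phi, 1.0)

    def test_single_stage_exponential_decay(self):
        m = 5e-3
        p = ModelParameters(N=1.0, muN=0.0, mu=(0, 0, 0, m),
                            alpha=(0,) * 4, beta=(0,) * 4)
        st_ = solve_pgf(p, 10.0)
        assert np.allclose(st_.phi[:, 3], np.exp(-m * st_.t), atol=1e-12)

    def test_rk4_step_halving_converged(self):
        p = fig2_params(0.5)
        a = solve_pgf(p, 50.0, step=1e-2).phi1[-1]
        b = solve_pgf(p, 50.0, step=5e-3).phi1[-1]
        assert abs(a - b) < 1e-8

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        alpha=st.floats(0.0, 2.0),
        lam=st.floats(0.0, 0.3),
        mu=st.floats(0.0, 9e-3),
        v=st.floats(0.0, 10.0),
    )
    def test_pgf_bounds_and_monotonicity(self, alpha, lam, mu, v):
        alpha = max(alpha, lam)  # death rate must stay non-negative
        p = ModelParameters(N=1e3, muN=v / 1e3, mu=(mu,) * 4,
                            alpha=(alpha,) * 4, beta=(alpha - lam,) * 4)
        st_ = solve_pgf(p, 30.0, step=1e-2)
        assert st_.phi.min() >= 0.0 and st_.phi.max() <= 1.0
        assert np.all(np.diff(st_.phi, axis=0) <= 1e-12)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            solve_pgf(fig2_params(0.5), -1.0)
        with pytest.raises(ValueError):
            solve_pgf(fig2_params(0.5), 10.0, step=0.0)


# ---------------------------------------------------------------------------
# exact hazard and survival identities
# ---------------------------------------------------------------------------

class TestHazardExact:
    def test_zero_at_and_below_lag(self):
        p = fig2_params(0.5, Tlag=5.0)
        h = hazard_exact(p, AGES).hazard
        assert np.all(h[AGES <= 5.0] == 0)

    def test_discrepancy_grows_with_division_rate(self):
        """Approximate-vs-exact gap at age 80 rises monotonically in alpha."""
        gaps = []
        for a in (0.5, 1.0, 10.0, 50.0):
            p = fig2_params(a)
            ha = hazard_approx(p, [80.0]).hazard[0]
            he = hazard_exact(p, [80.0]).hazard[0]
            gaps.append(abs(ha - he) / he)
        assert all(g2 > g1 for g1, g2 in zip(gaps, gaps[1:]))

    def test_approx_overestimates_at_high_division_rate(self):
        p = fig2_params(50.0)
        ha = hazard_approx(p, [80.0]).hazard[0]
        he = hazard_exact(p, [80.0]).hazard[0]
        assert ha > he

    def test_survival_equals_integrated_hazard(self):
        p = fig2_params(0.5)
        grid = np.linspace(0.0, 60.0, 1201)
        h = hazard_exact(p, grid).hazard
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (h[1:] + h[:-1]) * np.diff(grid))])
        st_ = solve_pgf(p, 60.0)
        S = st_.survival(grid)
        assert np.allclose(np.exp(-cum), S, atol=1e-8)


class TestDetectionProbability:
    def test_zero_before_lag_and_without_transformation(self):
        p = fig2_params(0.5, Tlag=5.0)
        assert detection_probability(p, 4.0) == 0.0
        p0 = ModelParameters(N=p.N, muN=p.muN, mu=(1e-5, 1e-5, 1e-5, 0.0),
                             alpha=p.alpha, beta=p.beta)
        assert detection_probability(p0, 60.0, method="approx") == 0.0

    def test_approx_branch_equals_integrated_approx_hazard(self):
        p = fig2_params(0.5)
        t = 60.0
        grid = np.linspace(0.0, t, 2001)
        h = hazard_approx(p, grid).hazard
        expected = 1.0 - np.exp(-np.trapezoid(h, grid))
        got = detection_probability(p, t, method="approx")
        assert got == pytest.approx(expected, rel=1e-4)


# ---------------------------------------------------------------------------
# labelled clone classes
# ---------------------------------------------------------------------------

class TestExpectedMutantClones:
    def test_kras_first_double_mutant_overtakes_single(self, table1_seq, table1_params):
        ce = expected_mutant_clones(table1_seq, table1_params, AGES)
        single = ce.classes["KRAS+"]
        double = ce.classes["KRAS+ & APC-/-"]
        assert single[10] > double[10]
        assert np.any(double > single)  # crossing before age 84

    def test_apc_first_single_mutant_dominates_for_life(self):
        seq = fh.MutationSequence.from_id("A1,A2,T1,T2,K")
        truth = fh.fitted_for("A1,A2,T1,T2,K")
        p = fh.build_model_parameters(seq, truth.theta, N=1e8, Tlag=5.0)
        ce = expected_mutant_clones(seq, p, AGES)
        single = ce.classes["APC-/-"]
        double = ce.classes["APC-/- & TP53-/-"]
        assert np.all(single[1:] > double[1:])

    def test_no_mutation_no_clones(self, table1_seq):
        p = ModelParameters(N=1e8, muN=0.0, mu=(0,) * 4,
                            alpha=(73.0,) * 4, beta=(73.0,) * 4)
        ce = expected_mutant_clones(table1_seq, p, AGES)
        for vals in ce.classes.values():
            assert np.all(vals == 0)

    def test_unclassifiable_stage_raises(self, table1_params):
        # TP53 completed first: its premalignant stages have no plotted class
        seq = fh.MutationSequence.from_id("T1,T2,K,A1,A2")
        with pytest.raises(ValueError):
            expected_mutant_clones(seq, table1_params, AGES)
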